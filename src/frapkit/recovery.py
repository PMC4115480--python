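"""Per-cell FRAP quantification.

The chain implemented here turns one raw trace into a half-recovery
time with quality-control diagnostics:

1. **Normalization** with correction for photobleaching during image
   acquisition (double normalization in the style of Phair): the
   background-subtracted ROI signal is ratioed to the
   background-subtracted whole-nucleus signal, then rescaled by the
   inverse prebleach ratio so that the prebleach level is 1. Any
   per-frame intensity loss common to ROI and nucleus — the imaging
   laser bleaching the whole field — cancels in the ratio.

2. **Double-exponential association fit** of the post-bleach curve,

       y(x) = y0 + A1 (1 - exp(-x / t1)) + A2 (1 - exp(-x / t2)),

   with amplitudes constrained non-negative and time constants
   positive, so the fitted model is non-decreasing and the
   half-recovery point is unique.

3. **Half-recovery time** ``t_half``: the time at which y reaches
   ``y0 + (A1 + A2) / 2``, found by bracketing bisection.

4. **QC filter**: cells whose fitted plateau exceeds 1.1 (focal drift)
   or whose adjusted R^2 falls below 0.95 (irregular recovery) are
   flagged as imaging artefacts, as are non-converged fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .trace import RawTrace

__all__ = [
    "NormalizedCurve",
    "FitResult",
    "QCThresholds",
    "QCVerdict",
    "CellResult",
    "NormalizationError",
    "FitDataError",
    "NoRecoveryError",
    "normalize_trace",
    "double_exponential",
    "fit_recovery",
    "compute_half_recovery",
    "qc_filter",
    "quantify_cell",
]


class NormalizationError(ValueError):
    """A frame's background-subtracted denominator is not positive."""

    def __init__(self, frame: int, message: str):
        self.frame = frame
        super().__init__(message)


class FitDataError(ValueError):
    """Too few or invalid post-bleach points to fit."""


class NoRecoveryError(ValueError):
    """Fitted amplitudes sum to zero: no recovery to halve."""


@dataclass(frozen=True)
class NormalizedCurve:
    """Relative fluorescence vs. time since the bleach event.

    ``time_post_s`` starts at 0 (first post-bleach frame);
    ``prebleach_norm`` keeps the normalized prebleach values as a
    diagnostic — their mean is exactly 1 by construction.
    """

    time_post_s: np.ndarray
    f_norm: np.ndarray
    prebleach_norm: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "time_post_s", np.asarray(self.time_post_s, float))
        object.__setattr__(self, "f_norm", np.asarray(self.f_norm, float))
        object.__setattr__(
            self, "prebleach_norm", np.asarray(self.prebleach_norm, float)
        )
        if self.time_post_s.size != self.f_norm.size:
            raise ValueError("time_post_s and f_norm lengths differ")
        if self.time_post_s.size and self.time_post_s[0] != 0.0:
            raise ValueError("time_post_s must start at 0")
        if np.any(np.diff(self.time_post_s) <= 0):
            raise ValueError("time_post_s must be strictly increasing")


@dataclass(frozen=True)
class FitResult:
    """Parameters of the double-exponential association fit.

    ``plateau`` is ``y0 + A1 + A2``; with canonical ordering
    ``t1 <= t2``. ``near_single_exponential`` flags fits where the two
    time constants are within 5% of each other and the split is
    therefore not identifiable (t_half is unaffected).
    """

    y0: float
    a1: float
    t1: float
    a2: float
    t2: float
    adj_r2: float
    converged: bool
    n_points: int
    rss: float = float("nan")
    message: str = ""
    near_single_exponential: bool = False

    @property
    def plateau(self) -> float:
        return self.y0 + self.a1 + self.a2


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion thresholds for fitted curves.

    Boundary values pass: a cell is removed only for plateau strictly
    above ``plateau_max`` or adjusted R^2 strictly below ``adj_r2_min``.
    """

    plateau_max: float = 1.1
    adj_r2_min: float = 0.95

    def __post_init__(self) -> None:
        if not self.plateau_max > 1:
            raise ValueError("plateau_max must exceed 1")
        if not 0 < self.adj_r2_min < 1:
            raise ValueError("adj_r2_min must be in (0, 1)")


@dataclass(frozen=True)
class QCVerdict:
    passed: bool
    reasons: tuple[str, ...] = ()


@dataclass(frozen=True)
class CellResult:
    """End-to-end quantification of one cell."""

    cell_id: str
    t_half_s: float | None
    fit: FitResult
    qc_pass: bool
    qc_reasons: tuple[str, ...]
    curve: NormalizedCurve | None = None


def normalize_trace(trace: RawTrace) -> NormalizedCurve:
    """Normalize a raw trace with acquisition-photobleach correction.

    For each frame t,

        f_norm(t) = (F_ROI(t) - F_BG(t)) / (F_total(t) - F_BG(t))
                    x (Fi_total - Fi_BG) / (Fi_ROI - Fi_BG)

    where Fi denotes the mean of a channel over the prebleach frames.
    Post-bleach frames are re-zeroed in time at the first post-bleach
    frame.

    Raises
    ------
    NormalizationError
        If any frame's ``F_total - F_BG`` is not positive, or the
        prebleach mean ROI signal is not positive; the error names the
        offending frame.
    """
    trace.check_prebleach_signal()
    pre = slice(0, trace.n_prebleach)
    fi_roi = float(np.mean(trace.f_roi[pre] - trace.f_bg[pre]))
    fi_total = float(np.mean(trace.f_total[pre] - trace.f_bg[pre]))
    if fi_roi <= 0:
        raise NormalizationError(
            0, f"{trace.cell_id}: prebleach mean ROI signal <= background"
        )
    denom = trace.f_total - trace.f_bg
    bad = np.flatnonzero(denom <= 0)
    if bad.size:
        raise NormalizationError(
            int(bad[0]),
            f"{trace.cell_id}: non-positive background-subtracted total "
            f"signal at frame {int(bad[0])}",
        )
    f_norm_all = (trace.f_roi - trace.f_bg) / denom * (fi_total / fi_roi)
    post = slice(trace.n_prebleach, None)
    t_post = trace.time_s[post] - trace.time_s[trace.n_prebleach]
    return NormalizedCurve(
        time_post_s=t_post,
        f_norm=f_norm_all[post],
        prebleach_norm=f_norm_all[pre],
    )


def double_exponential(
    x: np.ndarray, y0: float, a1: float, t1: float, a2: float, t2: float
) -> np.ndarray:
    """Double-exponential association model of fluorescence recovery."""
    x = np.asarray(x, float)
    return y0 + a1 * (1.0 - np.exp(-x / t1)) + a2 * (1.0 - np.exp(-x / t2))


def _adjusted_r2(y: np.ndarray, resid: np.ndarray, n_params: int) -> float:
    n = y.size
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        # flat data: define R^2 = 1 for a perfect fit, else 0
        r2 = 1.0 if ss_res == 0.0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    dof = n - n_params - 1
    if dof <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / dof


_MIN_POINTS = 12  # below this a 5-parameter fit is not identifiable


def fit_recovery(
    curve: NormalizedCurve,
    constrained: bool = True,
    max_restarts: int = 5,
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Fit the double-exponential association model to a recovery curve.

    Least squares over (y0, A1, t1, A2, t2) with A1, A2 >= 0 and
    t1, t2 > 0 (set ``constrained=False`` for an unconstrained
    sensitivity fit). Parameters are returned with t1 <= t2. Adjusted
    R^2 uses p = 5 free parameters. A failed fit is reported with
    ``converged=False``, never silently replaced.

    Initialization: y0 from the first post-bleach value, plateau from
    the mean of the final 10% of frames, time constants at one tenth
    and one half of the observed span, with up to ``max_restarts``
    jittered restarts on failure.
    """
    x = curve.time_post_s
    y = curve.f_norm
    if x.size < _MIN_POINTS:
        raise FitDataError(
            f"need >= {_MIN_POINTS} post-bleach points, got {x.size}"
        )
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise FitDataError("non-finite values in recovery curve")

    if rng is None:
        rng = np.random.default_rng(0)

    t_span = float(x[-1])
    y0_init = float(y[0])
    n_tail = max(1, x.size // 10)
    plateau_init = float(np.mean(y[-n_tail:]))
    amp = max(plateau_init - y0_init, 1e-3)

    def residuals(p: np.ndarray) -> np.ndarray:
        return double_exponential(x, *p) - y

    t_floor = 1e-6
    if constrained:
        # finite caps keep normalized-data fits physically meaningful:
        # amplitudes of order 1, time constants within identifiable range
        lower = np.array([-1.0, 0.0, t_floor, 0.0, t_floor])
        upper = np.array([2.0, 3.0, 1e5, 3.0, 1e5])
    else:
        lower = np.array([-np.inf, -np.inf, t_floor, -np.inf, t_floor])
        upper = np.array([np.inf, np.inf, np.inf, np.inf, np.inf])

    p0_base = np.array([y0_init, 0.5 * amp, t_span / 10, 0.5 * amp, t_span / 2])
    best = None
    for attempt in range(max_restarts + 1):
        p0 = p0_base.copy()
        if attempt > 0:
            jitter = rng.uniform(0.5, 2.0, size=5)
            p0 = p0 * jitter
            p0[0] = y0_init + rng.normal(scale=0.05)
        p0 = np.clip(p0, lower + 1e-12, None)
        try:
            sol = least_squares(
                residuals, p0, bounds=(lower, upper),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:  # numerical failure on this start
            continue
        if not sol.success:
            continue
        rss = float(sol.fun @ sol.fun)
        if best is None or rss < best[1]:
            best = (sol, rss)
        if best is not None and attempt == 0:
            break  # first start converged; no need to restart

    if best is None:
        return FitResult(
            y0=float("nan"), a1=float("nan"), t1=float("nan"),
            a2=float("nan"), t2=float("nan"), adj_r2=float("nan"),
            converged=False, n_points=int(x.size),
            message=f"no convergence after {max_restarts + 1} starts",
        )

    sol, rss = best
    y0_f, a1_f, t1_f, a2_f, t2_f = (float(v) for v in sol.x)
    if t1_f > t2_f:
        a1_f, a2_f, t1_f, t2_f = a2_f, a1_f, t2_f, t1_f
    amp_total = a1_f + a2_f
    near_single = t2_f / t1_f < 1.05 or (
        amp_total > 0 and min(a1_f, a2_f) < 1e-3 * amp_total
    )
    adj_r2 = _adjusted_r2(y, sol.fun, n_params=5)
    return FitResult(
        y0=y0_f, a1=a1_f, t1=t1_f, a2=a2_f, t2=t2_f,
        adj_r2=adj_r2, converged=True, n_points=int(x.size),
        rss=rss, message=sol.message, near_single_exponential=near_single,
    )


def compute_half_recovery(
    fit: FitResult, t_upper_hint: float = 8.0, tol_s: float = 1e-6
) -> float:
    """Half-recovery time of a fitted curve, by bracketing bisection.

    The target level is ``y_half = y0 + (A1 + A2) / 2``. The bracket
    starts at ``[0, t_upper_hint]`` and doubles its upper end until the
    model exceeds ``y_half``; bisection then converges to absolute time
    tolerance ``tol_s``. With non-negative amplitudes the model is
    strictly increasing, so the solution is unique.

    Raises
    ------
    NoRecoveryError
        If ``A1 + A2 <= 0``.
    ValueError
        If the fit did not converge.
    """
    if not fit.converged:
        raise ValueError("cannot compute half recovery of a non-converged fit")
    amp = fit.a1 + fit.a2
    if amp <= 0:
        raise NoRecoveryError("A1 + A2 = 0: no recovery to halve")
    y_half = fit.y0 + amp / 2.0

    def y(t: float) -> float:
        return float(
            double_exponential(np.array([t]), fit.y0, fit.a1, fit.t1, fit.a2, fit.t2)[0]
        )

    lo, hi = 0.0, float(t_upper_hint)
    if hi <= 0:
        hi = 1.0
    # the model plateaus strictly above y_half, so doubling terminates
    while y(hi) < y_half:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - unreachable for amp > 0
            raise RuntimeError("bracket expansion failed")
    while hi - lo > tol_s:
        mid = 0.5 * (lo + hi)
        if y(mid) < y_half:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def qc_filter(fit: FitResult, thresholds: QCThresholds | None = None) -> QCVerdict:
    """Apply plateau and adjusted-R^2 exclusion rules to a fit.

    Fails iff the fit did not converge, the plateau strictly exceeds
    ``plateau_max``, or the adjusted R^2 is strictly below
    ``adj_r2_min``. Total over valid inputs; reasons are enumerated.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    reasons: list[str] = []
    if not fit.converged:
        reasons.append("no_fit")
    else:
        if fit.plateau > thresholds.plateau_max:
            reasons.append("plateau")
        if fit.adj_r2 < thresholds.adj_r2_min:
            reasons.append("adj_r2")
    return QCVerdict(passed=not reasons, reasons=tuple(reasons))


def quantify_cell(
    trace: RawTrace,
    thresholds: QCThresholds | None = None,
    constrained: bool = True,
    keep_curve: bool = True,
) -> CellResult:
    """Normalize, fit, compute t_half and QC-filter one cell's trace.

    Stage errors are re-raised tagged with the cell id. A QC failure is
    not an error: the result records the verdict and its reasons.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    curve = normalize_trace(trace)  # error messages already carry cell_id
    try:
        fit = fit_recovery(curve, constrained=constrained)
    except FitDataError as exc:
        raise FitDataError(f"{trace.cell_id}: {exc}") from exc
    verdict = qc_filter(fit, thresholds)
    t_half: float | None = None
    if fit.converged and fit.a1 + fit.a2 > 0:
        t_half = compute_half_recovery(fit, t_upper_hint=max(curve.time_post_s[-1], 1.0))
    return CellResult(
        cell_id=trace.cell_id,
        t_half_s=t_half,
        fit=fit,
        qc_pass=verdict.passed,
        qc_reasons=verdict.reasons,
        curve=curve if keep_curve else None,
    )
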