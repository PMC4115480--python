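"""Synthetic FRAP trace generation with ground-truth kinetics.

The generator emulates the structure of confocal FRAP exports: five
prescans at the unbleached level, an instantaneous bleach event, and a
post-bleach recovery following a double-exponential association curve,
corrupted by per-frame acquisition photobleaching (a geometric
multiplicative loss applied to the fluorophore signal in both the ROI
and the whole-nucleus channels, but not to the non-fluorophore
background), an additive background level, and additive Gaussian
per-frame noise on each channel.

The ideal (noise-free) trace is constructed so that the
acquisition-photobleach-corrected normalization reproduces the truth
curve exactly: the recovery truth is defined in the double-normalized
space, where a recovery to 1 means full equilibration with the
fluorophore pool remaining after the bleach event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .recovery import compute_half_recovery, double_exponential, FitResult
from .trace import RawTrace

__all__ = [
    "KineticsTruth",
    "SimulationSpec",
    "simulate_recovery_trace",
    "simulate_group",
    "calibrate_kinetics_for_thalf",
    "truth_half_recovery",
    "cell_rng",
]


@dataclass(frozen=True)
class KineticsTruth:
    """Ground-truth double-exponential recovery parameters.

    ``y0`` is the relative fluorescence immediately after the bleach;
    ``a1, a2`` the association amplitudes and ``t1 <= t2`` the time
    constants (seconds). The plateau ``y0 + a1 + a2`` cannot exceed 1;
    the deficit is the immobile fraction.
    """

    y0: float
    a1: float
    t1: float
    a2: float
    t2: float

    def __post_init__(self) -> None:
        if not (0 <= self.y0 < 1):
            raise ValueError("y0 must be in [0, 1)")
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("time constants must be positive")
        if self.y0 + self.a1 + self.a2 > 1 + 1e-12:
            raise ValueError("y0 + A1 + A2 must not exceed 1")
        if self.t1 > self.t2:  # canonical ordering
            t1, t2, a1, a2 = self.t2, self.t1, self.a2, self.a1
            object.__setattr__(self, "t1", t1)
            object.__setattr__(self, "t2", t2)
            object.__setattr__(self, "a1", a1)
            object.__setattr__(self, "a2", a2)

    @property
    def plateau(self) -> float:
        return self.y0 + self.a1 + self.a2

    @property
    def immobile_fraction(self) -> float:
        return 1.0 - self.plateau

    def curve(self, x: np.ndarray) -> np.ndarray:
        return double_exponential(x, self.y0, self.a1, self.t1, self.a2, self.t2)


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions for a simulated treatment group of FRAP traces.

    Defaults follow the acquisition protocol the generator emulates:
    five prescans, roughly 0.25 s frame interval, recovery half-times
    kept in a 1-30 s practical range by the kinetics, and mostly-mobile
    pools (plateau near 0.9). Noise and cell-to-cell variability have
    no measured reference and are set to plausible magnitudes: additive
    per-frame noise at 2% of the prebleach ROI signal, and a 20%
    lognormal coefficient of variation on each cell's time constants.
    """

    kinetics: KineticsTruth = field(
        default_factory=lambda: KineticsTruth(y0=0.1, a1=0.48, t1=2.0, a2=0.32, t2=12.0)
    )
    n_cells: int = 10
    n_prebleach: int = 5
    frame_interval_s: float = 0.25
    duration_s: float = 60.0
    cell_cv: float = 0.2
    noise_sd: float = 4.0  # 2% of the default prebleach ROI scale
    # region means of larger regions are less noisy: the nucleus and
    # background regions are ~an order of magnitude larger than the
    # bleach ROI, so their per-frame noise is scaled down
    total_noise_factor: float = 1.0 / 3.0
    bg_noise_factor: float = 1.0 / 3.0
    # with the imaging laser attenuated, acquisition bleaching is mild:
    # 5e-4/frame loses ~11% of signal over a 240-frame series
    acq_bleach_rate: float = 5e-4
    background_level: float = 20.0
    roi_intensity_scale: float = 200.0
    total_intensity_scale: float = 180.0
    bleach_fraction_of_total: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_prebleach < 1:
            raise ValueError("n_prebleach must be >= 1")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.roi_intensity_scale <= 0 or self.total_intensity_scale <= 0:
            raise ValueError("intensity scales must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0 <= self.acq_bleach_rate < 1:
            raise ValueError("acq_bleach_rate must be in [0, 1)")
        if not 0 <= self.bleach_fraction_of_total < 1:
            raise ValueError("bleach_fraction_of_total must be in [0, 1)")
        if self.noise_sd < 0 or self.cell_cv < 0 or self.background_level < 0:
            raise ValueError("noise_sd, cell_cv, background_level must be >= 0")
        if self.total_noise_factor < 0 or self.bg_noise_factor < 0:
            raise ValueError("noise factors must be >= 0")
        if self.duration_s < self.frame_interval_s:
            raise ValueError("duration_s shorter than one frame interval")

    @property
    def n_post(self) -> int:
        return int(math.floor(self.duration_s / self.frame_interval_s)) + 1


def cell_rng(seed: int, cell_index: int, stream: int = 0) -> np.random.Generator:
    """Independent, reproducible random stream for one simulated cell."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(stream, cell_index))
    )


def _cell_kinetics(spec: SimulationSpec, rng: np.random.Generator) -> KineticsTruth:
    """Draw one cell's kinetics: lognormal variability on t1 and t2 only.

    Amplitudes stay fixed across cells so the group's truth t_half
    distribution remains unimodal and calibratable.
    """
    k = spec.kinetics
    if spec.cell_cv > 0:
        sigma = math.sqrt(math.log(1.0 + spec.cell_cv**2))
        mu = -0.5 * sigma**2  # unit-mean lognormal
        f1, f2 = np.exp(rng.normal(mu, sigma, size=2))
    else:
        f1 = f2 = 1.0
    return KineticsTruth(y0=k.y0, a1=k.a1, t1=k.t1 * f1, a2=k.a2, t2=k.t2 * f2)


def simulate_recovery_trace(
    spec: SimulationSpec, cell_index: int = 0
) -> tuple[RawTrace, KineticsTruth]:
    """Simulate one cell's raw FRAP trace and return it with its truth.

    The bleach event is instantaneous between the last prescan and the
    first post-bleach frame; no mid-bleach frame is emitted. Both the
    ROI and total-nucleus fluorophore signals decay geometrically by
    ``(1 - acq_bleach_rate)`` per acquired frame; the background
    channel is constant plus noise. Noise-free, the
    acquisition-corrected normalization of the returned trace equals
    the cell's truth curve exactly.
    """
    rng = cell_rng(spec.seed, cell_index)
    truth = _cell_kinetics(spec, rng)

    n_pre = spec.n_prebleach
    n_post = spec.n_post
    n = n_pre + n_post
    time_s = np.arange(n) * spec.frame_interval_s
    g = (1.0 - spec.acq_bleach_rate) ** np.arange(n)  # acquisition decay

    x = time_s[n_pre:] - time_s[n_pre]  # time since bleach
    y = truth.curve(x)

    fluor_total = np.empty(n)
    fluor_roi = np.empty(n)
    fluor_total[:n_pre] = spec.total_intensity_scale
    fluor_roi[:n_pre] = spec.roi_intensity_scale
    post_total = spec.total_intensity_scale * (1.0 - spec.bleach_fraction_of_total)
    fluor_total[n_pre:] = post_total
    # ROI defined relative to the remaining pool, so normalization
    # recovers the truth curve exactly (the loss factor cancels)
    fluor_roi[n_pre:] = (
        y * (spec.roi_intensity_scale / spec.total_intensity_scale) * post_total
    )
    fluor_total *= g
    fluor_roi *= g

    f_bg = np.full(n, spec.background_level)
    f_roi = fluor_roi + spec.background_level
    f_total = fluor_total + spec.background_level
    if spec.noise_sd > 0:
        f_roi = f_roi + rng.normal(0.0, spec.noise_sd, size=n)
        if spec.total_noise_factor > 0:
            f_total = f_total + rng.normal(
                0.0, spec.noise_sd * spec.total_noise_factor, size=n
            )
        if spec.bg_noise_factor > 0:
            f_bg = f_bg + rng.normal(
                0.0, spec.noise_sd * spec.bg_noise_factor, size=n
            )

    trace = RawTrace(
        cell_id=f"cell{cell_index:03d}",
        time_s=time_s,
        f_roi=f_roi,
        f_total=f_total,
        f_bg=f_bg,
        n_prebleach=n_pre,
    )
    return trace, truth


def simulate_group(
    spec: SimulationSpec, label: str | None = None
) -> tuple[list[RawTrace], list[KineticsTruth]]:
    """Simulate a full treatment group of traces.

    Cell ids are prefixed with ``label`` when given, so traces from
    several groups can share one table.
    """
    traces, truths = [], []
    for i in range(spec.n_cells):
        tr, truth = simulate_recovery_trace(spec, cell_index=i)
        if label is not None:
            tr = RawTrace(
                cell_id=f"{label}.{tr.cell_id}",
                time_s=tr.time_s, f_roi=tr.f_roi, f_total=tr.f_total,
                f_bg=tr.f_bg, n_prebleach=tr.n_prebleach,
            )
        traces.append(tr)
        truths.append(truth)
    return traces, truths


def truth_half_recovery(truth: KineticsTruth) -> float:
    """Analytic half-recovery time of a ground-truth kinetics record."""
    fit = FitResult(
        y0=truth.y0, a1=truth.a1, t1=truth.t1, a2=truth.a2, t2=truth.t2,
        adj_r2=1.0, converged=True, n_points=0,
    )
    return compute_half_recovery(fit, t_upper_hint=4.0 * truth.t2)


def calibrate_kinetics_for_thalf(
    target_thalf_s: float,
    amplitude_split: float = 0.6,
    t2_over_t1: float = 5.0,
    plateau: float = 0.95,
    y0: float = 0.1,
) -> KineticsTruth:
    """Build kinetics whose half-recovery time equals a target.

    ``amplitude_split`` is A1 / (A1 + A2) and ``t2_over_t1`` the ratio
    of the slow to the fast time constant. The half-recovery time does
    not depend on ``y0`` or on the overall amplitude scale, and it
    scales linearly with time, so the time constants follow in closed
    form from the t_half of the unit-t1 shape. The result satisfies
    ``truth_half_recovery(kinetics) == target`` to within 1e-4 s.

    Raises
    ------
    ValueError
        For a non-positive target, an infeasible split/ratio/plateau
        combination, or a plateau outside (y0, 1].
    """
    if not target_thalf_s > 0:
        raise ValueError("target t_half must be positive")
    if not 0 <= amplitude_split <= 1:
        raise ValueError("amplitude_split must be in [0, 1]")
    if t2_over_t1 < 1:
        raise ValueError("t2_over_t1 must be >= 1")
    if not 0 <= y0 < 1:
        raise ValueError("y0 must be in [0, 1)")
    if not y0 < plateau <= 1:
        raise ValueError("plateau must be in (y0, 1]")

    amp = plateau - y0
    a1 = amplitude_split * amp
    a2 = (1.0 - amplitude_split) * amp
    if a1 + a2 <= 0:
        raise ValueError("zero total amplitude: nothing recovers")

    # t_half of the unit-t1 shape, then scale time linearly
    unit = KineticsTruth(y0=0.0, a1=amplitude_split, t1=1.0,
                         a2=1.0 - amplitude_split, t2=t2_over_t1)
    unit_thalf = truth_half_recovery(unit)
    t1 = target_thalf_s / unit_thalf
    result = KineticsTruth(y0=y0, a1=a1, t1=t1, a2=a2, t2=t1 * t2_over_t1)
    achieved = truth_half_recovery(result)
    if abs(achieved - target_thalf_s) > 1e-4:
        raise ValueError(
            f"calibration infeasible: achieved t_half {achieved:.6f} s "
            f"differs from target {target_thalf_s:.6f} s"
        )
    return result
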