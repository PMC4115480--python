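"""Per-cell quantification: normalization, fitting, bisection, QC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from frapkit import (
    FitResult,
    QCThresholds,
    compute_half_recovery,
    double_exponential,
    fit_recovery,
    normalize_trace,
    qc_filter,
    quantify_cell,
)
from frapkit.recovery import (
    FitDataError,
    NormalizedCurve,
    NormalizationError,
    NoRecoveryError,
)

from conftest import make_trace


def fit_from_params(y0, a1, t1, a2, t2):
    return FitResult(y0=y0, a1=a1, t1=t1, a2=a2, t2=t2,
                     adj_r2=1.0, converged=True, n_points=0)


class TestNormalize:
    def test_ratio_only_case(self):
        """Zero background, constant total: post value 50 on prebleach 100
        normalizes to 0.5."""
        tr = make_trace()
        curve = normalize_trace(tr)
        assert curve.f_norm == pytest.approx(0.5)
        assert curve.prebleach_norm == pytest.approx(1.0)

    def test_direct_substitution(self):
        """Worked example: frame (ROI 40, BG 10, total 90) with prebleach
        means (110, 10, 210) gives (30/80)*(200/100) = 0.75."""
        n_pre = 5
        f_roi = np.array([110.0] * n_pre + [40.0])
        f_total = np.array([210.0] * n_pre + [90.0])
        f_bg = np.array([10.0] * n_pre + [10.0])
        tr = make_trace(f_roi=f_roi, f_total=f_total, f_bg=f_bg,
                        n_prebleach=n_pre, n_frames=6)
        curve = normalize_trace(tr)
        assert curve.f_norm[0] == pytest.approx((30 / 80) * (200 / 100))

    def test_noiseless_prebleach_normalizes_to_one(self, clean_spec):
        from frapkit import simulate_recovery_trace

        tr, _ = simulate_recovery_trace(clean_spec, 0)
        curve = normalize_trace(tr)
        np.testing.assert_allclose(curve.prebleach_norm, 1.0, atol=1e-12)

    def test_time_rezeroed_at_first_post_frame(self):
        tr = make_trace(n_frames=30)
        curve = normalize_trace(tr)
        assert curve.time_post_s[0] == 0.0
        assert curve.time_post_s.size == 25

    def test_nonpositive_denominator_names_frame(self):
        f_total = np.full(20, 100.0)
        f_bg = np.zeros(20)
        f_bg[7] = 150.0  # background above total at frame 7
        tr = make_trace(f_total=f_total, f_bg=f_bg)
        with pytest.raises(NormalizationError, match="frame 7") as err:
            normalize_trace(tr)
        assert err.value.frame == 7

    @given(
        gain=st.floats(0.1, 50.0),
        offset=st.floats(-20.0, 200.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_gain_and_offset_invariance(self, gain, offset):
        """Scaling all three channels by c > 0 or shifting them by a
        common constant leaves the normalized curve unchanged."""
        rng = np.random.default_rng(42)
        n = 40
        f_roi = 100.0 + rng.uniform(-5, 5, n)
        f_roi[5:] *= 0.5
        f_total = 220.0 + rng.uniform(-5, 5, n)
        f_bg = 10.0 + rng.uniform(-1, 1, n)
        tr = make_trace(f_roi=f_roi, f_total=f_total, f_bg=f_bg, n_frames=n)
        base = normalize_trace(tr).f_norm
        tr2 = make_trace(
            f_roi=gain * f_roi + offset,
            f_total=gain * f_total + offset,
            f_bg=gain * f_bg + offset,
            n_frames=n,
        )
        np.testing.assert_allclose(normalize_trace(tr2).f_norm, base,
                                   rtol=1e-10, atol=1e-12)

    def test_acquisition_decay_cancels_at_zero_background(self):
        """With zero background, a common per-frame multiplicative decay
        on ROI and total channels cancels in the ratio."""
        n = 60
        rng = np.random.default_rng(3)
        f_roi = np.r_[np.full(5, 100.0), 40 + 50 * rng.random(n - 5)]
        f_total = np.full(n, 250.0)
        tr = make_trace(f_roi=f_roi, f_total=f_total,
                        f_bg=np.zeros(n), n_frames=n)
        base = normalize_trace(tr).f_norm
        decay = 0.99 ** np.arange(n)
        tr2 = make_trace(f_roi=f_roi * decay, f_total=f_total * decay,
                         f_bg=np.zeros(n), n_frames=n)
        np.testing.assert_allclose(normalize_trace(tr2).f_norm, base,
                                   rtol=1e-12)


class TestFit:
    def make_curve(self, params, n=120, dt=0.25, noise=0.0, seed=0):
        x = np.arange(n) * dt
        y = double_exponential(x, *params)
        if noise:
            y = y + np.random.default_rng(seed).normal(0, noise, n)
        return NormalizedCurve(time_post_s=x, f_norm=y,
                               prebleach_norm=np.ones(5))

    def test_exact_recovery_of_noiseless_parameters(self):
        truth = (0.2, 0.5, 2.0, 0.3, 15.0)
        fit = fit_recovery(self.make_curve(truth))
        assert fit.converged
        for got, want in zip((fit.y0, fit.a1, fit.t1, fit.a2, fit.t2), truth):
            assert got == pytest.approx(want, rel=1e-6)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.plateau == pytest.approx(1.0, rel=1e-6)

    def test_noisy_fit_within_reported_uncertainty(self):
        """With sigma = 0.02 noise the constrained fit agrees with an
        independent unconstrained least-squares fit on the same points."""
        from scipy.optimize import curve_fit

        truth = (0.2, 0.5, 2.0, 0.3, 15.0)
        curve = self.make_curve(truth, noise=0.02, seed=7)
        fit = fit_recovery(curve)
        popt, pcov = curve_fit(
            double_exponential, curve.time_post_s, curve.f_norm,
            p0=truth, maxfev=10000,
        )
        se = np.sqrt(np.diag(pcov))
        # oracle parameters ordered t1 <= t2 for comparison
        if popt[2] > popt[4]:
            popt = popt[[0, 3, 4, 1, 2]]
            se = se[[0, 3, 4, 1, 2]]
        got = np.array([fit.y0, fit.a1, fit.t1, fit.a2, fit.t2])
        assert np.all(np.abs(got - popt) <= 3 * se + 1e-8)

    def test_flat_curve_degenerate_fit_flagged(self):
        x = np.arange(60) * 0.25
        curve = NormalizedCurve(time_post_s=x, f_norm=np.ones(60),
                                prebleach_norm=np.ones(5))
        fit = fit_recovery(curve)
        assert fit.converged
        assert fit.a1 + fit.a2 == pytest.approx(0.0, abs=1e-4)
        # degenerate for QC purposes: no recovery to halve
        with pytest.raises(NoRecoveryError):
            compute_half_recovery(
                FitResult(y0=fit.y0, a1=0.0, t1=fit.t1, a2=0.0, t2=fit.t2,
                          adj_r2=fit.adj_r2, converged=True, n_points=60)
            )

    def test_too_few_points_is_an_error(self):
        with pytest.raises(FitDataError):
            fit_recovery(self.make_curve((0.1, 0.5, 2, 0.3, 10), n=8))

    def test_canonical_time_constant_ordering(self):
        fit = fit_recovery(self.make_curve((0.1, 0.3, 12.0, 0.5, 1.5)))
        assert fit.t1 <= fit.t2
        assert fit.a1 == pytest.approx(0.5, rel=1e-4)

    def test_near_single_exponential_diagnostic(self):
        fit = fit_recovery(self.make_curve((0.0, 0.45, 5.0, 0.45, 5.0)))
        assert fit.near_single_exponential


class TestHalfRecovery:
    def test_single_exponential_closed_form(self):
        fit = fit_from_params(0.0, 1.0, 4.0, 0.0, 9.0)
        assert compute_half_recovery(fit) == pytest.approx(4 * math.log(2),
                                                           abs=1e-6)

    def test_equal_time_constants_reduce_to_single_exponential(self):
        tau = 3.7
        fit = fit_from_params(0.2, 0.3, tau, 0.4, tau)
        assert compute_half_recovery(fit) == pytest.approx(tau * math.log(2),
                                                           abs=1e-6)

    def test_against_dense_grid_oracle_fixture(self):
        """y0=0, A1=0.6, t1=2, A2=0.4, t2=10: grid search at 1e-4 s
        resolution places t_half near 2.36 s."""
        fit = fit_from_params(0.0, 0.6, 2.0, 0.4, 10.0)
        grid = np.arange(0.0, 10.0, 1e-4)
        y = double_exponential(grid, 0.0, 0.6, 2.0, 0.4, 10.0)
        oracle = grid[np.searchsorted(y, 0.5)]
        t = compute_half_recovery(fit)
        assert t == pytest.approx(oracle, abs=1e-4)
        assert t == pytest.approx(2.36, abs=0.005)

    def test_y0_and_amplitude_scale_invariance(self):
        """t_half ignores y0 and a common scaling of (A1, A2)."""
        base = compute_half_recovery(fit_from_params(0.0, 0.6, 2.0, 0.4, 10.0))
        shifted = compute_half_recovery(fit_from_params(0.3, 0.3, 2.0, 0.2, 10.0))
        assert shifted == pytest.approx(base, abs=1e-5)

    @given(
        t1=st.floats(0.2, 20.0),
        ratio=st.floats(1.0, 10.0),
        split=st.floats(0.05, 0.95),
        bump=st.floats(1.01, 2.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_time_constants(self, t1, ratio, split, bump):
        t2 = t1 * ratio
        a1, a2 = 0.9 * split, 0.9 * (1 - split)
        base = compute_half_recovery(fit_from_params(0.05, a1, t1, a2, t2))
        slower1 = compute_half_recovery(
            fit_from_params(0.05, a1, t1 * bump, a2, max(t2, t1 * bump)))
        slower2 = compute_half_recovery(
            fit_from_params(0.05, a1, t1, a2, t2 * bump))
        assert slower1 >= base - 1e-5
        assert slower2 >= base - 1e-5

    def test_zero_amplitude_is_an_error(self):
        with pytest.raises(NoRecoveryError):
            compute_half_recovery(fit_from_params(0.5, 0.0, 1.0, 0.0, 2.0))

    def test_nonconverged_fit_is_an_error(self):
        bad = FitResult(y0=0, a1=1, t1=1, a2=0, t2=2, adj_r2=0,
                        converged=False, n_points=0)
        with pytest.raises(ValueError):
            compute_half_recovery(bad)


class TestQC:
    def test_high_plateau_excluded(self):
        fit = fit_from_params(0.2, 0.6, 2.0, 0.35, 10.0)  # plateau 1.15
        verdict = qc_filter(fit, QCThresholds())
        assert not verdict.passed
        assert verdict.reasons == ("plateau",)

    def test_low_adjusted_r2_excluded(self):
        fit = FitResult(y0=0.1, a1=0.5, t1=2, a2=0.45, t2=10, adj_r2=0.93,
                        converged=True, n_points=100)  # plateau 1.05
        verdict = qc_filter(fit, QCThresholds())
        assert not verdict.passed
        assert verdict.reasons == ("adj_r2",)

    def test_boundary_values_pass(self):
        """Exclusion is strict: plateau exactly 1.1 and adjusted R^2
        exactly 0.95 both survive."""
        fit = FitResult(y0=0.1, a1=0.5, t1=2, a2=0.5, t2=10, adj_r2=0.95,
                        converged=True, n_points=100)  # plateau 1.1
        assert qc_filter(fit, QCThresholds()).passed

    def test_nonconverged_fails_with_no_fit_reason(self):
        bad = FitResult(y0=float("nan"), a1=float("nan"), t1=float("nan"),
                        a2=float("nan"), t2=float("nan"), adj_r2=float("nan"),
                        converged=False, n_points=0)
        verdict = qc_filter(bad)
        assert verdict.reasons == ("no_fit",)


class TestQuantifyCell:
    def test_noiseless_round_trip_recovers_truth_thalf(self, clean_spec):
        from frapkit import simulate_recovery_trace, truth_half_recovery

        tr, truth = simulate_recovery_trace(clean_spec, 0)
        res = quantify_cell(tr)
        assert res.qc_pass
        assert res.t_half_s == pytest.approx(truth_half_recovery(truth),
                                             abs=1e-4)

    def test_total_channel_corruption_fails_qc(self, clean_spec):
        """Shrinking the total channel post-bleach inflates the apparent
        plateau above 1.1 (focal-drift artefact) and the cell is removed."""
        from frapkit import simulate_recovery_trace
        from frapkit.trace import RawTrace

        tr, _ = simulate_recovery_trace(clean_spec, 0)
        f_total = tr.f_total.copy()
        f_total[tr.n_prebleach:] *= 0.75
        bad = RawTrace(cell_id=tr.cell_id, time_s=tr.time_s, f_roi=tr.f_roi,
                       f_total=f_total, f_bg=tr.f_bg,
                       n_prebleach=tr.n_prebleach)
        res = quantify_cell(bad)
        assert not res.qc_pass
        assert "plateau" in res.qc_reasons

    def test_bad_frame_error_carries_cell_id(self):
        f_total = np.full(20, 100.0)
        f_total[9] = -5.0
        tr = make_trace(cell_id="cellX", f_total=f_total)
        with pytest.raises(NormalizationError, match="cellX"):
            quantify_cell(tr)
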