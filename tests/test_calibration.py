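import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from srmpk import (
    CalibrationLevel,
    CalibrationModel,
    assess_heteroscedasticity,
    determine_lod_lloq,
    fit_weighted_linear,
    rsd,
    simulate_calibration_series,
)


def level(conc, areas, snr=None):
    return CalibrationLevel(nominal_conc=conc, replicate_areas=list(areas), mean_snr=snr)


class TestRsd:
    def test_identical_values_zero(self):
        assert rsd([5.0, 5.0, 5.0]) == 0.0

    def test_hand_computed_recovery_triplet(self):
        # sample sd 3.4486, mean 88.4667 -> 3.90%
        assert rsd([85.4, 87.8, 92.2]) == pytest.approx(3.90, abs=0.005)

    def test_two_point_closed_form(self):
        # sd = sqrt(2), mean = 2 -> 70.71%
        assert rsd([1.0, 3.0]) == pytest.approx(100 * math.sqrt(2) / 2, abs=0.01)

    def test_requires_two_values_and_nonzero_mean(self):
        with pytest.raises(ValueError):
            rsd([1.0])
        with pytest.raises(ValueError):
            rsd([-1.0, 1.0])


class TestWeightedFit:
    def test_noiseless_line_exact_under_any_weighting(self):
        levels = [level(c, [100.0 * c + 5.0] * 3) for c in (1.0, 10.0, 100.0)]
        for weighting in ("none", "1/x", "1/x2"):
            res = fit_weighted_linear(levels, weighting=weighting)
            assert res.slope == pytest.approx(100.0, rel=1e-9)
            assert res.intercept == pytest.approx(5.0, rel=1e-7)
            assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_three_point_case_matches_normal_equations_oracle(self):
        # independent closed-form weighted normal equations
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 4.2, 5.9])
        w = 1.0 / x
        Sw, Swx, Swy = w.sum(), (w * x).sum(), (w * y).sum()
        Swxx, Swxy = (w * x * x).sum(), (w * x * y).sum()
        slope_oracle = (Sw * Swxy - Swx * Swy) / (Sw * Swxx - Swx**2)
        intercept_oracle = (Swy - slope_oracle * Swx) / Sw

        levels = [level(xi, [yi]) for xi, yi in zip(x, y)]
        res = fit_weighted_linear(levels, weighting="1/x")
        assert res.slope == pytest.approx(slope_oracle, rel=1e-12)
        assert res.intercept == pytest.approx(intercept_oracle, rel=1e-12)

    def test_seven_level_simulation_recovers_slope_and_r2(self, noiseless_config):
        from dataclasses import replace

        cfg = replace(noiseless_config, baseline_rms=1.0, seed=21)
        series = simulate_calibration_series(
            cfg, replicates=10, noise_cv=0.02
        )
        from srmpk.peaks import NoiseEstimate, detect_peak

        noise = NoiseEstimate(rms=1.0, baseline_level=0.0, region=(11.0, 11.2))
        per_level: dict[float, list[float]] = {}
        for inj in series:
            peak = detect_peak(inj.traces[0], (11.3, 11.9), noise)
            per_level.setdefault(inj.level, []).append(peak.area if peak else 0.0)
        levels = [level(c, areas) for c, areas in sorted(per_level.items())]
        res = fit_weighted_linear(levels, weighting="1/x")
        # quantifier response slope = response_slope * quantifier fraction
        assert res.slope == pytest.approx(100.0 * 0.5, rel=0.02)
        assert res.r_squared > 0.999

    def test_levels_failing_acceptance_are_excluded_and_recorded(self):
        levels = [
            level(0.1, [8.0, 12.0, 10.0], snr=5.0),  # fails SNR
            level(1.0, [100.0, 160.0, 130.0], snr=50.0),  # RSD ~23% fails
            level(10.0, [1000.0, 1010.0, 990.0], snr=200.0),
            level(100.0, [10000.0, 10100.0, 9900.0], snr=500.0),
            level(1000.0, [100000.0, 101000.0, 99000.0], snr=900.0),
        ]
        res = fit_weighted_linear(levels)
        assert len(res.accepted_levels) == 3
        assert len(res.excluded_levels) == 2
        # bookkeeping: accepted + excluded = input
        assert len(res.accepted_levels) + len(res.excluded_levels) == len(levels)
        reasons = " ".join(r for _, r in res.excluded_levels)
        assert "SNR" in reasons and "RSD" in reasons

    def test_fewer_than_three_accepted_levels_is_an_error(self):
        levels = [level(1.0, [10.0]), level(2.0, [20.0])]
        with pytest.raises(ValueError, match="at least 3"):
            fit_weighted_linear(levels)

    def test_means_mode_fits_level_means(self):
        levels = [level(c, [10 * c - 1, 10 * c + 1]) for c in (1.0, 5.0, 25.0)]
        res = fit_weighted_linear(levels, fit_on="means")
        assert res.n_points == 3
        assert res.slope == pytest.approx(10.0, rel=1e-9)


class TestLodLloq:
    def test_printed_summary_decision(self):
        # per-level assay summaries: the lowest level detects (SNR 8) but is
        # too imprecise (RSD 27%); the next level up quantifies (RSD 2.39%)
        levels = [
            level(0.1, [1.0, 1.5, 0.8], snr=8.0),
            level(1.0, [10.0, 10.2, 10.1], snr=16.7),
        ]
        levels[0].replicate_areas = [1.0, 1.4, 0.75]  # RSD > 27%
        assert rsd(levels[0].replicate_areas) > 27
        lod, lloq = determine_lod_lloq(levels)
        assert lod == pytest.approx(0.1)
        assert lloq == pytest.approx(1.0)

    def test_all_levels_clean_lod_equals_lloq(self):
        levels = [level(c, [c * 10, c * 10.1], snr=100.0) for c in (1.0, 10.0)]
        lod, lloq = determine_lod_lloq(levels)
        assert lod == lloq == 1.0

    def test_rsd_boundary_inclusive_for_lloq(self):
        areas = [100.0, 100.0 + 100.0 * 0.15 * math.sqrt(2)]  # RSD exactly 15%
        lv = level(1.0, areas, snr=20.0)
        assert rsd(lv.replicate_areas) <= 15.0 + 1e-9
        lod, lloq = determine_lod_lloq([lv], rsd_max=rsd(lv.replicate_areas))
        assert lloq == 1.0

    def test_no_detectable_level_raises(self):
        with pytest.raises(ValueError, match="SNR"):
            determine_lod_lloq([level(1.0, [1.0, 1.1], snr=2.0)])


class TestHeteroscedasticity:
    def test_equal_variances_homoscedastic(self):
        lo = level(1.0, [10.0, 11.0, 9.0, 10.5, 9.5])
        hi = level(100.0, [1000.0, 1001.0, 999.0, 1000.5, 999.5])
        res = assess_heteroscedasticity(lo, hi)
        assert res.variance_ratio == pytest.approx(1.0)
        assert not res.heteroscedastic

    def test_cv_proportional_noise_detected(self, noiseless_config):
        rng = np.random.default_rng(5)
        lo_areas = 1.0 * (1 + 0.05 * rng.standard_normal(10))
        hi_areas = 1e5 * (1 + 0.05 * rng.standard_normal(10))
        res = assess_heteroscedasticity(level(1.0, lo_areas), level(1e5, hi_areas))
        assert res.heteroscedastic
        assert res.variance_ratio > res.f_critical

    def test_degenerate_zero_low_variance(self):
        res = assess_heteroscedasticity(
            level(1.0, [10.0, 10.0]), level(100.0, [900.0, 1100.0])
        )
        assert math.isinf(res.variance_ratio)
        assert res.heteroscedastic

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            assess_heteroscedasticity(level(1.0, [10.0]), level(2.0, [20.0, 21.0]))


class TestBackCalculation:
    def _curve(self):
        levels = [level(c, [100.0 * c + 5.0] * 3, snr=50.0) for c in (1.0, 10.0, 100.0)]
        return fit_weighted_linear(levels)

    def test_area_equal_intercept_flags_not_detected(self):
        curve = self._curve()
        res = curve.back_calculate(curve.intercept)
        assert res.conc == pytest.approx(0.0, abs=1e-9)
        assert "not-detected" in res.flags

    def test_simple_algebra(self):
        curve = self._curve()
        res = curve.back_calculate(1005.0)
        assert res.conc == pytest.approx(10.0, rel=1e-9)
        assert res.flags == []

    def test_negative_raw_reported_zero_with_flag(self):
        curve = self._curve()
        res = curve.back_calculate(curve.intercept - 50.0)
        assert res.conc == 0.0
        assert res.raw_conc < 0
        assert "negative-raw-reported-0" in res.flags

    def test_below_lloq_flagged(self):
        levels = [
            level(1.0, [105.0, 135.0], snr=10.0),  # RSD ~17.7% -> detect only
            level(10.0, [1005.0, 1006.0], snr=50.0),
            level(100.0, [10005.0, 10006.0], snr=200.0),
            level(1000.0, [100005.0, 100006.0], snr=500.0),
        ]
        curve = fit_weighted_linear(levels)
        assert curve.lod == 1.0 and curve.lloq == 10.0
        res = curve.back_calculate(100.0 * 5.0 + 5.0)
        assert "below-LLOQ" in res.flags

    def test_round_trip_noiseless_nominals(self):
        curve = self._curve()
        for conc in (1.0, 10.0, 100.0):
            res = curve.back_calculate(100.0 * conc + 5.0)
            assert res.conc == pytest.approx(conc, rel=1e-9)

    def test_round_trip_simulated_30_ng_ml(self, noiseless_config):
        series = simulate_calibration_series(
            noiseless_config, levels=[1.0, 10.0, 100.0], replicates=2, noise_cv=0.0
        )
        from srmpk.peaks import NoiseEstimate, detect_peak

        noise = NoiseEstimate(rms=0.5, baseline_level=0.0, region=(11.0, 11.2))
        per_level: dict[float, list[float]] = {}
        for inj in series:
            peak = detect_peak(inj.traces[0], (11.3, 11.9), noise)
            per_level.setdefault(inj.level, []).append(peak.area)
        curve = fit_weighted_linear(
            [level(c, a) for c, a in sorted(per_level.items())]
        )
        from srmpk import simulate_srm_chromatogram

        unknown = simulate_srm_chromatogram(noiseless_config, 30.0)[0]
        target = detect_peak(unknown, (11.3, 11.9), noise)
        assert curve.back_calculate(target.area).conc == pytest.approx(30.0, rel=1e-3)


@given(
    slope=st.floats(min_value=1.0, max_value=1e4),
    intercept=st.floats(min_value=-10.0, max_value=10.0),
)
def test_weighting_invariance_on_noiseless_data(slope, intercept):
    """On exact (homoscedastic, noiseless) data all weightings coincide."""
    levels = [
        CalibrationLevel(c, [slope * c + intercept] * 2)
        for c in (0.5, 5.0, 50.0, 500.0)
    ]
    fits = [fit_weighted_linear(levels, weighting=w) for w in ("none", "1/x", "1/x2")]
    slopes = [f.slope for f in fits]
    assert max(slopes) - min(slopes) <= 1e-6 * abs(slopes[0])


def test_summary_renders(noiseless_config):
    levels = [
        CalibrationLevel(c, [100.0 * c + 5.0] * 3, mean_snr=50.0)
        for c in (1.0, 10.0, 100.0)
    ]
    text = CalibrationModel(levels).fit().summary()
    assert "slope" in text and "LLOQ" in text
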