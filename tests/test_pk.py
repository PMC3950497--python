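import math

import numpy as np
import pytest
import scipy.integrate
from hypothesis import given, strategies as st

from srmpk import (
    ConcentrationTimeProfile,
    PKModel,
    PKSimConfig,
    auc_extrapolate_to_infinity,
    auc_model_closed_form,
    auc_trapezoidal,
    clearance,
    fit_absorption_model,
    half_life,
    observed_cmax_tmax,
    simulate_pk_profile,
    terminal_elimination_fit,
)
from srmpk.pk import FLAG_INSUFFICIENT_TERMINAL


def exponential_profile(c0=20.0, kel=0.006, times=(120, 180, 300, 480, 720)):
    pts = [(float(t), c0 * math.exp(-kel * t)) for t in times]
    return ConcentrationTimeProfile("EXP", 0.5, [(0.0, 0.0), (90.0, c0)] + pts)


class TestObservedCmaxTmax:
    def test_study_animals(self, profile_by_animal):
        assert observed_cmax_tmax(profile_by_animal["ST02"]) == (33.9, 90.0)
        assert observed_cmax_tmax(profile_by_animal["ST01"]) == (13.9, 90.0)

    def test_single_point(self):
        prof = ConcentrationTimeProfile("A", 0.5, [(60.0, 5.0)])
        assert observed_cmax_tmax(prof) == (5.0, 60.0)

    def test_tie_broken_to_earliest(self):
        prof = ConcentrationTimeProfile("A", 0.5, [(30.0, 7.0), (60.0, 7.0)])
        assert observed_cmax_tmax(prof) == (7.0, 30.0)

    def test_all_zero_profile_rejected(self):
        prof = ConcentrationTimeProfile("A", 0.5, [(0.0, 0.0), (10.0, 0.0)])
        with pytest.raises(ValueError):
            observed_cmax_tmax(prof)


class TestTerminalFit:
    def test_exact_exponential_recovered_to_machine_precision(self):
        fit = terminal_elimination_fit(exponential_profile())
        assert fit.kel == pytest.approx(0.006, rel=1e-12)
        assert fit.c0_extrapolated == pytest.approx(20.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_sparse_terminal_phase_flagged(self, profile_by_animal):
        # only one measurable point after Tmax -> no Kel, explicit flag
        fit = terminal_elimination_fit(profile_by_animal["ST03"])
        assert fit.kel is None
        assert FLAG_INSUFFICIENT_TERMINAL in fit.flags
        assert fit.n_points == 1

    def test_two_point_closed_form_with_relaxed_minimum(self):
        prof = ConcentrationTimeProfile(
            "A", 0.5, [(90.0, 5.0), (480.0, 1.8), (720.0, 1.5)]
        )
        fit = terminal_elimination_fit(prof, min_points=2)
        assert fit.kel == pytest.approx(math.log(1.8 / 1.5) / 240.0, rel=1e-9)

    def test_zero_concentrations_excluded_from_log_fit(self, profile_by_animal):
        # ST01 has conc 0 at 1440 min; the log-linear fit must skip it
        fit = terminal_elimination_fit(profile_by_animal["ST01"])
        assert fit.n_points == 4  # 120, 180, 480, 720


class TestHalfLife:
    @pytest.mark.parametrize(
        "kel,expected",
        [(0.005, 139), (0.007, 99), (0.006, 116), (math.log(2), 1)],
    )
    def test_published_rounding(self, kel, expected):
        assert round(half_life(kel)) == expected

    def test_positive_kel_required(self):
        with pytest.raises(ValueError):
            half_life(0.0)


class TestAucTrapezoidal:
    def test_flat_zero(self):
        assert auc_trapezoidal([(0.0, 0.0), (100.0, 0.0)]) == 0.0

    def test_rectangle(self):
        assert auc_trapezoidal([(0.0, 10.0), (10.0, 10.0)]) == 100.0

    def test_study_animal_observed_segment(self, profile_by_animal):
        pts = [p for p in profile_by_animal["ST01"].points if 15.0 <= p[0] <= 720.0]
        assert auc_trapezoidal(pts) == pytest.approx(2600.25, abs=1e-9)

    def test_requires_two_points(self):
        with pytest.raises(ValueError):
            auc_trapezoidal([(0.0, 1.0)])

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0.0, max_value=1000.0),
                st.floats(min_value=0.0, max_value=50.0),
            ),
            min_size=3,
            max_size=12,
            unique_by=lambda p: p[0],
        )
    )
    def test_additivity_over_split(self, raw_points):
        pts = sorted(raw_points)
        mid = len(pts) // 2
        if mid == 0 or mid >= len(pts) - 1:
            return
        whole = auc_trapezoidal(pts)
        left = auc_trapezoidal(pts[: mid + 1])
        right = auc_trapezoidal(pts[mid:])
        assert whole == pytest.approx(left + right, rel=1e-9, abs=1e-9)


class TestAucExtrapolation:
    def test_zero_last_concentration(self):
        assert auc_extrapolate_to_infinity(720.0, 0.0, 0.005) == 0.0

    def test_simple_algebra(self):
        assert auc_extrapolate_to_infinity(720.0, 1.5, 0.005) == pytest.approx(300.0)

    def test_matches_quadrature_of_exponential_tail(self):
        kel, c_last, t_last = 0.006, 1.3, 720.0
        tail, _ = scipy.integrate.quad(
            lambda t: c_last * math.exp(-kel * (t - t_last)), t_last, np.inf
        )
        assert auc_extrapolate_to_infinity(t_last, c_last, kel) == pytest.approx(
            tail, rel=1e-9
        )


class TestClosedFormAuc:
    def test_zero_c0(self):
        assert auc_model_closed_form(0.0, 0.01, 0.005, 90.0) == 0.0

    def test_matches_piecewise_quadrature(self):
        C0, K1, Kel, Tmax = 20.0, 0.02, 0.006, 90.0
        rising, _ = scipy.integrate.quad(
            lambda t: C0 * (1 - math.exp(-K1 * t)), 15.0, Tmax
        )
        tail, _ = scipy.integrate.quad(
            lambda t: C0 * math.exp(-Kel * t), Tmax, np.inf
        )
        assert auc_model_closed_form(C0, K1, Kel, Tmax) == pytest.approx(
            rising + tail, rel=1e-6
        )

    def test_quadrature_equivalence_over_parameter_grid(self):
        for K1 in (1e-3, 1e-2, 1e-1):
            for Kel in (1e-3, 1e-2, 1e-1):
                for Tmax in (30.0, 90.0, 180.0):
                    closed = auc_model_closed_form(10.0, K1, Kel, Tmax)
                    rising, _ = scipy.integrate.quad(
                        lambda t: 10.0 * (1 - math.exp(-K1 * t)), 15.0, Tmax
                    )
                    tail = 10.0 * math.exp(-Kel * Tmax) / Kel
                    assert closed == pytest.approx(rising + tail, rel=1e-6)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            auc_model_closed_form(10.0, 0.01, 0.005, 10.0)  # Tmax <= t_start
        with pytest.raises(ValueError):
            auc_model_closed_form(10.0, -0.01, 0.005, 90.0)

    @given(
        c0a=st.floats(min_value=1.0, max_value=30.0),
        delta=st.floats(min_value=0.1, max_value=10.0),
        kel=st.floats(min_value=1e-3, max_value=5e-2),
    )
    def test_strictly_increasing_in_c0(self, c0a, delta, kel):
        lo = auc_model_closed_form(c0a, 0.02, kel, 90.0)
        hi = auc_model_closed_form(c0a + delta, 0.02, kel, 90.0)
        assert hi > lo

    @given(
        kel=st.floats(min_value=1e-3, max_value=5e-2),
        factor=st.floats(min_value=1.1, max_value=5.0),
    )
    def test_strictly_decreasing_in_kel(self, kel, factor):
        lo_kel = auc_model_closed_form(10.0, 0.02, kel, 90.0)
        hi_kel = auc_model_closed_form(10.0, 0.02, kel * factor, 90.0)
        assert hi_kel < lo_kel


class TestClearance:
    @pytest.mark.parametrize(
        "dose,auc,expected",
        [(0.50, 2217.0, 225.5), (1.0, 1e6, 1.0), (0.45, 2516.0, 178.9)],
    )
    def test_known_values(self, dose, auc, expected):
        assert clearance(dose, auc) == pytest.approx(expected, abs=0.05)

    def test_positive_auc_required(self):
        with pytest.raises(ValueError):
            clearance(0.5, 0.0)


class TestAbsorptionModelFit:
    def test_noiseless_profile_recovered_within_1pct(self):
        cfg = PKSimConfig(C0=15.0, K1=0.02, Kel=0.006, Tmax=90.0, measurement_cv=0.0)
        prof = simulate_pk_profile(cfg)
        absorption, terminal, tmax = fit_absorption_model(prof)
        assert tmax == 90.0
        assert absorption.k1 == pytest.approx(0.02, rel=0.01)
        assert absorption.c0_rising == pytest.approx(15.0, rel=0.01)
        assert terminal.kel == pytest.approx(0.006, rel=0.01)
        assert terminal.c0_extrapolated == pytest.approx(15.0, rel=0.01)

    def test_refined_fit_matches_profiled_on_noiseless_data(self):
        cfg = PKSimConfig(C0=12.0, K1=0.015, Kel=0.005, Tmax=90.0, measurement_cv=0.0)
        prof = simulate_pk_profile(cfg)
        a0, _, _ = fit_absorption_model(prof, refine=False)
        a1, _, _ = fit_absorption_model(prof, refine=True)
        assert a1.k1 == pytest.approx(a0.k1, rel=1e-3)

    def test_kel_recovery_under_measurement_noise(self):
        """Median relative Kel error < 15% at 5% CV across 100 seeds."""
        errors = []
        for seed in range(100):
            cfg = PKSimConfig(
                C0=15.0, K1=0.02, Kel=0.006, Tmax=90.0,
                measurement_cv=0.05, seed=seed,
            )
            fit = terminal_elimination_fit(simulate_pk_profile(cfg))
            errors.append(abs(fit.kel - 0.006) / 0.006)
        assert float(np.median(errors)) < 0.15

    def test_kel_estimator_bias_small(self):
        """Mean Kel bias < 5% of truth over 100 seeded profiles at 5% CV."""
        kels = []
        for seed in range(100):
            cfg = PKSimConfig(
                C0=15.0, K1=0.02, Kel=0.006, Tmax=90.0,
                measurement_cv=0.05, seed=1000 + seed,
            )
            kels.append(terminal_elimination_fit(simulate_pk_profile(cfg)).kel)
        bias = abs(float(np.mean(kels)) - 0.006) / 0.006
        assert bias < 0.05

    def test_sparse_profile_flagged_no_kel(self, profile_by_animal):
        absorption, terminal, _ = fit_absorption_model(profile_by_animal["ST03"])
        assert terminal.kel is None
        assert FLAG_INSUFFICIENT_TERMINAL in terminal.flags
        assert absorption.k1 is not None  # rising phase is still fittable


class TestPKModel:
    def test_full_analysis_of_well_sampled_animal(self, profile_by_animal):
        res = PKModel(profile_by_animal["ST01"]).fit()
        p = res.params
        assert (p.cmax, p.tmax) == (13.9, 90.0)
        assert p.kel is not None and p.t_half == pytest.approx(math.log(2) / p.kel)
        assert p.auc15 is not None and p.cl == pytest.approx(0.5e6 / p.auc15)
        assert p.auc_trapz > 0
        assert "Pharmacokinetic analysis" in res.summary()

    def test_sparse_animal_reports_flags_and_absent_parameters(self, profile_by_animal):
        res = PKModel(profile_by_animal["ST03"]).fit()
        p = res.params
        assert FLAG_INSUFFICIENT_TERMINAL in p.flags
        assert p.kel is None and p.t_half is None and p.auc15 is None and p.cl is None
        assert (p.cmax, p.tmax) == (20.4, 90.0)

    def test_parameter_overrides_drive_model_auc(self, profile_by_animal):
        res = PKModel(
            profile_by_animal["ST01"],
            c0_override=10.57, k1_override=0.01, kel_override=0.005,
        ).fit()
        assert res.params.auc15 == pytest.approx(
            auc_model_closed_form(10.57, 0.01, 0.005, 90.0), rel=1e-12
        )

    def test_half_life_consistency_invariant(self, study_profiles):
        for prof in study_profiles:
            p = PKModel(prof).fit().params
            if p.kel is not None:
                assert p.t_half == pytest.approx(math.log(2) / p.kel, rel=1e-12)
            assert p.tmax in prof.times
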