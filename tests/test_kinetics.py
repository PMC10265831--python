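import numpy as np
import pytest

from glymkin.geometry import compartment_curves, split_region
from glymkin.io_core import TimeSignalCurve
from glymkin.kinetics import (
    ExchangeFit,
    cohort_qc_thresholds,
    compute_volumes,
    fit_exchange_rates,
    forward_model,
    qc_gate,
    thickness_search,
)
from glymkin.synth import (
    build_shell_phantom,
    default_times,
    gamma_variate_input,
    generate_inner_from_outer,
)


class TestForwardModel:
    def test_k1_zero(self, gamma_curve):
        out = forward_model(0.0, 0.05, gamma_curve.times, gamma_curve.values)
        np.testing.assert_allclose(out, 0.0)

    def test_zero_input(self, times40):
        out = forward_model(0.1, 0.05, times40, np.zeros_like(times40))
        np.testing.assert_allclose(out, 0.0)

    def test_step_response_closed_form(self):
        # step input: (k1/k2)(1 - exp(-k2 t)); exact for piecewise-linear data
        times = np.linspace(0, 60, 61)
        model = forward_model(0.1, 0.05, times, np.ones_like(times))
        expected = (0.1 / 0.05) * (1 - np.exp(-0.05 * times))
        np.testing.assert_allclose(model[1:], expected[1:], rtol=1e-12)
        assert model[-1] == pytest.approx(1.9004258632642703, rel=1e-10)

    def test_matches_rk4_oracle(self, gamma_curve):
        # dual route: exact convolution vs independent RK4 integration
        inner = generate_inner_from_outer(gamma_curve, 0.02, 0.012, refine=50)
        model = forward_model(0.02, 0.012, gamma_curve.times, gamma_curve.values)
        rel = np.linalg.norm(model - inner.values) / np.linalg.norm(inner.values)
        assert rel < 1e-6

    def test_k2_zero_reduces_to_cumulative_integral(self, gamma_curve):
        model = forward_model(0.03, 0.0, gamma_curve.times, gamma_curve.values)
        from scipy.integrate import cumulative_trapezoid

        oracle = 0.03 * cumulative_trapezoid(
            gamma_curve.values, gamma_curve.times, initial=0.0
        )
        np.testing.assert_allclose(model, oracle, rtol=1e-10, atol=1e-12)

    def test_accepts_curve_objects(self, gamma_curve):
        a = forward_model(0.02, 0.01, None, gamma_curve)
        b = forward_model(0.02, 0.01, gamma_curve.times, gamma_curve.values)
        np.testing.assert_array_equal(a, b)


class TestFitExchangeRates:
    def test_noise_free_recovery(self, exchange_pair):
        outer, inner, k1, k2 = exchange_pair
        fit = fit_exchange_rates(outer, inner)
        assert fit.k1 == pytest.approx(k1, rel=0.01)
        assert fit.k2 == pytest.approx(k2, rel=0.01)
        assert fit.usable

    def test_zero_inner_degenerate(self, gamma_curve, times40):
        zero = TimeSignalCurve(times40, np.zeros_like(times40))
        fit = fit_exchange_rates(gamma_curve, zero)
        assert fit.k1 == 0.0
        assert not fit.usable
        assert np.isnan(fit.k2)

    def test_mismatched_grids_rejected(self, gamma_curve):
        other = TimeSignalCurve(gamma_curve.times + 1.0, gamma_curve.values)
        with pytest.raises(ValueError, match="grid"):
            fit_exchange_rates(gamma_curve, other)

    def test_joint_scale_invariance(self, exchange_pair):
        outer, inner, _, _ = exchange_pair
        fit1 = fit_exchange_rates(outer, inner)
        c = 37.5
        fit2 = fit_exchange_rates(
            outer.with_values(c * outer.values), inner.with_values(c * inner.values)
        )
        assert fit2.k1 == pytest.approx(fit1.k1, rel=1e-6)
        assert fit2.k2 == pytest.approx(fit1.k2, rel=1e-6)
        assert fit2.ner == pytest.approx(fit1.ner, rel=1e-6)
        assert fit2.v_out == pytest.approx(c * fit1.v_out, rel=1e-9)

    def test_noisy_recovery_median(self, times40, rng):
        outer_clean = gamma_variate_input(20, 30, 2.0, 40.0, times40)
        inner_clean = generate_inner_from_outer(outer_clean, 0.02, 0.012)
        sigma = 0.01 * outer_clean.values.max()
        errs1, errs2 = [], []
        for _ in range(50):
            o = outer_clean.with_values(outer_clean.values + rng.normal(0, sigma, 40))
            i = inner_clean.with_values(inner_clean.values + rng.normal(0, sigma, 40))
            fit = fit_exchange_rates(o, i)
            errs1.append(abs(fit.k1 - 0.02) / 0.02)
            errs2.append(abs(fit.k2 - 0.012) / 0.012)
        assert np.median(errs1) < 0.10
        assert np.median(errs2) < 0.10

    def test_degenerate_pair_passthrough(self):
        from glymkin.geometry import CompartmentPair

        pair = CompartmentPair(1, 5, np.ones((2, 2, 2), bool), np.zeros((2, 2, 2), bool),
                               8, 0, usable=False, message="empty inner")
        fit = fit_exchange_rates(pair)
        assert not fit.usable
        assert "empty inner" in fit.message


class TestComputeVolumes:
    def test_symmetric_ner_is_one(self):
        times = np.linspace(0, 10, 11)
        v = np.ones(11)
        _, _, _, _, ner = compute_volumes(times, v, v, 0.02, 0.02)
        assert ner == pytest.approx(1.0)

    def test_direct_formula(self):
        # NER = (k2*V_in)/(k1*V_out) = (0.01*100)/(0.02*200) = 0.25
        times = np.linspace(0, 100, 101)
        i_out = np.full(101, 2.0)   # V_out = 200
        i_in = np.full(101, 1.0)    # V_in = 100
        v_out, v_in, v_oi, v_io, ner = compute_volumes(times, i_out, i_in, 0.02, 0.01)
        assert v_out == pytest.approx(200.0)
        assert v_in == pytest.approx(100.0)
        assert v_oi == pytest.approx(4.0)
        assert v_io == pytest.approx(1.0)
        assert ner == pytest.approx(0.25)

    def test_zero_denominator_gives_nan(self):
        times = np.linspace(0, 10, 11)
        *_, ner = compute_volumes(times, np.zeros(11), np.ones(11), 0.02, 0.01)
        assert np.isnan(ner)

    def test_ner_approaches_one_at_steady_state(self):
        # long constant input: I_in -> (k1/k2) I_out, so NER -> 1
        k1, k2 = 0.05, 0.02
        ners = []
        for horizon in (500.0, 5000.0, 50000.0):
            times = np.linspace(0, horizon, 2001)
            i_out = np.ones_like(times)
            i_in = forward_model(k1, k2, times, i_out)
            *_, ner = compute_volumes(times, i_out, i_in, k1, k2)
            ners.append(ner)
        assert np.all(np.diff(ners) > 0)
        assert ners[-1] == pytest.approx(1.0, abs=2e-3)


class TestThicknessSearch:
    @staticmethod
    def _phantom(s_star, seed=0, edge=13, noise=0.2):
        times = default_times()
        outer = gamma_variate_input(15, 35, 2.0, 40.0, times)
        inner = generate_inner_from_outer(outer, 0.04, 0.02)
        dyn, lab = build_shell_phantom(s_star, edge, outer, inner)
        if noise:
            rng = np.random.default_rng(seed)
            dyn.frames = dyn.frames + rng.normal(0, noise, dyn.frames.shape)
        return dyn, lab

    def test_recovers_planted_thickness(self):
        dyn, lab = self._phantom(3, seed=1)
        result = thickness_search(dyn, lab, 1, range(1, 6))
        assert result.optimal_s == 3

    def test_single_candidate_returned(self):
        dyn, lab = self._phantom(2, seed=2)
        result = thickness_search(dyn, lab, 1, [2])
        assert result.optimal_s == 2

    def test_degenerate_thicknesses_excluded(self):
        dyn, lab = self._phantom(2, seed=3, edge=9, noise=0.0)
        result = thickness_search(dyn, lab, 1, range(1, 7))
        degenerate = [r for r in result.records if not r.usable]
        assert any("empty" in r.message for r in degenerate)
        assert result.optimal_s is not None

    def test_all_degenerate_raises(self):
        dyn, lab = self._phantom(1, edge=5, noise=0.0)
        with pytest.raises(ValueError, match="usable"):
            thickness_search(dyn, lab, 1, [10, 11])

    def test_empty_range_rejected(self):
        dyn, lab = self._phantom(1, edge=5, noise=0.0)
        with pytest.raises(ValueError, match="nonempty"):
            thickness_search(dyn, lab, 1, [])


class TestQcGate:
    def _fit(self, v_out=100.0, v_in=50.0):
        return ExchangeFit(0.02, 0.01, None, 0.0, v_out=v_out, v_in=v_in,
                           v_out_to_in=0.02 * v_out, v_in_to_out=0.01 * v_in,
                           ner=0.25, usable=True)

    def test_zero_volume_unusable(self):
        gated = qc_gate(self._fit(v_in=0.0), 1.0)
        assert not gated.usable

    def test_median_volume_usable(self):
        gated = qc_gate(self._fit(), 5.0)
        assert gated.usable

    def test_gate_changes_only_flags(self):
        fit = self._fit(v_out=0.5)
        for threshold in (0.1, 1.0, 10.0):
            gated = qc_gate(fit, threshold)
            assert gated.k1 == fit.k1
            assert gated.k2 == fit.k2
            assert gated.ner == fit.ner
            assert gated.v_out == fit.v_out
        assert fit.usable  # original untouched

    def test_cohort_thresholds(self):
        fits = [self._fit(v_out=v, v_in=v / 2) for v in (80.0, 100.0, 120.0)]
        thr_out, thr_in = cohort_qc_thresholds(fits, fraction=0.05)
        assert thr_out == pytest.approx(5.0)
        assert thr_in == pytest.approx(2.5)


class TestParameterRecoveryGrid:
    def test_noise_free_grid_within_one_percent(self, times40):
        outer = gamma_variate_input(20, 30, 2.0, 40.0, times40)
        for k1 in (0.005, 0.02, 0.1):
            for k2 in (0.005, 0.02, 0.1):
                inner = generate_inner_from_outer(outer, k1, k2)
                fit = fit_exchange_rates(outer, inner)
                assert fit.k1 == pytest.approx(k1, rel=0.01)
                assert fit.k2 == pytest.approx(k2, rel=0.01)
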