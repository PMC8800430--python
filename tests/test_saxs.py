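"""Unified-model evaluation, fitting, and curve transforms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cellugel as cg
from cellugel.saxs import q_star

from .conftest import perturbed_init
from .oracle import unified_intensity_mp

Q_GRID = np.geomspace(0.07, 2.5, 120)


class TestEvaluateUnifiedModel:
    def test_background_only(self):
        p = cg.UnifiedModelParams(background=0.791, g1=0, b1=0, rg1=30.0, p1=2.0,
                                  g2=0, b2=0, rg2=5.0, p2=2.0)
        ev = cg.evaluate_unified_model(p, Q_GRID)
        assert np.allclose(ev.total, 0.791)

    def test_zero_q_limit_is_background_plus_guinier_prefactors(self, space_upper_params):
        p = space_upper_params
        q0 = 1e-4 / p.rg1
        total = cg.unified_intensity(p, np.array([q0]))[0]
        expected = p.background + p.g1 + p.g2  # 0.791 + 3360 + 56.4 = 3417.191
        assert total == pytest.approx(expected, rel=1e-6)

    def test_matches_arbitrary_precision_oracle_at_fixed_point(self, ground_middle_params):
        # frozen oracle value, mpmath at 40 digits
        total = cg.unified_intensity(ground_middle_params, np.array([0.5]))[0]
        assert total == pytest.approx(11.366901879759578, rel=1e-10)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_oracle_on_random_draws(self, seed):
        rng = np.random.default_rng(seed)
        d = dict(
            background=rng.uniform(0, 2),
            g1=rng.uniform(0, 5000), b1=rng.uniform(0, 5),
            rg1=rng.uniform(10, 50), p1=rng.uniform(0.5, 8),
            g2=rng.uniform(0, 100), b2=rng.uniform(0, 5),
            rg2=rng.uniform(1, 9), p2=rng.uniform(0.5, 8),
        )
        p = cg.UnifiedModelParams(**d)
        q = float(rng.uniform(0.01, 3.0))
        got = cg.unified_intensity(p, np.array([q]))[0]
        want = unified_intensity_mp(d, q)
        assert got == pytest.approx(want, rel=1e-10)  # >= 10 significant digits

    def test_q_star_never_below_q_and_model_positive(self, space_upper_params):
        ev = cg.evaluate_unified_model(space_upper_params, Q_GRID)
        assert np.all(ev.q_star_1 >= Q_GRID)
        assert np.all(ev.q_star_2 >= Q_GRID)
        assert np.all(ev.total > 0)

    def test_monotone_decreasing_beyond_last_guinier_knee(self, space_upper_params):
        q = np.geomspace(math.sqrt(3) / space_upper_params.rg2, 5.0, 200)
        p = cg.UnifiedModelParams(**{**space_upper_params.to_dict(), "background": 0.0})
        total = cg.unified_intensity(p, q)
        assert np.all(np.diff(total) <= 0)

    def test_rejects_nonpositive_q(self, space_upper_params):
        with pytest.raises(ValueError):
            cg.unified_intensity(space_upper_params, np.array([0.0, 0.5]))

    def test_rejects_unordered_levels(self):
        with pytest.raises(ValueError):
            cg.UnifiedModelParams(background=0, g1=1, b1=1, rg1=5.0, p1=2,
                                  g2=1, b2=1, rg2=30.0, p2=2)


class TestFitUnifiedModel:
    def test_noiseless_recovery_within_one_percent(self, noiseless_space_upper_curve,
                                                   space_upper_params):
        init = perturbed_init(space_upper_params, seed=42, frac=0.2)
        res = cg.fit_unified_model(noiseless_space_upper_curve, init)
        assert res.converged
        assert res.chi2_per_point < 1e-6
        for k, v in space_upper_params.to_dict().items():
            assert getattr(res.params, k) == pytest.approx(v, rel=0.01), k

    def test_noisy_recovery_of_small_radius_and_exponent(self, space_upper_params):
        cfg = cg.SynthConfig(kind="saxs", seed=0, noise=0.02, grid={"n": 300},
                             truth=space_upper_params.to_dict())
        curve = cg.generate_saxs_curve(cfg)
        res = cg.fit_unified_model(curve, perturbed_init(space_upper_params, 7, 0.15))
        assert res.params.rg2 == pytest.approx(space_upper_params.rg2, rel=0.05)
        assert abs(res.params.p1 - space_upper_params.p1) < 0.1

    def test_rg2_median_recovery_over_replicates(self, space_upper_params):
        """At 2% noise the small-structure radius recovers within 5% (median)."""
        errs = []
        for s in range(20):
            cfg = cg.SynthConfig(kind="saxs", seed=s, noise=0.02, grid={"n": 300},
                                 truth=space_upper_params.to_dict())
            curve = cg.generate_saxs_curve(cfg)
            res = cg.fit_unified_model(curve, perturbed_init(space_upper_params, 1000 + s, 0.15))
            errs.append(abs(res.params.rg2 - space_upper_params.rg2) / space_upper_params.rg2)
        assert np.median(errs) < 0.05

    def test_flat_curve_recovers_background(self):
        q = np.geomspace(0.07, 2.5, 100)
        curve = cg.ScatteringCurve(q, np.full(q.size, 3.7), np.full(q.size, 0.01))
        init = cg.UnifiedModelParams(background=2.0, g1=1, b1=0.1, rg1=30, p1=2,
                                     g2=1, b2=0.1, rg2=5, p2=2)
        res = cg.fit_unified_model(curve, init)
        assert res.params.background == pytest.approx(3.7, rel=0.01)

    def test_rejects_short_or_nonfinite_curves(self, space_upper_params):
        q = np.geomspace(0.07, 2.5, 20)
        curve = cg.ScatteringCurve(q, np.ones(q.size))
        with pytest.raises(ValueError):
            cg.fit_unified_model(curve, space_upper_params)
        q = np.geomspace(0.07, 2.5, 60)
        bad = np.ones(q.size)
        bad[5] = np.nan
        with pytest.raises(ValueError):
            cg.fit_unified_model(cg.ScatteringCurve(q, bad), space_upper_params)

    def test_ordering_bound_respected(self, noiseless_space_upper_curve, space_upper_params):
        res = cg.fit_unified_model(noiseless_space_upper_curve,
                                   perturbed_init(space_upper_params, 5, 0.1))
        assert res.params.rg1 > res.params.rg2


class TestKratky:
    def test_unit_intensity_gives_q_squared(self):
        curve = cg.ScatteringCurve(Q_GRID, np.ones_like(Q_GRID))
        out = cg.kratky_transform(curve)
        assert np.allclose(out.intensity, Q_GRID ** 2)

    def test_guinier_peak_at_sqrt3_over_rg(self):
        rg = 3.50
        q = np.linspace(0.01, 2.0, 4000)
        curve = cg.ScatteringCurve(q, 10.0 * np.exp(-(q ** 2) * rg ** 2 / 3.0))
        out = cg.kratky_transform(curve)
        q_peak = q[np.argmax(out.intensity)]
        assert q_peak == pytest.approx(math.sqrt(3) / rg, abs=2 * (q[1] - q[0]))

    def test_full_model_value_matches_oracle(self, ground_middle_params):
        q = np.array([0.5, 0.9, 1.5])  # includes the reported 0.9 nm^-1 peak region
        curve = cg.ScatteringCurve(
            np.geomspace(0.07, 2.5, 50),
            cg.unified_intensity(ground_middle_params, np.geomspace(0.07, 2.5, 50)))
        out = cg.kratky_transform(curve)
        # frozen oracle: 0.9^2 * I(0.9) for the ground-middle parameters
        i09 = np.interp(0.9, out.q, out.intensity)
        assert 0.81 * unified_intensity_mp(ground_middle_params.to_dict(), 0.9) == \
            pytest.approx(3.079254575634645, rel=1e-12)
        assert i09 == pytest.approx(3.079254575634645, rel=0.01)  # grid interpolation

    def test_sigma_propagates_as_q_squared(self):
        curve = cg.ScatteringCurve(Q_GRID, np.ones_like(Q_GRID),
                                   0.1 * np.ones_like(Q_GRID))
        out = cg.kratky_transform(curve)
        assert np.allclose(out.sigma, 0.1 * Q_GRID ** 2)


class TestSubtractReference:
    def test_self_subtraction_is_zero(self, noiseless_space_upper_curve):
        out = cg.subtract_reference(noiseless_space_upper_curve,
                                    noiseless_space_upper_curve)
        assert np.allclose(out.intensity, 0.0)

    def test_mismatched_grids_rejected(self, noiseless_space_upper_curve):
        other = cg.ScatteringCurve(noiseless_space_upper_curve.q[:-1],
                                   noiseless_space_upper_curve.intensity[:-1])
        with pytest.raises(ValueError):
            cg.subtract_reference(noiseless_space_upper_curve, other)

    def test_residual_equals_closed_form_model_difference(self, space_upper_params):
        d2 = {**space_upper_params.to_dict(), "g2": 80.0}
        p2 = cg.UnifiedModelParams(**d2)
        c1 = cg.generate_saxs_curve(cg.SynthConfig(kind="saxs", noise=0.0,
                                                   truth=space_upper_params.to_dict()))
        c2 = cg.generate_saxs_curve(cg.SynthConfig(kind="saxs", noise=0.0, truth=d2))
        out = cg.subtract_reference(c2, c1)
        expected = (cg.unified_intensity(p2, c1.q)
                    - cg.unified_intensity(space_upper_params, c1.q))
        assert np.allclose(out.intensity, expected, rtol=1e-12)

    def test_sigma_combines_in_quadrature(self):
        s1, s2 = np.full_like(Q_GRID, 0.3), np.full_like(Q_GRID, 0.4)
        a = cg.ScatteringCurve(Q_GRID, np.ones_like(Q_GRID), s1)
        b = cg.ScatteringCurve(Q_GRID, np.ones_like(Q_GRID), s2)
        out = cg.subtract_reference(a, b)
        assert np.allclose(out.sigma, 0.5)


class TestLocalPowerLawSlope:
    def test_exact_power_law(self):
        q = np.geomspace(0.05, 1.0, 200)
        curve = cg.ScatteringCurve(q, q ** -2.30)
        p, err = cg.local_power_law_slope(curve, 0.07, 0.5)
        assert p == pytest.approx(2.30, abs=1e-10)

    def test_constant_curve_has_zero_exponent(self):
        q = np.geomspace(0.05, 1.0, 100)
        p, _ = cg.local_power_law_slope(cg.ScatteringCurve(q, np.full(q.size, 4.2)),
                                        0.07, 0.5)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_model_slope_matches_independent_regression(self, space_upper_params):
        curve = cg.generate_saxs_curve(cg.SynthConfig(
            kind="saxs", noise=0.0, grid={"n": 400}, truth=space_upper_params.to_dict()))
        p, _ = cg.local_power_law_slope(curve, 0.07, 0.5)
        # independent normal-equations regression on the same window
        m = (curve.q >= 0.07) & (curve.q <= 0.5)
        x, y = np.log(curve.q[m]), np.log(curve.intensity[m])
        slope = (np.sum((x - x.mean()) * (y - y.mean()))
                 / np.sum((x - x.mean()) ** 2))
        assert p == pytest.approx(-slope, rel=1e-12)
        # platelet-like scattering: exponent sits in the low-2 range
        assert 2.0 < p < 2.6

    def test_empty_window_rejected(self, noiseless_space_upper_curve):
        with pytest.raises(ValueError):
            cg.local_power_law_slope(noiseless_space_upper_curve, 5.0, 6.0)


class TestAverageWithSem:
    @pytest.mark.parametrize("values, mean, sem", [
        ((6.48, 6.56, 6.78), 6.61, 0.09),   # published space Rg2 triplet
        ((6.22, 3.50, 4.00), 4.57, 0.84),   # published ground Rg2 triplet
        ((5.0, 5.0, 5.0), 5.0, 0.0),
    ])
    def test_mean_and_sem(self, values, mean, sem):
        m, s = cg.average_with_sem(values, ndigits=2)
        assert m == pytest.approx(mean, abs=5e-3)
        assert s == pytest.approx(sem, abs=5e-3)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            cg.average_with_sem([1.0])
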