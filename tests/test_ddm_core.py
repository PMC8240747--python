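"""Unit and property tests for the DDM core: drift parameterization,
closed-form predictions, the first-passage likelihood and the simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from effortddm.ddm_core import (DDMParameters, OfferCell, accept_probability,
                                _wfpt_density, drift_rate,
                                predict_acceptance_rate,
                                predict_mean_decision_time,
                                simulate_first_passage,
                                simulate_first_passage_batch,
                                wfpt_log_density)
from effortddm.errors import ConfigurationError


class TestDriftRate:
    def test_constant_when_weights_zero(self):
        p = DDMParameters(a=2.0, v0=0.7)
        for rew, eff in [(1, 0.1), (9, 0.52), (15, 0.8)]:
            assert drift_rate(p, OfferCell.from_levels(rew, eff)) == pytest.approx(0.7)

    def test_reward_scaling_identity(self):
        p = DDMParameters(a=2.0, v0=0.0, vr=1.0)
        assert drift_rate(p, OfferCell.from_levels(15, 0.1)) == pytest.approx(
            1.0 - 0.01 * 0.0, abs=1e-12)

    def test_hand_computed_example(self):
        # v0 + vr*r - ve*e - vre*r*e with r = 9/15 = 0.6, e = 0.52^2 = 0.2704
        p = DDMParameters(a=2.0, v0=1.0, vr=2.0, ve=1.5, vre=0.5)
        v = drift_rate(p, OfferCell.from_levels(9, 0.52))
        assert v == pytest.approx(1.0 + 2 * 0.6 - 1.5 * 0.2704 - 0.5 * 0.6 * 0.2704)
        assert v == pytest.approx(1.71328)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            DDMParameters(a=-1.0)
        with pytest.raises(ConfigurationError):
            DDMParameters(a=1.0, z=1.5)
        with pytest.raises(ConfigurationError):
            DDMParameters(a=1.0, v0=np.inf)


class TestClosedForms:
    def test_zero_drift_is_chance(self):
        assert predict_acceptance_rate(0.0, 1.3) == pytest.approx(0.5)

    def test_large_drift_saturates(self):
        assert predict_acceptance_rate(50.0, 1.0) >= 1 - 1e-9

    def test_direct_evaluation(self):
        assert predict_acceptance_rate(1.0, 1.0) == pytest.approx(
            1 / (1 + np.exp(-2)), rel=1e-9)
        assert predict_mean_decision_time(1.0, 1.5) == pytest.approx(
            1.5 * np.tanh(1.5), rel=1e-9)

    def test_decision_time_zero_drift_limit(self):
        a = 1.4
        assert abs(predict_mean_decision_time(1e-8, a) - a**2) < 1e-6

    def test_decision_time_large_drift_asymptote(self):
        assert predict_mean_decision_time(20.0, 1.0) == pytest.approx(1 / 20, rel=0.01)

    def test_domain_errors(self):
        with pytest.raises(ConfigurationError):
            predict_acceptance_rate(1.0, -1.0)
        with pytest.raises(ConfigurationError):
            predict_mean_decision_time(1.0, 1.0, c=0.0)

    @given(st.floats(-3, 3), st.floats(0.2, 3), st.floats(0.1, 5))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, v, a, k):
        # multiplying V, a and c by a common factor leaves Eq. 2 unchanged
        assert predict_acceptance_rate(k * v, k * a, c=k) == pytest.approx(
            predict_acceptance_rate(v, a), rel=1e-9, abs=1e-12)

    @given(st.floats(-2, 2), st.floats(-2, 2), st.floats(0.3, 2))
    @settings(max_examples=50, deadline=None)
    def test_acceptance_monotone_in_drift(self, v1, v2, a):
        lo, hi = sorted([v1, v2])
        assert predict_acceptance_rate(lo, a) <= predict_acceptance_rate(hi, a)


class TestWfptDensity:
    def test_normalizes_to_one(self):
        p = DDMParameters(a=1.2, z=0.5, t=0.3, v0=0.8)
        cell = OfferCell(reward=15, effort=0.8, r_scaled=1.0, e_scaled=0.64)
        ts = np.linspace(0.3001, 40, 150001)
        dens = np.exp(wfpt_log_density(ts, "accept", p, cell, outlier_prob=0.0)) + \
            np.exp(wfpt_log_density(ts, "reject", p, cell, outlier_prob=0.0))
        assert np.trapezoid(dens, ts) == pytest.approx(1.0, abs=1e-4)

    def test_zero_drift_symmetric_split(self):
        ts = np.linspace(1e-4, 60, 200001)
        f = _wfpt_density(ts, True, 0.0, 1.5, 0.5)
        assert np.trapezoid(f, ts) == pytest.approx(0.5, abs=1e-4)

    def test_accept_mass_equals_crossing_probability(self):
        for v, a, z in [(0.8, 1.2, 0.5), (-0.5, 2.0, 0.3), (1.5, 1.0, 0.7)]:
            ts = np.linspace(1e-5, 60, 200001)
            mass = np.trapezoid(_wfpt_density(ts, True, v, a, z), ts)
            assert mass == pytest.approx(accept_probability(v, a, z), abs=1e-4)

    def test_rt_before_nondecision_time(self):
        p = DDMParameters(a=1.2, z=0.5, t=0.5, v0=1.0)
        cell = OfferCell.from_levels(6, 0.38)
        assert wfpt_log_density(0.3, "accept", p, cell, outlier_prob=0.0) == -np.inf
        # with outlier mixture the same RT has finite log density
        assert np.isfinite(wfpt_log_density(0.3, "accept", p, cell, outlier_prob=0.05))

    def test_density_matches_simulated_distribution(self):
        # Kolmogorov-Smirnov distance between analytic accept-side CDF and
        # 1e5 simulated first passages
        v, a, z, t = 0.8, 1.2, 0.5, 0.3
        rng = np.random.default_rng(0)
        acc, rt = simulate_first_passage_batch(np.full(100_000, v), a, z, t, 1.0,
                                               rng, dt=1e-3)
        td = np.linspace(1e-4, 30, 60001)
        f = _wfpt_density(td, True, v, a, z)
        cdf = np.concatenate([[0.0], np.cumsum((f[1:] + f[:-1]) / 2 * np.diff(td))])
        cdf /= cdf[-1]
        x = np.sort(rt[acc] - t)
        emp = np.arange(1, x.size + 1) / x.size
        model = np.interp(x, td, cdf)
        ks = np.abs(emp - model).max()
        assert ks < 0.01


class TestSimulator:
    def test_symmetric_at_zero_drift(self):
        rng = np.random.default_rng(1)
        acc, _ = simulate_first_passage_batch(np.zeros(100_000), 1.6, 0.5, 0.2,
                                              1.0, rng, dt=1e-3)
        se = np.sqrt(0.25 / 100_000)
        assert abs(acc.mean() - 0.5) < 3 * se

    def test_rt_never_below_nondecision_time(self):
        rng = np.random.default_rng(2)
        _, rt = simulate_first_passage_batch(np.full(2000, 1.0), 1.2, 0.5, 0.4,
                                             1.0, rng, dt=1e-3)
        assert rt.min() >= 0.4

    def test_single_trial_interface(self):
        p = DDMParameters(a=1.5, z=0.5, t=0.3, v0=1.0)
        choice, rt = simulate_first_passage(p, OfferCell.from_levels(9, 0.24),
                                            rng=np.random.default_rng(3))
        assert choice in ("accept", "reject")
        assert rt >= p.t

    def test_matches_crossing_probability_with_bias(self):
        # the exact boundary-hit probability holds for any starting fraction
        rng = np.random.default_rng(4)
        for z in (0.3, 0.7):
            acc, _ = simulate_first_passage_batch(np.full(40_000, 0.6), 1.5, z,
                                                  0.0, 1.0, rng, dt=1e-3)
            p = accept_probability(0.6, 1.5, z)
            assert abs(acc.mean() - p) < 3 * np.sqrt(p * (1 - p) / 40_000)

    def test_reward_monotone_acceptance_on_grid(self):
        # with positive reward weight, predicted acceptance never decreases
        # with reward on the default 6x6 grid (recovery-default parameters)
        p = DDMParameters(a=2.0, v0=0.3, vr=1.8, ve=2.0, vre=0.3)
        for eff in (0.10, 0.38, 0.80):
            ar = [predict_acceptance_rate(
                drift_rate(p, OfferCell.from_levels(r, eff)), p.a / 2)
                for r in (1, 3, 6, 9, 12, 15)]
            assert np.all(np.diff(ar) >= 0)
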