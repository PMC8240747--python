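"""Tests for the hierarchical sampler, diagnostics and posterior checks."""

import numpy as np
import pandas as pd
import pytest

from effortddm.ddm_core import PARAM_NAMES, predict_acceptance_rate
from effortddm.errors import ConfigurationError, DataError
from effortddm.hierarchical_fit import (FitConfig, GroupPrior,
                                        PosteriorSamples, _from_trans,
                                        _run_chain, _to_trans,
                                        extract_subject_means,
                                        fit_hierarchical, fit_single_subject,
                                        posterior_predictive_check,
                                        posterior_probability, rhat,
                                        simulate_replicate, trials_hash)
from effortddm.preprocessing import exclude_trials
from effortddm.synthetic_cohort import CohortSpec, TaskDesign, simulate_cohort


@pytest.fixture(scope="module")
def fitted_small():
    """6-subject cohort with a short 2-chain fit, shared across tests.

    Generating means put the reward weight far above the effort weight on
    standardized regressor scales (vr*sd_r = 0.96 vs ve*sd_e = 0.11), which
    the contrast tests rely on.
    """
    means = _means(a=2.0, z=0.5, t=0.3, v0=0.3, vr=3.0, ve=0.5, vre=0.2)
    trials, covs = simulate_cohort(
        CohortSpec(n_participants=6, seed=21, group_means=means))
    flagged, _ = exclude_trials(trials)
    cfg = FitConfig(n_chains=2, n_samples=700, n_burn_in=300, seed=13)
    samples = fit_hierarchical(flagged, cfg)
    return trials, flagged, covs, samples


def _degenerate_samples(theta_by_subject: np.ndarray, subject_ids, trials,
                        n_draws=40, n_chains=2) -> PosteriorSamples:
    """All posterior mass on a single parameter point (for constructed checks)."""
    sub_t = np.tile(_to_trans(theta_by_subject)[None, None, :, :],
                    (n_chains, n_draws, 1, 1))
    return PosteriorSamples(
        subject_ids=list(subject_ids), subject_t=sub_t,
        group_mean_t=sub_t.mean(axis=2), group_sd_t=np.full_like(sub_t.mean(axis=2), 0.1),
        metadata={"config": FitConfig(n_chains=n_chains, n_samples=n_draws,
                                      n_burn_in=0, seed=0),
                  "data_hash": trials_hash(trials)})


class TestConfig:
    def test_burn_in_validation(self):
        with pytest.raises(ConfigurationError):
            FitConfig(n_samples=100, n_burn_in=100)

    def test_default_fidelity(self):
        cfg = FitConfig()
        assert (cfg.n_chains, cfg.n_samples, cfg.n_burn_in) == (6, 10_000, 1000)
        assert cfg.outlier_prob == 0.05 and cfg.noise_c == 1.0


class TestSamplerValidity:
    def test_conjugate_reduction_matches_closed_form(self):
        # replace the trial likelihood with a normal toy target on v0:
        # y_j ~ N(v0, 1), prior v0 ~ N(0, 2)  ->  known posterior
        rng = np.random.default_rng(0)
        y = rng.normal(1.2, 1.0, 25)

        def toy_loglik(sub, theta_t):
            return float(-0.5 * np.sum((y - theta_t[3]) ** 2))

        cfg = FitConfig(n_chains=1, n_samples=6000, n_burn_in=1000, seed=3)
        sub_draws, _, _ = _run_chain([{"pid": "s1"}], cfg, GroupPrior(),
                                     np.random.default_rng(5), hierarchical=False,
                                     loglik_fn=toy_loglik)
        draws = sub_draws[:, 0, 3]
        prec = 25 + 1 / 2.0**2
        post_mean = y.sum() / prec
        post_sd = 1 / np.sqrt(prec)
        mc_se = post_sd / np.sqrt(200)  # conservative ESS for a random walk
        assert draws.mean() == pytest.approx(post_mean, abs=4 * mc_se)
        assert draws.std() == pytest.approx(post_sd, rel=0.15)

    def test_seed_determinism(self):
        trials, _ = simulate_cohort(CohortSpec(n_participants=3, seed=33))
        cfg = FitConfig(n_chains=2, n_samples=120, n_burn_in=50, seed=11)
        s1 = fit_hierarchical(trials, cfg)
        s2 = fit_hierarchical(trials, cfg)
        assert np.array_equal(s1.subject_t, s2.subject_t)
        assert np.array_equal(s1.group_mean_t, s2.group_mean_t)

    def test_draws_respect_supports(self, fitted_small):
        *_, samples = fitted_small
        nat = samples.subject_natural
        assert (nat[..., 0] > 0).all()          # a
        assert ((nat[..., 1] > 0) & (nat[..., 1] < 1)).all()  # z
        assert (nat[..., 2] >= 0).all()         # t

    def test_kept_draw_count(self, fitted_small):
        *_, samples = fitted_small
        cfg = samples.metadata["config"]
        assert samples.subject_t.shape[:2] == (cfg.n_chains, cfg.n_kept)

    def test_needs_two_participants(self):
        trials, _ = simulate_cohort(CohortSpec(n_participants=1, seed=1))
        with pytest.raises(DataError):
            fit_hierarchical(trials, FitConfig(n_chains=1, n_samples=20,
                                               n_burn_in=10))

    def test_prior_predictive_spans_decision_space(self):
        # parameters drawn from the priors produce acceptance rates covering
        # nearly the whole unit interval -- the priors are not degenerate
        rng = np.random.default_rng(7)
        priors = GroupPrior()
        ars = []
        for _ in range(200):
            theta_t = rng.normal(priors.loc_array(), priors.scale_array())
            th = _from_trans(theta_t)
            v = th[3] + th[4] * 0.5 - th[5] * 0.25 - th[6] * 0.125
            ars.append(predict_acceptance_rate(v, th[0] / 2))
        assert min(ars) < 0.05 and max(ars) > 0.95


class TestSingleSubject:
    def test_flat_data_smoke(self):
        # all-accept, uniformly fast data: degenerate but must stay finite
        rng = np.random.default_rng(2)
        trials = pd.DataFrame({
            "participant_id": "p001", "block": 1,
            "trial_index": np.arange(1, 61),
            "reward": np.tile([1, 3, 6, 9, 12, 15], 10),
            "effort": np.tile([0.10, 0.24, 0.38, 0.52, 0.66, 0.80], 10),
            "choice": "accept", "rt": rng.uniform(0.5, 0.8, 60),
            "exempt": False})
        cfg = FitConfig(n_chains=1, n_samples=400, n_burn_in=150, seed=9)
        samples = fit_single_subject(trials, cfg)
        nat = samples.subject_natural
        assert np.isfinite(nat).all()
        # posterior mass on positive net drift: mean drift over offers > 0
        v = nat[..., 3] + nat[..., 4] * 0.5 - nat[..., 5] * 0.25 \
            - nat[..., 6] * 0.125
        assert v.mean() > 0

    def test_extreme_subject_ordered_correctly(self):
        base = dict(a=2.0, z=0.5, t=0.3, vr=1.0, ve=1.0, vre=0.2)
        frames = []
        for pid, v0 in [("slow", -0.5), ("avg", 0.3), ("fast", 2.0)]:
            spec = CohortSpec(
                n_participants=1, seed=5,
                group_means=_means(v0=v0, **base),
                group_sds={k: 0.0 for k in PARAM_NAMES},
                effect_aes_on_v0=0, effect_aes_on_vr=0, effect_bdi_on_a=0)
            t, _ = simulate_cohort(spec)
            frames.append(t.assign(participant_id=pid))
        cfg = FitConfig(n_chains=1, n_samples=500, n_burn_in=200, seed=4)
        means = {}
        for pid, frame in zip(["slow", "avg", "fast"], frames):
            s = fit_single_subject(frame, cfg)
            means[pid] = extract_subject_means(s)["v0"].iloc[0]
        assert means["slow"] < means["avg"] < means["fast"]

    def test_rejects_multiple_participants(self, fitted_small):
        trials, *_ = fitted_small
        with pytest.raises(DataError):
            fit_single_subject(trials, FitConfig(n_chains=1, n_samples=20,
                                                 n_burn_in=5))


class TestRhat:
    def _manual_samples(self, chains):
        arr = np.asarray(chains)[:, :, None, None]
        arr = np.repeat(arr, 7, axis=3)
        return PosteriorSamples(subject_ids=["p001"], subject_t=arr,
                                group_mean_t=arr[:, :, 0, :],
                                group_sd_t=np.abs(arr[:, :, 0, :]) + 1.0,
                                metadata={})

    def test_identical_chains_give_unity(self):
        # split-chain R-hat of exact copies is unity up to the small-sample
        # correction of the rank-normalized estimator
        rng = np.random.default_rng(0)
        c = rng.normal(size=500)
        report = rhat(self._manual_samples([c, c]))
        assert report.table["rhat"].max() == pytest.approx(1.0, abs=0.01)

    def test_iid_chains_below_1_05(self):
        rng = np.random.default_rng(1)
        report = rhat(self._manual_samples(rng.normal(size=(3, 1000))))
        assert report.max_rhat < 1.05

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(2)
        c1 = rng.normal(0, 1, 500)
        c2 = rng.normal(5, 1, 500)
        report = rhat(self._manual_samples([c1, c2]))
        assert report.max_rhat > 1.5
        assert len(report.flagged) > 0

    def test_single_chain_unavailable(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ConfigurationError):
            rhat(self._manual_samples(rng.normal(size=(1, 100))))


class TestPosteriorProbability:
    def test_self_contrast_is_zero(self, fitted_small):
        *_, samples = fitted_small
        assert posterior_probability(samples, "vr > vr") == 0.0

    def test_tautology_is_one(self, fitted_small):
        *_, samples = fitted_small
        assert posterior_probability(samples, "v0 > -inf") == 1.0

    def test_reward_dominates_effort_on_standardized_scale(self, fitted_small):
        # the fixture cohort is generated with vr*sd(r) >> ve*sd(e)
        *_, samples = fitted_small
        design = TaskDesign()
        r = np.array([x / 15 for x in design.reward_levels] * 6)
        e = np.repeat([x**2 for x in design.effort_levels], 6)
        p = posterior_probability(samples, "vr > ve",
                                  scales={"vr": r.std(), "ve": e.std()})
        assert p > 0.99

    def test_unknown_parameter_rejected(self, fitted_small):
        *_, samples = fitted_small
        with pytest.raises(DataError):
            posterior_probability(samples, "v9 > 0")


class TestSubjectMeans:
    def test_row_count_and_columns(self, fitted_small):
        *_, samples = fitted_small
        table = extract_subject_means(samples)
        assert len(table) == 6
        assert list(table.columns) == ["participant_id", *PARAM_NAMES]

    def test_degenerate_posterior_returns_the_draw(self):
        theta = np.array([[2.0, 0.5, 0.3, 0.4, 1.5, 1.8, 0.2]])
        trials = pd.DataFrame({"participant_id": ["p001"], "reward": [6],
                               "effort": [0.38], "choice": ["accept"],
                               "rt": [1.0]})
        s = _degenerate_samples(theta, ["p001"], trials)
        means = extract_subject_means(s)
        assert means.iloc[0][list(PARAM_NAMES)].to_numpy(float) == \
            pytest.approx(theta[0], rel=1e-9)


class TestPPC:
    def test_replicate_schema_and_size(self, fitted_small):
        trials, flagged, _, samples = fitted_small
        rep = simulate_replicate(samples, flagged, TaskDesign(), (0, 5),
                                 np.random.default_rng(0))
        kept = flagged.loc[~flagged["excluded"]]
        assert list(rep.columns) == list(kept.columns)
        assert len(rep) == len(kept)
        assert set(rep["choice"]) <= {"accept", "reject"}

    def test_well_specified_fit_covers_acceptance(self, fitted_small):
        trials, flagged, _, samples = fitted_small
        ppc = posterior_predictive_check(samples, flagged, n_replicates=40,
                                         seed=1)
        assert ppc.acceptance_coverage >= 0.85

    def test_misspecified_bias_is_flagged(self, fitted_small):
        # same subjects but posterior mass forced to z = 0.9: replicates
        # accept far too often, so observed acceptance falls outside the
        # predictive intervals in many cells
        trials, flagged, covs, samples = fitted_small
        theta = extract_subject_means(samples)[list(PARAM_NAMES)].to_numpy()
        theta[:, 1] = 0.9
        bad = _degenerate_samples(theta, samples.subject_ids, flagged)
        ppc = posterior_predictive_check(bad, flagged, n_replicates=40, seed=2)
        assert ppc.acceptance_coverage < 0.5

    def test_mismatched_data_rejected(self, fitted_small):
        trials, flagged, _, samples = fitted_small
        other = flagged.copy()
        other.loc[other.index[0], "rt"] += 1.0
        with pytest.raises(DataError):
            posterior_predictive_check(samples, other, n_replicates=2)


def _means(**kw):
    from effortddm.ddm_core import DDMParameters
    return DDMParameters(**kw)
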