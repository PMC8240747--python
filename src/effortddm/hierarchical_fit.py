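"""Hierarchical Bayesian estimation of the seven-parameter DDM.

Each subject has parameters (a, z, t, v0, vr, ve, vre); a, z and t are fixed
across conditions while the drift rate varies with the offer.  Subject
parameters are modelled as exchangeable Gaussian draws around group means in
an unconstrained space (log a, logit z, log t, raw drift weights), with
half-normal priors on the group SDs and weakly-informative normal priors on
the group means centred on literature-typical values (a ~ 2, t ~ 0.3 s,
z ~ 0.5, drift components ~ 0).

Sampling is adaptive Metropolis-within-Gibbs: per subject, block random-walk
updates of (a, z, t) and of the four drift weights against the Wiener
first-passage likelihood (with a fixed-probability uniform outlier mixture);
then a conjugate Gibbs update of each group mean and a Metropolis update of
each group SD.  Proposal scales adapt only during burn-in, preserving
detailed balance afterwards.  Everything is reproducible from the config
seed.

Convergence is assessed with split-R-hat and effective sample size (via
arviz); posterior predictive checks compare observed per-cell acceptance
rates and RT quantiles with replicate datasets simulated from posterior
draws.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .ddm_core import PARAM_NAMES, _wfpt_density, accept_probability, wfpt_trial_loglik
from .errors import ConfigurationError, DataError, NumericalError
from .synthetic_cohort import TaskDesign

__all__ = [
    "FitConfig",
    "GroupPrior",
    "PosteriorSamples",
    "ConvergenceReport",
    "PPCReport",
    "fit_hierarchical",
    "fit_single_subject",
    "fit_subjects_map",
    "rhat",
    "posterior_probability",
    "posterior_predictive_check",
    "extract_subject_means",
    "simulate_replicate",
]

logger = logging.getLogger(__name__)

_STRUCT_BLOCK = np.array([0, 1, 2])   # a, z, t
_DRIFT_BLOCK = np.array([3, 4, 5, 6])  # v0, vr, ve, vre


@dataclass(frozen=True)
class FitConfig:
    """MCMC configuration.

    Defaults mirror the reference fitting setup: six chains of 10 000
    samples, the first 1000 discarded as burn-in, a 5% outlier mixture and
    unit diffusion noise.  Scale these down for recovery experiments.
    """

    n_chains: int = 6
    n_samples: int = 10_000
    n_burn_in: int = 1000
    outlier_prob: float = 0.05
    noise_c: float = 1.0
    rt_range: tuple = (0.0, 10.0)
    thinning: int = 1
    target_accept: float = 0.3
    adapt_scale: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ConfigurationError("n_chains must be >= 1")
        if not (0 <= self.n_burn_in < self.n_samples):
            raise ConfigurationError("need 0 <= n_burn_in < n_samples")
        if not (0 <= self.outlier_prob < 1):
            raise ConfigurationError("outlier_prob must lie in [0, 1)")
        if self.noise_c <= 0:
            raise ConfigurationError("noise_c must be > 0")
        if self.thinning < 1:
            raise ConfigurationError("thinning must be >= 1")

    @property
    def n_kept(self) -> int:
        return (self.n_samples - self.n_burn_in) // self.thinning


def _to_trans(theta_nat: np.ndarray) -> np.ndarray:
    out = np.array(theta_nat, dtype=float, copy=True)
    out[..., 0] = np.log(theta_nat[..., 0])
    out[..., 1] = logit(theta_nat[..., 1])
    out[..., 2] = np.log(np.maximum(theta_nat[..., 2], 1e-6))
    return out


def _from_trans(theta_t: np.ndarray) -> np.ndarray:
    out = np.array(theta_t, dtype=float, copy=True)
    out[..., 0] = np.exp(theta_t[..., 0])
    out[..., 1] = expit(theta_t[..., 1])
    out[..., 2] = np.exp(theta_t[..., 2])
    return out


@dataclass(frozen=True)
class GroupPrior:
    """Priors on group means and SDs in the unconstrained space.

    ``mean_loc`` / ``mean_scale`` give the normal prior on each group mean
    (log scale for a and t, logit scale for z); ``sd_scale`` the half-normal
    scale of each group SD.  For single-subject fits the mean prior is used
    directly as the (fixed) subject prior.
    """

    mean_loc: dict = field(default_factory=lambda: {
        "a": float(np.log(2.0)), "z": 0.0, "t": float(np.log(0.3)),
        "v0": 0.0, "vr": 0.0, "ve": 0.0, "vre": 0.0})
    mean_scale: dict = field(default_factory=lambda: {
        "a": 0.5, "z": 0.5, "t": 0.5, "v0": 2.0, "vr": 2.0, "ve": 2.0, "vre": 1.0})
    sd_scale: dict = field(default_factory=lambda: {
        "a": 0.5, "z": 0.5, "t": 0.5, "v0": 1.0, "vr": 1.0, "ve": 1.0, "vre": 0.5})

    def __post_init__(self) -> None:
        for d in (self.mean_loc, self.mean_scale, self.sd_scale):
            missing = set(PARAM_NAMES) - set(d)
            if missing:
                raise ConfigurationError(f"prior missing parameters {sorted(missing)}")
        if any(self.mean_scale[p] <= 0 or self.sd_scale[p] <= 0 for p in PARAM_NAMES):
            raise ConfigurationError("prior scales must be > 0")

    def loc_array(self) -> np.ndarray:
        return np.array([self.mean_loc[p] for p in PARAM_NAMES])

    def scale_array(self) -> np.ndarray:
        return np.array([self.mean_scale[p] for p in PARAM_NAMES])

    def sd_scale_array(self) -> np.ndarray:
        return np.array([self.sd_scale[p] for p in PARAM_NAMES])


@dataclass
class PosteriorSamples:
    """Post-burn-in MCMC draws with chain structure.

    ``group_mean_t`` / ``group_sd_t`` have shape (chain, draw, 7) in the
    unconstrained space (absent for single-subject fits); ``subject_t`` has
    shape (chain, draw, n_subjects, 7).  Natural-scale views are computed on
    demand.
    """

    subject_ids: list
    subject_t: np.ndarray
    group_mean_t: np.ndarray | None
    group_sd_t: np.ndarray | None
    metadata: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.subject_t.shape[0]

    @property
    def subject_natural(self) -> np.ndarray:
        return _from_trans(self.subject_t)

    def group_mean_natural(self, param: str) -> np.ndarray:
        """Group-location draws mapped back to the natural scale (chain, draw)."""
        if self.group_mean_t is None:
            raise DataError("single-subject fit has no group-level draws")
        j = PARAM_NAMES.index(param)
        x = self.group_mean_t[:, :, j]
        if param == "a" or param == "t":
            return np.exp(x)
        if param == "z":
            return expit(x)
        return x

    def group_arrays(self, include_subjects: bool = False) -> dict:
        """Dict of (chain, draw) arrays, suitable for arviz diagnostics."""
        out = {}
        if self.group_mean_t is not None:
            for j, p in enumerate(PARAM_NAMES):
                out[f"mu_{p}"] = self.group_mean_t[:, :, j]
                out[f"sigma_{p}"] = self.group_sd_t[:, :, j]
        if include_subjects or self.group_mean_t is None:
            for i, sid in enumerate(self.subject_ids):
                for j, p in enumerate(PARAM_NAMES):
                    out[f"{p}[{sid}]"] = self.subject_t[:, :, i, j]
        return out

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format (chain, draw, parameter, value) table of all draws."""
        rows = []
        for name, arr in self.group_arrays(include_subjects=True).items():
            nc, nd = arr.shape
            rows.append(pd.DataFrame({
                "chain": np.repeat(np.arange(nc), nd),
                "draw": np.tile(np.arange(nd), nc),
                "parameter": name,
                "value": arr.reshape(-1)}))
        return pd.concat(rows, ignore_index=True)

    def save(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.8g")


@dataclass(frozen=True)
class ConvergenceReport:
    table: pd.DataFrame
    threshold: float = 1.1

    @property
    def flagged(self) -> pd.DataFrame:
        return self.table.loc[self.table["rhat"] > self.threshold]

    @property
    def max_rhat(self) -> float:
        return float(self.table["rhat"].max())

    def to_dict(self) -> dict:
        return {"threshold": self.threshold, "max_rhat": self.max_rhat,
                "n_flagged": int(len(self.flagged)),
                "parameters": self.table.to_dict(orient="records")}


def trials_hash(trials: pd.DataFrame) -> str:
    """Stable hash of the analysis-relevant trial columns."""
    cols = [c for c in ["participant_id", "reward", "effort", "choice", "rt"]
            if c in trials.columns]
    buf = trials[cols].to_csv(index=False, float_format="%.6f").encode()
    return hashlib.sha256(buf).hexdigest()


def _prepare_subject_data(trials: pd.DataFrame, design: TaskDesign):
    """Split the (included) trial table into per-subject likelihood inputs."""
    df = trials.loc[~trials["excluded"]] if "excluded" in trials.columns else trials
    if df.empty:
        raise DataError("no included trials to fit")
    data = []
    for pid, grp in df.groupby("participant_id", sort=True):
        acc = (grp["choice"] == "accept").to_numpy()
        if acc.all() or (~acc).all():
            logger.warning("participant %s has responses at only one boundary; "
                           "fit may be weakly identified", pid)
        data.append({
            "pid": pid,
            "rt": grp["rt"].to_numpy(float),
            "accept": acc,
            "r_scaled": grp["reward"].to_numpy(float) / design.max_reward,
            "e_scaled": grp["effort"].to_numpy(float) ** 2,
        })
    return data


def _subject_loglik(sub: dict, theta_t: np.ndarray, config: FitConfig) -> float:
    theta_nat = _from_trans(theta_t)
    return wfpt_trial_loglik(sub["rt"], sub["accept"], sub["r_scaled"], sub["e_scaled"],
                             theta_nat, c=config.noise_c,
                             outlier_prob=config.outlier_prob, rt_range=config.rt_range)


def _init_theta(sub: dict, priors: GroupPrior, rng: np.random.Generator,
                config: FitConfig, loglik_fn, max_retries: int = 10) -> np.ndarray:
    base = priors.loc_array().copy()
    if "rt" in sub:
        base[2] = np.log(max(0.5 * float(np.min(sub["rt"])), 1e-3))
    for attempt in range(max_retries):
        theta = base + (0.0 if attempt == 0 else rng.normal(0, 0.2, base.size))
        if np.isfinite(loglik_fn(sub, theta)):
            return theta
    raise NumericalError(f"could not initialize participant {sub['pid']} "
                         f"with finite likelihood after {max_retries} attempts")


def _run_chain(data, config: FitConfig, priors: GroupPrior,
               rng: np.random.Generator, hierarchical: bool,
               loglik_fn=None):
    """One adaptive Metropolis-within-Gibbs chain.

    ``loglik_fn(sub, theta_t)`` may replace the Wiener likelihood (used by
    the conjugate-reduction validity tests); it receives the unconstrained
    parameter vector.
    """
    if loglik_fn is None:
        def loglik_fn(sub, th):
            return _subject_loglik(sub, th, config)

    n_sub = len(data)
    m0, s0 = priors.loc_array(), priors.scale_array()
    hn = priors.sd_scale_array()

    theta = np.stack([_init_theta(sub, priors, rng, config, loglik_fn)
                      for sub in data])
    if hierarchical:
        mu = theta.mean(axis=0) + rng.normal(0, 0.05, 7)
        sigma = np.maximum(theta.std(axis=0), 0.1)
    else:
        mu, sigma = m0.copy(), s0.copy()

    cur_ll = np.array([loglik_fn(sub, theta[i]) for i, sub in enumerate(data)])
    # the drift block is the slow-mixing direction; sweep it twice per
    # iteration (separate adapted scales per sweep)
    blocks = (_STRUCT_BLOCK, _DRIFT_BLOCK, _DRIFT_BLOCK)
    # the drift weights are strongly collinear through the offer regressors;
    # precondition their block proposal with the inverse Gram matrix of the
    # per-trial drift design [1, r, -e, -r*e] so proposals move along the
    # posterior's long axes
    transforms = []
    for sub in data:
        T = [np.eye(3), np.eye(4), np.eye(4)]
        if "r_scaled" in sub:
            r, e = sub["r_scaled"], sub["e_scaled"]
            G = np.column_stack([np.ones_like(r), r, -e, -r * e])
            C = np.linalg.inv(G.T @ G / len(r) + 1e-8 * np.eye(4))
            C /= np.trace(C) / 4.0
            T[1] = T[2] = np.linalg.cholesky(C)
        transforms.append(T)
    scales = np.full((n_sub, len(blocks)), config.adapt_scale)
    sigma_scales = np.full(7, 0.2)
    asis_scales = np.full(7, 0.3)

    n_kept = config.n_kept
    sub_draws = np.empty((n_kept, n_sub, 7))
    mu_draws = np.empty((n_kept, 7)) if hierarchical else None
    sigma_draws = np.empty((n_kept, 7)) if hierarchical else None

    kept = 0
    for it in range(config.n_samples):
        adapting = it < config.n_burn_in
        delta = min(0.05, 2.0 / np.sqrt(it + 1.0)) if adapting else 0.0

        for i, sub in enumerate(data):
            for b, idx in enumerate(blocks):
                prop = theta[i].copy()
                prop[idx] += scales[i, b] * (transforms[i][b]
                                             @ rng.standard_normal(idx.size))
                ll_new = loglik_fn(sub, prop)
                lp_new = np.sum(-0.5 * ((prop - mu) / sigma) ** 2)
                lp_old = np.sum(-0.5 * ((theta[i] - mu) / sigma) ** 2)
                log_r = (ll_new + lp_new) - (cur_ll[i] + lp_old)
                accepted = np.log(rng.random()) < log_r
                if accepted:
                    theta[i] = prop
                    cur_ll[i] = ll_new
                if adapting:
                    scales[i, b] *= np.exp(delta * ((1.0 if accepted else 0.0)
                                                    - config.target_accept))

        if hierarchical:
            # conjugate Gibbs for each group mean
            var_post = 1.0 / (1.0 / s0**2 + n_sub / sigma**2)
            mean_post = var_post * (m0 / s0**2 + theta.sum(axis=0) / sigma**2)
            mu = mean_post + np.sqrt(var_post) * rng.standard_normal(7)
            # Metropolis on log group SDs (half-normal prior, log-scale proposal)
            for j in range(7):
                prop_s = sigma[j] * np.exp(sigma_scales[j] * rng.standard_normal())
                dev = theta[:, j] - mu[j]

                def _sd_target(s):
                    return (-n_sub * np.log(s) - np.sum(dev**2) / (2 * s**2)
                            - s**2 / (2 * hn[j]**2) + np.log(s))

                accepted = np.log(rng.random()) < _sd_target(prop_s) - _sd_target(sigma[j])
                if accepted:
                    sigma[j] = prop_s
                if adapting:
                    sigma_scales[j] *= np.exp(delta * ((1.0 if accepted else 0.0)
                                                       - config.target_accept))

        if hierarchical:
            # ancillarity (rescaling) move: jointly scale one group SD and
            # all subject deviations around the group mean.  This traverses
            # the funnel between a weakly identified subject parameter and
            # its group SD, which per-coordinate moves cross very slowly.
            # One parameter per iteration keeps the cost at n_sub extra
            # likelihood evaluations; only the drift weights need it (the
            # structural parameters are strongly identified by the data).
            j = 3 + it % 4
            k = float(np.exp(asis_scales[j] * rng.standard_normal()))
            theta_prop = theta.copy()
            theta_prop[:, j] = mu[j] + k * (theta[:, j] - mu[j])
            ll_new = np.array([loglik_fn(sub, theta_prop[i])
                               for i, sub in enumerate(data)])
            # normal-population terms cancel against the Jacobian up to k
            log_alpha = (np.sum(ll_new - cur_ll)
                         - (k**2 - 1.0) * sigma[j]**2 / (2 * hn[j]**2)
                         + np.log(k))
            accepted = np.log(rng.random()) < log_alpha
            if accepted:
                theta = theta_prop
                cur_ll = ll_new
                sigma[j] *= k
            if adapting:
                asis_scales[j] *= np.exp(delta * ((1.0 if accepted else 0.0)
                                                  - config.target_accept))

        if it >= config.n_burn_in and (it - config.n_burn_in) % config.thinning == 0:
            if kept < n_kept:
                sub_draws[kept] = theta
                if hierarchical:
                    mu_draws[kept] = mu
                    sigma_draws[kept] = sigma
                kept += 1

    return sub_draws[:kept], (mu_draws[:kept] if hierarchical else None), \
        (sigma_draws[:kept] if hierarchical else None)


def _fit(trials, config, priors, design, hierarchical, loglik_fn=None) -> PosteriorSamples:
    design = design or TaskDesign()
    priors = priors or GroupPrior()
    data = _prepare_subject_data(trials, design)
    if hierarchical and len(data) < 2:
        raise DataError("hierarchical fit needs at least 2 participants")

    streams = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    subs, mus, sigmas = [], [], []
    for c, stream in enumerate(streams):
        s, m, g = _run_chain(data, config, priors, np.random.default_rng(stream),
                             hierarchical, loglik_fn=loglik_fn)
        logger.info("chain %d finished: %d kept draws", c, s.shape[0])
        subs.append(s)
        mus.append(m)
        sigmas.append(g)

    return PosteriorSamples(
        subject_ids=[d["pid"] for d in data],
        subject_t=np.stack(subs),
        group_mean_t=np.stack(mus) if hierarchical else None,
        group_sd_t=np.stack(sigmas) if hierarchical else None,
        metadata={"config": config, "priors": priors, "design": design,
                  "data_hash": trials_hash(trials), "hierarchical": hierarchical,
                  "scaling": {"reward": f"reward / {design.max_reward}",
                              "effort": "squared force fraction"}})


def fit_hierarchical(trials: pd.DataFrame, config: FitConfig | None = None,
                     priors: GroupPrior | None = None,
                     design: TaskDesign | None = None) -> PosteriorSamples:
    """Fit the population model with subject as a hierarchical factor."""
    return _fit(trials, config or FitConfig(), priors, design, hierarchical=True)


def fit_single_subject(trials: pd.DataFrame, config: FitConfig | None = None,
                       priors: GroupPrior | None = None,
                       design: TaskDesign | None = None) -> PosteriorSamples:
    """Fit one subject with the (fixed) group-mean prior as subject prior."""
    if trials["participant_id"].nunique() != 1:
        raise DataError("fit_single_subject expects exactly one participant")
    return _fit(trials, config or FitConfig(), priors, design, hierarchical=False)


def fit_subjects_map(trials: pd.DataFrame, config: FitConfig | None = None,
                     priors: GroupPrior | None = None,
                     design: TaskDesign | None = None) -> pd.DataFrame:
    """Fast per-subject maximum a posteriori estimates (no MCMC).

    Optimizes the penalized likelihood (Wiener likelihood plus the group-mean
    prior, treated as a fixed ridge) per subject in the unconstrained space.
    Used by scaled-down recovery experiments where full posterior inference
    per replicate would be wasteful; returns one row per participant with the
    seven natural-scale parameter estimates.
    """
    config = config or FitConfig()
    priors = priors or GroupPrior()
    design = design or TaskDesign()
    data = _prepare_subject_data(trials, design)
    rows = []
    for sub in data:
        x0 = priors.loc_array().copy()
        x0[2] = np.log(max(0.5 * float(np.min(sub["rt"])), 1e-3))
        loc, scale = priors.loc_array(), priors.scale_array()

        def neg_post(x):
            ll = _subject_loglik(sub, x, config)
            lp = np.sum(-0.5 * ((x - loc) / scale) ** 2)
            return -(ll + lp)

        res = minimize(neg_post, x0, method="L-BFGS-B",
                       options={"maxiter": 500})
        if not (res.success and np.isfinite(res.fun)):
            # simplex fallback for the rare rough-gradient failure
            res = minimize(neg_post, x0, method="Nelder-Mead",
                           options={"maxiter": 4000, "xatol": 1e-5, "fatol": 1e-6})
            res = minimize(neg_post, res.x, method="L-BFGS-B",
                           options={"maxiter": 200})
        if not np.isfinite(res.fun):
            raise NumericalError(f"MAP fit failed for participant {sub['pid']}")
        rows.append({"participant_id": sub["pid"],
                     **dict(zip(PARAM_NAMES, _from_trans(res.x)))})
    return pd.DataFrame(rows)


def rhat(samples: PosteriorSamples, include_subjects: bool = False,
         threshold: float = 1.1) -> ConvergenceReport:
    """Split-R-hat and effective sample size per parameter (via arviz)."""
    import arviz as az

    if samples.n_chains < 2:
        raise ConfigurationError("R-hat requires at least 2 chains")
    arrays = samples.group_arrays(include_subjects=include_subjects)
    ds = az.convert_to_dataset({k: v for k, v in arrays.items()})
    r = az.rhat(ds)
    e = az.ess(ds)
    table = pd.DataFrame({
        "parameter": list(arrays.keys()),
        "rhat": [float(r[k].values) for k in arrays],
        "ess_bulk": [float(e[k].values) for k in arrays],
    })
    table["flagged"] = table["rhat"] > threshold
    return ConvergenceReport(table=table, threshold=threshold)


def posterior_probability(samples: PosteriorSamples, contrast: str,
                          scales: dict | None = None) -> float:
    """Fraction of post-burn-in draws satisfying a group-level contrast.

    ``contrast`` is of the form ``"vr > ve"`` or ``"v0 > 0"`` over the
    natural-scale group means.  Optional ``scales`` multiply named
    parameters before comparison, e.g. by the SDs of the reward and effort
    regressors over the design grid so that weights are compared on
    commensurate scales.
    """
    parts = contrast.split()
    if len(parts) != 3 or parts[1] not in (">", "<"):
        raise DataError(f"cannot parse contrast {contrast!r}; expected 'x > y'")

    def _resolve(tok: str) -> np.ndarray:
        if tok in PARAM_NAMES:
            x = samples.group_mean_natural(tok).reshape(-1)
            if scales and tok in scales:
                x = x * scales[tok]
            return x
        try:
            return np.array(float(tok))
        except ValueError:
            raise DataError(f"unknown parameter {tok!r} in contrast") from None

    left, right = _resolve(parts[0]), _resolve(parts[2])
    sat = left > right if parts[1] == ">" else left < right
    return float(np.mean(sat))


def extract_subject_means(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior-mean natural-scale parameters, one row per participant."""
    means = samples.subject_natural.mean(axis=(0, 1))  # (n_subjects, 7)
    out = pd.DataFrame(means, columns=list(PARAM_NAMES))
    out.insert(0, "participant_id", samples.subject_ids)
    return out


# ---------------------------------------------------------------------------
# Posterior predictive checking
# ---------------------------------------------------------------------------

def _sample_subject_rts(theta_nat: np.ndarray, r_scaled: np.ndarray,
                        e_scaled: np.ndarray, rng: np.random.Generator,
                        c: float, rt_cap: float = 10.0, n_grid: int = 400):
    """Draw (choice, rt) per trial from one subject's analytic DDM.

    Choices come from the exact boundary-hit probability; RTs from the
    marginal first-passage density via grid inverse-CDF per offer cell.
    """
    a, z, t = theta_nat[0], theta_nat[1], theta_nat[2]
    v0, vr, ve, vre = theta_nat[3:]
    cells, inv = np.unique(np.column_stack([r_scaled, e_scaled]), axis=0,
                           return_inverse=True)
    V = v0 + vr * cells[:, 0] - ve * cells[:, 1] - vre * cells[:, 0] * cells[:, 1]
    p_acc = np.atleast_1d(accept_probability(V, a, z, c))

    td = np.linspace(1e-4, rt_cap, n_grid)
    dens = (_wfpt_density(td[None, :], True, V[:, None], a, z, c)
            + _wfpt_density(td[None, :], False, V[:, None], a, z, c))
    cdf = np.concatenate([np.zeros((len(V), 1)),
                          np.cumsum((dens[:, 1:] + dens[:, :-1]) / 2.0
                                    * np.diff(td), axis=1)], axis=1)

    n = r_scaled.size
    accept = rng.random(n) < p_acc[inv]
    u = rng.random(n) * cdf[inv, -1]
    rt = np.empty(n)
    for ci in range(len(V)):
        m = inv == ci
        if np.any(m):
            rt[m] = np.interp(u[m], cdf[ci], td)
    return accept, rt + t


def simulate_replicate(samples: PosteriorSamples, trials: pd.DataFrame,
                       design: TaskDesign, draw: tuple,
                       rng: np.random.Generator, rt_cap: float = 10.0) -> pd.DataFrame:
    """One replicate dataset (same schema and size as the input) from a draw.

    ``draw`` is a (chain, iteration) index into the posterior.
    """
    ch, it = draw
    theta = samples.subject_natural[ch, it]  # (n_subjects, 7)
    c = samples.metadata["config"].noise_c
    df = trials.loc[~trials["excluded"]].copy() if "excluded" in trials.columns \
        else trials.copy()
    for i, pid in enumerate(samples.subject_ids):
        m = df["participant_id"] == pid
        if not m.any():
            continue
        r = df.loc[m, "reward"].to_numpy(float) / design.max_reward
        e = df.loc[m, "effort"].to_numpy(float) ** 2
        acc, rt = _sample_subject_rts(theta[i], r, e, rng, c, rt_cap=rt_cap)
        df.loc[m, "choice"] = np.where(acc, "accept", "reject")
        df.loc[m, "rt"] = rt
    return df


@dataclass(frozen=True)
class PPCReport:
    """Observed vs posterior-predictive per-cell statistics.

    ``acceptance`` has one row per offer cell with the observed pooled
    acceptance rate, the central 95% predictive interval over replicates and
    a coverage flag; ``rt_quantiles`` likewise for the 0.1/0.5/0.9 RT
    quantiles.
    """

    acceptance: pd.DataFrame
    rt_quantiles: pd.DataFrame
    n_replicates: int

    @property
    def acceptance_coverage(self) -> float:
        return float(self.acceptance["covered"].mean())

    @property
    def rt_coverage(self) -> float:
        return float(self.rt_quantiles["covered"].mean())

    def to_dict(self) -> dict:
        return {"n_replicates": self.n_replicates,
                "acceptance_coverage": self.acceptance_coverage,
                "rt_coverage": self.rt_coverage,
                "acceptance": self.acceptance.to_dict(orient="records"),
                "rt_quantiles": self.rt_quantiles.to_dict(orient="records")}


def _cell_stats(df: pd.DataFrame) -> tuple:
    """Per-cell pooled acceptance (subjects weighted equally) and RT quantiles."""
    acc = (df.assign(accept=(df["choice"] == "accept").astype(float))
             .groupby(["participant_id", "reward", "effort"], sort=True)["accept"].mean()
             .groupby(["reward", "effort"]).mean())
    qs = (df.groupby(["reward", "effort"], sort=True)["rt"]
            .quantile([0.1, 0.5, 0.9]).unstack())
    return acc, qs


def posterior_predictive_check(samples: PosteriorSamples, trials: pd.DataFrame,
                               design: TaskDesign | None = None,
                               n_replicates: int = 50,
                               seed: int = 0) -> PPCReport:
    """Simulate replicate datasets from posterior draws and score coverage.

    Raises :class:`DataError` if the trial table does not hash to the one the
    model was fitted on.
    """
    design = design or TaskDesign()
    if trials_hash(trials) != samples.metadata.get("data_hash"):
        raise DataError("trial table does not match the dataset used for fitting")
    rng = np.random.default_rng(seed)
    obs = trials.loc[~trials["excluded"]] if "excluded" in trials.columns else trials
    obs_acc, obs_q = _cell_stats(obs)

    nc, nd = samples.subject_t.shape[:2]
    draws = [(int(rng.integers(nc)), int(rng.integers(nd)))
             for _ in range(n_replicates)]
    rep_acc, rep_q = [], []
    for dr in draws:
        rep = simulate_replicate(samples, trials, design, dr, rng)
        a, q = _cell_stats(rep)
        rep_acc.append(a)
        rep_q.append(q)
    rep_acc = pd.concat(rep_acc, axis=1)
    lo_a, hi_a = rep_acc.quantile(0.025, axis=1), rep_acc.quantile(0.975, axis=1)

    acc_tab = pd.DataFrame({"observed": obs_acc, "lo": lo_a, "hi": hi_a})
    acc_tab["covered"] = (acc_tab["observed"] >= acc_tab["lo"]) & \
        (acc_tab["observed"] <= acc_tab["hi"])
    acc_tab = acc_tab.reset_index()

    q_rows = []
    for q in (0.1, 0.5, 0.9):
        stack = pd.concat([r[q] for r in rep_q], axis=1)
        lo, hi = stack.quantile(0.025, axis=1), stack.quantile(0.975, axis=1)
        tab = pd.DataFrame({"quantile": q, "observed": obs_q[q], "lo": lo, "hi": hi})
        tab["covered"] = (tab["observed"] >= tab["lo"]) & (tab["observed"] <= tab["hi"])
        q_rows.append(tab.reset_index())
    return PPCReport(acceptance=acc_tab, rt_quantiles=pd.concat(q_rows, ignore_index=True),
                     n_replicates=n_replicates)
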