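"""Mixed-effects logistic models of trial-level accept/reject choices.

The choice model has fixed effects of reward, squared effort (quadratic
effort cost) and apathy -- coded either continuously (AES score) or as the
conventional binary cut-off AES > 34 -- with all interactions among the
three, and a Gaussian random intercept per participant.  The two apathy
codings are compared by BIC.

Estimation is maximum marginal likelihood: the random intercept is
integrated out by Gauss-Hermite quadrature and the marginal likelihood
maximized over the fixed effects and the random-intercept SD, with analytic
gradients.  With the random-intercept variance forced to zero the model
reduces exactly to pooled logistic regression (a tested invariant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .errors import ConfigurationError, DataError, NumericalError

__all__ = ["ChoiceModelSpec", "ModelFit", "fit_mixed_logit", "compare_models"]

logger = logging.getLogger(__name__)

APATHY_CUTOFF = 34.0  # AES > 34 defines the apathetic group in binary coding


@dataclass(frozen=True)
class ChoiceModelSpec:
    """Fixed-effect structure and apathy coding of a choice model."""

    apathy_coding: str = "continuous"   # "continuous" | "binary"
    binary_threshold: float = APATHY_CUTOFF
    standardize: bool = True            # z-score continuous regressors
    squared_effort: bool = True

    def __post_init__(self) -> None:
        if self.apathy_coding not in ("continuous", "binary"):
            raise ConfigurationError("apathy_coding must be 'continuous' or 'binary'")


@dataclass(frozen=True)
class ModelFit:
    """Coefficient table and fit indices of one mixed-logit fit."""

    coefficients: pd.DataFrame
    loglik: float
    bic: float
    n_obs: int
    n_params: int
    sigma_u: float
    converged: bool
    spec: ChoiceModelSpec
    notes: tuple = field(default=())

    def term(self, name: str) -> pd.Series:
        row = self.coefficients.loc[self.coefficients["term"] == name]
        if row.empty:
            raise DataError(f"no term named {name!r}; have "
                            f"{list(self.coefficients['term'])}")
        return row.iloc[0]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise DataError("cannot standardize a constant regressor")
    return (x - x.mean()) / sd


def build_design(trials: pd.DataFrame, covariates: pd.DataFrame,
                 spec: ChoiceModelSpec):
    """Assemble (y, X, term names, subject index) for the choice model."""
    df = trials.loc[~trials["excluded"]] if "excluded" in trials.columns else trials
    df = df.merge(covariates[["participant_id", "aes"]], on="participant_id",
                  how="left", validate="many_to_one")
    if df["aes"].isna().any():
        missing = df.loc[df["aes"].isna(), "participant_id"].unique()
        raise DataError(f"participants missing AES scores: {list(missing)[:5]}")
    df = df.sort_values(["participant_id", "trial_index"], kind="stable")

    y = (df["choice"] == "accept").to_numpy(float)
    rew = df["reward"].to_numpy(float)
    eff = df["effort"].to_numpy(float)
    eff = eff**2 if spec.squared_effort else eff
    if spec.apathy_coding == "continuous":
        ap = df["aes"].to_numpy(float)
        ap = _zscore(ap) if spec.standardize else ap
    else:
        ap = (df["aes"].to_numpy(float) > spec.binary_threshold).astype(float)
    if spec.standardize:
        rew, eff = _zscore(rew), _zscore(eff)

    cols = {"intercept": np.ones_like(y), "reward": rew, "effort": eff,
            "apathy": ap, "reward:effort": rew * eff, "reward:apathy": rew * ap,
            "effort:apathy": eff * ap, "reward:effort:apathy": rew * eff * ap}
    X = np.column_stack(list(cols.values()))
    subj = pd.factorize(df["participant_id"].to_numpy())[0]
    return y, X, list(cols.keys()), subj


def _marginal_loglik_and_grad(params: np.ndarray, y, X, starts, nodes, logw,
                              sigma_fixed: float | None):
    """Marginal log likelihood (and gradient) after GH integration.

    ``params`` is (beta..., log sigma) unless ``sigma_fixed`` is given, in
    which case it is just beta.  ``starts`` are the first row of each
    subject in the (subject-sorted) data.
    """
    p = X.shape[1]
    beta = params[:p]
    sigma = np.exp(params[p]) if sigma_fixed is None else sigma_fixed
    eta0 = X @ beta
    offs = np.sqrt(2.0) * sigma * nodes           # (Q,)
    eta = eta0[None, :] + offs[:, None]           # (Q, n)
    lp = y[None, :] * eta - np.logaddexp(0.0, eta)
    s = np.add.reduceat(lp, starts, axis=1)       # (Q, I)
    li = logsumexp(logw[:, None] + s, axis=0)     # (I,)
    ll = float(np.sum(li))

    # posterior node weights per subject, expanded to observations
    W = np.exp(logw[:, None] + s - li[None, :])   # (Q, I)
    n = X.shape[0]
    lengths = np.diff(np.append(starts, n))
    Wobs = np.repeat(W, lengths, axis=1)          # (Q, n)
    R = Wobs * (y[None, :] - expit(eta))
    g_beta = X.T @ R.sum(axis=0)
    if sigma_fixed is None:
        g_logsig = float(np.sum(R.sum(axis=1) * offs))  # d eta / d log sigma = offs
        grad = np.append(g_beta, g_logsig)
    else:
        grad = g_beta
    return -ll, -grad


def fit_mixed_logit(trials: pd.DataFrame, covariates: pd.DataFrame,
                    spec: ChoiceModelSpec | None = None, n_quad: int = 15,
                    sigma_fixed: float | None = None,
                    ridge: float = 0.0) -> ModelFit:
    """Fit the random-intercept logistic choice model.

    ``sigma_fixed`` pins the random-intercept SD (0 reduces the model to
    pooled logistic regression).  On suspected complete separation the model
    is refitted with a small ridge penalty and flagged, never silently.
    """
    spec = spec or ChoiceModelSpec()
    y, X, names, subj = build_design(trials, covariates, spec)
    if len(np.unique(subj)) < 2:
        raise DataError("mixed model needs at least 2 participants")
    starts = np.flatnonzero(np.diff(np.append(-1, subj)))
    gh_x, gh_w = np.polynomial.hermite.hermgauss(n_quad)
    logw = np.log(gh_w) - 0.5 * np.log(np.pi)

    p = X.shape[1]
    x0 = np.zeros(p + (0 if sigma_fixed is not None else 1))
    if sigma_fixed is None:
        x0[p - 1 + 1] = np.log(0.5)

    def obj(params):
        nll, ng = _marginal_loglik_and_grad(params, y, X, starts, gh_x, logw,
                                            sigma_fixed)
        if ridge > 0:
            nll = nll + 0.5 * ridge * np.sum(params[:p] ** 2)
            ng = ng + np.append(ridge * params[:p], np.zeros(ng.size - p))
        return nll, ng

    res = minimize(obj, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    notes = []
    converged = bool(res.success)
    separated = np.any(np.abs(res.x[:p]) > 15)
    if separated and ridge == 0.0:
        logger.warning("possible complete separation (|beta| > 15); "
                       "refitting with ridge penalty")
        fit = fit_mixed_logit(trials, covariates, spec, n_quad=n_quad,
                              sigma_fixed=sigma_fixed, ridge=1e-3)
        return ModelFit(**{**fit.__dict__,
                           "notes": fit.notes + ("separation_fallback",)})
    if not converged:
        notes.append("optimizer_not_converged")

    nll, _ = _marginal_loglik_and_grad(res.x, y, X, starts, gh_x, logw, sigma_fixed)
    ll = -nll
    n_obs = len(y)
    k = res.x.size
    bic = -2.0 * ll + k * np.log(n_obs)

    # observed-information SEs from a central-difference Hessian of the
    # (unpenalized) negative log likelihood
    hess = _numeric_hessian(
        lambda v: _marginal_loglik_and_grad(v, y, X, starts, gh_x, logw,
                                            sigma_fixed)[1], res.x)
    try:
        cov = np.linalg.inv(0.5 * (hess + hess.T))
        se = np.sqrt(np.maximum(np.diag(cov)[:p], 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        notes.append("singular_information_matrix")
        converged = False
    beta = res.x[:p]
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    fvals = tvals**2
    dof = n_obs - k
    pvals = stats.f.sf(fvals, 1, dof)
    coef = pd.DataFrame({"term": names, "estimate": beta, "se": se,
                         "t": tvals, "F": fvals, "p": pvals, "df_denom": dof})
    sigma_u = float(np.exp(res.x[p])) if sigma_fixed is None else float(sigma_fixed)
    return ModelFit(coefficients=coef, loglik=ll, bic=float(bic), n_obs=n_obs,
                    n_params=k, sigma_u=sigma_u, converged=converged, spec=spec,
                    notes=tuple(notes))


def _numeric_hessian(grad_fn, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    n = x.size
    H = np.empty((n, n))
    for j in range(n):
        step = eps * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += step
        xm[j] -= step
        H[:, j] = (grad_fn(xp) - grad_fn(xm)) / (2 * step)
    return H


def compare_models(fit_continuous: ModelFit, fit_binary: ModelFit) -> dict:
    """BIC comparison of the two apathy codings on identical observations."""
    if fit_continuous.n_obs != fit_binary.n_obs:
        raise DataError(
            f"model comparison needs identical observations "
            f"({fit_continuous.n_obs} vs {fit_binary.n_obs})")
    delta = fit_binary.bic - fit_continuous.bic
    if abs(delta) < 1e-9:
        preferred = "tie"
    else:
        preferred = "continuous" if delta > 0 else "binary"
    return {"bic_continuous": fit_continuous.bic, "bic_binary": fit_binary.bic,
            "delta_bic": float(delta), "preferred": preferred,
            "n_obs": fit_continuous.n_obs}
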