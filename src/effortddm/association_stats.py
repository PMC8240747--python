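"""Robust regressions and correlations linking behaviour to clinical scores.

The analysis suite mirrors the behavioural-association models of the study
design: overall acceptance rate regressed on apathy (AES), alone and
adjusted for depression (BDI), age and cognition; and each of the seven
subject-level DDM parameters regressed on AES, BDI and age.  Point estimates
are ordinary least squares; uncertainty uses heteroscedasticity-consistent
(HC3) sandwich standard errors, with per-term F statistics formed from the
squared robust t.  Pearson correlations relate the clinical measures to one
another.

Missing covariates are handled complete-case, with the number of dropped
rows logged in each result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DataError

__all__ = ["RegressionResult", "AssociationSuiteReport", "robust_regression",
           "pearson_correlation", "run_association_suite"]

logger = logging.getLogger(__name__)

DDM_PARAMS = ("a", "z", "t", "v0", "vr", "ve", "vre")


@dataclass(frozen=True)
class RegressionResult:
    """One fitted model: terms, estimates, robust SEs, per-term F tests."""

    formula: str
    table: pd.DataFrame      # term, estimate, se, t, F, p, df_num, df_denom
    n: int
    df_resid: int
    n_dropped: int = 0

    def term(self, name: str) -> pd.Series:
        row = self.table.loc[self.table["term"] == name]
        if row.empty:
            raise DataError(f"model {self.formula!r} has no term {name!r}")
        return row.iloc[0]


@dataclass(frozen=True)
class AssociationSuiteReport:
    """Ordered regression results plus Pearson correlation records."""

    regressions: list = field(default_factory=list)
    correlations: pd.DataFrame | None = None

    def tidy(self) -> pd.DataFrame:
        """One row per model x term."""
        frames = []
        for r in self.regressions:
            t = r.table.copy()
            t.insert(0, "model", r.formula)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    def result(self, formula: str) -> RegressionResult:
        for r in self.regressions:
            if r.formula == formula:
                return r
        raise DataError(f"no model with formula {formula!r}")


def robust_regression(outcome: str, predictors: list, data: pd.DataFrame,
                      cluster: str | None = None) -> RegressionResult:
    """OLS with HC3 sandwich standard errors (optionally cluster-robust).

    Per-term F(1, df) statistics are the squared robust t statistics.
    Missing rows are dropped complete-case (count recorded); perfectly
    collinear predictors raise :class:`DataError` naming the offenders.
    """
    cols = [outcome] + list(predictors)
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise DataError(f"columns missing from data: {missing}")
    sub = data[cols + ([cluster] if cluster else [])].dropna()
    n_dropped = len(data) - len(sub)
    if n_dropped:
        logger.info("robust_regression(%s): dropped %d incomplete rows",
                    outcome, n_dropped)
    k = len(predictors) + 1
    if len(sub) < k + 2:
        raise DataError(f"only {len(sub)} complete rows for {k + 1} terms")

    X = sm.add_constant(sub[list(predictors)].to_numpy(float))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(sub[list(predictors)].to_numpy(float), rowvar=False)
        pairs = [(predictors[i], predictors[j])
                 for i in range(len(predictors)) for j in range(i + 1, len(predictors))
                 if abs(corr[i, j]) > 0.999999]
        raise DataError(f"rank-deficient design matrix; collinear terms: {pairs}")

    if cluster:
        fit = sm.OLS(sub[outcome].to_numpy(float), X).fit(
            cov_type="cluster", cov_kwds={"groups": sub[cluster]})
    else:
        fit = sm.OLS(sub[outcome].to_numpy(float), X).fit(cov_type="HC3")
    terms = ["intercept"] + list(predictors)
    tvals = fit.params / fit.bse
    fvals = tvals**2
    df_resid = int(fit.df_resid)
    pvals = stats.f.sf(fvals, 1, df_resid)
    table = pd.DataFrame({"term": terms, "estimate": fit.params, "se": fit.bse,
                          "t": tvals, "F": fvals, "p": pvals,
                          "df_num": 1, "df_denom": df_resid})
    formula = f"{outcome} ~ {' + '.join(predictors)}"
    return RegressionResult(formula=formula, table=table.reset_index(drop=True),
                            n=len(sub), df_resid=df_resid, n_dropped=n_dropped)


def pearson_correlation(x, y) -> tuple:
    """Product-moment correlation; returns (r, df, two-sided p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise DataError(f"need at least 3 complete pairs, got {x.size}")
    if x.std() == 0 or y.std() == 0:
        raise DataError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), int(x.size - 2), float(p)


def run_association_suite(subject_params: pd.DataFrame, covariates: pd.DataFrame,
                          acceptance_summary: pd.DataFrame,
                          extra_covariates: list | None = None,
                          bonferroni: bool = False) -> AssociationSuiteReport:
    """Run the full association model set on one cohort.

    Inputs are aligned by ``participant_id``: per-subject parameter estimates
    (columns a, z, t, v0, vr, ve, vre), the covariate table (aes, bdi, age,
    cognition) and per-subject overall acceptance rates (column
    ``acceptance_rate``).  Fits, in order: acceptance ~ AES;
    acceptance ~ AES + BDI + age + cognition; and each DDM parameter ~
    AES + BDI + age (plus any ``extra_covariates`` columns, e.g. disease
    severity).  Also reports the AES-BDI Pearson correlation.  With
    ``bonferroni`` the tidy table gains a suite-wide adjusted p column;
    per-model tests are otherwise reported unadjusted.
    """
    extra = list(extra_covariates or [])
    need = {"aes", "bdi", "age", "cognition"} | set(extra)
    missing = sorted(need - set(covariates.columns))
    if missing:
        raise DataError(f"covariate table missing columns: {missing}")
    for name, df, col in [("subject_params", subject_params, "a"),
                          ("acceptance_summary", acceptance_summary, "acceptance_rate")]:
        if "participant_id" not in df.columns or col not in df.columns:
            raise DataError(f"{name} must have participant_id and {col} columns")

    data = (covariates.merge(acceptance_summary, on="participant_id", validate="one_to_one")
                      .merge(subject_params, on="participant_id", validate="one_to_one"))

    regressions = [
        robust_regression("acceptance_rate", ["aes"] + extra, data),
        robust_regression("acceptance_rate", ["aes", "bdi", "age", "cognition"] + extra, data),
    ]
    for p in DDM_PARAMS:
        regressions.append(robust_regression(p, ["aes", "bdi", "age"] + extra, data))

    r, df, pv = pearson_correlation(data["aes"], data["bdi"])
    correlations = pd.DataFrame([{"pair": "aes~bdi", "r": r, "df": df, "p": pv}])

    report = AssociationSuiteReport(regressions=regressions, correlations=correlations)
    if bonferroni:
        tidy = report.tidy()
        m = (tidy["term"] != "intercept").sum()
        tidy["p_bonferroni"] = np.minimum(tidy["p"] * m, 1.0)
    return report
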