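"""Trial exclusion rules and decision-space summaries.

Two exclusion rules are applied to the raw trial table, in order:

1. trials with reaction time strictly below 0.4 s are discarded as
   accidental responses;
2. per participant, trials with reaction time strictly above that
   participant's mean + 3 SD (computed on their remaining trials) are
   discarded as lapses of attention.

Excluded rows are flagged with a reason, never deleted, so the archived raw
table is always recoverable.  Force-exempt trials are retained: the choice
and its latency were produced before the exemption was revealed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .synthetic_cohort import TaskDesign

__all__ = ["ExclusionReport", "DecisionSpaceSummary", "exclude_trials",
           "acceptance_matrix", "overall_acceptance"]

logger = logging.getLogger(__name__)

FAST_RT_CUTOFF = 0.4   # seconds; strict less-than
SLOW_SD_MULTIPLIER = 3.0  # strict greater-than mean + 3 SD, per participant


@dataclass(frozen=True)
class ExclusionReport:
    n_total: int
    n_excluded_fast: int
    n_excluded_slow: int
    per_participant: pd.DataFrame = field(repr=False)

    @property
    def n_kept(self) -> int:
        return self.n_total - self.n_excluded_fast - self.n_excluded_slow

    @property
    def fraction_excluded(self) -> float:
        return (self.n_excluded_fast + self.n_excluded_slow) / self.n_total if self.n_total else 0.0

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_kept": self.n_kept,
            "n_excluded_fast": self.n_excluded_fast,
            "n_excluded_slow": self.n_excluded_slow,
            "fraction_excluded": self.fraction_excluded,
            "per_participant": self.per_participant.to_dict(orient="records"),
        }


@dataclass(frozen=True)
class DecisionSpaceSummary:
    """Per-cell acceptance proportions and mean RTs over included trials.

    ``acceptance`` / ``mean_rt`` are (reward x effort) DataFrames pooled over
    participants (each participant weighted equally); ``per_participant`` is
    the tidy per-subject version; ``empty_cells`` lists (participant, reward,
    effort) combinations with zero included trials (reported, never silently
    zero-filled).
    """

    acceptance: pd.DataFrame
    mean_rt: pd.DataFrame
    per_participant: pd.DataFrame = field(repr=False)
    empty_cells: pd.DataFrame = field(repr=False)


def exclude_trials(trials: pd.DataFrame,
                   fast_cutoff: float = FAST_RT_CUTOFF,
                   sd_multiplier: float = SLOW_SD_MULTIPLIER):
    """Apply both exclusion rules; returns (flagged table, ExclusionReport).

    The returned table contains *all* rows with added boolean ``excluded``
    and string ``exclusion_reason`` ("fast" / "slow" / "") columns; filter on
    ``~excluded`` for analysis.  The slow rule uses each participant's mean
    and SD over their trials that survived the fast rule; participants with
    fewer than 2 surviving trials have the slow rule skipped (logged).  The
    result does not depend on row order and is idempotent under re-application
    to the kept subset.
    """
    if "rt" not in trials.columns:
        raise DataError("trial table has no 'rt' column")
    rt = trials["rt"].to_numpy(float)
    if np.any(~np.isfinite(rt)) or np.any(rt <= 0):
        raise DataError("reaction times must be positive and finite")

    out = trials.reset_index(drop=True)
    fast = rt < fast_cutoff
    slow = np.zeros(len(out), dtype=bool)
    for pid, grp in out.groupby("participant_id", sort=False):
        keep = ~fast[grp.index.to_numpy()]
        vals = grp["rt"].to_numpy(float)[keep]
        if vals.size < 2:
            logger.info("exclude_trials: participant %s has %d usable trial(s); "
                        "slow-RT rule skipped", pid, vals.size)
            continue
        thresh = vals.mean() + sd_multiplier * vals.std(ddof=1)
        mask = keep & (grp["rt"].to_numpy(float) > thresh)
        slow[grp.index.to_numpy()[mask]] = True

    out["excluded"] = fast | slow
    out["exclusion_reason"] = np.select([fast, slow], ["fast", "slow"], default="")
    per = (out.assign(fast=fast, slow=slow)
              .groupby("participant_id", sort=False)
              .agg(n_total=("rt", "size"), n_fast=("fast", "sum"), n_slow=("slow", "sum"))
              .reset_index())
    report = ExclusionReport(n_total=len(out), n_excluded_fast=int(fast.sum()),
                             n_excluded_slow=int(slow.sum()), per_participant=per)
    return out, report


def _cell_grid(design: TaskDesign) -> pd.MultiIndex:
    return pd.MultiIndex.from_product(
        [list(design.reward_levels), list(design.effort_levels)],
        names=["reward", "effort"])


def acceptance_matrix(trials: pd.DataFrame, design: TaskDesign) -> DecisionSpaceSummary:
    """Summarize the decision space: per-cell acceptance and mean RT.

    Input should already be exclusion-flagged (rows with ``excluded`` True
    are dropped; an unflagged table is used as-is).  The pooled matrices
    average the per-participant cell statistics, weighting participants
    equally.  Rows referencing unknown reward/effort levels raise a
    :class:`DataError` naming the offender.
    """
    df = trials.loc[~trials["excluded"]] if "excluded" in trials.columns else trials
    known_r = set(design.reward_levels)
    known_e = set(np.round(design.effort_levels, 9))
    bad = df.loc[~df["reward"].isin(known_r) |
                 ~df["effort"].round(9).isin(known_e)]
    if len(bad):
        row = bad.iloc[0]
        raise DataError(
            f"trial {row.get('trial_index', '?')} of participant "
            f"{row['participant_id']} has unknown offer "
            f"(reward={row['reward']}, effort={row['effort']})")

    df = df.assign(accept=(df["choice"] == "accept").astype(float))
    per = (df.groupby(["participant_id", "reward", "effort"], sort=True)
             .agg(n_trials=("accept", "size"), acceptance=("accept", "mean"),
                  mean_rt=("rt", "mean"))
             .reset_index())

    grid = _cell_grid(design)
    full = (per.set_index(["reward", "effort"])
               .groupby("participant_id", group_keys=True)
               .apply(lambda g: g.reindex(grid), include_groups=False)
               .reset_index())
    empty = full.loc[full["n_trials"].isna(), ["participant_id", "reward", "effort"]]
    if len(empty):
        logger.info("acceptance_matrix: %d empty participant-cells flagged", len(empty))

    pooled_acc = (full.pivot_table(index="reward", columns="effort",
                                   values="acceptance", aggfunc="mean")
                      .reindex(index=list(design.reward_levels),
                               columns=list(design.effort_levels)))
    pooled_rt = (full.pivot_table(index="reward", columns="effort",
                                  values="mean_rt", aggfunc="mean")
                     .reindex(index=list(design.reward_levels),
                              columns=list(design.effort_levels)))
    return DecisionSpaceSummary(acceptance=pooled_acc, mean_rt=pooled_rt,
                                per_participant=per,
                                empty_cells=empty.reset_index(drop=True))


def overall_acceptance(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant overall acceptance rate over included trials."""
    df = trials.loc[~trials["excluded"]] if "excluded" in trials.columns else trials
    return (df.assign(accept=(df["choice"] == "accept").astype(float))
              .groupby("participant_id", sort=True)["accept"].mean()
              .rename("acceptance_rate").reset_index())
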