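"""Synthetic cohorts for the reward-by-effort grip-force choice task.

The task offers a reward (virtual apples: 1, 3, 6, 9, 12 or 15) in exchange
for squeezing a dynamometer at a required fraction of the participant's own
maximum voluntary contraction (MVC: 10, 24, 38, 52, 66 or 80%).  Each of the
36 offers is presented five times, 180 trials in five blocks, in one fixed
pseudo-random order shared by every participant; a quarter of accepted trials
are force-exempt (reward granted without squeezing).

Because the clinical data are not public, this module generates cohorts with
the *statistical* structure the downstream analyses assume: subject-level DDM
parameters drawn around group means, apathy (AES) lowering baseline drift and
raising the reward weight, depression (BDI) raising the decision boundary,
and AES correlated with BDI at about 0.38.  Choices and reaction times are
then simulated from each subject's true drift-diffusion process.

The default generating effect sizes are calibration choices for recovery
experiments, NOT estimates taken from any patient cohort.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ddm_core import DDMParameters, simulate_first_passage_batch
from .errors import ConfigurationError

__all__ = [
    "TaskDesign",
    "ParticipantProfile",
    "CohortSpec",
    "build_session_schedule",
    "sample_participants",
    "simulate_cohort",
    "TRIAL_COLUMNS",
    "COVARIATE_COLUMNS",
]

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = ["participant_id", "block", "trial_index", "reward", "effort",
                 "choice", "rt", "exempt"]
COVARIATE_COLUMNS = ["participant_id", "aes", "bdi", "age", "cognition", "mvc"]

#: instrument ranges used to clip Gaussian covariate draws
INSTRUMENT_RANGES = {
    "aes": (0.0, 72.0),       # Apathy Evaluation Scale
    "bdi": (0.0, 63.0),       # Beck Depression Inventory
    "age": (18.0, 110.0),
    "cognition": (0.0, 100.0),  # ACE-III
    "mvc": (1.0, math.inf),
}


@dataclass(frozen=True)
class TaskDesign:
    """Structure of one session of the effort-based decision-making task."""

    reward_levels: tuple = (1, 3, 6, 9, 12, 15)
    effort_levels: tuple = (0.10, 0.24, 0.38, 0.52, 0.66, 0.80)
    repetitions_per_cell: int = 5
    n_blocks: int = 5
    exemption_probability: float = 0.25
    force_window: float = 5.0      # seconds allowed to reach the target force
    sustain_duration: float = 1.0  # seconds the force must be held

    def __post_init__(self) -> None:
        r = tuple(self.reward_levels)
        e = tuple(self.effort_levels)
        object.__setattr__(self, "reward_levels", r)
        object.__setattr__(self, "effort_levels", e)
        if len(r) < 1 or any(b <= a for a, b in zip(r, r[1:])):
            raise ConfigurationError("reward_levels must be strictly increasing")
        if len(e) < 1 or any(b <= a for a, b in zip(e, e[1:])):
            raise ConfigurationError("effort_levels must be strictly increasing")
        if not all(0 < x <= 1 for x in e):
            raise ConfigurationError("effort_levels must lie in (0, 1] (fractions of MVC)")
        if self.repetitions_per_cell < 1 or self.n_blocks < 1:
            raise ConfigurationError("repetitions_per_cell and n_blocks must be >= 1")
        if (self.n_trials % self.n_blocks) != 0:
            raise ConfigurationError(
                f"{self.n_trials} trials cannot be split into {self.n_blocks} equal blocks")
        if not (0 <= self.exemption_probability <= 1):
            raise ConfigurationError("exemption_probability must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return len(self.reward_levels) * len(self.effort_levels)

    @property
    def n_trials(self) -> int:
        return self.n_cells * self.repetitions_per_cell

    @property
    def max_reward(self) -> float:
        return float(self.reward_levels[-1])


@dataclass(frozen=True)
class ParticipantProfile:
    """Covariates of one (synthetic) participant plus true DDM parameters."""

    participant_id: str
    aes: float
    bdi: float
    age: float
    cognition: float
    mvc: float
    true_params: DDMParameters | None = None


def _default_group_means() -> DDMParameters:
    return DDMParameters(a=2.0, z=0.5, t=0.3, v0=0.3, vr=1.8, ve=2.0, vre=0.3)


def _default_group_sds() -> dict:
    return {"a": 0.3, "z": 0.05, "t": 0.05, "v0": 0.3, "vr": 0.4, "ve": 0.4, "vre": 0.15}


def _default_covariates() -> dict:
    # means/SDs follow the demographic profile of a late-onset small vessel
    # disease cohort; MVC is in arbitrary force units
    return {"aes": (32.0, 8.0), "bdi": (10.0, 7.0), "age": (68.0, 11.0),
            "cognition": (90.0, 8.0), "mvc": (300.0, 60.0)}


@dataclass(frozen=True)
class CohortSpec:
    """Generative specification of a synthetic cohort.

    Effect slopes are in parameter units per standard deviation of the
    (specified, not sample) covariate distribution.  Defaults equal half the
    between-subject SD of the affected parameter -- calibration values for
    recovery experiments, not estimates from any dataset.
    """

    n_participants: int = 82
    group_means: DDMParameters = field(default_factory=_default_group_means)
    group_sds: dict = field(default_factory=_default_group_sds)
    effect_aes_on_v0: float = -0.15
    effect_aes_on_vr: float = 0.20
    effect_bdi_on_a: float = 0.15
    aes_bdi_correlation: float = 0.38
    covariate_distributions: dict = field(default_factory=_default_covariates)
    execution_failure_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if not (-1 <= self.aes_bdi_correlation <= 1):
            raise ConfigurationError("aes_bdi_correlation must lie in [-1, 1]")
        if any(s < 0 for s in self.group_sds.values()):
            raise ConfigurationError("group_sds must be non-negative")
        if not (0 <= self.execution_failure_rate < 1):
            raise ConfigurationError("execution_failure_rate must lie in [0, 1)")
        missing = {"aes", "bdi", "age", "cognition", "mvc"} - set(self.covariate_distributions)
        if missing:
            raise ConfigurationError(f"covariate_distributions missing {sorted(missing)}")


def build_session_schedule(design: TaskDesign, seed: int) -> pd.DataFrame:
    """One fixed pseudo-random offer order, identical for every participant.

    Each (reward, effort) cell appears exactly ``repetitions_per_cell`` times.
    Repetitions are dealt round-robin across blocks so each block carries a
    balanced spread of reward levels (a full factorial per block when
    repetitions equal the number of blocks), then shuffled within block with
    a generator seeded only by ``seed``.

    Returns a DataFrame with columns block, trial_index, reward, effort.
    """
    rng = np.random.default_rng(seed)
    per_block = design.n_trials // design.n_blocks
    blocks: list[list[tuple]] = [[] for _ in range(design.n_blocks)]
    k = 0
    for rep in range(design.repetitions_per_cell):
        for rew in design.reward_levels:
            for eff in design.effort_levels:
                blocks[k % design.n_blocks].append((rew, eff))
                k += 1
    if any(len(b) != per_block for b in blocks):
        # only reachable for degenerate designs the divisibility check missed
        raise ConfigurationError("offers do not distribute evenly across blocks")
    rows = []
    idx = 1
    for b, offers in enumerate(blocks, start=1):
        order = rng.permutation(len(offers))
        for j in order:
            rew, eff = offers[j]
            rows.append((b, idx, rew, eff))
            idx += 1
    return pd.DataFrame(rows, columns=["block", "trial_index", "reward", "effort"])


def _standardize(x: np.ndarray, name: str, dists: dict) -> np.ndarray:
    mean, sd = dists[name]
    return (x - mean) / sd if sd > 0 else np.zeros_like(x)


def sample_participants(spec: CohortSpec, rng: np.random.Generator) -> list[ParticipantProfile]:
    """Draw covariates and true DDM parameters for a cohort.

    AES and BDI are sampled from a bivariate normal with the specified
    correlation and clipped to instrument ranges (clips logged); age,
    cognition and MVC are independent.  True parameters are the group means
    plus covariate effects on standardized AES/BDI plus independent Gaussian
    subject noise, truncated into the parameter supports (a > 0, 0 < z < 1,
    t >= 0) with every truncation logged.
    """
    n = spec.n_participants
    d = spec.covariate_distributions
    rho = spec.aes_bdi_correlation
    cov = np.array([[d["aes"][1]**2, rho * d["aes"][1] * d["bdi"][1]],
                    [rho * d["aes"][1] * d["bdi"][1], d["bdi"][1]**2]])
    ab = rng.multivariate_normal([d["aes"][0], d["bdi"][0]], cov, size=n)
    raw = {
        "aes": ab[:, 0],
        "bdi": ab[:, 1],
        "age": rng.normal(d["age"][0], d["age"][1], n),
        "cognition": rng.normal(d["cognition"][0], d["cognition"][1], n),
        "mvc": rng.normal(d["mvc"][0], d["mvc"][1], n),
    }
    cols = {}
    for name, x in raw.items():
        lo, hi = INSTRUMENT_RANGES[name]
        clipped = np.clip(x, lo, hi)
        n_clip = int(np.sum(clipped != x))
        if n_clip:
            logger.info("sample_participants: clipped %d/%d %s draws to [%s, %s]",
                        n_clip, n, name, lo, hi)
        cols[name] = clipped

    aes_z = _standardize(cols["aes"], "aes", d)
    bdi_z = _standardize(cols["bdi"], "bdi", d)
    mu = spec.group_means
    if mu.a + spec.effect_bdi_on_a * (-3.0) <= 0 and spec.group_sds["a"] == 0:
        raise ConfigurationError("group mean decision boundary is infeasible")

    profiles = []
    n_trunc = 0
    for i in range(n):
        vals = {
            "a": mu.a + spec.effect_bdi_on_a * bdi_z[i] + rng.normal(0, spec.group_sds["a"]),
            "z": mu.z + rng.normal(0, spec.group_sds["z"]),
            "t": mu.t + rng.normal(0, spec.group_sds["t"]),
            "v0": mu.v0 + spec.effect_aes_on_v0 * aes_z[i] + rng.normal(0, spec.group_sds["v0"]),
            "vr": mu.vr + spec.effect_aes_on_vr * aes_z[i] + rng.normal(0, spec.group_sds["vr"]),
            "ve": mu.ve + rng.normal(0, spec.group_sds["ve"]),
            "vre": mu.vre + rng.normal(0, spec.group_sds["vre"]),
        }
        trunc = {"a": max(vals["a"], 0.05), "z": float(np.clip(vals["z"], 0.02, 0.98)),
                 "t": max(vals["t"], 0.0)}
        if any(trunc[k] != vals[k] for k in trunc):
            n_trunc += 1
        vals.update(trunc)
        profiles.append(ParticipantProfile(
            participant_id=f"p{i + 1:03d}",
            aes=float(cols["aes"][i]), bdi=float(cols["bdi"][i]),
            age=float(cols["age"][i]), cognition=float(cols["cognition"][i]),
            mvc=float(cols["mvc"][i]),
            true_params=DDMParameters(**vals)))
    if n_trunc:
        logger.info("sample_participants: truncated parameters into support for %d/%d subjects",
                    n_trunc, n)
    return profiles


def covariate_table(profiles: list[ParticipantProfile]) -> pd.DataFrame:
    """Long-format covariate table, with true_* columns when ground truth exists."""
    rows = []
    for p in profiles:
        row = {"participant_id": p.participant_id, "aes": p.aes, "bdi": p.bdi,
               "age": p.age, "cognition": p.cognition, "mvc": p.mvc}
        if p.true_params is not None:
            row.update({f"true_{k}": v for k, v in
                        dataclasses.asdict(p.true_params).items()})
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_cohort(spec: CohortSpec, design: TaskDesign | None = None,
                    out_dir: str | Path | None = None, dt: float = 1e-3,
                    noise_c: float = 1.0):
    """Simulate a full cohort session; returns (trial table, covariate table).

    Every participant sees the same seeded offer schedule; choices and RTs
    come from each subject's true drift-diffusion process via the
    first-passage simulator; accepted trials are flagged force-exempt with
    the design's exemption probability.  Fully reproducible from
    ``spec.seed``.  If ``out_dir`` is given, writes ``trials.csv``,
    ``covariates.csv`` and ``schedule.csv``.
    """
    design = design or TaskDesign()
    ss = np.random.SeedSequence(spec.seed)
    s_sched, s_part, s_trials = ss.spawn(3)
    schedule = build_session_schedule(design, seed=int(s_sched.generate_state(1)[0] % (2**31)))
    profiles = sample_participants(spec, np.random.default_rng(s_part))

    r_scaled = schedule["reward"].to_numpy(float) / design.max_reward
    e_scaled = schedule["effort"].to_numpy(float) ** 2

    frames = []
    streams = s_trials.spawn(len(profiles))
    for p, stream in zip(profiles, streams):
        rng = np.random.default_rng(stream)
        q = p.true_params
        V = q.v0 + q.vr * r_scaled - q.ve * e_scaled - q.vre * r_scaled * e_scaled
        acc, rt = simulate_first_passage_batch(V, q.a, q.z, q.t, noise_c, rng, dt=dt)
        exempt = acc & (rng.random(acc.size) < design.exemption_probability)
        df = schedule.copy()
        df.insert(0, "participant_id", p.participant_id)
        df["choice"] = np.where(acc, "accept", "reject")
        df["rt"] = rt
        df["exempt"] = exempt
        if spec.execution_failure_rate > 0:
            squeeze = acc & ~exempt
            df["exec_success"] = np.where(
                squeeze, rng.random(acc.size) >= spec.execution_failure_rate, True)
        frames.append(df)
    trials = pd.concat(frames, ignore_index=True)
    covs = covariate_table(profiles)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        trials.to_csv(out / "trials.csv", index=False, float_format="%.6f")
        covs.to_csv(out / "covariates.csv", index=False, float_format="%.6f")
        schedule.to_csv(out / "schedule.csv", index=False)
    return trials, covs
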