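"""Four-armed bandit task structure: drifting reward schedules, random offers,
binary outcomes, and the tidy per-trial record format used by every analysis.

The task is a card game: four decks, two offered per trial, binary outcome
drawn from a slowly drifting per-deck probability. Win blocks pay +1/0,
loss blocks pay 0/-1; both are recoded to ``reward01`` in {0, 1} so that
learning models see a single outcome scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "RewardSchedule",
    "TrialRecord",
    "CohortDataset",
    "generate_reward_schedule",
    "generate_offers",
    "sample_outcome",
    "write_trials",
    "read_trials",
    "write_schedule",
    "read_schedule",
]

BLOCK_TYPES = ("win", "loss")

#: payoff shown to the participant, keyed by (block_type, reward01)
PAYOFF_MAP: Mapping[tuple[str, int], int] = {
    ("win", 1): 1,
    ("win", 0): 0,
    ("loss", 1): 0,
    ("loss", 0): -1,
}

TRIAL_COLUMNS = [
    "participant_id",
    "block",
    "block_type",
    "trial",
    "offer_a",
    "offer_b",
    "choice",
    "payoff",
    "reward01",
    "rt_ms",
]


class ConfigurationError(ValueError):
    """Invalid task configuration (non-positive sizes, bad labels...)."""


@dataclass(frozen=True)
class TaskConfig:
    """Design parameters of the bandit task.

    Defaults follow the study design: 4 cards, 4 alternating win/loss
    blocks of 50 trials, probability random walk with increment SD 0.03.
    """

    n_arms: int = 4
    n_blocks: int = 4
    trials_per_block: int = 50
    drift_sd: float = 0.03
    first_block_type: str = "win"
    p_init_low: float = 0.25
    p_init_high: float = 0.75

    def __post_init__(self) -> None:
        if self.n_arms < 2:
            raise ConfigurationError(f"n_arms must be >= 2, got {self.n_arms}")
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ConfigurationError("n_blocks and trials_per_block must be positive")
        if self.drift_sd < 0:
            raise ConfigurationError(f"drift_sd must be >= 0, got {self.drift_sd}")
        if self.first_block_type not in BLOCK_TYPES:
            raise ConfigurationError(f"unknown block type {self.first_block_type!r}")

    @property
    def block_types(self) -> tuple[str, ...]:
        """Alternating win/loss labels, starting from ``first_block_type``."""
        first = BLOCK_TYPES.index(self.first_block_type)
        return tuple(BLOCK_TYPES[(first + b) % 2] for b in range(self.n_blocks))

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def with_first_block(self, block_type: str) -> "TaskConfig":
        return replace(self, first_block_type=block_type)


@dataclass(frozen=True)
class RewardSchedule:
    """True per-arm reward probabilities, shape ``(n_blocks, trials, n_arms)``."""

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 3:
            raise ConfigurationError("schedule must be block x trial x arm")
        if np.any(p < 0) or np.any(p > 1):
            raise ConfigurationError("schedule probabilities must lie in [0, 1]")
        object.__setattr__(self, "p", p)

    @property
    def n_blocks(self) -> int:
        return self.p.shape[0]

    @property
    def trials_per_block(self) -> int:
        return self.p.shape[1]

    @property
    def n_arms(self) -> int:
        return self.p.shape[2]


@dataclass(frozen=True)
class TrialRecord:
    """One choice event."""

    participant_id: str
    block: int
    block_type: str
    trial: int
    offer_a: int
    offer_b: int
    choice: int | None
    payoff: int | None
    reward01: int | None
    rt_ms: int | None = None

    def __post_init__(self) -> None:
        if self.offer_a == self.offer_b:
            raise ValueError("offered arms must be distinct")
        if self.choice is not None and self.choice not in (self.offer_a, self.offer_b):
            raise ValueError(
                f"choice {self.choice} outside offered pair "
                f"({self.offer_a}, {self.offer_b})"
            )
        if self.block_type not in BLOCK_TYPES:
            raise ValueError(f"unknown block type {self.block_type!r}")
        if self.reward01 is not None and PAYOFF_MAP[(self.block_type, self.reward01)] != self.payoff:
            raise ValueError(
                f"payoff {self.payoff} inconsistent with reward01 {self.reward01} "
                f"in a {self.block_type} block"
            )


@dataclass
class CohortDataset:
    """Trial records for a cohort plus (optionally) the true schedules.

    ``records`` is a tidy frame with :data:`TRIAL_COLUMNS`; ``schedules``
    maps participant_id to that participant's :class:`RewardSchedule`.
    """

    records: pd.DataFrame
    schedules: dict[str, RewardSchedule] = field(default_factory=dict)
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"records missing columns: {missing}")

    @property
    def participant_ids(self) -> list[str]:
        return list(dict.fromkeys(self.records["participant_id"]))

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    def participant(self, pid: str) -> pd.DataFrame:
        return self.records[self.records["participant_id"] == pid]

    def drop_blocks(self, blocks: Iterable[int]) -> "CohortDataset":
        blocks = set(blocks)
        kept = self.records[~self.records["block"].isin(blocks)].reset_index(drop=True)
        return CohortDataset(kept, self.schedules, self.provenance)

    def keep_blocks(self, blocks: Iterable[int]) -> "CohortDataset":
        blocks = set(blocks)
        kept = self.records[self.records["block"].isin(blocks)].reset_index(drop=True)
        return CohortDataset(kept, self.schedules, self.provenance)

    def blocks(self) -> list[int]:
        return sorted(self.records["block"].unique())


def _reflect_unit(x: np.ndarray) -> np.ndarray:
    """Fold values into [0, 1] by reflecting at both bounds."""
    # period-2 triangular fold: handles arbitrarily large overshoot
    y = np.mod(x, 2.0)
    return np.where(y > 1.0, 2.0 - y, y)


def generate_reward_schedule(config: TaskConfig, seed: int) -> RewardSchedule:
    """Bounded Gaussian random walk of reward probabilities.

    Each arm drifts independently within each block: start Uniform(0.25,
    0.75), then per-trial increments N(0, drift_sd) reflected at 0 and 1.
    Blocks get independent walks (separate learning contexts).
    """
    rng = np.random.default_rng(seed)
    p = np.empty((config.n_blocks, config.trials_per_block, config.n_arms))
    for b in range(config.n_blocks):
        cur = rng.uniform(config.p_init_low, config.p_init_high, size=config.n_arms)
        for t in range(config.trials_per_block):
            p[b, t] = cur
            step = rng.normal(0.0, config.drift_sd, size=config.n_arms)
            cur = _reflect_unit(cur + step)
    return RewardSchedule(p)


def generate_offers(config: TaskConfig, seed: int) -> np.ndarray:
    """Random pair of distinct arms per trial, shape ``(n_blocks, trials, 2)``.

    Pairs are uniform i.i.d. over the ``C(n_arms, 2)`` unordered pairs.
    """
    rng = np.random.default_rng(seed)
    pairs = np.array(list(itertools.combinations(range(config.n_arms), 2)))
    idx = rng.integers(0, len(pairs), size=(config.n_blocks, config.trials_per_block))
    return pairs[idx]


def sample_outcome(
    p_reward: float, block_type: str, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw the binary outcome and map it to the block's payoff scale."""
    if not 0.0 <= p_reward <= 1.0:
        raise ValueError(f"p_reward must be in [0, 1], got {p_reward}")
    if block_type not in BLOCK_TYPES:
        raise ValueError(f"unknown block type {block_type!r}")
    reward01 = int(rng.random() < p_reward)
    return reward01, PAYOFF_MAP[(block_type, reward01)]


# ---------------------------------------------------------------------------
# CSV round trip


class TrialParseError(ValueError):
    """A trial file row violated the schema; the message names the row."""


def write_trials(path, dataset: CohortDataset) -> None:
    df = dataset.records.loc[:, TRIAL_COLUMNS].copy()
    for col in ("choice", "payoff", "reward01", "rt_ms"):
        df[col] = df[col].astype("Int64")
    df.to_csv(path, index=False)


def read_trials(path, schedules: dict[str, RewardSchedule] | None = None) -> CohortDataset:
    """Read a trial CSV, validating every row.

    ``rt_ms`` may be absent entirely (simulated cohorts have no RTs);
    RT-dependent analyses check for it and refuse gracefully.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = [c for c in TRIAL_COLUMNS if c != "rt_ms"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrialParseError(f"missing required columns: {missing}")
    if "rt_ms" not in df.columns:
        df["rt_ms"] = pd.array([pd.NA] * len(df), dtype="Int64")
    for col in ("choice", "payoff", "reward01", "rt_ms"):
        df[col] = pd.array(df[col], dtype="Int64")

    for i, row in enumerate(df.itertuples(index=False)):
        if row.offer_a == row.offer_b:
            raise TrialParseError(f"row {i}: offered arms are not distinct")
        if row.block_type not in BLOCK_TYPES:
            raise TrialParseError(f"row {i}: unknown block type {row.block_type!r}")
        if pd.notna(row.choice) and row.choice not in (row.offer_a, row.offer_b):
            raise TrialParseError(
                f"row {i}: choice {row.choice} outside offered pair "
                f"({row.offer_a}, {row.offer_b})"
            )
        if pd.notna(row.reward01):
            expected = PAYOFF_MAP[(row.block_type, int(row.reward01))]
            if pd.isna(row.payoff) or int(row.payoff) != expected:
                raise TrialParseError(
                    f"row {i}: payoff {row.payoff} inconsistent with "
                    f"reward01 {row.reward01} in a {row.block_type} block"
                )
    return CohortDataset(df, schedules or {}, provenance="file")


def write_schedule(path, schedule: RewardSchedule) -> None:
    """Companion CSV of the true probabilities: block, trial, p_arm0.."""
    nb, nt, na = schedule.p.shape
    rows = {
        "block": np.repeat(np.arange(1, nb + 1), nt),
        "trial": np.tile(np.arange(1, nt + 1), nb),
    }
    for a in range(na):
        rows[f"p_arm{a}"] = schedule.p[:, :, a].ravel()
    pd.DataFrame(rows).to_csv(path, index=False)


def read_schedule(path) -> RewardSchedule:
    df = pd.read_csv(path)
    arm_cols = sorted(
        (c for c in df.columns if c.startswith("p_arm")), key=lambda c: int(c[5:])
    )
    if not arm_cols:
        raise TrialParseError("schedule file has no p_arm columns")
    nb = int(df["block"].max())
    nt = int(df["trial"].max())
    p = np.empty((nb, nt, len(arm_cols)))
    for b in range(nb):
        sub = df[df["block"] == b + 1].sort_values("trial")
        if len(sub) != nt:
            raise TrialParseError(f"block {b + 1} has {len(sub)} trials, expected {nt}")
        p[b] = sub[arm_cols].to_numpy()
    return RewardSchedule(p)


def records_from_trials(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Build a tidy frame from row objects (mostly a test convenience)."""
    df = pd.DataFrame([t.__dict__ for t in trials], columns=TRIAL_COLUMNS)
    for col in ("choice", "payoff", "reward01", "rt_ms"):
        df[col] = pd.array(df[col], dtype="Int64")
    return df
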