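"""The four Q-learning models of choice among offered cards.

* ``baseline`` — only the chosen card's value moves, toward the reward.
* ``double_two_pe`` — the unchosen card additionally moves toward the
  inverted outcome ``1 - reward`` via its own prediction error.
* ``double_one_pe`` — a single prediction error for the chosen card, a
  scaled and sign-flipped share of which is applied to the unchosen card.
* ``select_reject`` — separate value ledgers for selecting and rejecting
  each card (8 values for 4 cards); both the chosen card's select value
  and the unchosen card's reject value move toward the observed reward,
  and decisions integrate select and reject values with weight ``omega``.

All models consume the recoded reward in {0, 1}; win and loss blocks are
computationally identical. Values are clamped to [0, 1] after each update
and reset to 0.5 at every block start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .synthetic_task import (
    PAYOFF_MAP,
    TRIAL_COLUMNS,
    CohortDataset,
    RewardSchedule,
    TaskConfig,
    generate_offers,
    generate_reward_schedule,
)

__all__ = [
    "MODEL_IDS",
    "PARAM_NAMES",
    "ModelParams",
    "QState",
    "PredictionErrors",
    "init_state",
    "choice_prob",
    "update_state",
    "truncate_q",
    "sequence_loglik",
    "simulate_agent",
    "simulate_cohort",
]

MODEL_IDS = ("baseline", "double_two_pe", "double_one_pe", "select_reject")

#: free parameters of each model, in canonical order
PARAM_NAMES = {
    "baseline": ("alpha_chosen", "beta"),
    "double_two_pe": ("alpha_chosen", "alpha_unchosen", "beta"),
    "double_one_pe": ("alpha_chosen", "alpha_unchosen", "beta"),
    "select_reject": ("alpha_chosen", "omega", "beta"),
}

Q_INIT = 0.5


def _check_model(model: str) -> None:
    if model not in MODEL_IDS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_IDS}")


@dataclass(frozen=True)
class ModelParams:
    """Natural-scale parameters; only the generating model's fields are set."""

    model: str
    alpha_chosen: float
    beta: float
    alpha_unchosen: float | None = None
    omega: float | None = None

    def __post_init__(self) -> None:
        _check_model(self.model)
        names = PARAM_NAMES[self.model]
        if ("alpha_unchosen" in names) != (self.alpha_unchosen is not None):
            raise ValueError(f"alpha_unchosen misconfigured for {self.model}")
        if ("omega" in names) != (self.omega is not None):
            raise ValueError(f"omega misconfigured for {self.model}")
        if not 0.0 <= self.alpha_chosen <= 1.0:
            raise ValueError("alpha_chosen must lie in [0, 1]")
        if self.alpha_unchosen is not None and not 0.0 <= self.alpha_unchosen <= 1.0:
            raise ValueError("alpha_unchosen must lie in [0, 1]")
        if self.omega is not None and not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must lie in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES[self.model]])

    @classmethod
    def from_array(cls, model: str, values) -> "ModelParams":
        _check_model(model)
        kwargs = dict(zip(PARAM_NAMES[model], values))
        return cls(model=model, **kwargs)

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES[self.model]}


@dataclass
class QState:
    """Learned values. ``q`` for single-ledger models; ``q_select`` /
    ``q_reject`` for the dual-ledger model."""

    model: str
    q: np.ndarray | None = None
    q_select: np.ndarray | None = None
    q_reject: np.ndarray | None = None

    def copy(self) -> "QState":
        return QState(
            self.model,
            None if self.q is None else self.q.copy(),
            None if self.q_select is None else self.q_select.copy(),
            None if self.q_reject is None else self.q_reject.copy(),
        )

    def values(self) -> np.ndarray:
        if self.model == "select_reject":
            return np.concatenate([self.q_select, self.q_reject])
        return self.q


@dataclass(frozen=True)
class PredictionErrors:
    delta_chosen: float
    delta_unchosen: float | None = None


def init_state(model: str, n_arms: int) -> QState:
    """Fresh block-start state: every value at 0.5."""
    _check_model(model)
    if n_arms < 2:
        raise ValueError(f"n_arms must be >= 2, got {n_arms}")
    if model == "select_reject":
        return QState(
            model,
            q_select=np.full(n_arms, Q_INIT),
            q_reject=np.full(n_arms, Q_INIT),
        )
    return QState(model, q=np.full(n_arms, Q_INIT))


def _net_values(state: QState, arm1: int, arm2: int, omega: float) -> tuple[float, float]:
    """Integrated decision values for an offered pair under select-reject.

    Each offer's value mixes its own select value with the *other* offer's
    reject value: choosing a card is also rejecting the alternative.
    """
    v1 = omega * state.q_select[arm1] + (1.0 - omega) * state.q_reject[arm2]
    v2 = omega * state.q_select[arm2] + (1.0 - omega) * state.q_reject[arm1]
    return v1, v2


def choice_prob(
    model: str, state: QState, offer: tuple[int, int], params: ModelParams
) -> tuple[float, float]:
    """Softmax probability of choosing each offered arm; sums to 1."""
    _check_model(model)
    a, b = offer
    if a == b:
        raise ValueError("offered arms must be distinct")
    if model == "select_reject":
        va, vb = _net_values(state, a, b, params.omega)
    else:
        va, vb = state.q[a], state.q[b]
    x = params.beta * (va - vb)
    pa = 1.0 / (1.0 + np.exp(-x))
    return float(pa), float(1.0 - pa)


def truncate_q(state: QState) -> QState:
    """Clamp every value into [0, 1]."""
    out = state.copy()
    for arr in (out.q, out.q_select, out.q_reject):
        if arr is not None:
            np.clip(arr, 0.0, 1.0, out=arr)
    return out


def update_state(
    model: str,
    state: QState,
    offer: tuple[int, int],
    choice: int,
    reward01: int,
    params: ModelParams,
) -> tuple[QState, PredictionErrors]:
    """One trial's learning step; unoffered arms never change."""
    _check_model(model)
    if reward01 not in (0, 1):
        raise ValueError(
            f"reward01 must be 0 or 1, got {reward01!r} (recode raw payoffs first)"
        )
    a, b = offer
    if choice not in (a, b):
        raise ValueError(f"choice {choice} outside offered pair {offer}")
    unchosen = b if choice == a else a
    out = state.copy()

    if model == "baseline":
        delta = reward01 - out.q[choice]
        out.q[choice] += params.alpha_chosen * delta
        pes = PredictionErrors(delta)
    elif model == "double_two_pe":
        delta = reward01 - out.q[choice]
        delta_u = (1 - reward01) - out.q[unchosen]
        out.q[choice] += params.alpha_chosen * delta
        out.q[unchosen] += params.alpha_unchosen * delta_u
        pes = PredictionErrors(delta, delta_u)
    elif model == "double_one_pe":
        delta = reward01 - out.q[choice]
        out.q[choice] += params.alpha_chosen * delta
        out.q[unchosen] += params.alpha_unchosen * (-delta)
        pes = PredictionErrors(delta)
    else:  # select_reject: both ledgers move toward the observed reward
        delta = reward01 - out.q_select[choice]
        delta_u = reward01 - out.q_reject[unchosen]
        out.q_select[choice] += params.alpha_chosen * delta
        out.q_reject[unchosen] += params.alpha_chosen * delta_u
        pes = PredictionErrors(delta, delta_u)

    return truncate_q(out), pes


def _iter_block_trials(records: pd.DataFrame) -> Iterator[tuple]:
    trials = records["trial"].to_numpy()
    if len(records["block"].unique()) > 1:
        raise ValueError("records span multiple blocks; fit one block at a time")
    if np.any(np.diff(trials) <= 0):
        raise ValueError("records must be sorted by trial within the block")
    yield from records.itertuples(index=False)


def sequence_loglik(
    model: str, params: ModelParams, records: pd.DataFrame
) -> tuple[float, np.ndarray]:
    """Log-likelihood of one participant-block's choice sequence.

    The state starts fresh at the block start and is updated after every
    answered trial. No-response trials contribute neither likelihood nor
    update. Returns the total and the per-answered-trial log-probabilities.
    """
    n_arms = int(max(records["offer_a"].max(), records["offer_b"].max())) + 1
    state = init_state(model, max(n_arms, 2))
    logps = []
    for row in _iter_block_trials(records):
        if pd.isna(row.choice):
            continue
        offer = (int(row.offer_a), int(row.offer_b))
        choice = int(row.choice)
        pa, pb = choice_prob(model, state, offer, params)
        p = pa if choice == offer[0] else pb
        logps.append(np.log(p))
        state, _ = update_state(model, state, offer, choice, int(row.reward01), params)
    logps = np.array(logps)
    return float(logps.sum()), logps


def simulate_agent(
    model: str,
    params: ModelParams,
    schedule: RewardSchedule,
    offers: np.ndarray,
    config: TaskConfig,
    seed: int,
    participant_id: str = "agent0",
) -> pd.DataFrame:
    """Forward-simulate one agent through the task; choices are sampled."""
    _check_model(model)
    if schedule.p.shape[:2] != offers.shape[:2]:
        raise ValueError("schedule and offers disagree on blocks/trials")
    rng = np.random.default_rng(seed)
    block_types = config.block_types
    rows = []
    for b in range(schedule.n_blocks):
        state = init_state(model, schedule.n_arms)
        btype = block_types[b]
        for t in range(schedule.trials_per_block):
            a, o = int(offers[b, t, 0]), int(offers[b, t, 1])
            pa, _ = choice_prob(model, state, (a, o), params)
            choice = a if rng.random() < pa else o
            reward01 = int(rng.random() < schedule.p[b, t, choice])
            payoff = PAYOFF_MAP[(btype, reward01)]
            rows.append((participant_id, b + 1, btype, t + 1, a, o, choice, payoff, reward01, None))
            state, _ = update_state(model, state, (a, o), choice, reward01, params)
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    for col in ("choice", "payoff", "reward01", "rt_ms"):
        df[col] = pd.array(df[col], dtype="Int64")
    return df


def simulate_cohort(
    model: str,
    agent_params: list[ModelParams],
    config: TaskConfig,
    seed: int,
    counterbalance: bool = True,
) -> CohortDataset:
    """Simulate a cohort: each agent gets fresh schedules and offers.

    ``counterbalance`` alternates which block type comes first across agents.
    """
    ss = np.random.SeedSequence(seed)
    frames = []
    schedules: dict[str, RewardSchedule] = {}
    for i, params in enumerate(agent_params):
        cfg = config
        if counterbalance and i % 2 == 1:
            other = "loss" if config.first_block_type == "win" else "win"
            cfg = config.with_first_block(other)
        s_sched, s_off, s_agent = [int(s.generate_state(1)[0]) for s in ss.spawn(3)]
        schedule = generate_reward_schedule(cfg, s_sched)
        offers = generate_offers(cfg, s_off)
        pid = f"agent{i:03d}"
        frames.append(
            simulate_agent(model, params, schedule, offers, cfg, s_agent, pid)
        )
        schedules[pid] = schedule
    records = pd.concat(frames, ignore_index=True)
    return CohortDataset(records, schedules, provenance=f"{model}:seed={seed}")
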