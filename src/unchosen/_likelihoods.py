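"""Fast cohort-level likelihood kernels with analytic parameter gradients.

These are the inner loops of hierarchical fitting and cross-validation:
a forward pass over trials per participant-block segment, propagating
value sensitivities with respect to the learning-rate parameters so that
gradient-based MCMC gets exact gradients. They must agree with the
readable reference implementation in :mod:`unchosen.rl_models` to
numerical precision (enforced by tests).

Rows are packed per cohort: sorted by (participant, block, trial),
no-response trials removed, with a flag marking each block start where
values reset to 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .rl_models import MODEL_IDS
from .synthetic_task import CohortDataset

__all__ = [
    "PackedCohort",
    "pack_cohort",
    "cohort_loglik_grad",
    "cohort_rowwise_logp",
    "cohort_mean_choice_prob",
]


@dataclass(frozen=True)
class PackedCohort:
    """Flat arrays for one cohort's answered trials."""

    pidx: np.ndarray  # participant index per row
    new_seg: np.ndarray  # 1 at the first row of each participant-block
    arm_a: np.ndarray
    arm_b: np.ndarray
    cidx: np.ndarray  # 0 if arm_a was chosen, 1 if arm_b
    reward: np.ndarray
    n_arms: int
    participant_ids: tuple[str, ...]
    index: pd.DataFrame  # participant_id, block, trial per row

    @property
    def n_rows(self) -> int:
        return len(self.pidx)

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)


def pack_cohort(
    data: CohortDataset, participant_ids: tuple[str, ...] | None = None
) -> PackedCohort:
    """Pack answered trials into contiguous per-participant-block segments.

    ``participant_ids`` fixes the participant index order (needed so that
    training and held-out packs of the same cohort agree); by default the
    order of first appearance is used.
    """
    df = data.records
    df = df[df["choice"].notna()].copy()
    if participant_ids is None:
        participant_ids = tuple(dict.fromkeys(df["participant_id"]))
    order = {p: i for i, p in enumerate(participant_ids)}
    unknown = set(df["participant_id"]) - set(participant_ids)
    if unknown:
        raise ValueError(f"records contain unknown participants: {sorted(unknown)}")
    df["_pidx"] = df["participant_id"].map(order)
    df = df.sort_values(["_pidx", "block", "trial"], kind="stable").reset_index(drop=True)

    pidx = df["_pidx"].to_numpy(np.int64)
    block = df["block"].to_numpy(np.int64)
    new_seg = np.ones(len(df), dtype=np.int8)
    if len(df) > 1:
        same = (pidx[1:] == pidx[:-1]) & (block[1:] == block[:-1])
        new_seg[1:] = (~same).astype(np.int8)
    arm_a = df["offer_a"].to_numpy(np.int64)
    arm_b = df["offer_b"].to_numpy(np.int64)
    choice = df["choice"].to_numpy(np.int64)
    cidx = (choice == arm_b).astype(np.int64)
    if not np.all((choice == arm_a) | (choice == arm_b)):
        raise ValueError("a choice lies outside its offered pair")
    n_arms = int(max(arm_a.max(), arm_b.max())) + 1 if len(df) else 2
    return PackedCohort(
        pidx=pidx,
        new_seg=new_seg,
        arm_a=arm_a,
        arm_b=arm_b,
        cidx=cidx,
        reward=df["reward01"].to_numpy(np.int64),
        n_arms=n_arms,
        participant_ids=tuple(participant_ids),
        index=df[["participant_id", "block", "trial"]].reset_index(drop=True),
    )


@njit(cache=True, inline="always")
def _log_sigmoid(x):
    # returns (log p, p) for p = sigmoid(x), numerically stable
    if x >= 0.0:
        e = np.exp(-x)
        return -np.log1p(e), 1.0 / (1.0 + e)
    e = np.exp(x)
    return x - np.log1p(e), e / (1.0 + e)


# ---------------------------------------------------------------------------
# log-likelihood + gradient, one kernel per model


@njit(cache=True)
def _llg_baseline(pidx, new_seg, arm_a, arm_b, cidx, reward, theta, n_arms, grad):
    total = 0.0
    q = np.empty(n_arms)
    dqa = np.empty(n_arms)
    for n in range(pidx.shape[0]):
        if new_seg[n]:
            q[:] = 0.5
            dqa[:] = 0.0
        p = pidx[n]
        alpha = theta[p, 0]
        beta = theta[p, 1]
        if cidx[n] == 0:
            i, j = arm_a[n], arm_b[n]
        else:
            i, j = arm_b[n], arm_a[n]
        dv = q[i] - q[j]
        ll, s = _log_sigmoid(beta * dv)
        total += ll
        g = 1.0 - s
        grad[p, 1] += g * dv
        grad[p, 0] += g * beta * (dqa[i] - dqa[j])
        delta = reward[n] - q[i]
        dqa[i] = (1.0 - alpha) * dqa[i] + delta
        q[i] += alpha * delta
    return total


@njit(cache=True)
def _llg_double_two(pidx, new_seg, arm_a, arm_b, cidx, reward, theta, n_arms, grad):
    total = 0.0
    q = np.empty(n_arms)
    dqc = np.empty(n_arms)
    dqu = np.empty(n_arms)
    for n in range(pidx.shape[0]):
        if new_seg[n]:
            q[:] = 0.5
            dqc[:] = 0.0
            dqu[:] = 0.0
        p = pidx[n]
        ac = theta[p, 0]
        au = theta[p, 1]
        beta = theta[p, 2]
        if cidx[n] == 0:
            i, j = arm_a[n], arm_b[n]
        else:
            i, j = arm_b[n], arm_a[n]
        dv = q[i] - q[j]
        ll, s = _log_sigmoid(beta * dv)
        total += ll
        g = 1.0 - s
        grad[p, 2] += g * dv
        grad[p, 0] += g * beta * (dqc[i] - dqc[j])
        grad[p, 1] += g * beta * (dqu[i] - dqu[j])
        r = reward[n]
        delta = r - q[i]
        dqc[i] = (1.0 - ac) * dqc[i] + delta
        dqu[i] = (1.0 - ac) * dqu[i]
        q[i] += ac * delta
        delta_u = (1 - r) - q[j]
        dqu[j] = (1.0 - au) * dqu[j] + delta_u
        dqc[j] = (1.0 - au) * dqc[j]
        q[j] += au * delta_u
    return total


@njit(cache=True)
def _llg_double_one(pidx, new_seg, arm_a, arm_b, cidx, reward, theta, n_arms, grad):
    total = 0.0
    q = np.empty(n_arms)
    dqc = np.empty(n_arms)
    dqu = np.empty(n_arms)
    for n in range(pidx.shape[0]):
        if new_seg[n]:
            q[:] = 0.5
            dqc[:] = 0.0
            dqu[:] = 0.0
        p = pidx[n]
        ac = theta[p, 0]
        au = theta[p, 1]
        beta = theta[p, 2]
        if cidx[n] == 0:
            i, j = arm_a[n], arm_b[n]
        else:
            i, j = arm_b[n], arm_a[n]
        dv = q[i] - q[j]
        ll, s = _log_sigmoid(beta * dv)
        total += ll
        g = 1.0 - s
        grad[p, 2] += g * dv
        grad[p, 0] += g * beta * (dqc[i] - dqc[j])
        grad[p, 1] += g * beta * (dqu[i] - dqu[j])
        delta = reward[n] - q[i]
        ddelta_dac = -dqc[i]
        ddelta_dau = -dqu[i]
        dqc[i] = (1.0 - ac) * dqc[i] + delta
        dqu[i] = (1.0 - ac) * dqu[i]
        q[i] += ac * delta
        # unchosen moves opposite the chosen card's surprise; may overshoot
        qj = q[j] - au * delta
        if qj > 1.0:
            q[j] = 1.0
            dqc[j] = 0.0
            dqu[j] = 0.0
        elif qj < 0.0:
            q[j] = 0.0
            dqc[j] = 0.0
            dqu[j] = 0.0
        else:
            dqc[j] = dqc[j] - au * ddelta_dac
            dqu[j] = dqu[j] - delta - au * ddelta_dau
            q[j] = qj
    return total


@njit(cache=True)
def _llg_select_reject(pidx, new_seg, arm_a, arm_b, cidx, reward, theta, n_arms, grad):
    total = 0.0
    qs = np.empty(n_arms)
    qr = np.empty(n_arms)
    dqs = np.empty(n_arms)
    dqr = np.empty(n_arms)
    for n in range(pidx.shape[0]):
        if new_seg[n]:
            qs[:] = 0.5
            qr[:] = 0.5
            dqs[:] = 0.0
            dqr[:] = 0.0
        p = pidx[n]
        alpha = theta[p, 0]
        omega = theta[p, 1]
        beta = theta[p, 2]
        if cidx[n] == 0:
            i, j = arm_a[n], arm_b[n]
        else:
            i, j = arm_b[n], arm_a[n]
        vi = omega * qs[i] + (1.0 - omega) * qr[j]
        vj = omega * qs[j] + (1.0 - omega) * qr[i]
        dv = vi - vj
        ll, s = _log_sigmoid(beta * dv)
        total += ll
        g = 1.0 - s
        grad[p, 2] += g * dv
        grad[p, 1] += g * beta * ((qs[i] - qr[j]) - (qs[j] - qr[i]))
        dvi_da = omega * dqs[i] + (1.0 - omega) * dqr[j]
        dvj_da = omega * dqs[j] + (1.0 - omega) * dqr[i]
        grad[p, 0] += g * beta * (dvi_da - dvj_da)
        r = reward[n]
        delta = r - qs[i]
        dqs[i] = (1.0 - alpha) * dqs[i] + delta
        qs[i] += alpha * delta
        delta_u = r - qr[j]
        dqr[j] = (1.0 - alpha) * dqr[j] + delta_u
        qr[j] += alpha * delta_u
    return total


_LLG = {
    "baseline": _llg_baseline,
    "double_two_pe": _llg_double_two,
    "double_one_pe": _llg_double_one,
    "select_reject": _llg_select_reject,
}


def cohort_loglik_grad(
    model: str, packed: PackedCohort, theta: np.ndarray
) -> tuple[float, np.ndarray]:
    """Total choice log-likelihood and its gradient w.r.t. natural params.

    ``theta`` has shape (n_participants, n_params) on the natural scale,
    columns in the canonical parameter order of the model.
    """
    if model not in MODEL_IDS:
        raise ValueError(f"unknown model {model!r}")
    theta = np.ascontiguousarray(theta, dtype=np.float64)
    grad = np.zeros_like(theta)
    total = _LLG[model](
        packed.pidx,
        packed.new_seg,
        packed.arm_a,
        packed.arm_b,
        packed.cidx,
        packed.reward,
        theta,
        packed.n_arms,
        grad,
    )
    return float(total), grad


# ---------------------------------------------------------------------------
# per-row choice probabilities (for pointwise predictive densities)


@njit(cache=True)
def _probs_single_ledger(
    pidx, new_seg, arm_a, arm_b, cidx, reward, theta, n_arms, mode, out
):
    """Forward pass for the three single-ledger models.

    ``mode``: 0 baseline, 1 double_two_pe, 2 double_one_pe. Writes the
    probability of the observed choice into ``out`` per row.
    """
    q = np.empty(n_arms)
    for n in range(pidx.shape[0]):
        if new_seg[n]:
            q[:] = 0.5
        p = pidx[n]
        ac = theta[p, 0]
        if mode == 0:
            au = 0.0
            beta = theta[p, 1]
        else:
            au = theta[p, 1]
            beta = theta[p, 2]
        if cidx[n] == 0:
            i, j = arm_a[n], arm_b[n]
        else:
            i, j = arm_b[n], arm_a[n]
        _, s = _log_sigmoid(beta * (q[i] - q[j]))
        out[n] = s
        r = reward[n]
        delta = r - q[i]
        q[i] += ac * delta
        if mode == 1:
            q[j] += au * ((1 - r) - q[j])
        elif mode == 2:
            qj = q[j] - au * delta
            q[j] = min(1.0, max(0.0, qj))


@njit(cache=True)
def _probs_select_reject(pidx, new_seg, arm_a, arm_b, cidx, reward, theta, n_arms, out):
    qs = np.empty(n_arms)
    qr = np.empty(n_arms)
    for n in range(pidx.shape[0]):
        if new_seg[n]:
            qs[:] = 0.5
            qr[:] = 0.5
        p = pidx[n]
        alpha = theta[p, 0]
        omega = theta[p, 1]
        beta = theta[p, 2]
        if cidx[n] == 0:
            i, j = arm_a[n], arm_b[n]
        else:
            i, j = arm_b[n], arm_a[n]
        vi = omega * qs[i] + (1.0 - omega) * qr[j]
        vj = omega * qs[j] + (1.0 - omega) * qr[i]
        _, s = _log_sigmoid(beta * (vi - vj))
        out[n] = s
        r = reward[n]
        qs[i] += alpha * (r - qs[i])
        qr[j] += alpha * (r - qr[j])


def _rowwise_probs(model: str, packed: PackedCohort, theta: np.ndarray) -> np.ndarray:
    theta = np.ascontiguousarray(theta, dtype=np.float64)
    out = np.empty(packed.n_rows)
    args = (
        packed.pidx,
        packed.new_seg,
        packed.arm_a,
        packed.arm_b,
        packed.cidx,
        packed.reward,
        theta,
        packed.n_arms,
    )
    if model == "select_reject":
        _probs_select_reject(*args, out)
    else:
        mode = {"baseline": 0, "double_two_pe": 1, "double_one_pe": 2}[model]
        _probs_single_ledger(*args, mode, out)
    return out


def cohort_rowwise_logp(model: str, packed: PackedCohort, theta: np.ndarray) -> np.ndarray:
    """Per-trial log-probability of the observed choices at fixed params."""
    return np.log(_rowwise_probs(model, packed, theta))


def cohort_mean_choice_prob(
    model: str, packed: PackedCohort, thetas: np.ndarray
) -> np.ndarray:
    """Posterior-mean probability of each observed choice.

    ``thetas`` has shape (n_draws, n_participants, n_params); returns the
    across-draw mean probability per row (the Monte-Carlo predictive).
    """
    if thetas.ndim != 3:
        raise ValueError("thetas must be draws x participants x params")
    acc = np.zeros(packed.n_rows)
    for s in range(thetas.shape[0]):
        acc += _rowwise_probs(model, packed, thetas[s])
    return acc / thetas.shape[0]
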