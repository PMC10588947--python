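"""Self-contained No-U-Turn sampler with dual-averaging step-size and
diagonal mass-matrix adaptation.

The sampler takes an arbitrary ``logp_grad(x) -> (float, ndarray)``
callable on the unconstrained scale; the heavy likelihood gradients live
in compiled kernels, so a pure-Python tree builder is fast enough here.
Draws are exactly reproducible for a given seed and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["NutsConfig", "NutsResult", "sample_nuts"]

_DIVERGENCE_THRESHOLD = 1000.0


@dataclass(frozen=True)
class NutsConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 500
    seed: int = 0
    target_accept: float = 0.8
    max_treedepth: int = 10
    init_jitter: float = 0.5

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if self.draws < 1 or self.warmup < 10:
            raise ValueError("warmup must be >= 10 and draws >= 1")


@dataclass
class NutsResult:
    draws: np.ndarray  # (chains, draws, dim)
    divergences: np.ndarray  # per chain
    step_sizes: np.ndarray  # per chain, post-adaptation
    mean_accept: np.ndarray  # per chain


def _leapfrog(f, q, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    q = q + eps * inv_mass * p
    lp, grad = f(q)
    p = p + 0.5 * eps * grad
    return q, p, lp, grad


def _kinetic(p, inv_mass):
    return 0.5 * float(np.dot(p, inv_mass * p))


def _find_reasonable_epsilon(f, q, lp, grad, inv_mass, rng):
    eps = 1.0
    p = rng.standard_normal(q.shape) / np.sqrt(inv_mass)
    joint0 = lp - _kinetic(p, inv_mass)
    _, p1, lp1, _ = _leapfrog(f, q, p, grad, eps, inv_mass)
    joint1 = lp1 - _kinetic(p1, inv_mass) if np.isfinite(lp1) else -np.inf
    a = 1.0 if joint1 - joint0 > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**a
        _, p1, lp1, _ = _leapfrog(f, q, p, grad, eps, inv_mass)
        joint1 = lp1 - _kinetic(p1, inv_mass) if np.isfinite(lp1) else -np.inf
        if a * (joint1 - joint0) <= a * np.log(0.5):
            break
    return eps


class _Tree:
    """One NUTS trajectory tree (slice variant)."""

    __slots__ = ("f", "inv_mass", "rng", "log_u", "joint0", "eps", "alpha", "n_alpha", "diverged")

    def __init__(self, f, inv_mass, rng, log_u, joint0, eps):
        self.f = f
        self.inv_mass = inv_mass
        self.rng = rng
        self.log_u = log_u
        self.joint0 = joint0
        self.eps = eps
        self.alpha = 0.0
        self.n_alpha = 0
        self.diverged = False

    def build(self, q, p, grad, v, depth):
        """Returns (q-, p-, g-, q+, p+, g+, q_prop, n, keep_going)."""
        if depth == 0:
            q1, p1, lp1, g1 = _leapfrog(self.f, q, p, grad, v * self.eps, self.inv_mass)
            if np.isfinite(lp1):
                joint = lp1 - _kinetic(p1, self.inv_mass)
            else:
                joint = -np.inf
            n = 1 if self.log_u <= joint else 0
            ok = self.log_u < joint + _DIVERGENCE_THRESHOLD
            if not ok:
                self.diverged = True
            self.alpha += min(1.0, np.exp(min(0.0, joint - self.joint0)))
            self.n_alpha += 1
            return q1, p1, g1, q1, p1, g1, q1, n, ok
        qm, pm, gm, qp, pp, gp, qprop, n1, ok = self.build(q, p, grad, v, depth - 1)
        if ok:
            if v == -1:
                qm, pm, gm, _, _, _, qprop2, n2, ok = self.build(qm, pm, gm, v, depth - 1)
            else:
                _, _, _, qp, pp, gp, qprop2, n2, ok = self.build(qp, pp, gp, v, depth - 1)
            if n1 + n2 > 0 and self.rng.random() < n2 / (n1 + n2):
                qprop = qprop2
            n1 += n2
            if ok:
                dq = qp - qm
                ok = (
                    np.dot(dq, self.inv_mass * pm) >= 0
                    and np.dot(dq, self.inv_mass * pp) >= 0
                )
        return qm, pm, gm, qp, pp, gp, qprop, n1, ok


def _run_chain(f, dim, config, seed, init):
    rng = np.random.default_rng(seed)
    q = np.asarray(init, dtype=float)
    lp, grad = f(q)
    if not np.isfinite(lp):
        raise ValueError("log posterior is not finite at the initial point")
    inv_mass = np.ones(dim)

    # step-size dual averaging (Nesterov-style)
    gamma, t0, kappa = 0.05, 10.0, 0.75
    eps = _find_reasonable_epsilon(f, q, lp, grad, inv_mass, rng)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    adapt_m = 0

    warmup, draws = config.warmup, config.draws
    mass_lo = int(0.3 * warmup)
    mass_hi = int(0.85 * warmup)
    mass_buf = []

    out = np.empty((draws, dim))
    divergences = 0
    accepts = []

    for m in range(warmup + draws):
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        joint0 = lp - _kinetic(p0, inv_mass)
        log_u = joint0 - rng.exponential()
        tree = _Tree(f, inv_mass, rng, log_u, joint0, eps)
        qm = qp = q
        pm = pp = p0
        gm = gp = grad
        q_new = q
        n = 1
        ok = True
        depth = 0
        while ok and depth < config.max_treedepth:
            v = -1 if rng.random() < 0.5 else 1
            if v == -1:
                qm, pm, gm, _, _, _, qprop, n2, ok = tree.build(qm, pm, gm, v, depth)
            else:
                _, _, _, qp, pp, gp, qprop, n2, ok = tree.build(qp, pp, gp, v, depth)
            if ok and n2 > 0 and rng.random() < min(1.0, n2 / n):
                q_new = qprop
            n += n2
            if ok:
                dq = qp - qm
                ok = (
                    np.dot(dq, inv_mass * pm) >= 0
                    and np.dot(dq, inv_mass * pp) >= 0
                )
            depth += 1
        if not np.array_equal(q_new, q):
            q = q_new
            lp, grad = f(q)
        accept_stat = tree.alpha / max(tree.n_alpha, 1)

        if m < warmup:
            adapt_m += 1
            frac = 1.0 / (adapt_m + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (config.target_accept - accept_stat)
            log_eps = mu - np.sqrt(adapt_m) / gamma * h_bar
            w = adapt_m ** (-kappa)
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = np.exp(log_eps)
            if mass_lo <= m < mass_hi:
                mass_buf.append(q.copy())
            if m == mass_hi - 1 and len(mass_buf) > 10:
                sample = np.array(mass_buf)
                var = sample.var(axis=0, ddof=1)
                nb = len(mass_buf)
                var = (nb / (nb + 5.0)) * var + 1e-3 * (5.0 / (nb + 5.0))
                inv_mass = var
                # re-tune the step size for the new metric
                eps = _find_reasonable_epsilon(f, q, lp, grad, inv_mass, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, adapt_m = 0.0, 0.0, 0
            if m == warmup - 1:
                eps = np.exp(log_eps_bar)
        else:
            out[m - warmup] = q
            if tree.diverged:
                divergences += 1
            accepts.append(accept_stat)

    return out, divergences, eps, float(np.mean(accepts))


def sample_nuts(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    dim: int,
    config: NutsConfig,
    init: np.ndarray | None = None,
) -> NutsResult:
    """Sample ``config.chains`` independent NUTS chains (sequentially)."""
    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.spawn(config.chains)
    draws = np.empty((config.chains, config.draws, dim))
    divergences = np.empty(config.chains, dtype=int)
    step_sizes = np.empty(config.chains)
    mean_accept = np.empty(config.chains)
    for c, cs in enumerate(chain_seeds):
        rng_init = np.random.default_rng(cs.spawn(1)[0])
        x0 = np.zeros(dim) if init is None else np.asarray(init, dtype=float)
        x0 = x0 + config.init_jitter * rng_init.standard_normal(dim)
        chain_draws, div, eps, acc = _run_chain(logp_grad, dim, config, cs, x0)
        draws[c] = chain_draws
        divergences[c] = div
        step_sizes[c] = eps
        mean_accept[c] = acc
    return NutsResult(draws, divergences, step_sizes, mean_accept)
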