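"""No-U-Turn sampler (NUTS) with dual-averaging step size and diagonal mass
matrix adaptation.

A self-contained gradient-based MCMC backend: multinomial trajectory
sampling along doubling leapfrog trajectories, the generalized u-turn
criterion, Stan-style windowed warmup (step-size adaptation throughout,
expanding covariance windows for the diagonal metric), and divergence
bookkeeping.  The target is supplied as a callable returning the log
density and its gradient on the unconstrained scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["NutsConfig", "nuts_chain"]

_MAX_ENERGY_ERROR = 1000.0  # divergence threshold on the Hamiltonian error


@dataclass
class NutsConfig:
    warmup: int = 1000
    draws: int = 1000
    max_treedepth: int = 10
    target_accept: float = 0.9
    init_step: float = 0.1
    init_jitter: float = 1.0


@dataclass
class _State:
    q: np.ndarray
    p: np.ndarray
    grad: np.ndarray
    logp: float


@dataclass
class _Tree:
    left: _State
    right: _State
    proposal: _State
    logw: float
    divergent: bool
    turning: bool
    sum_alpha: float
    n_alpha: int


class _DualAveraging:
    """Nesterov dual averaging of log step size (standard NUTS schedule)."""

    def __init__(self, step0: float, target: float):
        self.mu = np.log(10.0 * step0)
        self.target = target
        self.log_step = np.log(step0)
        self.log_step_bar = 0.0
        self.h_bar = 0.0
        self.count = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept_stat: float) -> float:
        self.count += 1
        w = 1.0 / (self.count + self.t0)
        self.h_bar = (1 - w) * self.h_bar + w * (self.target - accept_stat)
        self.log_step = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        eta = self.count ** -self.kappa
        self.log_step_bar = eta * self.log_step + (1 - eta) * self.log_step_bar
        return np.exp(self.log_step)

    @property
    def adapted_step(self) -> float:
        return float(np.exp(self.log_step_bar))


def _kinetic(p: np.ndarray, minv: np.ndarray) -> float:
    return 0.5 * float(p @ (minv * p))


def _leapfrog(state: _State, eps: float, minv: np.ndarray, logp_grad) -> _State:
    p = state.p + 0.5 * eps * state.grad
    q = state.q + eps * (minv * p)
    logp, grad = logp_grad(q)
    p = p + 0.5 * eps * grad
    return _State(q, p, grad, logp)


def _energy(state: _State, minv: np.ndarray) -> float:
    return state.logp - _kinetic(state.p, minv)


def _turning(left: _State, right: _State, minv: np.ndarray) -> bool:
    dq = right.q - left.q
    return (dq @ (minv * left.p)) < 0 or (dq @ (minv * right.p)) < 0


def _build_tree(
    depth: int,
    state: _State,
    direction: int,
    eps: float,
    h0: float,
    minv: np.ndarray,
    logp_grad,
    rng: np.random.Generator,
) -> _Tree:
    if depth == 0:
        new = _leapfrog(state, direction * eps, minv, logp_grad)
        h = _energy(new, minv)
        dh = h - h0
        divergent = not np.isfinite(h) or (h0 - h) > _MAX_ENERGY_ERROR
        alpha = float(min(1.0, np.exp(min(dh, 0.0)))) if np.isfinite(dh) else 0.0
        logw = dh if np.isfinite(dh) else -np.inf
        return _Tree(new, new, new, logw, divergent, False, alpha, 1)

    first = _build_tree(depth - 1, state, direction, eps, h0, minv, logp_grad, rng)
    if first.divergent or first.turning:
        return first
    edge = first.right if direction > 0 else first.left
    second = _build_tree(depth - 1, edge, direction, eps, h0, minv, logp_grad, rng)

    logw = np.logaddexp(first.logw, second.logw)
    # multinomial sampling within the subtree
    take_second = np.log(rng.random()) < second.logw - logw
    proposal = second.proposal if take_second else first.proposal
    left = first.left if direction > 0 else second.left
    right = second.right if direction > 0 else first.right
    turning = second.turning or _turning(left, right, minv)
    return _Tree(
        left,
        right,
        proposal,
        logw,
        second.divergent,
        turning,
        first.sum_alpha + second.sum_alpha,
        first.n_alpha + second.n_alpha,
    )


def _nuts_step(
    q: np.ndarray,
    logp: float,
    grad: np.ndarray,
    eps: float,
    minv: np.ndarray,
    max_depth: int,
    logp_grad,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, np.ndarray, float, bool]:
    """One NUTS transition; returns (q, logp, grad, accept_stat, divergent)."""
    p0 = rng.standard_normal(q.shape) / np.sqrt(minv)
    current = _State(q, p0, grad, logp)
    h0 = _energy(current, minv)

    left = right = current
    sample = current
    logw_total = 0.0
    sum_alpha = 0.0
    n_alpha = 0
    divergent = False

    for depth in range(max_depth):
        direction = 1 if rng.random() < 0.5 else -1
        start = right if direction > 0 else left
        tree = _build_tree(depth, start, direction, eps, h0, minv, logp_grad, rng)
        sum_alpha += tree.sum_alpha
        n_alpha += tree.n_alpha
        if tree.divergent:
            divergent = True
            break
        if direction > 0:
            right = tree.right
        else:
            left = tree.left
        if tree.turning:
            break
        # biased progressive sampling: favor the new subtree
        if np.log(rng.random()) < tree.logw - logw_total:
            sample = tree.proposal
        logw_total = np.logaddexp(logw_total, tree.logw)
        if _turning(left, right, minv):
            break

    accept_stat = sum_alpha / max(n_alpha, 1)
    return sample.q, sample.logp, sample.grad, accept_stat, divergent


def _find_initial_step(
    q: np.ndarray, logp: float, grad: np.ndarray, minv: np.ndarray, logp_grad, rng
) -> float:
    """Heuristic: double/halve eps until the one-step acceptance crosses 1/2."""
    eps = 1.0
    p0 = rng.standard_normal(q.shape) / np.sqrt(minv)
    state = _State(q, p0, grad, logp)
    h0 = _energy(state, minv)

    def dh(eps):
        try:
            new = _leapfrog(state, eps, minv, logp_grad)
        except FloatingPointError:
            return -np.inf
        h = _energy(new, minv)
        return h - h0 if np.isfinite(h) else -np.inf

    direction = 1 if dh(eps) > np.log(0.5) else -1
    for _ in range(50):
        eps_new = eps * (2.0 if direction == 1 else 0.5)
        if (dh(eps_new) > np.log(0.5)) != (direction == 1):
            break
        eps = eps_new
    return eps


def _warmup_windows(n_warmup: int) -> list[tuple[int, int]]:
    """Stan-style schedule: (init buffer, doubling windows, term buffer)."""
    if n_warmup < 60:
        return []
    init, term = int(0.15 * n_warmup), int(0.10 * n_warmup)
    windows = []
    start, size = init, 25
    while start + size < n_warmup - term:
        end = start + size
        if start + 3 * size >= n_warmup - term:
            end = n_warmup - term  # absorb the remainder into the last window
        windows.append((start, end))
        start, size = end, 2 * size
    return windows


def nuts_chain(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    q0: np.ndarray,
    config: NutsConfig,
    rng: np.random.Generator,
) -> dict:
    """Run one adaptive NUTS chain.

    Returns a dict with ``draws`` (draws x dim), ``divergences`` (count in
    the sampling phase), ``step_size`` and ``inv_mass``.
    """
    # transient over/underflow during early exploration is handled by the
    # divergence checks; do not let it spam warnings
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        return _nuts_chain_inner(logp_grad, q0, config, rng)


def _nuts_chain_inner(logp_grad, q0, config, rng) -> dict:
    q = np.array(q0, dtype=float)
    logp, grad = logp_grad(q)
    if not np.isfinite(logp):
        raise RuntimeError("non-finite log posterior at the initial point")
    minv = np.ones_like(q)

    eps = _find_initial_step(q, logp, grad, minv, logp_grad, rng)
    da = _DualAveraging(eps, config.target_accept)
    windows = _warmup_windows(config.warmup)
    win_idx = 0
    acc = _Welford(len(q))

    for it in range(config.warmup):
        q, logp, grad, astat, _ = _nuts_step(
            q, logp, grad, eps, minv, config.max_treedepth, logp_grad, rng
        )
        eps = da.update(astat)
        if win_idx < len(windows):
            lo, hi = windows[win_idx]
            if lo <= it:
                acc.add(q)
            if it == hi - 1:
                var = acc.variance()
                n = acc.count
                # regularize toward unit metric as Stan does
                minv = (n / (n + 5.0)) * var + (5.0 / (n + 5.0)) * 1e-3
                acc = _Welford(len(q))
                win_idx += 1
                eps = _find_initial_step(q, logp, grad, minv, logp_grad, rng)
                da = _DualAveraging(eps, config.target_accept)

    eps = da.adapted_step if config.warmup >= 60 else eps
    draws = np.empty((config.draws, len(q)))
    divergences = 0
    for it in range(config.draws):
        q, logp, grad, _, div = _nuts_step(
            q, logp, grad, eps, minv, config.max_treedepth, logp_grad, rng
        )
        divergences += int(div)
        draws[it] = q
    return {"draws": draws, "divergences": divergences, "step_size": eps, "inv_mass": minv}


class _Welford:
    """Online mean/variance accumulator for metric adaptation."""

    def __init__(self, dim: int):
        self.count = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def add(self, x: np.ndarray) -> None:
        self.count += 1
        delta = x - self.mean
        self.mean += delta / self.count
        self.m2 += delta * (x - self.mean)

    def variance(self) -> np.ndarray:
        if self.count < 2:
            return np.ones_like(self.mean)
        return self.m2 / (self.count - 1)
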