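"""A No-U-Turn Hamiltonian Monte Carlo sampler over a generic log density.

Multinomial NUTS: trajectory states are selected with probability
proportional to their Boltzmann weight, the trajectory doubles until a
U-turn or the maximum tree depth, step size is tuned by dual averaging
toward a target acceptance statistic, and the mass matrix (diagonal or
dense) is estimated from warmup draws over expanding windows. The
Hamiltonian ("energy") of the selected state is recorded per draw so the
energy-based BFMI diagnostic can be computed downstream; transitions whose
energy error exceeds 1000 are flagged divergent.

The target density is supplied as ``logp_grad(x) -> (logp, grad)`` on an
unconstrained parameter vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["NUTSChain", "sample_nuts_chain"]

_DIVERGENCE_THRESHOLD = 1000.0
_MAX_TREEDEPTH = 10


class _Metric:
    """Euclidean metric: ``cov`` is the inverse mass matrix (posterior covariance).

    Diagonal when ``cov`` is 1-d, dense otherwise. Momenta are drawn from
    N(0, cov^-1); velocities are ``cov @ p``.
    """

    def __init__(self, cov: np.ndarray):
        self.cov = cov
        self.diag = cov.ndim == 1
        if not self.diag:
            # cov = L L^T; momentum p = L^-T xi has covariance (L L^T)^-1
            self._chol = np.linalg.cholesky(cov)

    def velocity(self, p: np.ndarray) -> np.ndarray:
        return self.cov * p if self.diag else self.cov @ p

    def kinetic(self, p: np.ndarray) -> float:
        return 0.5 * float(p @ self.velocity(p))

    def sample_momentum(self, rng: np.random.Generator, dim: int) -> np.ndarray:
        xi = rng.normal(size=dim)
        if self.diag:
            return xi / np.sqrt(self.cov)
        return np.linalg.solve(self._chol.T, xi)


@dataclass
class NUTSChain:
    """One chain's post-warmup output."""

    draws: np.ndarray  # (n_draws, dim)
    energy: np.ndarray  # (n_draws,)
    divergent: np.ndarray  # (n_draws,) bool
    accept_stat: np.ndarray  # (n_draws,)
    tree_depth: np.ndarray  # (n_draws,) int
    step_size: float
    inv_metric: np.ndarray


class _Leaf:
    __slots__ = ("q", "p", "grad", "logp", "H")

    def __init__(self, q, p, grad, logp, H):
        self.q, self.p, self.grad, self.logp, self.H = q, p, grad, logp, H


def _leapfrog(logp_grad, q, p, grad, eps, metric):
    p1 = p + 0.5 * eps * grad
    q1 = q + eps * metric.velocity(p1)
    lp1, g1 = logp_grad(q1)
    p2 = p1 + 0.5 * eps * g1
    return q1, p2, lp1, g1


def _is_turning(q_minus, p_minus, q_plus, p_plus, metric) -> bool:
    dq = q_plus - q_minus
    return (
        float(dq @ metric.velocity(p_minus)) < 0.0
        or float(dq @ metric.velocity(p_plus)) < 0.0
    )


def _find_reasonable_epsilon(logp_grad, q, lp, grad, metric, rng) -> float:
    eps = 1.0
    p = metric.sample_momentum(rng, q.size)
    h0 = -lp + metric.kinetic(p)
    _, p1, lp1, _ = _leapfrog(logp_grad, q, p, grad, eps, metric)
    h1 = -lp1 + metric.kinetic(p1) if np.isfinite(lp1) else np.inf
    direction = 1.0 if (h0 - h1) > math.log(0.5) else -1.0
    for _ in range(60):
        eps *= 2.0**direction
        _, p1, lp1, _ = _leapfrog(logp_grad, q, p, grad, eps, metric)
        h1 = -lp1 + metric.kinetic(p1) if np.isfinite(lp1) else np.inf
        if direction * (h0 - h1) < direction * math.log(0.5):
            break
    return eps


class _TreeState:
    """Running state of one trajectory doubling."""

    __slots__ = (
        "minus",
        "plus",
        "proposal",
        "log_sum_w",
        "sum_accept",
        "n_leapfrog",
        "divergent",
        "turning",
    )

    def __init__(self, leaf):
        self.minus = leaf
        self.plus = leaf
        self.proposal = leaf
        self.log_sum_w = 0.0
        self.sum_accept = 0.0
        self.n_leapfrog = 0
        self.divergent = False
        self.turning = False


def _build_tree(logp_grad, depth, leaf, direction, eps, h0, metric, rng):
    """Recursively build a subtree of 2**depth leapfrog steps.

    Returns (subtree_state, outermost_leaf). ``subtree_state.log_sum_w`` is
    relative to exp(-h0). Leaf momenta are stored in canonical (forward)
    orientation; backward integration negates on the way in and out.
    """
    if depth == 0:
        q1, p1, lp1, g1 = _leapfrog(
            logp_grad, leaf.q, direction * leaf.p, leaf.grad, eps, metric
        )
        h1 = (-lp1 + metric.kinetic(p1)) if np.isfinite(lp1) else np.inf
        new = _Leaf(q1, direction * p1, g1, lp1, h1)
        state = _TreeState(new)
        d_h = h1 - h0
        state.divergent = (not np.isfinite(d_h)) or d_h > _DIVERGENCE_THRESHOLD
        state.log_sum_w = -d_h if np.isfinite(d_h) else -np.inf
        state.sum_accept = min(1.0, math.exp(-d_h)) if np.isfinite(d_h) else 0.0
        state.n_leapfrog = 1
        return state, new

    first, edge = _build_tree(
        logp_grad, depth - 1, leaf, direction, eps, h0, metric, rng
    )
    if first.divergent or first.turning:
        return first, edge
    second, edge = _build_tree(
        logp_grad, depth - 1, edge, direction, eps, h0, metric, rng
    )
    first.n_leapfrog += second.n_leapfrog
    first.sum_accept += second.sum_accept
    first.divergent = second.divergent
    total = np.logaddexp(first.log_sum_w, second.log_sum_w)
    if math.log(rng.random() + 1e-300) < second.log_sum_w - total:
        first.proposal = second.proposal
    first.log_sum_w = total
    if direction > 0:
        first.plus = second.plus
    else:
        first.minus = second.minus
    first.turning = second.turning or _is_turning(
        first.minus.q, first.minus.p, first.plus.q, first.plus.p, metric
    )
    return first, edge


def _nuts_transition(logp_grad, leaf, eps, metric, rng, max_treedepth):
    """One NUTS draw; returns (leaf, energy, divergent, accept, depth)."""
    p0 = metric.sample_momentum(rng, leaf.q.size)
    h0 = -leaf.logp + metric.kinetic(p0)
    current = _Leaf(leaf.q, p0, leaf.grad, leaf.logp, h0)
    tree = _TreeState(current)
    divergent = False
    depth = 0
    while depth < max_treedepth:
        direction = 1.0 if rng.random() < 0.5 else -1.0
        start = tree.plus if direction > 0 else tree.minus
        sub, _ = _build_tree(logp_grad, depth, start, direction, eps, h0, metric, rng)
        tree.n_leapfrog += sub.n_leapfrog
        tree.sum_accept += sub.sum_accept
        divergent = divergent or sub.divergent
        if sub.divergent or sub.turning:
            break
        # biased progressive sampling toward the new subtree
        if math.log(rng.random() + 1e-300) < sub.log_sum_w - tree.log_sum_w:
            tree.proposal = sub.proposal
        tree.log_sum_w = np.logaddexp(tree.log_sum_w, sub.log_sum_w)
        if direction > 0:
            tree.plus = sub.plus
        else:
            tree.minus = sub.minus
        depth += 1
        if _is_turning(tree.minus.q, tree.minus.p, tree.plus.q, tree.plus.p, metric):
            break
    accept = tree.sum_accept / max(tree.n_leapfrog, 1)
    prop = tree.proposal
    return prop, prop.H, divergent, accept, depth


def _adaptation_windows(n_tune: int) -> list[int]:
    """Iteration indices (within warmup) at which the metric is re-estimated."""
    if n_tune < 60:
        return []
    init_buffer = max(int(0.15 * n_tune), 10) if n_tune < 150 else 75
    term_buffer = max(int(0.1 * n_tune), 10) if n_tune < 150 else 50
    base = 25
    ends = []
    start = init_buffer
    width = base
    while start + width <= n_tune - term_buffer:
        if start + 2 * width > n_tune - term_buffer:
            width = n_tune - term_buffer - start  # absorb the remainder
        ends.append(start + width)
        start += width
        width *= 2
    return ends


class _DualAveraging:
    """Nesterov dual averaging of log step size toward a target accept rate."""

    def __init__(self, eps0: float, target: float):
        self.target = target
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75
        self.restart(eps0)

    def update(self, accept: float) -> float:
        self.count += 1
        frac = 1.0 / (self.count + self.t0)
        self.h_bar = (1.0 - frac) * self.h_bar + frac * (self.target - accept)
        self.log_eps = self.mu - math.sqrt(self.count) / self.gamma * self.h_bar
        eta = self.count ** -self.kappa
        self.log_eps_bar = (1.0 - eta) * self.log_eps_bar + eta * self.log_eps
        return math.exp(self.log_eps)

    def restart(self, eps0: float) -> None:
        self.mu = math.log(10.0 * eps0)
        self.log_eps = math.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    @property
    def adapted(self) -> float:
        return math.exp(self.log_eps_bar)


def _estimate_cov(samples: np.ndarray, dense: bool) -> np.ndarray:
    """Regularized covariance of warmup draws, shrunk toward the unit metric."""
    n, dim = samples.shape
    shrink = n / (n + 5.0)
    floor = 1e-3 * (5.0 / (n + 5.0))
    if dense and n > 9:
        cov = np.cov(samples, rowvar=False)
        return shrink * cov + floor * np.eye(dim)
    return shrink * samples.var(axis=0, ddof=1) + floor


def sample_nuts_chain(
    logp_grad,
    x0: np.ndarray,
    n_tune: int,
    n_draws: int,
    target_accept: float = 0.99,
    rng: np.random.Generator | None = None,
    max_treedepth: int = _MAX_TREEDEPTH,
    dense_metric: bool = True,
) -> NUTSChain:
    """Run one NUTS chain: warmup with adaptation, then ``n_draws`` draws.

    A dense metric (full warmup covariance) is used when ``dense_metric``
    and the dimension is small enough for the estimate to be stable;
    otherwise the metric stays diagonal.
    """
    rng = rng or np.random.default_rng()
    x0 = np.asarray(x0, dtype=float)
    dim = x0.size
    lp, grad = logp_grad(x0)
    if not np.isfinite(lp):
        raise FloatingPointError("log density is not finite at the initial point")
    leaf = _Leaf(x0, np.zeros(dim), grad, lp, 0.0)
    metric = _Metric(np.ones(dim))

    eps = _find_reasonable_epsilon(logp_grad, leaf.q, leaf.logp, leaf.grad, metric, rng)
    da = _DualAveraging(eps, target_accept)
    window_ends = _adaptation_windows(n_tune)
    window_samples: list[np.ndarray] = []

    for it in range(n_tune):
        leaf, _, _, accept, _ = _nuts_transition(
            logp_grad, leaf, eps, metric, rng, max_treedepth
        )
        eps = da.update(accept)
        window_samples.append(leaf.q)
        if (it + 1) in window_ends:
            samples = np.asarray(window_samples)
            # a dense estimate needs comfortably more draws than dimensions
            use_dense = dense_metric and samples.shape[0] >= max(2 * dim, 10)
            metric = _Metric(_estimate_cov(samples, use_dense))
            window_samples = []
            eps = _find_reasonable_epsilon(
                logp_grad, leaf.q, leaf.logp, leaf.grad, metric, rng
            )
            da.restart(eps)
    if n_tune > 0:
        eps = da.adapted

    draws = np.empty((n_draws, dim))
    energy = np.empty(n_draws)
    divergent = np.zeros(n_draws, dtype=bool)
    accept_stat = np.empty(n_draws)
    tree_depth = np.empty(n_draws, dtype=int)
    for it in range(n_draws):
        leaf, h, div, accept, depth = _nuts_transition(
            logp_grad, leaf, eps, metric, rng, max_treedepth
        )
        draws[it] = leaf.q
        energy[it] = h
        divergent[it] = div
        accept_stat[it] = accept
        tree_depth[it] = depth
    return NUTSChain(
        draws=draws,
        energy=energy,
        divergent=divergent,
        accept_stat=accept_stat,
        tree_depth=tree_depth,
        step_size=eps,
        inv_metric=metric.cov,
    )
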