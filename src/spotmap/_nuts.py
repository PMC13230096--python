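"""No-U-Turn sampler with dual-averaging step-size and diagonal
mass-matrix adaptation.

Self-contained gradient-based MCMC used to fit the hierarchical spatial
model.  The implementation follows the classic recursive tree-doubling
formulation with a slice variable, a windowed warmup schedule for the
diagonal metric, and a divergence threshold on the Hamiltonian error.
Model-agnostic: the caller supplies ``logp_and_grad``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Tuple

import numpy as np

__all__ = ["NutsResult", "nuts_sample"]

_DIVERGENCE_THRESHOLD = 1000.0
_MAX_ENERGY = 1e18

LogpGrad = Callable[[np.ndarray], Tuple[float, np.ndarray]]


@dataclass
class NutsResult:
    draws: np.ndarray        # (n_draws, dim)
    logp: np.ndarray         # (n_draws,)
    diverging: np.ndarray    # (n_draws,) bool
    tree_depth: np.ndarray   # (n_draws,) int
    accept_stat: np.ndarray  # (n_draws,)
    step_size: float
    inv_mass: np.ndarray


def _kinetic(r: np.ndarray, inv_mass: np.ndarray) -> float:
    return 0.5 * float(np.dot(r * inv_mass, r))


class _Leapfrog:
    def __init__(self, f: LogpGrad, eps: float, inv_mass: np.ndarray):
        self.f = f
        self.eps = eps
        self.inv_mass = inv_mass

    def step(self, theta, r, grad, direction):
        eps = direction * self.eps
        r1 = r + 0.5 * eps * grad
        theta1 = theta + eps * self.inv_mass * r1
        logp1, grad1 = self.f(theta1)
        if not np.isfinite(logp1):
            logp1, grad1 = -np.inf, np.zeros_like(theta1)
        r1 = r1 + 0.5 * eps * grad1
        return theta1, r1, logp1, grad1


class _Tree:
    __slots__ = (
        "theta_minus", "r_minus", "grad_minus",
        "theta_plus", "r_plus", "grad_plus",
        "theta_prop", "logp_prop",
        "n", "cont", "alpha", "n_alpha", "diverged",
    )

    def __init__(self, theta, r, grad, theta_prop, logp_prop, n, cont,
                 alpha, n_alpha, diverged):
        self.theta_minus = self.theta_plus = theta
        self.r_minus = self.r_plus = r
        self.grad_minus = self.grad_plus = grad
        self.theta_prop = theta_prop
        self.logp_prop = logp_prop
        self.n = n
        self.cont = cont
        self.alpha = alpha
        self.n_alpha = n_alpha
        self.diverged = diverged


def _no_uturn(theta_minus, r_minus, theta_plus, r_plus, inv_mass) -> bool:
    d = theta_plus - theta_minus
    return (np.dot(d, inv_mass * r_minus) >= 0.0
            and np.dot(d, inv_mass * r_plus) >= 0.0)


def _build_tree(lf, theta, r, grad, log_u, direction, depth, joint0, rng):
    if depth == 0:
        theta1, r1, logp1, grad1 = lf.step(theta, r, grad, direction)
        joint = logp1 - _kinetic(r1, lf.inv_mass)
        diverged = (not np.isfinite(joint)) or (log_u - joint > _DIVERGENCE_THRESHOLD)
        n = 1 if log_u <= joint else 0
        alpha = min(1.0, np.exp(min(joint - joint0, 0.0))) if np.isfinite(joint) else 0.0
        return _Tree(theta1, r1, grad1, theta1, logp1, n, not diverged,
                     alpha, 1, diverged)

    tree = _build_tree(lf, theta, r, grad, log_u, direction, depth - 1, joint0, rng)
    if not tree.cont:
        return tree
    if direction == 1:
        sub = _build_tree(lf, tree.theta_plus, tree.r_plus, tree.grad_plus,
                          log_u, direction, depth - 1, joint0, rng)
        tree.theta_plus = sub.theta_plus
        tree.r_plus = sub.r_plus
        tree.grad_plus = sub.grad_plus
    else:
        sub = _build_tree(lf, tree.theta_minus, tree.r_minus, tree.grad_minus,
                          log_u, direction, depth - 1, joint0, rng)
        tree.theta_minus = sub.theta_minus
        tree.r_minus = sub.r_minus
        tree.grad_minus = sub.grad_minus
    total = tree.n + sub.n
    if sub.n > 0 and rng.random() < sub.n / total:
        tree.theta_prop = sub.theta_prop
        tree.logp_prop = sub.logp_prop
    tree.n = total
    tree.alpha += sub.alpha
    tree.n_alpha += sub.n_alpha
    tree.diverged = tree.diverged or sub.diverged
    tree.cont = (sub.cont and not sub.diverged
                 and _no_uturn(tree.theta_minus, tree.r_minus,
                               tree.theta_plus, tree.r_plus, lf.inv_mass))
    return tree


def _find_initial_step_size(f, theta, logp, grad, inv_mass, rng) -> float:
    """Heuristic: double/halve eps until the one-step acceptance crosses 1/2."""
    eps = 1.0
    r = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    joint0 = logp - _kinetic(r, inv_mass)
    lf = _Leapfrog(f, eps, inv_mass)
    theta1, r1, logp1, _ = lf.step(theta, r, grad, 1)
    joint1 = logp1 - _kinetic(r1, inv_mass)
    delta = joint1 - joint0 if np.isfinite(joint1) else -np.inf
    direction = 1 if delta > np.log(0.5) else -1
    for _ in range(100):
        eps *= 2.0 ** direction
        lf.eps = eps
        theta1, r1, logp1, _ = lf.step(theta, r, grad, 1)
        joint1 = logp1 - _kinetic(r1, inv_mass)
        delta = joint1 - joint0 if np.isfinite(joint1) else -np.inf
        if direction == 1 and delta <= np.log(0.5):
            break
        if direction == -1 and delta >= np.log(0.5):
            break
    return max(eps, 1e-10)


class _Welford:
    def __init__(self, dim: int):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def update(self, x: np.ndarray) -> None:
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self.m2 += delta * (x - self.mean)

    def variance(self) -> np.ndarray:
        if self.n < 2:
            return np.ones_like(self.mean)
        var = self.m2 / (self.n - 1)
        # Stan-style shrinkage toward a small diagonal
        w = self.n / (self.n + 5.0)
        return w * var + 1e-3 * (1.0 - w)


def _adaptation_windows(warmup: int) -> tuple[int, int, list[int]]:
    """(init_buffer, term_buffer, metric-update iteration indices)."""
    if warmup >= 150:
        init_buf, term_buf, base = 75, 50, 25
    else:
        init_buf = max(int(0.15 * warmup), 1)
        term_buf = max(int(0.10 * warmup), 1)
        base = max(warmup - init_buf - term_buf, 1)
    ends = []
    pos = init_buf
    size = base
    while pos + size < warmup - term_buf:
        ends.append(pos + size)
        pos += size
        size *= 2
    ends.append(warmup - term_buf)
    return init_buf, term_buf, ends


def nuts_sample(
    logp_and_grad: LogpGrad,
    init: np.ndarray,
    *,
    warmup: int,
    draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.9,
    max_treedepth: int = 10,
) -> NutsResult:
    """Run one NUTS chain; returns post-warmup draws only."""
    theta = np.asarray(init, dtype=float).copy()
    dim = theta.size
    logp, grad = logp_and_grad(theta)
    if not np.isfinite(logp):
        raise ValueError("non-finite log density at initial point")

    inv_mass = np.ones(dim)
    eps = _find_initial_step_size(logp_and_grad, theta, logp, grad, inv_mass, rng)

    # dual averaging state
    mu = np.log(10.0 * eps)
    log_eps_bar = 0.0
    h_bar = 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    init_buf, term_buf, window_ends = _adaptation_windows(warmup)
    welford = _Welford(dim)
    window_iter = iter(window_ends)
    next_window_end = next(window_iter, None)

    total = warmup + draws
    out = np.empty((draws, dim))
    out_logp = np.empty(draws)
    out_div = np.zeros(draws, dtype=bool)
    out_depth = np.zeros(draws, dtype=np.int64)
    out_accept = np.zeros(draws)

    da_iter = 0
    for it in range(total):
        adapting = it < warmup
        lf = _Leapfrog(logp_and_grad, eps, inv_mass)
        r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        joint0 = logp - _kinetic(r0, inv_mass)
        log_u = joint0 - rng.exponential()

        tree = _Tree(theta, r0, grad, theta, logp, 1, True, 0.0, 0, False)
        depth = 0
        diverged = False
        while tree.cont and depth < max_treedepth:
            direction = 1 if rng.random() < 0.5 else -1
            if direction == 1:
                sub = _build_tree(lf, tree.theta_plus, tree.r_plus, tree.grad_plus,
                                  log_u, 1, depth, joint0, rng)
                tree.theta_plus = sub.theta_plus
                tree.r_plus = sub.r_plus
                tree.grad_plus = sub.grad_plus
            else:
                sub = _build_tree(lf, tree.theta_minus, tree.r_minus, tree.grad_minus,
                                  log_u, -1, depth, joint0, rng)
                tree.theta_minus = sub.theta_minus
                tree.r_minus = sub.r_minus
                tree.grad_minus = sub.grad_minus
            diverged = diverged or sub.diverged
            if sub.cont and sub.n > 0 and rng.random() < min(1.0, sub.n / tree.n):
                tree.theta_prop = sub.theta_prop
                tree.logp_prop = sub.logp_prop
            tree.n += sub.n
            tree.alpha += sub.alpha
            tree.n_alpha += sub.n_alpha
            tree.cont = (sub.cont
                         and _no_uturn(tree.theta_minus, tree.r_minus,
                                       tree.theta_plus, tree.r_plus, inv_mass))
            depth += 1

        if not np.array_equal(tree.theta_prop, theta):
            theta = tree.theta_prop
            logp = tree.logp_prop
            _, grad = logp_and_grad(theta)
        accept_stat = tree.alpha / max(tree.n_alpha, 1)

        if adapting:
            da_iter += 1
            frac = 1.0 / (da_iter + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - accept_stat)
            log_eps = mu - np.sqrt(da_iter) / gamma * h_bar
            weight = da_iter ** (-kappa)
            log_eps_bar = weight * log_eps + (1.0 - weight) * log_eps_bar
            eps = float(np.exp(log_eps))

            in_slow = init_buf <= it < warmup - term_buf
            if in_slow:
                welford.update(theta)
            if next_window_end is not None and it + 1 == next_window_end:
                if welford.n >= 10:
                    inv_mass = welford.variance()
                welford = _Welford(dim)
                next_window_end = next(window_iter, None)
                # restart step-size adaptation around the current value
                eps = _find_initial_step_size(
                    logp_and_grad, theta, logp, grad, inv_mass, rng
                )
                mu = np.log(10.0 * eps)
                h_bar = 0.0
                log_eps_bar = np.log(eps)
                da_iter = 0
            if it == warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            i = it - warmup
            out[i] = theta
            out_logp[i] = logp
            out_div[i] = diverged
            out_depth[i] = depth
            out_accept[i] = accept_stat

    return NutsResult(out, out_logp, out_div, out_depth, out_accept,
                      float(eps), inv_mass)
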