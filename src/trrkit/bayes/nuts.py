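"""No-U-Turn sampler with dual-averaging step-size adaptation.

A self-contained implementation of the efficient NUTS variant
(Hoffman & Gelman, 2014, Algorithm 6) with a diagonal mass matrix
estimated during warmup in expanding windows, in the style of Stan's
adaptation schedule.  Operates on any target exposing
``logp_and_grad(theta) -> (float, ndarray)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NUTSResult", "sample_nuts"]

_MAX_DELTA = 1000.0  # energy error declaring a divergence


@dataclass
class NUTSResult:
    """Raw draws from one or more chains on the unconstrained scale."""

    draws: np.ndarray            # (n_chains, n_draws, dim)
    step_size: np.ndarray        # final step size per chain
    n_divergent: np.ndarray      # post-warmup divergences per chain
    treedepth: np.ndarray        # (n_chains, n_draws)
    accept_stat: np.ndarray      # (n_chains, n_draws)
    logp: np.ndarray             # (n_chains, n_draws)

    @property
    def divergence_fraction(self) -> float:
        return float(self.n_divergent.sum()) / max(self.treedepth.size, 1)


def _leapfrog(target, theta, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    theta = theta + eps * inv_mass * p
    lp, grad = target.logp_and_grad(theta)
    p = p + 0.5 * eps * grad
    return theta, p, lp, grad


def _kinetic(p, inv_mass):
    return 0.5 * float(np.dot(p, inv_mass * p))


def _find_reasonable_step(target, theta, rng, inv_mass):
    eps = 1.0
    lp, grad = target.logp_and_grad(theta)
    p = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    h0 = lp - _kinetic(p, inv_mass)
    t1, p1, lp1, _ = _leapfrog(target, theta, p, grad, eps, inv_mass)
    h1 = lp1 - _kinetic(p1, inv_mass)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.8) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        t1, p1, lp1, _ = _leapfrog(target, theta, p, grad, eps, inv_mass)
        h1 = lp1 - _kinetic(p1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.8):
            break
    return float(np.clip(eps, 1e-8, 1e3))


class _Tree:
    """State carried through the recursive tree doubling."""

    __slots__ = (
        "theta_m", "p_m", "grad_m", "theta_p", "p_p", "grad_p",
        "theta_prop", "lp_prop", "grad_prop", "n_valid", "stop",
        "alpha_sum", "n_alpha", "divergent",
    )


def _build_tree(target, state, log_u, v, depth, eps, h0, inv_mass, rng):
    """Recursively double; returns a _Tree."""
    if depth == 0:
        theta, p, lp, grad = _leapfrog(
            target, state[0], state[1], state[2], v * eps, inv_mass
        )
        h = lp - _kinetic(p, inv_mass) if np.isfinite(lp) else -np.inf
        t = _Tree()
        t.theta_m = t.theta_p = theta
        t.p_m = t.p_p = p
        t.grad_m = t.grad_p = grad
        t.theta_prop, t.lp_prop, t.grad_prop = theta, lp, grad
        t.n_valid = int(log_u <= h)
        t.divergent = bool(log_u > h + _MAX_DELTA) or not np.isfinite(h)
        t.stop = t.divergent
        t.alpha_sum = float(min(1.0, np.exp(h - h0))) if np.isfinite(h) else 0.0
        t.n_alpha = 1
        return t

    t = _build_tree(target, state, log_u, v, depth - 1, eps, h0, inv_mass, rng)
    if not t.stop:
        if v == -1:
            sub = _build_tree(
                target, (t.theta_m, t.p_m, t.grad_m), log_u, v, depth - 1, eps, h0,
                inv_mass, rng,
            )
            t.theta_m, t.p_m, t.grad_m = sub.theta_m, sub.p_m, sub.grad_m
        else:
            sub = _build_tree(
                target, (t.theta_p, t.p_p, t.grad_p), log_u, v, depth - 1, eps, h0,
                inv_mass, rng,
            )
            t.theta_p, t.p_p, t.grad_p = sub.theta_p, sub.p_p, sub.grad_p
        total = t.n_valid + sub.n_valid
        if sub.n_valid > 0 and rng.random() < sub.n_valid / total:
            t.theta_prop, t.lp_prop, t.grad_prop = (
                sub.theta_prop, sub.lp_prop, sub.grad_prop,
            )
        t.n_valid = total
        dtheta = t.theta_p - t.theta_m
        uturn = (
            np.dot(dtheta, inv_mass * t.p_m) < 0 or np.dot(dtheta, inv_mass * t.p_p) < 0
        )
        t.stop = sub.stop or uturn
        t.divergent = t.divergent or sub.divergent
        t.alpha_sum += sub.alpha_sum
        t.n_alpha += sub.n_alpha
    return t


def sample_nuts(
    target,
    theta0: np.ndarray,
    n_iter: int,
    n_warmup: int,
    rng: np.random.Generator,
    max_treedepth: int = 8,
    target_accept: float = 0.8,
) -> NUTSResult:
    """Run one NUTS chain; returns post-warmup draws."""
    dim = theta0.size
    inv_mass = np.ones(dim)
    theta = theta0.copy()
    lp, grad = target.logp_and_grad(theta)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite density")

    eps = _find_reasonable_step(target, theta, rng, inv_mass)
    # dual averaging state; da_t restarts whenever the metric changes
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar, da_t = 0.0, 0.0, 0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    # mass-adaptation windows (Stan-like: init buffer, doubling windows, term buffer)
    init_buf = min(75, max(10, n_warmup // 10))
    term_buf = min(50, max(10, n_warmup // 10))
    window_ends = []
    w = 25
    pos = init_buf
    while pos + w < n_warmup - term_buf:
        window_ends.append(min(pos + w, n_warmup - term_buf))
        pos += w
        w *= 2
    if not window_ends and n_warmup > init_buf + term_buf:
        window_ends = [n_warmup - term_buf]
    welford_n, welford_m, welford_s = 0, np.zeros(dim), np.zeros(dim)

    n_keep = n_iter - n_warmup
    draws = np.empty((n_keep, dim))
    logps = np.empty(n_keep)
    depths = np.zeros(n_keep, dtype=np.int64)
    accepts = np.zeros(n_keep)
    n_div = 0

    for it in range(n_iter):
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - _kinetic(p0, inv_mass)
        log_u = h0 + np.log(rng.random())
        theta_m = theta_p = theta
        p_m = p_p = p0
        grad_m = grad_p = grad
        depth, n_valid, stop = 0, 1, False
        alpha_sum, n_alpha, divergent = 0.0, 1, False
        theta_new, lp_new, grad_new = theta, lp, grad
        while not stop and depth < max_treedepth:
            v = 1 if rng.random() < 0.5 else -1
            if v == -1:
                t = _build_tree(
                    target, (theta_m, p_m, grad_m), log_u, v, depth, eps, h0,
                    inv_mass, rng,
                )
                theta_m, p_m, grad_m = t.theta_m, t.p_m, t.grad_m
            else:
                t = _build_tree(
                    target, (theta_p, p_p, grad_p), log_u, v, depth, eps, h0,
                    inv_mass, rng,
                )
                theta_p, p_p, grad_p = t.theta_p, t.p_p, t.grad_p
            if not t.stop and t.n_valid > 0 and rng.random() < t.n_valid / max(n_valid, 1):
                theta_new, lp_new, grad_new = t.theta_prop, t.lp_prop, t.grad_prop
            n_valid += t.n_valid
            divergent = divergent or t.divergent
            alpha_sum, n_alpha = t.alpha_sum, t.n_alpha
            dtheta = theta_p - theta_m
            stop = t.stop or (
                np.dot(dtheta, inv_mass * p_m) < 0 or np.dot(dtheta, inv_mass * p_p) < 0
            )
            depth += 1
        theta, lp, grad = theta_new, lp_new, grad_new
        accept_stat = alpha_sum / max(n_alpha, 1)

        if it < n_warmup:
            # dual averaging
            da_t += 1
            frac = 1.0 / (da_t + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - accept_stat)
            log_eps = mu - np.sqrt(da_t) / gamma * h_bar
            w_k = da_t ** (-kappa)
            log_eps_bar = w_k * log_eps + (1 - w_k) * log_eps_bar
            eps = float(np.exp(log_eps))
            # mass-matrix accumulation
            if it >= init_buf and window_ends and it < window_ends[-1]:
                welford_n += 1
                delta = theta - welford_m
                welford_m += delta / welford_n
                welford_s += delta * (theta - welford_m)
                if it + 1 == window_ends[0]:
                    if welford_n > 4:
                        var = welford_s / (welford_n - 1)
                        # regularized as in Stan
                        var = (welford_n / (welford_n + 5.0)) * var + 1e-3 * (
                            5.0 / (welford_n + 5.0)
                        )
                        inv_mass = var
                        eps = _find_reasonable_step(target, theta, rng, inv_mass)
                        mu = np.log(10.0 * eps)
                        log_eps_bar, h_bar, da_t = 0.0, 0.0, 0
                    welford_n, welford_m[:], welford_s[:] = 0, 0.0, 0.0
                    window_ends.pop(0)
            if it + 1 == n_warmup:
                eps = float(np.exp(log_eps_bar))
        else:
            k = it - n_warmup
            draws[k] = theta
            logps[k] = lp
            depths[k] = depth
            accepts[k] = accept_stat
            n_div += int(divergent)

    return NUTSResult(
        draws=draws[None, :, :],
        step_size=np.array([eps]),
        n_divergent=np.array([n_div]),
        treedepth=depths[None, :],
        accept_stat=accepts[None, :],
        logp=logps[None, :],
    )
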