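"""A compact Hamiltonian Monte Carlo sampler with warmup adaptation.

Static-trajectory HMC with jittered path length, dual-averaging step-size
adaptation toward a target acceptance rate, and a diagonal mass matrix
estimated from the second half of warmup. Gradients are supplied
analytically by the caller, which keeps the sampler dependency-free and fast
for the few-hundred-dimensional hierarchical posteriors this package fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class HMCResult:
    draws: np.ndarray  # (n_draws, dim)
    accept_rate: float
    divergences: int
    step_size: float


def _leapfrog(
    q: np.ndarray,
    p: np.ndarray,
    grad: np.ndarray,
    eps: float,
    n_steps: int,
    logp_grad: LogpGrad,
    inv_mass: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    p = p + 0.5 * eps * grad
    logp = -np.inf
    for step in range(n_steps):
        q = q + eps * inv_mass * p
        if not np.all(np.isfinite(q)):
            return q, p, -np.inf, grad
        logp, grad = logp_grad(q)
        if not np.isfinite(logp):
            return q, p, -np.inf, grad
        if step != n_steps - 1:
            p = p + eps * grad
    p = p + 0.5 * eps * grad
    return q, p, logp, grad


def sample_chain(
    logp_grad: LogpGrad,
    q0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    max_leapfrog: int = 24,
    target_accept: float = 0.8,
    init_step: float = 0.1,
) -> HMCResult:
    """Run one HMC chain; returns post-warmup draws only."""
    dim = len(q0)
    q = q0.copy()
    logp, grad = logp_grad(q)
    inv_mass = np.ones(dim)

    # Dual-averaging state (step-size adaptation).
    mu = np.log(10.0 * init_step)
    log_eps = np.log(init_step)
    log_eps_bar = 0.0
    h_bar = 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    window: list[np.ndarray] = []  # warmup draws used for mass estimation
    mass_switch = n_warmup // 2
    draws = np.empty((n_draws, dim))
    divergences = 0
    accepts = 0.0
    total = 0

    with np.errstate(over="ignore", invalid="ignore"):
        for it in range(n_warmup + n_draws):
            warming = it < n_warmup
            eps = float(np.exp(log_eps if warming else log_eps_bar))
            n_steps = int(rng.integers(max(1, max_leapfrog // 2), max_leapfrog + 1))
            p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
            h0 = -logp + 0.5 * float(np.sum(inv_mass * p0 * p0))
            q_new, p_new, logp_new, grad_new = _leapfrog(
                q, p0, grad, eps, n_steps, logp_grad, inv_mass
            )
            h1 = -logp_new + 0.5 * float(np.sum(inv_mass * p_new * p_new))
            delta_h = h0 - h1
            if not np.isfinite(delta_h) or delta_h < -500.0:
                alpha = 0.0
                if not warming:
                    divergences += 1
            else:
                alpha = min(1.0, float(np.exp(min(delta_h, 0.0))))
            if rng.random() < alpha:
                q, logp, grad = q_new, logp_new, grad_new
            if warming:
                m = it + 1
                h_bar = (1 - 1 / (m + t0)) * h_bar + (target_accept - alpha) / (m + t0)
                log_eps = mu - np.sqrt(m) / gamma * h_bar
                eta = m ** (-kappa)
                log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
                if it >= mass_switch // 2:
                    window.append(q.copy())
                if it == mass_switch and len(window) > 10:
                    var = np.var(np.asarray(window), axis=0)
                    inv_mass = np.clip(var, 1e-4, 1e4)
                    window = []
                    # restart step-size adaptation under the new metric
                    mu = np.log(10.0 * np.exp(log_eps))
                    h_bar = 0.0
            else:
                draws[it - n_warmup] = q
                accepts += alpha
                total += 1

    return HMCResult(
        draws=draws,
        accept_rate=accepts / max(total, 1),
        divergences=divergences,
        step_size=float(np.exp(log_eps_bar)),
    )
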