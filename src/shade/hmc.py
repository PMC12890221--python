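"""Adaptive Hamiltonian Monte Carlo on an unconstrained parameter vector.

A compact HMC implementation used for posterior inference throughout the
package: leapfrog integration with a diagonal mass matrix, dual-averaging
step-size adaptation toward a target acceptance rate, and a variance-based
mass update during warmup.  Trajectory lengths are jittered to avoid
resonance.  The model supplies a callable returning the unnormalized log
posterior and its gradient; the sampler is model-agnostic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sample_chain", "sample_posterior"]

_DIVERGENCE_ENERGY = 1000.0


def _leapfrog(logp_grad, q, p, eps, n_steps, inv_mass):
    logp, grad = logp_grad(q)
    for _ in range(n_steps):
        p = p + 0.5 * eps * grad
        q = q + eps * inv_mass * p
        logp, grad = logp_grad(q)
        if not np.isfinite(logp):
            return q, p, -np.inf, grad
        p = p + 0.5 * eps * grad
    return q, p, logp, grad


def _find_initial_step(logp_grad, q, inv_mass, rng):
    """Heuristic: double/halve eps until the one-step acceptance crosses 0.5."""
    eps = 0.1
    logp0, _ = logp_grad(q)
    p0 = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    h0 = logp0 - 0.5 * np.sum(inv_mass * p0**2)
    _, p1, logp1, _ = _leapfrog(logp_grad, q, p0, eps, 1, inv_mass)
    h1 = logp1 - 0.5 * np.sum(inv_mass * p1**2)
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        _, p1, logp1, _ = _leapfrog(logp_grad, q, p0, eps, 1, inv_mass)
        h1 = logp1 - 0.5 * np.sum(inv_mass * p1**2)
        if direction * (h1 - h0) < direction * np.log(0.5):
            break
    return eps


def sample_chain(
    logp_grad,
    init,
    n_warmup=500,
    n_draws=500,
    seed=0,
    target_accept=0.8,
    path_length=1.0,
    max_leapfrog=64,
):
    """Run one HMC chain; returns (draws, stats).

    ``draws`` has shape (n_draws, dim).  ``stats`` reports the mean
    acceptance probability, divergence count and adapted step size.
    """
    rng = np.random.default_rng(seed)
    q = np.asarray(init, dtype=float).copy()
    dim = q.size
    inv_mass = np.ones(dim)
    eps = _find_initial_step(logp_grad, q, inv_mass, rng)

    # dual averaging state (re-initialized after the mass-matrix update)
    def fresh_da(eps0):
        return {"mu": np.log(10.0 * eps0), "log_eps_bar": 0.0, "h_bar": 0.0, "t": 0}

    da = fresh_da(eps)
    gamma, t0, kappa = 0.05, 10.0, 0.75

    mass_window = []
    window_start = int(0.4 * n_warmup)
    window_end = int(0.9 * n_warmup)

    draws = np.empty((n_draws, dim))
    logp, _ = logp_grad(q)
    n_div = 0
    accept_probs = []

    total = n_warmup + n_draws
    for it in range(total):
        warm = it < n_warmup
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = logp - 0.5 * np.sum(inv_mass * p0**2)
        n_base = max(1, min(max_leapfrog, int(round(path_length / eps))))
        n_steps = int(rng.integers(max(1, int(0.7 * n_base)), n_base + 1))
        q1, p1, logp1, _ = _leapfrog(logp_grad, q, p0, eps, n_steps, inv_mass)
        h1 = logp1 - 0.5 * np.sum(inv_mass * p1**2) if np.isfinite(logp1) else -np.inf
        delta_h = h1 - h0
        if not np.isfinite(delta_h) or delta_h < -_DIVERGENCE_ENERGY:
            alpha = 0.0
            if not warm:
                n_div += 1
        else:
            alpha = min(1.0, np.exp(min(delta_h, 0.0)))
            if np.log(rng.uniform()) < delta_h:
                q, logp = q1, logp1
        if warm:
            da["t"] += 1
            frac = 1.0 / (da["t"] + t0)
            da["h_bar"] = (1 - frac) * da["h_bar"] + frac * (target_accept - alpha)
            log_eps = da["mu"] - np.sqrt(da["t"]) / gamma * da["h_bar"]
            w = da["t"] ** (-kappa)
            da["log_eps_bar"] = w * log_eps + (1 - w) * da["log_eps_bar"]
            eps = np.exp(log_eps)
            if window_start <= it < window_end:
                mass_window.append(q.copy())
            if it == window_end - 1 and len(mass_window) >= 10:
                var = np.var(np.asarray(mass_window), axis=0)
                inv_mass = np.clip(var, 1e-6, 1e6)
                eps = _find_initial_step(logp_grad, q, inv_mass, rng)
                da = fresh_da(eps)
            if it == n_warmup - 1:
                eps = np.exp(da["log_eps_bar"])
        else:
            accept_probs.append(alpha)
            draws[it - n_warmup] = q
    stats = {
        "accept_rate": float(np.mean(accept_probs)) if accept_probs else np.nan,
        "divergences": n_div,
        "step_size": float(eps),
    }
    return draws, stats


def sample_posterior(
    logp_grad,
    init,
    n_warmup=500,
    n_draws=500,
    chains=2,
    seed=0,
    target_accept=0.8,
    jitter=0.1,
    **kwargs,
):
    """Run several chains from jittered starts; returns (chains, draws, dim)
    array plus per-chain stats."""
    rng = np.random.default_rng(seed)
    init = np.asarray(init, dtype=float)
    all_draws = np.empty((chains, n_draws, init.size))
    stats = []
    for c in range(chains):
        start = init + jitter * rng.standard_normal(init.size)
        chain_seed = int(rng.integers(0, 2**31 - 1))
        d, s = sample_chain(
            logp_grad, start, n_warmup=n_warmup, n_draws=n_draws,
            seed=chain_seed, target_accept=target_accept, **kwargs,
        )
        all_draws[c] = d
        stats.append(s)
    return all_draws, stats
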