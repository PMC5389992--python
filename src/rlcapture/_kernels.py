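"""Numba-compiled trial walkers used by the likelihood and the MCMC sampler.

Stimuli are encoded 0..5 (A..F). Trials enter as (n_subjects, T) integer
arrays; an `include` mask drops omitted trials and trials outside the fit
scope (excluded trials contribute neither a likelihood factor nor a Q update).
"""
from __future__ import annotations

import numpy as np
from numba import njit

P_FLOOR = 1e-12


@njit(cache=True)
def _p_first(delta: float) -> float:
    # P(choose first | beta*(q_first - q_second) = delta), overflow-safe
    if delta >= 0.0:
        return 1.0 / (1.0 + np.exp(-delta))
    e = np.exp(delta)
    return e / (1.0 + e)


@njit(cache=True)
def seq_loglik_many(
    chosen: np.ndarray,       # (n, T) int64, stimulus index of the choice
    first: np.ndarray,        # (n, T) int64, first presented stimulus
    second: np.ndarray,       # (n, T) int64, second presented stimulus
    reward: np.ndarray,       # (n, T) int64 in {0, 1}
    include: np.ndarray,      # (n, T) bool
    alpha_high: np.ndarray,   # (n,)
    alpha_low: np.ndarray,    # (n,)
    beta: np.ndarray,         # (n,)
    q_init: float,
) -> np.ndarray:
    n, T = chosen.shape
    out = np.zeros(n)
    for i in range(n):
        q = np.full(6, q_init)
        for t in range(T):
            if not include[i, t]:
                continue
            a = first[i, t]
            b = second[i, t]
            c = chosen[i, t]
            p = _p_first(beta[i] * (q[a] - q[b]))
            if c != a:
                p = 1.0 - p
            if p < P_FLOOR:
                p = P_FLOOR
            out[i] += np.log(p)
            r = reward[i, t]
            if r == 1:
                q[c] += alpha_high[i] * (1.0 - q[c])
            else:
                q[c] += alpha_low[i] * (0.0 - q[c])
    return out


@njit(cache=True)
def simulate_choices(
    first: np.ndarray,        # (T,) int64
    second: np.ndarray,       # (T,) int64
    p_high: np.ndarray,       # (6,) scheduled P(high reward) per stimulus
    alpha_high: float,
    alpha_low: float,
    beta: float,
    q_init: float,
    u_choice: np.ndarray,     # (T,) uniforms for the choice draw
    u_reward: np.ndarray,     # (T,) uniforms for the reward draw
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-simulate one agent; returns (chosen index, reward) per trial."""
    T = first.shape[0]
    chosen = np.empty(T, dtype=np.int64)
    reward = np.empty(T, dtype=np.int64)
    q = np.full(6, q_init)
    for t in range(T):
        a = first[t]
        b = second[t]
        p = _p_first(beta * (q[a] - q[b]))
        c = a if u_choice[t] < p else b
        r = 1 if u_reward[t] < p_high[c] else 0
        chosen[t] = c
        reward[t] = r
        if r == 1:
            q[c] += alpha_high * (1.0 - q[c])
        else:
            q[c] += alpha_low * (0.0 - q[c])
    return chosen, reward


@njit(cache=True)
def final_q_values(
    chosen: np.ndarray,
    reward: np.ndarray,
    include: np.ndarray,
    alpha_high: float,
    alpha_low: float,
    q_init: float,
) -> np.ndarray:
    """Q values after walking one subject's trial sequence."""
    q = np.full(6, q_init)
    for t in range(chosen.shape[0]):
        if not include[t]:
            continue
        c = chosen[t]
        if reward[t] == 1:
            q[c] += alpha_high * (1.0 - q[c])
        else:
            q[c] += alpha_low * (0.0 - q[c])
    return q
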