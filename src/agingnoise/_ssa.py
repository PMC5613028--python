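"""Numba kernels for exact stochastic simulation of the two-state promoter model.

Reaction set (promoter g in {0, 1}, mRNA m, protein p):

    OFF -> ON        rate r_on          (g: 0 -> 1)
    ON  -> OFF       rate r_off         (g: 1 -> 0)
    ON  -> ON + M    rate k_m           (m -> m + 1, only while g = 1)
    M   -> 0         rate gamma_m * m
    M   -> M + P     rate k_p * m
    P   -> 0         rate gamma_p * p

Direct-method Gillespie sampling; waiting times are exponential in the total
propensity. All kernels are seeded explicitly so trajectories are bit-identical
for identical inputs.
"""

import numpy as np
from numba import njit

__all__ = ["ssa_segment", "ssa_ensemble_final"]


@njit(cache=True)
def ssa_segment(
    r_on, r_off, k_m, gamma_m, k_p, gamma_p,
    g0, m0, p0,
    sample_times, t_end, seed,
):
    """Advance one trajectory from t=0 to t_end, recording state at sample_times.

    sample_times must be sorted and lie in [0, t_end]. Recorded state at a
    sample time is the state immediately before any event at that instant.
    Returns (g_out, m_out, p_out, g_final, m_final, p_final). Zero total
    propensity freezes the state until t_end.
    """
    np.random.seed(seed)
    t = 0.0
    g = g0
    m = m0
    p = p0
    n = sample_times.shape[0]
    g_out = np.empty(n, np.int64)
    m_out = np.empty(n, np.int64)
    p_out = np.empty(n, np.int64)
    i = 0
    while True:
        a1 = r_on if g == 0 else 0.0
        a2 = r_off if g == 1 else 0.0
        a3 = k_m if g == 1 else 0.0
        a4 = gamma_m * m
        a5 = k_p * m
        a6 = gamma_p * p
        a0 = a1 + a2 + a3 + a4 + a5 + a6
        if a0 <= 0.0:
            t_next = np.inf
        else:
            t_next = t + np.random.exponential(1.0 / a0)
        while i < n and sample_times[i] <= t_next:
            g_out[i] = g
            m_out[i] = m
            p_out[i] = p
            i += 1
        if t_next >= t_end:
            break
        t = t_next
        u = np.random.random() * a0
        if u < a1:
            g = 1
        elif u < a1 + a2:
            g = 0
        elif u < a1 + a2 + a3:
            m += 1
        elif u < a1 + a2 + a3 + a4:
            m -= 1
        elif u < a1 + a2 + a3 + a4 + a5:
            p += 1
        else:
            p -= 1
    return g_out, m_out, p_out, g, m, p


@njit(cache=True)
def ssa_ensemble_final(
    r_on, r_off, k_m, gamma_m, k_p, gamma_p,
    p_on_init, m_on, p_on_state, m_off, p_off_state,
    t_end, seeds,
):
    """Final (m, p) of independent replicates at t_end, one RNG stream per seed.

    The promoter initial state is Bernoulli(p_on_init) per replicate; mRNA and
    protein start at the supplied state-conditional values.
    """
    n = seeds.shape[0]
    m_fin = np.empty(n, np.int64)
    p_fin = np.empty(n, np.int64)
    empty = np.empty(0, np.float64)
    for r in range(n):
        np.random.seed(seeds[r])
        if np.random.random() < p_on_init:
            g0, m0, p0 = 1, m_on, p_on_state
        else:
            g0, m0, p0 = 0, m_off, p_off_state
        sub = np.random.randint(0, 2**31 - 1)
        _, _, _, _, m, p = ssa_segment(
            r_on, r_off, k_m, gamma_m, k_p, gamma_p,
            g0, m0, p0, empty, t_end, sub,
        )
        m_fin[r] = m
        p_fin[r] = p
    return m_fin, p_fin
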