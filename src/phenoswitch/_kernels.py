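"""Numba kernels for exact stochastic simulation of the feedback networks.

State is ``(G, M, P, P2)``: promoter state (0 basal, 1 active), mRNA, free
monomer and free dimer counts.  The active state is reached by a bound
dimer (dimer motif) or a concerted monomer pair (cooperative motif).  The
parameter vector layout is fixed by :data:`PARAM_NAMES`; rates are in
number units (dimerization propensity ``k1n * P * (P-1)``, promoter
association ``konn * P2`` or ``konpn * P * (P-1)``).

The direct (first-reaction-free) Gillespie method is used; each kernel seeds
numba's own RNG so identical seeds give bit-identical event sequences.
"""

import numpy as np
from numba import njit

PARAM_NAMES = (
    "k_m0", "k_ma", "gamma_m", "k_p", "gamma_p", "gamma_p2",
    "k1n", "km1", "konn", "koff", "konpn",
)

MOTIF_COOP = 0
MOTIF_DIMER = 1


@njit(cache=False)
def _propensities(motif, c, G, M, P, P2, a):
    # c = parameter vector per PARAM_NAMES
    a[0] = c[0] + (c[1] if G == 1 else 0.0)         # transcription
    a[1] = c[2] * M                                 # mRNA decay
    a[2] = c[3] * M                                 # translation
    a[3] = c[4] * P                                 # monomer decay
    if motif == MOTIF_DIMER:
        a[4] = c[6] * P * (P - 1)                   # dimerization
        a[5] = c[7] * P2                            # dissociation
        a[6] = c[5] * P2                            # dimer decay
        a[7] = c[8] * P2 if G == 0 else 0.0         # promoter binding
    else:
        a[4] = 0.0
        a[5] = 0.0
        a[6] = 0.0
        a[7] = c[10] * P * (P - 1) if G == 0 else 0.0  # pair binding
    a[8] = c[9] if G == 1 else 0.0                  # promoter unbinding
    s = 0.0
    for i in range(9):
        s += a[i]
    return s


@njit(cache=False)
def _fire(r, u, a_tot, a, G, M, P, P2):
    # select and execute one reaction; r unused placeholder for signature clarity
    thresh = u * a_tot
    acc = 0.0
    k = 8
    for i in range(9):
        acc += a[i]
        if thresh < acc:
            k = i
            break
    if k == 0:
        M += 1
    elif k == 1:
        M -= 1
    elif k == 2:
        P += 1
    elif k == 3:
        P -= 1
    elif k == 4:
        P -= 2
        P2 += 1
    elif k == 5:
        P += 2
        P2 -= 1
    elif k == 6:
        P2 -= 1
    elif k == 7:
        G += 1
    else:
        G -= 1
    return G, M, P, P2


@njit(cache=False)
def simulate_kernel(motif, c, G, M, P, P2, t_max, sample_times, seed):
    """SSA trajectory recorded at the given sample times."""
    np.random.seed(seed)
    n = sample_times.shape[0]
    Gs = np.empty(n, dtype=np.int64)
    Ms = np.empty(n, dtype=np.int64)
    Ps = np.empty(n, dtype=np.int64)
    P2s = np.empty(n, dtype=np.int64)
    a = np.zeros(9)
    t = 0.0
    idx = 0
    while idx < n:
        a_tot = _propensities(motif, c, G, M, P, P2, a)
        if a_tot <= 0.0:
            t_next = t_max + 1.0
        else:
            t_next = t + (-np.log(np.random.random())) / a_tot
        while idx < n and sample_times[idx] < t_next:
            Gs[idx] = G
            Ms[idx] = M
            Ps[idx] = P
            P2s[idx] = P2
            idx += 1
        if t_next > t_max:
            break
        t = t_next
        G, M, P, P2 = _fire(0, np.random.random(), a_tot, a, G, M, P, P2)
    while idx < n:  # absorbing / silent tail
        Gs[idx] = G
        Ms[idx] = M
        Ps[idx] = P
        P2s[idx] = P2
        idx += 1
    return Gs, Ms, Ps, P2s


@njit(cache=False)
def first_passage_kernel(motif, c, G0, M0, P0, P20, saddle, target, to_high,
                         burnin, t_cap, seed, max_restarts):
    """One first-passage replicate with basin-confined burn-in.

    The state is initialized at the origin fixed point and relaxed for
    ``burnin`` time units; if the total protein crosses the deterministic
    saddle ``saddle`` during burn-in the relaxation restarts from scratch
    (rejection), removing initialization bias.  The clock then starts and
    the replicate ends when total protein first reaches ``target``
    (``to_high``: from below; else from above) or at ``t_cap`` (censored).

    Returns (time, completed, restarts).
    """
    np.random.seed(seed)
    a = np.zeros(9)
    restarts = 0
    while True:
        G, M, P, P2 = G0, M0, P0, P20
        t = 0.0
        rejected = False
        while t < burnin:
            a_tot = _propensities(motif, c, G, M, P, P2, a)
            if a_tot <= 0.0:
                break
            t += (-np.log(np.random.random())) / a_tot
            if t >= burnin:
                break
            G, M, P, P2 = _fire(0, np.random.random(), a_tot, a, G, M, P, P2)
            pt = P + 2 * P2
            if (to_high and pt >= saddle) or ((not to_high) and pt <= saddle):
                rejected = True
                break
        if not rejected:
            break
        restarts += 1
        if restarts >= max_restarts:
            return -1.0, False, restarts
    # timed phase
    t = 0.0
    while t < t_cap:
        a_tot = _propensities(motif, c, G, M, P, P2, a)
        if a_tot <= 0.0:
            return t_cap, False, restarts
        t += (-np.log(np.random.random())) / a_tot
        if t >= t_cap:
            return t_cap, False, restarts
        G, M, P, P2 = _fire(0, np.random.random(), a_tot, a, G, M, P, P2)
        pt = P + 2 * P2
        if (to_high and pt >= target) or ((not to_high) and pt <= target):
            return t, True, restarts
    return t_cap, False, restarts
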