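"""Compiled event loop for the nucleosome-lattice Gillespie simulator.

The public surface lives in :mod:`sirswitch.sim`; this module only holds the
numba-jitted kernels.  State encoding (shared with ``sim``):

    0 = U (unmodified), 1 = A (acetylated), 2 = M (methylated),
    3 = E (active), 4 = S (silenced / Sir-bound)

The lattice array holds sites 1..L at indices 0..L-1 (index 0 is the
telomere-proximal site).  A virtual permanent-S nucleation source sits at
lattice position 0 (array index -1, never stored); the distal site may be
pinned to E.  Sir units are integers: ``count(S) + free_sir == N_sir_total``
is checked after every event.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# state codes
_U, _A, _M, _E, _S = 0, 1, 2, 3, 4


@njit(cache=True, inline="always")
def _kernel_sum_S(sites, i, kw, nucleation, L):
    """Kernel-weighted count of S neighbours of site index i (0-based).

    The virtual nucleation source at lattice position 0 counts as S with
    weight ``nucleation`` (the nucleation-centre strength, 0..1) at genomic
    distance i+1 from site index i.
    """
    tot = 0.0
    R = kw.shape[0]
    for d in range(1, R + 1):
        w = kw[d - 1]
        j = i - d
        if j >= 0:
            if sites[j] == _S:
                tot += w
        elif j == -1:
            tot += w * nucleation
        j = i + d
        if j < L and sites[j] == _S:
            tot += w
    return tot


@njit(cache=True, inline="always")
def _kernel_sum_E(sites, i, kw, L):
    tot = 0.0
    R = kw.shape[0]
    for d in range(1, R + 1):
        w = kw[d - 1]
        j = i - d
        if j >= 0 and sites[j] == _E:
            tot += w
        j = i + d
        if j < L and sites[j] == _E:
            tot += w
    return tot


@njit(cache=True)
def propensity_vector(sites, free_sir, n_total,
                      kb, kd, kt, ks, ka, ku, km, f,
                      kw, meth_u, meth_a, deac_m,
                      nucleation, distal_pinned):
    """Return (n_rx, site[], to_state[], propensity[]) for the current state.

    Mirrors the reaction enumeration of ``sim.enumerate_reactions`` exactly;
    the equivalence of the two routes is asserted in the test suite.
    """
    L = sites.shape[0]
    cap = 4 * L
    r_site = np.empty(cap, np.int64)
    r_to = np.empty(cap, np.uint8)
    prop = np.empty(cap, np.float64)
    m = 0
    free_frac = free_sir / n_total
    for i in range(L):
        if distal_pinned and i == L - 1:
            continue
        s = sites[i]
        if s == _U:
            if kb > 0.0:
                r_site[m] = i; r_to[m] = _A; prop[m] = kb; m += 1
            if meth_u and kt > 0.0:
                nE = _kernel_sum_E(sites, i, kw, L)
                if nE > 0.0:
                    r_site[m] = i; r_to[m] = _M; prop[m] = kt * nE; m += 1
            if ks > 0.0 and free_sir > 0:
                nS = _kernel_sum_S(sites, i, kw, nucleation, L)
                if nS > 0.0:
                    r_site[m] = i; r_to[m] = _S
                    prop[m] = f * ks * free_frac * nS; m += 1
        elif s == _A:
            p = km
            if kd > 0.0:
                nS = _kernel_sum_S(sites, i, kw, nucleation, L)
                p += f * kd * nS
            r_site[m] = i; r_to[m] = _U; prop[m] = p; m += 1
            if ka > 0.0:
                r_site[m] = i; r_to[m] = _E; prop[m] = ka; m += 1
            if meth_a and kt > 0.0:
                nE = _kernel_sum_E(sites, i, kw, L)
                if nE > 0.0:
                    r_site[m] = i; r_to[m] = _M; prop[m] = kt * nE; m += 1
        elif s == _M:
            p = km
            if deac_m and kd > 0.0:
                nS = _kernel_sum_S(sites, i, kw, nucleation, L)
                p += f * kd * nS
            r_site[m] = i; r_to[m] = _U; prop[m] = p; m += 1
        elif s == _E:
            if km > 0.0:
                r_site[m] = i; r_to[m] = _U; prop[m] = km; m += 1
        else:  # _S
            p = ku + km
            if p > 0.0:
                r_site[m] = i; r_to[m] = _U; prop[m] = p; m += 1
    return m, r_site, r_to, prop


@njit(cache=True)
def run_core(sites, free_sir, n_total,
             kb, kd, kt, ks, ka, ku, km, f,
             kw, meth_u, meth_a, deac_m,
             nucleation, distal_pinned,
             duration, sample_times, win_lo, win_hi,
             seed, max_events, keep_snapshots):
    """Run the Gillespie loop in place on ``sites``.

    Records the (pre-event) state at each time in ``sample_times``.
    ``win_lo``/``win_hi`` are inclusive 1-based site numbers for the
    occupancy readout.  Returns the recorded series, final free pool,
    elapsed time, event count, a conservation flag (True iff
    count(S)+free == n_total held after every event) and an absorbed flag.
    """
    np.random.seed(seed)
    L = sites.shape[0]
    n_samp = sample_times.shape[0]
    occ = np.zeros(n_samp, np.float64)
    nS_arr = np.zeros(n_samp, np.int64)
    free_arr = np.zeros(n_samp, np.int64)
    if keep_snapshots:
        snaps = np.zeros((n_samp, L), np.uint8)
    else:
        snaps = np.zeros((1, L), np.uint8)

    nS = 0
    for i in range(L):
        if sites[i] == _S:
            nS += 1
    win_n = win_hi - win_lo + 1
    cons_ok = True
    absorbed = False
    t = 0.0
    si = 0
    events = 0

    while True:
        m, r_site, r_to, prop = propensity_vector(
            sites, free_sir, n_total, kb, kd, kt, ks, ka, ku, km, f,
            kw, meth_u, meth_a, deac_m, nucleation, distal_pinned)
        total = 0.0
        for q in range(m):
            total += prop[q]
        if total <= 0.0:
            absorbed = True
            break
        dt = np.random.exponential(1.0 / total)
        t_next = t + dt
        # the current state persists on [t, t_next): record samples it covers
        while si < n_samp and sample_times[si] < t_next:
            wS = 0
            for i in range(win_lo - 1, win_hi):
                if sites[i] == _S:
                    wS += 1
            occ[si] = wS / win_n
            nS_arr[si] = nS
            free_arr[si] = free_sir
            if keep_snapshots:
                for i in range(L):
                    snaps[si, i] = sites[i]
            si += 1
        if t_next >= duration:
            t = duration
            break
        t = t_next
        u = np.random.random() * total
        acc = 0.0
        j = m - 1
        for q in range(m):
            acc += prop[q]
            if u < acc:
                j = q
                break
        i = r_site[j]
        to = r_to[j]
        s_old = sites[i]
        sites[i] = to
        if s_old == _S:
            free_sir += 1
            nS -= 1
        if to == _S:
            free_sir -= 1
            nS += 1
        events += 1
        if nS + free_sir != n_total:
            cons_ok = False
        if events >= max_events:
            break

    # state persists to the end of the horizon: fill remaining samples
    while si < n_samp:
        wS = 0
        for i in range(win_lo - 1, win_hi):
            if sites[i] == _S:
                wS += 1
        occ[si] = wS / win_n
        nS_arr[si] = nS
        free_arr[si] = free_sir
        if keep_snapshots:
            for i in range(L):
                snaps[si, i] = sites[i]
        si += 1

    return occ, nS_arr, free_arr, snaps, free_sir, t, events, cons_ok, absorbed
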