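"""Numba-compiled inner loop of the compartmental kinetic Monte Carlo engine.

Event selection is the Gillespie direct method, organised hierarchically:
a Fenwick (binary indexed) tree over per-compartment total propensities
selects the compartment in O(log C); the firing channel inside the
compartment (reactions first, then outgoing per-species transfer channels)
is selected by a cumulative scan over the handful of local channels. Only
the one or two compartments touched by an event have their propensity
recomputed.

Propensities (particle_scale = moles represented per simulated particle,
V in litres):

    unimolecular        a = k * n1
    bimolecular A+B     a = k * n1 * n2 * particle_scale / V
    bimolecular A+A     a = k * n1 * (n1-1) * particle_scale / V
    transfer i->j, s    a = rate[i->j, s] * n[i, s]

The generator is numpy's legacy MT19937 seeded once per call, so identical
seeds give bit-identical trajectories.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def _fw_update(tree, i, delta):
    i += 1
    while i < tree.shape[0]:
        tree[i] += delta
        i += i & (-i)


@njit(cache=False)
def _fw_total(tree, n):
    # prefix sum up to n
    s = 0.0
    i = n
    while i > 0:
        s += tree[i]
        i -= i & (-i)
    return s


@njit(cache=False)
def _fw_find(tree, n, log2n, u):
    """Smallest index i with prefix_sum(i+1) > u; clamps to n-1."""
    pos = 0
    rem = u
    mask = 1 << log2n
    while mask > 0:
        nxt = pos + mask
        if nxt <= n and tree[nxt] <= rem:
            pos = nxt
            rem -= tree[nxt]
        mask >>= 1
    if pos >= n:
        pos = n - 1
    return pos


@njit(cache=False)
def _comp_propensity(c, counts, volumes, scale,
                     edge_dst, edge_rate, eptr, eidx,
                     rx_sp1, rx_sp2, rx_k):
    a = 0.0
    for r in range(rx_k.shape[0]):
        s1 = rx_sp1[r]
        s2 = rx_sp2[r]
        n1 = counts[c, s1]
        if s2 < 0:
            a += rx_k[r] * n1
        elif s1 == s2:
            a += rx_k[r] * n1 * (n1 - 1) * scale / volumes[c]
        else:
            a += rx_k[r] * n1 * counts[c, s2] * scale / volumes[c]
    S = counts.shape[1]
    for k in range(eptr[c], eptr[c + 1]):
        e = eidx[k]
        for s in range(S):
            a += edge_rate[e, s] * counts[c, s]
    return a


@njit(cache=False)
def ssa_run(counts, volumes, scale,
            edge_dst, edge_rate, eptr, eidx,
            rx_sp1, rx_sp2, rx_k, rx_delta,
            t0, t_end, record_times, seed, record_comp):
    """Evolve ``counts`` in place; returns recorded totals and status.

    Returns (rec_totals [T,S], rec_comp [T,C,S] or dummy, t_final, absorbed).
    """
    np.random.seed(seed)
    C, S = counts.shape
    T = record_times.shape[0]
    rec = np.zeros((T, S), dtype=np.int64)
    if record_comp:
        comp_rec = np.zeros((T, C, S), dtype=np.int64)
    else:
        comp_rec = np.zeros((1, 1, 1), dtype=np.int64)

    totals = np.zeros(S, dtype=np.int64)
    for c in range(C):
        for s in range(S):
            totals[s] += counts[c, s]

    a = np.zeros(C)
    for c in range(C):
        a[c] = _comp_propensity(c, counts, volumes, scale,
                                edge_dst, edge_rate, eptr, eidx,
                                rx_sp1, rx_sp2, rx_k)
    log2n = 0
    while (1 << (log2n + 1)) <= C:
        log2n += 1
    tree = np.zeros(C + 1)
    for c in range(C):
        _fw_update(tree, c, a[c])

    t = t0
    ri = 0
    absorbed = False
    R = rx_k.shape[0]
    while True:
        A = _fw_total(tree, C)
        if A <= 0.0:
            absorbed = True
            break
        dt = -np.log(np.random.random()) / A
        t_new = t + dt
        while ri < T and record_times[ri] < t_new and record_times[ri] <= t_end:
            for s in range(S):
                rec[ri, s] = totals[s]
            if record_comp:
                for c in range(C):
                    for s in range(S):
                        comp_rec[ri, c, s] = counts[c, s]
            ri += 1
        if t_new > t_end:
            t = t_end
            break
        t = t_new

        c = _fw_find(tree, C, log2n, np.random.random() * A)
        # select channel within compartment c
        r_local = np.random.random() * a[c]
        cum = 0.0
        fired = False
        other = -1
        for r in range(R):
            s1 = rx_sp1[r]
            s2 = rx_sp2[r]
            n1 = counts[c, s1]
            if s2 < 0:
                p = rx_k[r] * n1
            elif s1 == s2:
                p = rx_k[r] * n1 * (n1 - 1) * scale / volumes[c]
            else:
                p = rx_k[r] * n1 * counts[c, s2] * scale / volumes[c]
            cum += p
            if r_local < cum:
                for s in range(S):
                    d = rx_delta[r, s]
                    if d != 0:
                        counts[c, s] += d
                        totals[s] += d
                fired = True
                break
        if not fired:
            done = False
            for k in range(eptr[c], eptr[c + 1]):
                e = eidx[k]
                for s in range(S):
                    p = edge_rate[e, s] * counts[c, s]
                    cum += p
                    if r_local < cum:
                        d = edge_dst[e]
                        counts[c, s] -= 1
                        counts[d, s] += 1
                        other = d
                        done = True
                        break
                if done:
                    break
            if not done:
                # numerical slack: propensity drifted; refresh compartment
                pass

        a_new = _comp_propensity(c, counts, volumes, scale,
                                 edge_dst, edge_rate, eptr, eidx,
                                 rx_sp1, rx_sp2, rx_k)
        _fw_update(tree, c, a_new - a[c])
        a[c] = a_new
        if other >= 0:
            a_new = _comp_propensity(other, counts, volumes, scale,
                                     edge_dst, edge_rate, eptr, eidx,
                                     rx_sp1, rx_sp2, rx_k)
            _fw_update(tree, other, a_new - a[other])
            a[other] = a_new

    while ri < T:
        for s in range(S):
            rec[ri, s] = totals[s]
        if record_comp:
            for c in range(C):
                for s in range(S):
                    comp_rec[ri, c, s] = counts[c, s]
        ri += 1
    return rec, comp_rec, t, absorbed
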