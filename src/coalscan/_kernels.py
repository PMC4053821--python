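"""JIT-compiled core of the multispecies-coalescent simulator.

One kernel draws a batch of independent gene trees on a fixed species
tree (with optional admixture pulses) and sprinkles infinite-sites
mutations on them, returning site patterns as lineage bitmasks.  The
batch formulation keeps half-million-window replicate studies tractable
on one CPU.
"""

from __future__ import annotations

import numpy as np
from numba import njit

EV_SPECIATION = 0
EV_PULSE = 1


@njit(cache=True)
def simulate_batch(
    sp_parent,      # int32[M] species-tree parent (root -1)
    sp_time,        # float64[M] node ages, generations
    sp_ne,          # float64[M] Ne of branch above node (root: ancestral Ne)
    lin_branch0,    # int32[S] initial species branch (tip index) per lineage
    ev_time,        # float64[E] event times ascending
    ev_type,        # int32[E] 0 speciation (node ev_a) / 1 pulse
    ev_a,           # int32[E] speciation node, or pulse recipient branch
    ev_b,           # int32[E] pulse donor branch
    ev_gamma,       # float64[E] pulse migration probability
    seg_len,        # float64[W] sequence length per draw (bp)
    mu,             # mutation rate per site per generation
    seed,           # RNG seed (numba-global stream)
    store_trees,    # bool: keep per-draw (parent, age) arrays
    site_cap,       # capacity of the site output buffers
):
    np.random.seed(seed)
    S = lin_branch0.shape[0]
    G = 2 * S - 1
    W = seg_len.shape[0]
    E = ev_time.shape[0]
    M = sp_parent.shape[0]

    gparent_out = np.full((W if store_trees else 1, G), -1, dtype=np.int32)
    gtime_out = np.zeros((W if store_trees else 1, G), dtype=np.float64)
    site_mask = np.zeros(site_cap, dtype=np.int64)
    site_seg = np.zeros(site_cap, dtype=np.int32)
    n_sites = 0

    gparent = np.empty(G, dtype=np.int32)
    gtime = np.empty(G, dtype=np.float64)
    branch_of = np.empty(G, dtype=np.int32)
    active = np.empty(S, dtype=np.int32)
    members = np.empty(S, dtype=np.int32)
    mask = np.empty(G, dtype=np.int64)

    for w in range(W):
        for i in range(G):
            gparent[i] = -1
            gtime[i] = 0.0
        for i in range(S):
            branch_of[i] = lin_branch0[i]
            active[i] = i
        n_active = S
        nxt = S
        t_start = 0.0

        for e in range(E + 1):
            t_end = ev_time[e] if e < E else np.inf
            if t_end > t_start and n_active > 1:
                for b in range(M):
                    # coalesce within branch b over [t_start, t_end)
                    tcur = t_start
                    while True:
                        k = 0
                        for q in range(n_active):
                            if branch_of[active[q]] == b:
                                members[k] = q
                                k += 1
                        if k < 2:
                            break
                        rate = k * (k - 1) / (4.0 * sp_ne[b])
                        tcur += np.random.exponential(1.0 / rate)
                        if tcur >= t_end:
                            break
                        ai = np.random.randint(0, k)
                        aj = np.random.randint(0, k - 1)
                        if aj >= ai:
                            aj += 1
                        pi = members[ai]
                        pj = members[aj]
                        gparent[active[pi]] = nxt
                        gparent[active[pj]] = nxt
                        gtime[nxt] = tcur
                        branch_of[nxt] = b
                        active[pi] = nxt
                        active[pj] = active[n_active - 1]
                        n_active -= 1
                        nxt += 1
            if e < E:
                if ev_type[e] == EV_SPECIATION:
                    v = ev_a[e]
                    for q in range(n_active):
                        if sp_parent[branch_of[active[q]]] == v:
                            branch_of[active[q]] = v
                else:
                    r = ev_a[e]
                    d = ev_b[e]
                    g = ev_gamma[e]
                    if g > 0.0:  # gamma = 0 is a no-op, bit-identical output
                        for q in range(n_active):
                            if branch_of[active[q]] == r:
                                if np.random.random() < g:
                                    branch_of[active[q]] = d
                t_start = t_end

        # descendant-leaf bitmasks (children always precede parents)
        for i in range(G):
            mask[i] = np.int64(1) << i if i < S else np.int64(0)
        for i in range(G - 1):
            mask[gparent[i]] |= mask[i]

        # infinite-sites mutations: Poisson(mu * L * branch length) each
        L = seg_len[w]
        for i in range(G - 1):
            blen = gtime[gparent[i]] - gtime[i]
            nm = np.random.poisson(mu * L * blen)
            for _ in range(nm):
                if n_sites < site_cap:
                    site_mask[n_sites] = mask[i]
                    site_seg[n_sites] = w
                n_sites += 1

        if store_trees:
            for i in range(G):
                gparent_out[w, i] = gparent[i]
                gtime_out[w, i] = gtime[i]

    return gparent_out, gtime_out, site_mask, site_seg, n_sites
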