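"""Gene-tree analytics.

Per-window tree inference uses neighbor joining on Jukes-Cantor
distances as a deterministic stand-in for a full ML search; externally
computed Newick trees drop in through :class:`~coalscan.gtree.TreeSet`.
The downstream statistics -- clade relative frequencies over a tree
database, majority-rule-extended frequency consensus, the STAR
average-rank species tree and Robinson-Foulds distances -- are agnostic
to where the trees came from.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .gtree import GeneTree, TreeSet, root_at, tree_from_clades

__all__ = [
    "jc_distance_matrix", "nj_tree", "bootstrap_trees", "clade_frequencies",
    "consensus_tree", "star_species_tree", "rf_distance", "assemble_supermatrices",
]


def jc_distance_matrix(
    variants: np.ndarray,
    n_total_sites: int,
    labels: Sequence[str],
    weights: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Jukes-Cantor-corrected pairwise distances from a variant matrix.

    ``variants`` is (n_variant_sites, n_taxa) of allele codes; all
    unlisted alignment columns are invariant, so the raw p-distance for
    a pair is (weighted) mismatch count / ``n_total_sites``.  The JC
    correction d = -3/4 ln(1 - 4p/3) requires p < 3/4; the offending
    pair is named otherwise.
    """
    n = len(labels)
    if weights is None:
        weights = np.ones(len(variants))
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mism = float(((variants[:, i] != variants[:, j]) * weights).sum())
            p = mism / n_total_sites
            if p >= 0.75:
                raise ValueError(
                    f"JC correction undefined for pair ({labels[i]}, {labels[j]}): "
                    f"raw distance {p:.3f} >= 0.75"
                )
            D[i, j] = D[j, i] = -0.75 * np.log1p(-4.0 * p / 3.0)
    return D


def nj_tree(dist: np.ndarray, labels: Sequence[str]) -> GeneTree:
    """Neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken lexicographically by the joined
    clusters' smallest leaf labels, so identical input always yields an
    identical Newick string.  NJ is consistent: an additive matrix
    returns the generating topology with exact branch lengths.
    Negative limb estimates are clipped to zero.
    """
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least three taxa")
    D = np.asarray(dist, dtype=np.float64).copy()
    if D.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    if not np.all(np.isfinite(D)):
        raise ValueError("pairwise distances must be finite")

    total_nodes = 2 * n - 2  # unrooted binary: n leaves + n-2 internals
    parent = np.full(total_nodes + 1, -1, dtype=np.int32)  # +1: rooting node
    blen = np.zeros(total_nodes + 1)
    active = list(range(n))              # node ids of live clusters
    rep = {i: labels[i] for i in range(n)}   # lexicographic representative
    dmat = {(i, j): D[i, j] for i in range(n) for j in range(n) if i < j}

    def dget(a, b):
        return dmat[(a, b) if a < b else (b, a)]

    nxt = n
    while len(active) > 2:
        r = len(active)
        sums = {a: sum(dget(a, b) for b in active if b != a) for a in active}
        best = None
        for ii in range(r):
            for jj in range(ii + 1, r):
                a, b = active[ii], active[jj]
                q = (r - 2) * dget(a, b) - sums[a] - sums[b]
                key = tuple(sorted((rep[a], rep[b])))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and key < best[1]
                ):
                    best = (q, key, a, b)
        _, _, a, b = best
        dab = dget(a, b)
        la = 0.5 * dab + (sums[a] - sums[b]) / (2.0 * (r - 2))
        lb = dab - la
        parent[a] = parent[b] = nxt
        blen[a] = max(la, 0.0)
        blen[b] = max(lb, 0.0)
        for c in active:
            if c not in (a, b):
                dmat[(min(c, nxt), max(c, nxt))] = 0.5 * (
                    dget(a, c) + dget(b, c) - dab
                )
        active = [c for c in active if c not in (a, b)] + [nxt]
        rep[nxt] = min(rep[a], rep[b])
        nxt += 1

    a, b = active
    # root the unrooted result on the final edge (arbitrary but fixed)
    root = nxt
    parent[a] = parent[b] = root
    d_final = max(dget(a, b), 0.0)
    blen[a] = d_final / 2.0
    blen[b] = d_final / 2.0
    return GeneTree(tuple(labels), parent[:root + 1], blen[:root + 1])


def bootstrap_trees(
    variants: np.ndarray,
    n_total_sites: int,
    labels: Sequence[str],
    b: int = 100,
    seed: int = 1,
    window=None,
) -> TreeSet:
    """``b`` site-resampled NJ replicates of one window alignment.

    The alignment is the variant matrix plus its implicit invariant
    columns; each replicate draws ``n_total_sites`` columns with
    replacement (multinomially), re-estimates JC distances and re-runs
    NJ.  Reproducible under seed.
    """
    rng = np.random.default_rng(seed)
    k = len(variants)
    trees = []
    p_var = np.full(k, 1.0 / n_total_sites)
    for _ in range(b):
        weights = None
        if k:
            w = rng.multinomial(n_total_sites, np.append(p_var, 1.0 - k / n_total_sites))
            weights = w[:k].astype(np.float64)
        D = jc_distance_matrix(variants, n_total_sites, labels, weights=weights)
        t = nj_tree(D, labels)
        t.window = window
        trees.append(t)
    return TreeSet(trees, taxa=labels)


def clade_frequencies(trees: TreeSet, rooted: bool = False) -> dict[frozenset, float]:
    """Relative frequency of each observed clade (rooted) or non-trivial
    bipartition (unrooted, reported as the side excluding the first
    universe taxon) across the tree database."""
    if len(trees) == 0:
        raise ValueError("empty tree set")
    universe = list(trees.taxa)
    counts: dict[int, int] = {}
    for t in trees:
        items = t.clades(universe) if rooted else t.bipartitions(universe)
        for m in items:
            counts[m] = counts.get(m, 0) + 1
    out = {}
    for m, c in counts.items():
        members = frozenset(universe[i] for i in range(len(universe)) if m >> i & 1)
        out[members] = c / len(trees)
    return out


def consensus_tree(trees: TreeSet, min_frequency: float = 0.0) -> GeneTree:
    """Majority-rule-extended frequency consensus.

    Bipartitions are sorted by descending frequency (ties broken by the
    bitmask for determinism) and added greedily while compatible with
    everything already kept; node support is the bipartition frequency.
    With ``min_frequency`` = 0 this is the fully extended consensus.
    """
    if len(trees) == 0:
        raise ValueError("empty tree set")
    universe = list(trees.taxa)
    for t in trees:
        if set(t.labels) != set(universe):
            raise ValueError("consensus requires identical taxon sets")
    counts: dict[int, int] = {}
    for t in trees:
        for m in t.bipartitions(universe):
            counts[m] = counts.get(m, 0) + 1
    order = sorted(counts, key=lambda m: (-counts[m], m))
    kept: dict[int, float] = {}
    for m in order:
        freq = counts[m] / len(trees)
        if freq < min_frequency:
            break
        if all(_compatible(m, k) for k in kept):
            kept[m] = freq
    return tree_from_clades(kept, universe)


def _compatible(a: int, b: int) -> bool:
    """Split compatibility for masks normalized away from a common taxon:
    nested or disjoint."""
    i = a & b
    return i == 0 or i == a or i == b


def star_species_tree(trees: TreeSet, outgroup: str) -> GeneTree:
    """STAR species tree from average coalescence ranks.

    Each gene tree is rooted on the outgroup; the root gets rank equal
    to the taxon count, every internal node rank = parent rank - 1, and
    the distance between two taxa in a tree is twice the rank of their
    MRCA.  Ranks are averaged across gene trees (trees lacking the
    outgroup are skipped; their count is in ``.n_skipped`` on the
    result) and neighbor joining on the averaged matrix gives the
    species-tree topology, finally rooted on the outgroup.
    """
    if len(trees) == 0:
        raise ValueError("empty tree set")
    universe = list(trees.taxa)
    n = len(universe)
    idx = {lab: i for i, lab in enumerate(universe)}
    total = np.zeros((n, n))
    used = 0
    skipped = 0
    for t in trees:
        if outgroup not in t.labels:
            skipped += 1
            continue
        rt = root_at(t, outgroup)
        masks = rt.leaf_masks(universe)
        rank = np.zeros(rt.n_nodes)
        rank[rt.root] = n
        for i in sorted(range(rt.n_nodes), reverse=True):
            p = rt.parent[i]
            if p >= 0:
                rank[i] = rank[p] - 1
        ch = rt.children()
        for v in range(rt.n_leaves, rt.n_nodes):
            kids = ch[v]
            for ai in range(len(kids)):
                for bi in range(ai + 1, len(kids)):
                    ma, mb = int(masks[kids[ai]]), int(masks[kids[bi]])
                    for x in _bits(ma):
                        for y in _bits(mb):
                            total[x, y] += 2.0 * rank[v]
                            total[y, x] += 2.0 * rank[v]
        used += 1
    if used == 0:
        raise ValueError(f"no gene tree contains the outgroup {outgroup!r}")
    avg = total / used
    result = root_at(nj_tree(avg, universe), outgroup)
    result.n_skipped = skipped
    return result


def _bits(m: int):
    while m:
        low = m & -m
        yield low.bit_length() - 1
        m ^= low


def rf_distance(t1: GeneTree, t2: GeneTree) -> int:
    """Robinson-Foulds distance: the number of non-trivial bipartitions
    present in exactly one of the two trees (identical leaf sets
    required).  Bounded by 2(n-3) for binary trees on n leaves."""
    if set(t1.labels) != set(t2.labels):
        raise ValueError("RF distance requires identical leaf sets")
    universe = sorted(t1.labels)
    return len(t1.bipartitions(universe) ^ t2.bipartitions(universe))


def assemble_supermatrices(
    bin_lengths: Sequence[int],
    target_length: int,
    n_matrices: int,
    seed: int = 1,
    with_replacement: bool = False,
) -> list[list[int]]:
    """Randomly join genomic bins into supermatrix groups of roughly
    ``target_length`` bp each (a group closes as soon as it reaches the
    target).  Bins are drawn without replacement across groups by
    default, so the groups are unique; returns bin-index lists.
    """
    rng = np.random.default_rng(seed)
    pool = list(rng.permutation(len(bin_lengths)))
    groups: list[list[int]] = []
    for _ in range(n_matrices):
        group: list[int] = []
        acc = 0
        while acc < target_length:
            if not pool:
                if not with_replacement:
                    raise ValueError(
                        "bins exhausted before filling all supermatrices"
                    )
                pool = list(rng.permutation(len(bin_lengths)))
            k = pool.pop()
            group.append(int(k))
            acc += int(bin_lengths[k])
        groups.append(group)
    return groups
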