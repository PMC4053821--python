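"""ABBA-BABA D statistics with weighted block jackknife.

For a quartet (P1, P2, P3, O) under the phylogeny (((P1,P2),P3),O),
sites where the outgroup carries the ancestral allele A are classified
by the (P1,P2,P3) pattern: (A,B,B) = ABBA, (B,A,B) = BABA, everything
else ignored.  Under lineage sorting alone E[ABBA] = E[BABA], so

    D = (nABBA - nBABA) / (nABBA + nBABA)

is centred on zero; a significant deviation indicates gene flow or
structure violating the bifurcating tree.  Significance comes from a
delete-one block jackknife over contiguous genomic blocks (a
site-count-weighted variant after Busing et al. 1999 is available),
with Bonferroni control across the full all-quartets enumeration.  The
admixture fraction f is the standard excess-sharing ratio using the
donor's two (pseudo-)haplotypes as numerator and denominator proxies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .intervals import IntervalSet

__all__ = [
    "QuartetConfig", "SitePatternCounts", "QuartetResult", "AdmixtureFraction",
    "DerivedMatrix", "polarize", "count_patterns", "d_statistic",
    "block_jackknife", "all_quartets", "bonferroni", "dstat", "dstat_all",
    "admixture_fraction", "results_table",
]


@dataclass(frozen=True)
class QuartetConfig:
    """One (((P1, P2), P3), O) configuration."""

    p1: str
    p2: str
    p3: str
    outgroup: str

    def __post_init__(self):
        if len({self.p1, self.p2, self.p3, self.outgroup}) != 4:
            raise ValueError("quartet taxa must be distinct")


@dataclass
class SitePatternCounts:
    abba: float
    baba: float
    block_abba: np.ndarray    # per-block ABBA weight (blocks with data only)
    block_baba: np.ndarray
    n_sites: int              # sites evaluated (non-missing in the quartet)

    @property
    def n_informative(self) -> float:
        return self.abba + self.baba


@dataclass
class QuartetResult:
    config: QuartetConfig
    abba: float
    baba: float
    d: float
    se: float
    z: float
    p: float
    p_bonferroni: float = np.nan
    significant: Optional[bool] = None
    n_blocks: int = 0
    n_sites: int = 0


@dataclass
class AdmixtureFraction:
    donor: str
    recipient: str
    f_hat: float
    se_f: float
    n_blocks: int = 0


class DerivedMatrix:
    """Outgroup-polarized derived-allele fractions.

    ``freq[s, j]`` is taxon j's derived-allele fraction at site s (0/1
    for haploid or pseudo-haploid data, {0, 0.5, 1} for diploid
    frequency mode), NaN where missing.  Sites where the outgroup was
    heterozygous or missing have been dropped (counts retained).
    """

    def __init__(self, taxa, freq, chrom, pos, window,
                 n_dropped_outgroup: int = 0):
        self.taxa = tuple(taxa)
        self.freq = freq
        self.chrom = chrom
        self.pos = pos
        self.window = window
        self.n_dropped_outgroup = n_dropped_outgroup

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def column(self, label: str) -> np.ndarray:
        return self.freq[:, self.taxa.index(label)]


def polarize(
    matrix: GenotypeMatrix,
    outgroup: str,
    mode: str = "pseudohaploid",
    seed: int = 0,
) -> DerivedMatrix:
    """Polarize a genotype matrix against the outgroup.

    The outgroup's (haploid or homozygous) allele defines the ancestral
    state A; every taxon is re-expressed as its derived-allele fraction.
    Sites with a heterozygous or missing outgroup are dropped.  In
    ``pseudohaploid`` mode heterozygotes are first resolved to a single
    random allele with a seeded RNG; ``freq`` mode keeps fractional
    dosages.
    """
    if mode not in ("pseudohaploid", "freq"):
        raise ValueError("mode must be 'pseudohaploid' or 'freq'")
    og = matrix.taxon_index(outgroup)
    og_state = _outgroup_state(matrix, og)
    keep = np.isfinite(og_state) & ((og_state == 0.0) | (og_state == 1.0))
    n_dropped = int((~keep).sum())
    work = matrix.pseudo_haploid(seed) if mode == "pseudohaploid" else matrix
    freq = work.derived_fraction()[keep]
    flip = og_state[keep] == 1.0
    freq[flip] = 1.0 - freq[flip]
    cols = [j for j in range(len(matrix.taxa)) if j != og]
    return DerivedMatrix(
        [matrix.taxa[j] for j in cols],
        freq[:, cols],
        matrix.chrom[keep],
        matrix.pos[keep],
        matrix.window[keep],
        n_dropped_outgroup=n_dropped,
    )


def _outgroup_state(matrix: GenotypeMatrix, og: int) -> np.ndarray:
    """The outgroup's derived fraction on the raw genotypes: 0/1 only for
    haploid or homozygous calls, so heterozygotes are dropped rather than
    resolved."""
    g = matrix.geno[:, og, :].astype(np.float64)
    g[matrix.geno[:, og, :] < 0] = np.nan
    return g.mean(axis=1)


Blocks = Union[None, int, np.ndarray, IntervalSet]


def _block_ids(derived: DerivedMatrix, blocks: Blocks) -> np.ndarray:
    """Per-site block index from window provenance, a fixed block size in
    bp, an explicit per-site array, or a BED-style partition (which must
    cover every site)."""
    if blocks is None:
        if np.any(derived.window < 0):
            raise ValueError("no window provenance; pass an explicit block partition")
        return derived.window.astype(np.int64)
    if isinstance(blocks, (int, np.integer)):
        return (derived.pos // int(blocks)).astype(np.int64)
    if isinstance(blocks, IntervalSet):
        ids = np.full(derived.n_sites, -1, dtype=np.int64)
        index = {}
        for k, (c, s, e) in enumerate(blocks):
            index.setdefault(c, []).append((s, e, k))
        for c, ivs in index.items():
            arr = np.array(ivs)
            sel = np.flatnonzero(derived.chrom == c)
            if len(sel) == 0:
                continue
            j = np.searchsorted(arr[:, 0], derived.pos[sel], side="right") - 1
            ok = (j >= 0) & (derived.pos[sel] < arr[np.maximum(j, 0), 1])
            ids[sel[ok]] = arr[j[ok], 2]
        if np.any(ids < 0):
            bad = int(np.flatnonzero(ids < 0)[0])
            raise ValueError(
                f"site {derived.chrom[bad]}:{derived.pos[bad] + 1} outside the "
                "block partition (partition must be exhaustive)"
            )
        return ids
    return np.asarray(blocks, dtype=np.int64)


def count_patterns(
    derived: DerivedMatrix,
    quartet: QuartetConfig,
    blocks: Blocks = None,
) -> SitePatternCounts:
    """ABBA/BABA weights for one quartet with per-block tallies.

    With derived fractions x1, x2, x3 the per-site weights are
    (1-x1) x2 x3 for ABBA and x1 (1-x2) x3 for BABA, which reduce to
    0/1 indicators for pseudo-haploid input.  Sites with missing data
    in P1, P2 or P3 are skipped for this quartet only.
    """
    x1 = derived.column(quartet.p1)
    x2 = derived.column(quartet.p2)
    x3 = derived.column(quartet.p3)
    ok = np.isfinite(x1) & np.isfinite(x2) & np.isfinite(x3)
    ids = _block_ids(derived, blocks)[ok]
    x1, x2, x3 = x1[ok], x2[ok], x3[ok]
    abba_w = (1.0 - x1) * x2 * x3
    baba_w = x1 * (1.0 - x2) * x3
    uniq, inv = np.unique(ids, return_inverse=True)
    block_abba = np.bincount(inv, weights=abba_w, minlength=len(uniq))
    block_baba = np.bincount(inv, weights=baba_w, minlength=len(uniq))
    return SitePatternCounts(
        float(abba_w.sum()), float(baba_w.sum()),
        block_abba, block_baba, int(ok.sum()),
    )


def d_statistic(counts: SitePatternCounts) -> float:
    """D = (nABBA - nBABA) / (nABBA + nBABA); NaN (undefined, not 0)
    when there are no informative sites."""
    tot = counts.abba + counts.baba
    if tot <= 0:
        return float("nan")
    return (counts.abba - counts.baba) / tot


def block_jackknife(
    counts: SitePatternCounts,
    weighting: str = "blocks",
) -> tuple[float, float, float, int]:
    """Delete-one block jackknife for D over blocks with informative
    sites.

    The default (``weighting="blocks"``) treats each block as one
    exchangeable unit -- the delete-one jackknife is valid for
    independent blocks of unequal size, and because a block's
    informative sites typically descend from one local genealogy, the
    block, not the site, is the right unit (site-level weighting
    understates the variance under that clustering; both choices agree
    for equal blocks).  ``weighting="sites"`` gives the classic
    informative-site-count weighted estimator of Busing et al. (1999)
    for comparison with tools that use it.  Returns (SE, Z, two-sided
    p, blocks used); all NaN when fewer than two blocks carry
    informative sites.
    """
    A, B = counts.block_abba, counts.block_baba
    m = A + B
    keep = m > 0
    A, B, m = A[keep], B[keep], m[keep]
    g = len(m)
    if g < 2:
        return float("nan"), float("nan"), float("nan"), g
    At, Bt = A.sum(), B.sum()
    n = m.sum()
    d = (At - Bt) / (At + Bt)
    d_loo = ((At - A) - (Bt - B)) / (n - m)
    if weighting == "blocks":
        var = float((g - 1) / g * ((d_loo - d_loo.mean()) ** 2).sum())
    elif weighting == "sites":
        h = n / m
        theta_j = g * d - float(((1.0 - m / n) * d_loo).sum())
        tau = h * d - (h - 1.0) * d_loo
        var = float(np.mean((tau - theta_j) ** 2 / (h - 1.0)))
    else:
        raise ValueError("weighting must be 'blocks' or 'sites'")
    se = float(np.sqrt(var))
    if se <= 1e-9 * max(1.0, abs(d)):
        # no resampling variability (e.g. every informative site shares
        # one pattern): the normal approximation is meaningless
        return se, float("nan"), float("nan"), g
    z = d / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return se, z, p, g


def dstat(
    derived: DerivedMatrix,
    quartet: QuartetConfig,
    blocks: Blocks = None,
    weighting: str = "blocks",
) -> QuartetResult:
    """Full D-statistic for one quartet: counts, D, jackknife SE, Z, p."""
    counts = count_patterns(derived, quartet, blocks)
    d = d_statistic(counts)
    se, z, p, g = block_jackknife(counts, weighting=weighting)
    return QuartetResult(quartet, counts.abba, counts.baba, d, se, z, p,
                         n_blocks=g, n_sites=counts.n_sites)


def all_quartets(
    taxa: Sequence[str],
    outgroup: str,
    tree=None,
) -> list[QuartetConfig]:
    """Every (P1,P2),P3 configuration over the ingroup, one per unordered
    {P1,P2} pair (D(P1,P2,..) = -D(P2,P1,..) makes the other order
    redundant): 3 * C(n,3) configurations for n ingroup taxa.  With a
    species tree supplied (an object with ``labels`` and ``leaf_masks``-
    compatible structure, e.g. GeneTree), only configurations whose
    (P1,P2) pair is more closely related than either is to P3 are kept.
    """
    ingroup = sorted(t for t in taxa if t != outgroup)
    if len(ingroup) < 3:
        raise ValueError("need at least three ingroup taxa")
    configs = []
    for a, b, c in itertools.combinations(ingroup, 3):
        for (p1, p2), p3 in (((a, b), c), ((a, c), b), ((b, c), a)):
            if tree is not None and not _is_cherry(tree, p1, p2, p3):
                continue
            configs.append(QuartetConfig(p1, p2, p3, outgroup))
    return configs


def _is_cherry(tree, p1: str, p2: str, p3: str) -> bool:
    """True when MRCA(p1,p2) excludes p3 (so ((p1,p2),p3) matches the tree)."""
    universe = list(tree.labels)
    masks = tree.leaf_masks(universe)
    b1 = 1 << universe.index(p1)
    b2 = 1 << universe.index(p2)
    b3 = 1 << universe.index(p3)
    best = None
    for m in masks:
        m = int(m)
        if (m & b1) and (m & b2):
            if best is None or m.bit_count() < best.bit_count():
                best = m
    return best is not None and not (best & b3)


def bonferroni(
    results: Sequence[QuartetResult],
    m: Optional[int] = None,
    alpha: float = 0.01,
) -> list[QuartetResult]:
    """Multiply raw p-values by the number of D computations (capped at
    1) and call significance on the adjusted value at ``alpha``."""
    m = m if m is not None else len(results)
    for r in results:
        r.p_bonferroni = min(1.0, r.p * m) if np.isfinite(r.p) else np.nan
        r.significant = bool(r.p_bonferroni < alpha) if np.isfinite(r.p) else None
    return list(results)


def dstat_all(
    derived: DerivedMatrix,
    outgroup: str,
    blocks: Blocks = None,
    tree=None,
    alpha: float = 0.01,
) -> list[QuartetResult]:
    """D for every quartet configuration, Bonferroni-adjusted."""
    configs = all_quartets(list(derived.taxa) + [outgroup], outgroup, tree=tree)
    results = [dstat(derived, q, blocks) for q in configs]
    return bonferroni(results, alpha=alpha)


def dstat_batch(
    derived: DerivedMatrix,
    configs: Sequence[QuartetConfig],
    blocks: Blocks = None,
    alpha: float = 0.01,
    weighting: str = "blocks",
) -> list[QuartetResult]:
    """Fast path for many quartets on 0/1 (haploid or pseudo-haploid)
    derived data: one boolean pattern scan + bincount per quartet over a
    pre-factorized block index.  Numerically identical to
    :func:`dstat` (asserted in the test suite); falls back to it for
    fractional input."""
    ids = _block_ids(derived, blocks)
    uniq, inv = np.unique(ids, return_inverse=True)
    nb = len(uniq)
    X = derived.freq
    finite = np.isfinite(X)
    zero_one = np.all((X[finite] == 0.0) | (X[finite] == 1.0))
    if not zero_one:
        return bonferroni(
            [dstat(derived, q, blocks, weighting=weighting) for q in configs],
            alpha=alpha,
        )
    col = {t: j for j, t in enumerate(derived.taxa)}
    B1 = X == 1.0
    B0 = X == 0.0
    ok_col = finite
    all_ok = bool(finite.all())
    results = []
    for q in configs:
        i1, i2, i3 = col[q.p1], col[q.p2], col[q.p3]
        if all_ok:
            n_sites = X.shape[0]
            abba = B0[:, i1] & B1[:, i2] & B1[:, i3]
            baba = B1[:, i1] & B0[:, i2] & B1[:, i3]
        else:
            ok = ok_col[:, i1] & ok_col[:, i2] & ok_col[:, i3]
            n_sites = int(ok.sum())
            abba = ok & B0[:, i1] & B1[:, i2] & B1[:, i3]
            baba = ok & B1[:, i1] & B0[:, i2] & B1[:, i3]
        A = np.bincount(inv[abba], minlength=nb).astype(np.float64)
        B = np.bincount(inv[baba], minlength=nb).astype(np.float64)
        counts = SitePatternCounts(float(A.sum()), float(B.sum()), A, B, n_sites)
        d = d_statistic(counts)
        se, z, p, g = block_jackknife(counts, weighting=weighting)
        results.append(QuartetResult(q, counts.abba, counts.baba, d, se, z, p,
                                     n_blocks=g, n_sites=n_sites))
    return bonferroni(results, alpha=alpha)


def results_table(results: Sequence[QuartetResult]) -> pd.DataFrame:
    """Fixed-column-order table for diffable TSV output."""
    rows = [
        {
            "P1": r.config.p1, "P2": r.config.p2, "P3": r.config.p3,
            "O": r.config.outgroup,
            "nABBA": r.abba, "nBABA": r.baba, "D": r.d, "SE": r.se,
            "Z": r.z, "p": r.p, "p_bonf": r.p_bonferroni,
            "n_blocks": r.n_blocks, "n_sites": r.n_sites,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["P1", "P2", "P3", "O", "nABBA", "nBABA", "D", "SE", "Z", "p",
                 "p_bonf", "n_blocks", "n_sites"],
    )


def admixture_fraction(
    matrix: GenotypeMatrix,
    p1: str,
    p2: str,
    donor: str,
    outgroup: str,
    blocks: Blocks = None,
    donor_proxies: Optional[tuple[str, str]] = None,
    seed: int = 0,
) -> AdmixtureFraction:
    """Excess-sharing admixture fraction for donor -> P2 gene flow.

    f = S(P1, P2, P3a, O) / S(P1, P3b, P3a, O), S = nABBA - nBABA,
    where P3a/P3b are the donor's two lineages: its phased haplotypes
    for a diploid donor, or the explicitly supplied ``donor_proxies``
    pair of taxa.  The denominator plays the role of total replacement
    of P2 by donor lineages.  SE comes from the same delete-one block
    jackknife applied to the ratio.  A non-positive denominator leaves
    f undefined (NaN).
    """
    if donor_proxies is None and matrix.ploidy != 2:
        raise ValueError(
            "donor haplotype proxies require a diploid matrix or explicit "
            "donor_proxies"
        )
    og = matrix.taxon_index(outgroup)
    og_state = _outgroup_state(matrix, og)
    keep = np.isfinite(og_state) & ((og_state == 0.0) | (og_state == 1.0))
    flip = og_state[keep] == 1.0
    work = matrix.pseudo_haploid(seed)
    f_all = work.derived_fraction()

    def pol(col: np.ndarray) -> np.ndarray:
        col = col[keep].copy()
        col[flip] = 1.0 - col[flip]
        return col

    x1 = pol(f_all[:, matrix.taxon_index(p1)])
    x2 = pol(f_all[:, matrix.taxon_index(p2)])
    if donor_proxies is not None:
        x3a = pol(f_all[:, matrix.taxon_index(donor_proxies[0])])
        x3b = pol(f_all[:, matrix.taxon_index(donor_proxies[1])])
    else:
        jd = matrix.taxon_index(donor)
        hap = matrix.geno[:, jd, :2].astype(np.float64)
        hap[matrix.geno[:, jd, :2] < 0] = np.nan
        x3a = pol(hap[:, 0])
        x3b = pol(hap[:, 1])

    derived = DerivedMatrix(
        [t for t in matrix.taxa if t != outgroup],
        f_all[keep][:, [j for j in range(len(matrix.taxa)) if j != og]],
        matrix.chrom[keep], matrix.pos[keep], matrix.window[keep],
    )
    ok = np.isfinite(x1) & np.isfinite(x2) & np.isfinite(x3a) & np.isfinite(x3b)
    ids = _block_ids(derived, blocks)[ok]
    x1, x2, x3a, x3b = x1[ok], x2[ok], x3a[ok], x3b[ok]

    num_abba = (1 - x1) * x2 * x3a
    num_baba = x1 * (1 - x2) * x3a
    den_abba = (1 - x1) * x3b * x3a
    den_baba = x1 * (1 - x3b) * x3a

    uniq, inv = np.unique(ids, return_inverse=True)
    bn = np.bincount(inv, weights=num_abba - num_baba, minlength=len(uniq))
    bd = np.bincount(inv, weights=den_abba - den_baba, minlength=len(uniq))
    bw = np.bincount(
        inv, weights=num_abba + num_baba + den_abba + den_baba, minlength=len(uniq)
    )
    keep_b = bw > 0
    bn, bd, bw = bn[keep_b], bd[keep_b], bw[keep_b]
    g = len(bw)
    Sn, Sd = float(bn.sum()), float(bd.sum())
    if Sd <= 0 or g < 2:
        return AdmixtureFraction(donor, p2, float("nan"), float("nan"), g)
    f = Sn / Sd
    f_loo = (Sn - bn) / (Sd - bd)
    var = float((g - 1) / g * ((f_loo - f_loo.mean()) ** 2).sum())
    return AdmixtureFraction(donor, p2, f, float(np.sqrt(var)), g)
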