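"""Synthetic genomes under the multispecies coalescent with admixture.

Windows are unlinked: each carries an independent gene tree (free
recombination between windows, none within, unless sub-window
recombination is enabled to drive tree churn for the correlation
scans).  Mutations follow the infinite-sites model, so every variable
site is biallelic with a single origin, matching the assumptions of the
ABBA-BABA site-pattern logic downstream.  Identical config + seed gives
bit-identical output.

A pileup-level generator (:func:`simulate_pileup`) adds read-stack
artifacts -- SNP clusters, near-indel SNPs, high-depth (CNV-like)
segments -- with exact ground-truth labels so filter recall/precision
is computable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._kernels import EV_PULSE, EV_SPECIATION, simulate_batch
from .genotypes import GenotypeMatrix
from .gtree import GeneTree, TreeSet
from .intervals import IntervalSet
from .sitefilter import PileupSite
from .sptree import AdmixturePulse, SimulationConfig, SpeciesTreeModel

__all__ = [
    "sample_gene_tree", "drop_mutations", "simulate_genome", "simulate_pileup",
    "SimResult", "MutationWindow", "PileupTruth", "lineage_labels",
]


def lineage_labels(model: SpeciesTreeModel, ploidy: str) -> tuple[str, ...]:
    """Leaf labels of simulated gene trees: taxon names in haploid mode,
    ``TAX.1``/``TAX.2`` for the two lineages of a diploid individual."""
    if ploidy == "haploid":
        return tuple(model.labels)
    return tuple(f"{t}.{k}" for t in model.labels for k in (1, 2))


def _kernel_inputs(model: SpeciesTreeModel, pulses: list[AdmixturePulse], ploidy: str):
    n = model.n_taxa
    p = 2 if ploidy == "diploid" else 1
    lin_branch0 = np.repeat(np.arange(n, dtype=np.int32), p)
    ev = []
    for v in range(n, 2 * n - 1):
        ev.append((float(model.node_time[v]), EV_SPECIATION, v, -1, 0.0))
    for pl in pulses:
        rb = model.branch_at(pl.recipient, pl.time)
        db = model.branch_at(pl.donor, pl.time)
        ev.append((float(pl.time), EV_PULSE, rb, db, float(pl.proportion)))
    ev.sort(key=lambda x: (x[0], x[1]))
    ev_time = np.array([e[0] for e in ev], dtype=np.float64)
    ev_type = np.array([e[1] for e in ev], dtype=np.int32)
    ev_a = np.array([e[2] for e in ev], dtype=np.int32)
    ev_b = np.array([e[3] for e in ev], dtype=np.int32)
    ev_gamma = np.array([e[4] for e in ev], dtype=np.float64)
    return lin_branch0, ev_time, ev_type, ev_a, ev_b, ev_gamma, p


def _run_kernel(model, pulses, ploidy, seg_len, mu, seed, store_trees):
    lin0, ev_t, ev_ty, ev_a, ev_b, ev_g, p = _kernel_inputs(model, pulses, ploidy)
    S = len(lin0)
    # generous first-guess site capacity; deterministic re-run on overflow
    height = float(model.node_time[model.root]) + 8.0 * float(model.node_ne[model.root])
    cap = int(0.6 * mu * float(np.sum(seg_len)) * S * height) + 4096
    # mix the user seed before it reaches the kernel's Mersenne Twister:
    # similar raw seeds produce correlated MT initial states, which shows
    # up as excess between-replicate variance in D
    kernel_seed = int(np.random.SeedSequence(int(seed)).generate_state(1)[0] % (2**31))
    while True:
        out = simulate_batch(
            model.parent, model.node_time, model.node_ne, lin0,
            ev_t, ev_ty, ev_a, ev_b, ev_g,
            np.asarray(seg_len, dtype=np.float64), float(mu),
            kernel_seed, store_trees, cap,
        )
        gparent, gtime, site_mask, site_seg, n_sites = out
        if n_sites <= cap:
            return gparent, gtime, site_mask[:n_sites], site_seg[:n_sites], S, p
        cap = int(n_sites * 1.2) + 1024


def sample_gene_tree(
    model: SpeciesTreeModel,
    pulses: Optional[list[AdmixturePulse]] = None,
    seed: int = 1,
    ploidy: str = "haploid",
) -> GeneTree:
    """Draw one gene tree (coalescence times in generations).

    Backwards in time, lineages in an admixture pulse's recipient branch
    migrate to the donor branch independently with probability gamma;
    within each species-tree branch, pairwise coalescence occurs at rate
    1/(2 Ne) per pair per generation.
    """
    pulses = list(pulses or [])
    SimulationConfig(model, pulses, n_windows=1, window_length=1, seed=seed,
                     ploidy=ploidy)  # validates pulses against the model
    gparent, gtime, _, _, S, p = _run_kernel(
        model, pulses, ploidy, np.array([1.0]), 0.0, seed, True
    )
    return GeneTree.from_times(lineage_labels(model, ploidy), gparent[0], gtime[0])


@dataclass
class MutationWindow:
    """Infinite-sites mutations on one gene tree: ``carriers[s, j]`` is
    True when leaf ``j`` carries the derived allele of site ``s``."""

    positions: np.ndarray
    carriers: np.ndarray
    labels: tuple[str, ...]

    @property
    def n_sites(self) -> int:
        return len(self.positions)


def drop_mutations(tree: GeneTree, mu: float, length: int, seed: int) -> MutationWindow:
    """Poisson(mu * length * branch length) mutations per branch; each
    yields one biallelic site carried by exactly the leaves below it,
    at a distinct position in the window.  Raises when the expected
    mutation count exceeds the window length (infinite-sites violation).
    """
    total_blen = float(tree.blen.sum())
    expected = mu * length * total_blen
    if expected > length:
        raise ValueError(
            f"expected mutation count {expected:.3g} exceeds window length {length}"
            " under the infinite-sites model"
        )
    rng = np.random.default_rng(seed)
    masks = tree.leaf_masks(tree.labels)
    S = tree.n_leaves
    site_masks = []
    for i in range(tree.n_nodes - 1):
        nm = rng.poisson(mu * length * tree.blen[i])
        site_masks.extend([int(masks[i])] * int(nm))
    n = len(site_masks)
    if n > length:
        raise ValueError(f"{n} mutations cannot occupy {length} distinct positions")
    positions = np.sort(rng.choice(length, size=n, replace=False))
    arr = np.array(site_masks, dtype=np.int64)
    carriers = ((arr[:, None] >> np.arange(S)) & 1).astype(bool)
    return MutationWindow(positions, carriers, tree.labels)


@dataclass
class SimResult:
    """Output of :func:`simulate_genome`."""

    matrix: GenotypeMatrix
    trees: Optional[TreeSet]
    windows: IntervalSet
    recomb_rate: Optional[np.ndarray]  # per-window covariate, None unless enabled
    config: SimulationConfig


def simulate_genome(config: SimulationConfig, return_trees: bool = True) -> SimResult:
    """Simulate a windowed genome: an independent gene tree per window
    (or per sub-window segment when ``subwindow_recombination`` is on),
    infinite-sites mutations, and the concatenated genotype matrix with
    window provenance.

    With sub-window recombination enabled, each window is tiled into
    ``bins_per_window`` bins and a per-window recombination rate
    r_w ~ LogNormal is drawn; 1 + Poisson(churn_per_rate * r_w)
    breakpoints (capped by the bin boundaries available) partition the
    bins into runs, and all bins in a run share one gene tree.  The
    number of distinct intra-window trees thus increases monotonically
    in r_w -- low-rate windows carry near-identical bin trees (mean
    pairwise RF near 0), high-rate windows carry independent ones --
    which is the covariate the correlation scans exercise.
    """
    model, L = config.model, config.window_length
    rng = np.random.default_rng(config.seed)

    if config.subwindow_recombination:
        bpw = config.bins_per_window
        rates = rng.lognormal(config.recomb_rate_meanlog, config.recomb_rate_sdlog,
                              config.n_windows)
        n_breaks = np.minimum(rng.poisson(config.churn_per_rate * rates), bpw - 1)
    else:
        bpw = 1
        rates = None
        n_breaks = np.zeros(config.n_windows, dtype=np.int64)

    # one kernel "segment" per run of bins sharing a gene tree
    seg_window, seg_start, seg_end = [], [], []
    seg_bins: list[tuple[int, int]] = []  # bin index range within the window
    bin_edges = np.linspace(0, L, bpw + 1).astype(np.int64)
    for w in range(config.n_windows):
        k = int(n_breaks[w])
        cuts = np.sort(rng.choice(bpw - 1, size=k, replace=False)) + 1 if k else []
        bounds = np.concatenate([[0], cuts, [bpw]]).astype(np.int64)
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg_window.append(w)
            seg_start.append(int(w * L + bin_edges[a]))
            seg_end.append(int(w * L + bin_edges[b]))
            seg_bins.append((int(a), int(b)))
    seg_window = np.array(seg_window, dtype=np.int64)
    seg_start = np.array(seg_start, dtype=np.int64)
    seg_end = np.array(seg_end, dtype=np.int64)
    seg_len = (seg_end - seg_start).astype(np.float64)

    gparent, gtime, site_mask, site_seg, S, p = _run_kernel(
        model, config.pulses, config.ploidy, seg_len, model.mu, config.seed,
        return_trees,
    )

    # distinct positions per segment (infinite sites within a window)
    counts = np.bincount(site_seg, minlength=len(seg_len))
    if np.any(counts > seg_len.astype(np.int64)):
        raise ValueError("mutation count exceeds segment length under infinite sites")
    pos = np.empty(len(site_seg), dtype=np.int64)
    offset = 0
    for s in range(len(seg_len)):
        c = int(counts[s])
        if c:
            pos[offset:offset + c] = seg_start[s] + np.sort(
                rng.choice(int(seg_len[s]), size=c, replace=False)
            )
            offset += c

    bits = ((site_mask[:, None] >> np.arange(S)) & 1).astype(np.int8)
    geno = bits.reshape(len(site_mask), model.n_taxa, p)
    matrix = GenotypeMatrix(
        model.labels,
        np.full(len(pos), config.chrom),
        pos,
        geno,
        seg_window[site_seg],
    )

    trees = None
    if return_trees:
        labels = lineage_labels(model, config.ploidy)
        out_trees = []
        for s in range(len(seg_len)):
            w = int(seg_window[s])
            a, b = seg_bins[s]
            for bi in range(a, b):
                out_trees.append(GeneTree.from_times(
                    labels, gparent[s], gtime[s],
                    window=(config.chrom,
                            int(w * L + bin_edges[bi]),
                            int(w * L + bin_edges[bi + 1])),
                ))
        trees = TreeSet(out_trees, taxa=labels)

    windows = IntervalSet(
        (config.chrom, w * L, (w + 1) * L) for w in range(config.n_windows)
    )
    return SimResult(matrix, trees, windows, rates, config)


def inject_singleton_errors(
    matrix: GenotypeMatrix,
    genome_length: int,
    rate: float,
    seed: int,
) -> GenotypeMatrix:
    """Independent per-taxon singleton sequencing errors at ``rate`` per
    base: each error miscalls one allele copy of one taxon at a
    previously invariant position, creating a spurious singleton site.
    (Errors landing on the rare already-variant positions would not
    produce singletons and are outside this error model.)  Singletons
    are never ABBA or BABA patterns, which is what makes the D statistic
    robust to this error class.
    """
    rng = np.random.default_rng(seed)
    geno = matrix.geno.copy()

    # new singleton sites at previously invariant positions
    n_taxa, ploidy = geno.shape[1], geno.shape[2]
    new_chrom, new_pos, new_geno, new_win = [], [], [], []
    window_len = genome_length // max(int(matrix.window.max()) + 1, 1)
    existing = set(zip(matrix.chrom.tolist(), matrix.pos.tolist()))
    chrom0 = str(matrix.chrom[0]) if matrix.n_sites else "1"
    for j in range(n_taxa):
        k = rng.binomial(genome_length, rate)
        for p in rng.integers(0, genome_length, size=k):
            p = int(p)
            if (chrom0, p) in existing:
                continue  # already handled by the flip pass
            g = np.zeros((n_taxa, ploidy), dtype=np.int8)
            g[j, int(rng.integers(ploidy))] = 1
            new_chrom.append(chrom0)
            new_pos.append(p)
            new_geno.append(g)
            new_win.append(p // window_len if window_len else 0)
    if not new_pos:
        return GenotypeMatrix(matrix.taxa, matrix.chrom, matrix.pos, geno,
                              matrix.window)
    chrom = np.concatenate([matrix.chrom, np.array(new_chrom)])
    pos = np.concatenate([matrix.pos, np.array(new_pos, dtype=np.int64)])
    allg = np.concatenate([geno, np.stack(new_geno)])
    win = np.concatenate([matrix.window, np.array(new_win, dtype=np.int32)])
    order = np.argsort(pos, kind="stable")
    return GenotypeMatrix(matrix.taxa, chrom[order], pos[order], allg[order],
                          win[order])


# -- pileup fixture --------------------------------------------------------

@dataclass
class PileupTruth:
    """Ground-truth labels for a simulated pileup (1-based positions)."""

    snp_positions: set[int]          # clean truth SNPs
    cluster_snps: set[int]           # SNPs injected as 3-in-10bp clusters
    indel_positions: set[int]
    near_indel_snps: set[int]        # SNPs injected within 3 bp of an indel
    high_depth: IntervalSet          # CNV-like segments (0-based half-open)
    genotypes: dict[int, tuple[str, str]]


def simulate_pileup(
    length: int = 100_000,
    chrom: str = "1",
    coverage: float = 12.0,
    error_rate: float = 0.0,
    snp_rate: float = 0.002,
    het_fraction: float = 0.5,
    n_clusters: int = 5,
    n_indels: int = 5,
    n_high_depth: int = 2,
    high_depth_length: int = 2000,
    high_depth_mult: float = 2.5,
    base_q: tuple[float, float] = (37.0, 4.0),
    map_q: tuple[float, float] = (50.0, 6.0),
    seed: int = 1,
) -> tuple[list[PileupSite], PileupTruth]:
    """Generate a pileup with known clean SNPs and injected artifacts.

    Depth is Poisson(``coverage``), scaled by ``high_depth_mult`` inside
    CNV-like segments; qualities are normal draws (mean, sd) clipped at
    [2, 60]; with probability ``error_rate`` a read's base is replaced by
    a uniformly random other base.  Injected artifacts (3-SNP clusters
    within 10 bp, SNPs exactly 3 bp from an indel, high-depth segments)
    are disjoint from clean SNPs and from each other, and every label is
    returned so downstream filter recall/precision is exact.
    """
    rng = np.random.default_rng(seed)
    ref = rng.choice(list("ACGT"), size=length)
    genotypes: dict[int, tuple[str, str]] = {}
    reserved = np.zeros(length, dtype=bool)

    def other_base(b: str) -> str:
        choices = [x for x in "ACGT" if x != b]
        return choices[int(rng.integers(3))]

    def add_snp(p0: int) -> None:  # p0 is 0-based
        alt = other_base(ref[p0])
        if rng.random() < het_fraction:
            genotypes[p0 + 1] = tuple(sorted((ref[p0], alt)))
        else:
            genotypes[p0 + 1] = (alt, alt)

    def place(width: int) -> int:
        """A start position whose ``width`` bp are unreserved."""
        for _ in range(10_000):
            s = int(rng.integers(10, max(length - width - 10, 11)))
            if not reserved[s:s + width].any():
                return s
        raise ValueError("cannot place artifacts: genome too crowded")

    # high-depth segments, non-overlapping, away from the ends
    hd = []
    for _ in range(n_high_depth):
        s = place(high_depth_length)
        reserved[s:s + high_depth_length] = True
        hd.append((chrom, s, s + high_depth_length))
    high_depth = IntervalSet(sorted(hd))

    cluster_snps: set[int] = set()
    for _ in range(n_clusters):
        s = place(20) + 5
        reserved[s - 5:s + 15] = True
        for off in (0, 4, 9):  # 3 SNPs spanning exactly 10 bp
            add_snp(s + off)
            cluster_snps.add(s + off + 1)

    indel_positions: set[int] = set()
    near_indel_snps: set[int] = set()
    for _ in range(n_indels):
        s = place(17) + 8
        reserved[s - 8:s + 9] = True
        indel_positions.add(s + 1)
        snp0 = s + int(rng.choice([-3, -2, -1, 1, 2, 3]))
        add_snp(snp0)
        near_indel_snps.add(snp0 + 1)

    n_clean = rng.binomial(length, snp_rate)
    free = np.flatnonzero(~reserved)
    clean0 = rng.choice(free, size=min(n_clean, len(free)), replace=False)
    for p0 in clean0:
        add_snp(int(p0))
    snp_positions = {int(p0) + 1 for p0 in clean0}

    hd_mask = high_depth.mask(chrom, length)
    depth = rng.poisson(np.where(hd_mask, coverage * high_depth_mult, coverage))
    depth = np.maximum(depth, 0)
    total_reads = int(depth.sum())
    bq_all = np.clip(np.round(rng.normal(base_q[0], base_q[1], total_reads)), 2, 60)
    mq_all = np.clip(np.round(rng.normal(map_q[0], map_q[1], total_reads)), 2, 60)
    err_all = rng.random(total_reads) < error_rate
    pick_all = rng.integers(0, 2, total_reads)

    sites: list[PileupSite] = []
    off = 0
    for p0 in range(length):
        d = int(depth[p0])
        g = genotypes.get(p0 + 1, (ref[p0], ref[p0]))
        bases = []
        for r in range(d):
            b = g[pick_all[off + r]]
            if err_all[off + r]:
                b = other_base(b)
            bases.append(b)
        sites.append(PileupSite(
            chrom, p0 + 1, str(ref[p0]), bases,
            [int(q) for q in bq_all[off:off + d]],
            [int(m) for m in mq_all[off:off + d]],
            indel=(p0 + 1) in indel_positions,
        ))
        off += d

    truth = PileupTruth(snp_positions, cluster_snps, indel_positions,
                        near_indel_snps, high_depth, genotypes)
    return sites, truth
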