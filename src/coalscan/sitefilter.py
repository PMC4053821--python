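"""Callable-site selection from pileup records.

Implements the depth/quality genotype filter (>=3 passing reads at base
and mapping quality >=20), SNP-cluster and near-indel exclusion, 1-kbp
bin acceptance (mean depth strictly under twice the genome-wide average
and >=90% of positions callable), chaining of exactly adjacent bins,
multi-sample intersection, minimum-span region selection, and the
per-allele effective-coverage filter used for high-variance (mtDNA-like)
contigs:

    C_j(a) = sum over reads i carrying a of (1 - 10^(-m_i/10)) (1 - 10^(-q_i/10))

with a site kept iff the major allele's effective coverage is at least
70% of the total.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalSet, intersect_samples  # noqa: F401  (re-export)

__all__ = [
    "PileupSite", "GenotypeCall", "EffectiveCoverage",
    "call_genotypes", "filter_snp_artifacts", "accept_bins", "chain_bins",
    "intersect_samples", "select_spans", "effective_coverage",
    "filter_mt_sites", "mt_report", "read_pileup_tsv", "write_pileup_tsv",
    "write_calls_vcf",
]


@dataclass
class PileupSite:
    """One position's read stack (1-based ``pos``, pileup convention)."""

    chrom: str
    pos: int
    ref: str
    bases: list[str]
    base_q: list[int]
    map_q: list[int]
    indel: bool = False  # an indel is reported at/adjacent to this position

    def __post_init__(self):
        if not (len(self.bases) == len(self.base_q) == len(self.map_q)):
            raise ValueError(f"ragged pileup vectors at {self.chrom}:{self.pos}")
        if any(q < 0 for q in self.base_q) or any(m < 0 for m in self.map_q):
            raise ValueError(f"negative quality at {self.chrom}:{self.pos}")

    @property
    def depth(self) -> int:
        return len(self.bases)


@dataclass
class GenotypeCall:
    chrom: str
    pos: int
    ref: str
    alleles: Optional[tuple[str, str]]  # None = missing
    depth: int                          # passing reads supporting the call
    flags: set[str] = field(default_factory=set)

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @property
    def is_snp(self) -> bool:
        return self.alleles is not None and any(a != self.ref for a in self.alleles)

    @property
    def is_callable(self) -> bool:
        """Non-missing and not removed by an artifact filter."""
        return self.alleles is not None and not (
            self.flags & {"snpcluster", "nearindel"}
        )


def call_genotypes(
    sites: Iterable[PileupSite],
    min_depth: int = 3,
    min_q: int = 20,
    min_mq: int = 20,
) -> list[GenotypeCall]:
    """Diploid genotype calls from pileup sites sorted by (chrom, pos).

    Reads below ``min_q`` base quality or ``min_mq`` mapping quality are
    excluded; sites with fewer than ``min_depth`` passing reads are
    missing (flag ``lowdepth``).  The call is heterozygous when the minor
    allele is seen in >=2 passing reads making up >=20% of them, else
    homozygous for the majority allele (ties broken to the
    lexicographically smaller base).
    """
    out: list[GenotypeCall] = []
    prev: Optional[tuple[str, int]] = None
    for s in sites:
        key = (s.chrom, s.pos)
        if prev is not None and key <= prev and key[0] == prev[0]:
            raise ValueError(f"pileup not sorted at {s.chrom}:{s.pos}")
        prev = key
        passing = [
            b for b, q, m in zip(s.bases, s.base_q, s.map_q)
            if q >= min_q and m >= min_mq
        ]
        if len(passing) < min_depth:
            out.append(GenotypeCall(s.chrom, s.pos, s.ref, None, len(passing),
                                    {"lowdepth"}))
            continue
        counts = Counter(passing)
        # majority allele; count ties resolved lexicographically
        major = min(counts, key=lambda a: (-counts[a], a))
        rest = {a: c for a, c in counts.items() if a != major}
        if rest:
            minor = min(rest, key=lambda a: (-rest[a], a))
            n_minor = rest[minor]
            if n_minor >= 2 and n_minor / len(passing) >= 0.20:
                out.append(GenotypeCall(s.chrom, s.pos, s.ref,
                                        tuple(sorted((major, minor))), len(passing)))
                continue
        out.append(GenotypeCall(s.chrom, s.pos, s.ref, (major, major), len(passing)))
    return out


def filter_snp_artifacts(
    calls: Sequence[GenotypeCall],
    indel_positions: Iterable[tuple[str, int]] = (),
    cluster_span: int = 10,
    cluster_count: int = 3,
    indel_distance: int = 3,
) -> list[GenotypeCall]:
    """Flag SNP clusters and near-indel SNPs.

    Any window of ``cluster_span`` consecutive bp containing
    ``cluster_count`` or more SNP calls flags them all (``snpcluster``);
    any SNP within ``indel_distance`` bp of an indel position, in either
    direction, is flagged ``nearindel``.  Both filters are pure site
    predicates, so their application order does not matter.  Non-SNP
    calls are untouched.  Returns new call objects; inputs are not
    mutated.
    """
    out = [GenotypeCall(c.chrom, c.pos, c.ref, c.alleles, c.depth, set(c.flags))
           for c in calls]
    by_chrom: dict[str, list[int]] = {}
    for i, c in enumerate(out):
        if c.is_snp:
            by_chrom.setdefault(c.chrom, []).append(i)
    indels: dict[str, np.ndarray] = {}
    for chrom, pos in indel_positions:
        indels.setdefault(chrom, [])
        indels[chrom].append(pos)
    indels = {c: np.sort(np.asarray(p)) for c, p in indels.items()}

    for chrom, idx in by_chrom.items():
        pos = np.array([out[i].pos for i in idx])
        # sliding inclusive span: pos_j - pos_i <= cluster_span - 1
        j = 0
        for i in range(len(idx)):
            if j < i:
                j = i
            while j + 1 < len(idx) and pos[j + 1] - pos[i] <= cluster_span - 1:
                j += 1
            if j - i + 1 >= cluster_count:
                for k in range(i, j + 1):
                    out[idx[k]].flags.add("snpcluster")
        ip = indels.get(chrom)
        if ip is not None and len(ip):
            for i in idx:
                k = np.searchsorted(ip, out[i].pos)
                near = False
                if k < len(ip) and ip[k] - out[i].pos <= indel_distance:
                    near = True
                if k > 0 and out[i].pos - ip[k - 1] <= indel_distance:
                    near = True
                if near:
                    out[i].flags.add("nearindel")
    return out


def accept_bins(
    calls: Sequence[GenotypeCall],
    depth: dict[str, np.ndarray],
    bin_size: int = 1000,
    max_depth_mult: float = 2.0,
    min_callable: float = 0.90,
    genome_mean_depth: Optional[float] = None,
) -> IntervalSet:
    """1-kbp genomic bin acceptance.

    ``depth`` maps chromosome to a per-position raw read-depth array (its
    length defines the chromosome length).  A bin passes iff its mean
    depth is strictly under ``max_depth_mult`` times the genome-wide mean
    (computed over all positions of this sample unless supplied) and at
    least ``min_callable`` of its positions carry a callable genotype.
    The final partial bin of each chromosome is excluded.
    """
    if genome_mean_depth is None:
        total = sum(float(d.sum()) for d in depth.values())
        n = sum(len(d) for d in depth.values())
        genome_mean_depth = total / n if n else 0.0
    threshold = max_depth_mult * genome_mean_depth

    callable_mask = {c: np.zeros(len(d), dtype=bool) for c, d in depth.items()}
    for c in calls:
        if c.is_callable and c.chrom in callable_mask:
            i = c.pos - 1
            if 0 <= i < len(callable_mask[c.chrom]):
                callable_mask[c.chrom][i] = True

    ivs, meta = [], []
    for chrom, d in depth.items():
        for s in range(0, len(d) - bin_size + 1, bin_size):
            mean_d = float(d[s:s + bin_size].mean())
            frac = float(callable_mask[chrom][s:s + bin_size].mean())
            if mean_d < threshold and frac >= min_callable:
                ivs.append((chrom, s, s + bin_size))
                meta.append({"callable_fraction": frac, "mean_depth": mean_d})
    return IntervalSet(ivs, metadata=meta)


def chain_bins(bins: IntervalSet) -> IntervalSet:
    """Merge runs of exactly adjacent bins; see IntervalSet.chain."""
    return bins.chain()


def select_spans(
    regions: IntervalSet,
    callable_masks: dict[str, dict[str, np.ndarray]],
    min_span: int = 5000,
    max_missing: float = 0.10,
) -> IntervalSet:
    """Keep regions of length >= ``min_span`` whose missing-data fraction
    is strictly below ``max_missing`` in *every* sample.

    ``callable_masks[sample][chrom]`` is a per-position boolean callable
    indicator for that sample.
    """
    kept = []
    for chrom, start, end in regions:
        if end - start < min_span:
            continue
        ok = True
        for sample, masks in callable_masks.items():
            m = masks[chrom][start:end]
            # integer-exact strict inequality: missing/len < max_missing
            n_missing = len(m) - int(m.sum())
            if n_missing * 1e9 >= round(max_missing * 1e9) * len(m):
                ok = False
                break
        if ok:
            kept.append((chrom, start, end))
    return IntervalSet(kept)


# -- effective coverage (mtDNA-style filter) -------------------------------

@dataclass
class EffectiveCoverage:
    pos: int
    per_allele: dict[str, float]
    major: Optional[str]
    major_fraction: float
    no_data: bool = False


def effective_coverage(site: PileupSite) -> EffectiveCoverage:
    """Per-allele effective coverage, downweighting each read by its base
    and mapping error probabilities:
    C(a) = sum over reads carrying a of (1 - 10^(-m/10)) (1 - 10^(-q/10)).
    """
    per: dict[str, float] = {}
    for b, q, m in zip(site.bases, site.base_q, site.map_q):
        w = (1.0 - 10.0 ** (-m / 10.0)) * (1.0 - 10.0 ** (-q / 10.0))
        per[b] = per.get(b, 0.0) + w
    total = sum(per.values())
    if total <= 0.0:
        return EffectiveCoverage(site.pos, per, None, 0.0, no_data=True)
    major = min(per, key=lambda a: (-per[a], a))
    return EffectiveCoverage(site.pos, per, major, per[major] / total)


def filter_mt_sites(
    sites: Sequence[PileupSite],
    min_major_fraction: float = 0.70,
) -> list[PileupSite]:
    """Keep sites whose major-allele effective coverage is at least
    ``min_major_fraction`` of the total; zero-coverage sites are dropped
    (flagged no-data in the report)."""
    kept = []
    for s in sites:
        ec = effective_coverage(s)
        if not ec.no_data and ec.major_fraction >= min_major_fraction:
            kept.append(s)
    return kept


def mt_report(
    sites: Sequence[PileupSite],
    min_major_fraction: float = 0.70,
) -> pd.DataFrame:
    """Per-site effective-coverage table (pos, per-allele C, major
    fraction, kept flag) suitable for TSV export."""
    rows = []
    for s in sites:
        ec = effective_coverage(s)
        rows.append({
            "pos": s.pos,
            "alleles": ",".join(f"{a}:{c:.6g}" for a, c in sorted(ec.per_allele.items())),
            "major": ec.major or ".",
            "major_fraction": ec.major_fraction,
            "kept": (not ec.no_data) and ec.major_fraction >= min_major_fraction,
        })
    return pd.DataFrame(rows)


# -- pileup / VCF text I/O -------------------------------------------------

def write_pileup_tsv(sites: Iterable[PileupSite], path) -> None:
    """Columns: chrom, pos (1-based), ref, depth, bases, base qualities
    (phred+33 string), mapping qualities (comma list), indel flag."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\tdepth\tbases\tbaseq\tmapq\tindel\n")
        for s in sites:
            bq = "".join(chr(min(q, 93) + 33) for q in s.base_q)
            mq = ",".join(str(m) for m in s.map_q)
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.depth}\t"
                     f"{''.join(s.bases)}\t{bq}\t{mq}\t{int(s.indel)}\n")


def read_pileup_tsv(path) -> list[PileupSite]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "bases": str, "baseq": str,
                                            "mapq": str})
    out = []
    for row in df.itertuples(index=False):
        bases = list(row.bases) if isinstance(row.bases, str) else []
        bq = [ord(c) - 33 for c in row.baseq] if isinstance(row.baseq, str) else []
        mq = ([int(x) for x in str(row.mapq).split(",")]
              if isinstance(row.mapq, str) and row.mapq != "" else [])
        out.append(PileupSite(row.chrom, int(row.pos), row.ref, bases, bq, mq,
                              bool(row.indel)))
    return out


def write_calls_vcf(calls: Sequence[GenotypeCall], path) -> None:
    """Genotype calls as a minimal single-sample VCF with FILTER tags
    (lowdepth, snpcluster, nearindel)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for f in ("lowdepth", "snpcluster", "nearindel"):
            fh.write(f'##FILTER=<ID={f},Description="{f}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for c in calls:
            if c.alleles is None:
                gt, alt = "./.", "."
            else:
                alts = sorted(set(a for a in c.alleles if a != c.ref))
                alt = ",".join(alts) if alts else "."
                code = {c.ref: 0, **{a: i + 1 for i, a in enumerate(alts)}}
                gt = "/".join(str(code[a]) for a in c.alleles)
            filt = ";".join(sorted(c.flags)) if c.flags else "PASS"
            fh.write(f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{alt}\t.\t{filt}\t.\tGT\t{gt}\n")
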