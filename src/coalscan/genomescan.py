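"""Windowed genome scans and rank correlations.

Three tracks over fixed-size (default 1 Mb) windows: mean sequence
divergence of the panel to the outgroup, mean pairwise Robinson-Foulds
distance among the gene trees falling in each window, and an external
(or simulated) recombination-rate covariate; plus Kendall tau-b rank
correlation between any two tracks.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
from scipy import stats

from .genotypes import GenotypeMatrix
from .gtree import TreeSet
from .intervals import IntervalSet
from .trees import rf_distance

__all__ = ["WindowTrack", "CorrelationResult", "divergence_track", "rf_track",
           "kendall_tau"]


@dataclass
class WindowTrack:
    """Per-window scalar values over a fixed-size tiling.

    ``values`` is NaN (missing, not zero) where a window has no data;
    ``counts`` holds the number of contributing sites or trees;
    ``partial`` flags windows shorter than the nominal size (kept in the
    track, excluded from correlations).
    """

    windows: IntervalSet
    values: np.ndarray
    counts: np.ndarray
    partial: np.ndarray
    name: str = ""

    def to_bedgraph(self, path) -> None:
        self.windows.to_bed(path, values=self.values)


@dataclass
class CorrelationResult:
    tau: float
    p: float
    n: int


def _tiling(span_end: int, window: int, chrom: str) -> IntervalSet:
    return IntervalSet.windows({chrom: span_end}, window)


def divergence_track(
    matrix: GenotypeMatrix,
    outgroup: str,
    window: int = 1_000_000,
    callable_sites: Optional[IntervalSet] = None,
    genome_length: Optional[int] = None,
) -> WindowTrack:
    """Mean divergence of all samples to the outgroup per window.

    Per sample, divergence = differing sites / callable sites against
    the outgroup sequence; heterozygous comparisons count 0.5 in diploid
    mode (the expectation for a sampled allele).  The track value is the
    across-sample mean; windows with zero callable sites are missing.
    Assumes a single chromosome of ``genome_length`` bp (defaults to the
    last site's position rounded up to a full window).
    """
    chrom = str(matrix.chrom[0]) if matrix.n_sites else "1"
    if genome_length is None:
        genome_length = int(matrix.pos.max()) + 1 if matrix.n_sites else window
    tiles = _tiling(genome_length, window, chrom)
    n_win = len(tiles)
    og = matrix.taxon_index(outgroup)
    others = [j for j in range(len(matrix.taxa)) if j != og]

    frac = matrix.derived_fraction()
    # expected pairwise difference between a random sample allele and a
    # random outgroup allele: p(1-q) + q(1-p)
    p = frac[:, others]
    q = frac[:, [og]]
    diff = p * (1 - q) + q * (1 - p)
    valid = np.isfinite(diff)

    widx = (matrix.pos // window).astype(np.int64)
    values = np.full(n_win, np.nan)
    counts = np.zeros(n_win, dtype=np.int64)
    partial = np.zeros(n_win, dtype=bool)
    for w, (c, s, e) in enumerate(tiles):
        partial[w] = (e - s) < window
        if callable_sites is None:
            callable_bp = e - s
        else:
            callable_bp = callable_sites.intersect(
                IntervalSet([(c, s, e)])
            ).total_length()
        sel = widx == w
        counts[w] = int(sel.sum())
        if callable_bp == 0:
            continue
        per_sample = np.where(valid[sel], diff[sel], 0.0).sum(axis=0) / callable_bp
        values[w] = float(per_sample.mean())
    return WindowTrack(tiles, values, counts, partial, name="divergence")


def rf_track(
    trees: TreeSet,
    window: int = 1_000_000,
    genome_length: Optional[int] = None,
) -> WindowTrack:
    """Mean pairwise Robinson-Foulds distance among the trees whose
    window provenance midpoint falls in each scan window; windows with
    fewer than two trees are missing."""
    provs = [t.window for t in trees]
    if any(p is None for p in provs):
        raise ValueError("rf_track requires per-tree window provenance")
    chrom = provs[0][0]
    if genome_length is None:
        genome_length = max(p[2] for p in provs)
    tiles = _tiling(genome_length, window, chrom)
    n_win = len(tiles)
    groups: dict[int, list[int]] = {}
    for i, (c, s, e) in enumerate(provs):
        mid = (s + e) // 2
        groups.setdefault(mid // window, []).append(i)
    values = np.full(n_win, np.nan)
    counts = np.zeros(n_win, dtype=np.int64)
    partial = np.array([(e - s) < window for _, s, e in tiles])
    for w in range(n_win):
        members = groups.get(w, [])
        counts[w] = len(members)
        if len(members) < 2:
            continue
        dists = [
            rf_distance(trees[i], trees[j]) for i, j in combinations(members, 2)
        ]
        values[w] = float(np.mean(dists))
    return WindowTrack(tiles, values, counts, partial, name="mean_rf")


def kendall_tau(x: WindowTrack, y: WindowTrack) -> CorrelationResult:
    """Kendall tau-b between two tracks with tie correction.

    Windows missing in either track, and partial windows, are excluded.
    Raises when fewer than two complete pairs remain; returns NaN tau
    when either track is constant (tau undefined).
    """
    if len(x.values) != len(y.values):
        raise ValueError("tracks must share a window tiling")
    ok = (np.isfinite(x.values) & np.isfinite(y.values)
          & ~x.partial & ~y.partial)
    xv, yv = x.values[ok], y.values[ok]
    n = int(ok.sum())
    if n < 2:
        raise ValueError("need at least two complete window pairs")
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        return CorrelationResult(float("nan"), float("nan"), n)
    tau, p = stats.kendalltau(xv, yv)
    return CorrelationResult(float(tau), float(p), n)
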