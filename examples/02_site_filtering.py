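"""Callable-site selection on a labelled synthetic pileup.

Generates a 50-kbp pileup with injected SNP clusters, near-indel SNPs
and a high-depth (CNV-like) segment, then runs the full filter chain:
genotype calls at >=3 reads with base/mapping quality >=20, cluster and
indel exclusion, 1-kbp bin acceptance and chaining.
"""

import numpy as np

import coalscan as cs
from coalscan.sitefilter import accept_bins, chain_bins

sites, truth = cs.simulate_pileup(length=50_000, coverage=12.0, seed=7,
                                  n_clusters=4, n_indels=4, n_high_depth=1)
calls = cs.call_genotypes(sites)
flagged = cs.filter_snp_artifacts(
    calls, indel_positions=[("1", p) for p in truth.indel_positions])

n_missing = sum(c.is_missing for c in flagged)
n_cluster = sum("snpcluster" in c.flags for c in flagged)
n_indel = sum("nearindel" in c.flags for c in flagged)
print(f"{len(flagged)} sites: {n_missing} low-depth, "
      f"{n_cluster} in SNP clusters (truth: {len(truth.cluster_snps)}), "
      f"{n_indel} near indels (truth: {len(truth.near_indel_snps)})")

depth = {"1": np.array([s.depth for s in sites], dtype=float)}
bins = accept_bins(flagged, depth)
regions = chain_bins(bins)
print(f"{len(bins)} accepted 1-kbp bins -> {len(regions)} chained regions, "
      f"{regions.total_length()} bp callable of 50,000")
print("high-depth truth segment:", list(truth.high_depth))
# Bins overlapping the 2.5x-depth segment fail the strict
# depth < 2 x genome mean rule, which is why the callable span is
# shorter than the genome.

# effective-coverage filter for an mtDNA-like high-variance site
s = cs.PileupSite("MT", 100, "A", ["A", "A", "G"], [40, 40, 10], [40, 40, 10])
ec = cs.effective_coverage(s)
print(f"\nmtDNA-style site: C = { {a: round(c, 4) for a, c in ec.per_allele.items()} }, "
      f"major fraction {ec.major_fraction:.3f} -> "
      f"{'kept' if ec.major_fraction >= 0.70 else 'filtered'} at the 70% rule")
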