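# Methods

`coalscan` packages the bespoke computations of a multi-genome
speciation-with-gene-flow analysis — callable-site selection, ABBA-BABA
D statistics, gene-tree discordance analytics and windowed genome scans
— together with a multispecies-coalescent simulator that generates the
kind of data those computations assume, so every stage is testable
without any sequence download.

## The simulator

**Model.** A rooted binary ultrametric species tree over taxon labels,
with per-branch durations in generations and per-branch diploid
effective population sizes Ne. Within a branch, every pair of lineages
coalesces at rate 1/(2 Ne) per generation. Time units are generations
throughout; coalescent units are t/(2 Ne), computed where needed rather
than stored, to keep conversions unambiguous. Admixture is modelled as
directed pulses: at the pulse time, looking backwards, each lineage in
the recipient branch moves to the donor branch independently with
probability gamma. A gamma = 0 pulse is a bit-exact no-op.

**Windows are unlinked.** Each window carries an independent gene tree
(free recombination between windows, none within). This matches the
per-bin tree model of the downstream analytics and keeps the D-statistic
block jackknife exact: with windows as blocks, blocks really are
independent. Sub-window recombination can be enabled for the
correlation scans (below).

**Mutations.** Infinite sites: each branch of the gene tree receives
Poisson(mu · L · branch length) mutations, each creating one biallelic
site carried by exactly the leaves below it, at a distinct position in
the window. The D-statistic site-pattern logic assumes single-origin
biallelic sites, which this guarantees by construction. A configuration
whose expected mutation count exceeds the window length is rejected.

**The bundled panel.** The default species tree has 10 ingroup taxa —
six Eurasian wild-boar population samples (EUA, EUB, JPN, NCH, SCH,
SUM) on a ladder from 0.1 to 0.5 M generations, four island species
(VER, BAR, CEL, CEB) joining between 0.8 and 1.15 M generations — and a
warthog outgroup (WAR) at 2.6 M generations, attached at the root.
With Ne = 1e5 on every branch the internal branches span 0.4–2.25
coalescent units, giving pervasive incomplete lineage sorting across
the ingroup (the regime the analyses are designed for). The default
mutation rate is 1e-9 per site per generation, chosen so a 5-kbp window
yields roughly 60 variant sites: enough informative sites per quartet
for the jackknife to be in its asymptotic regime, at desk-scale compute.
These are free parameters of the generator, not estimates for any real
taxon.

**Recombination covariate.** For the correlation scans each window can
be tiled into `bins_per_window` (default 8) bins; a per-window rate
r_w ~ LogNormal(0, 0.7) is drawn and min(Poisson(3 r_w), bins-1)
breakpoints partition the bins into runs that share a single gene tree.
More recombination therefore means more distinct trees inside a window:
the mean pairwise Robinson-Foulds distance among a window's bin trees
rises from ~0 (one shared tree) to the independent-draw expectation.
The covariate is generated, not mechanistic — it exists to exercise the
rank-correlation machinery with a known-direction link, not to model a
linkage map.

**Pileup fixture.** A separate generator emits pileup-level records
(per-read base calls, base and mapping qualities, depth ~ Poisson)
with injected artifacts — 3-SNP clusters spanning exactly 10 bp, SNPs
placed 1–3 bp from an indel, and 2.5x-depth CNV-like segments — each
with exact ground-truth labels, so filter recall and false-positive
rates are computable, not estimated. Qualities are clipped normal
draws; reads are independent. What this does *not* emulate: alignment
error correlated along reads, reference bias, mapping-quality/position
interactions, or indel realignment — so passing filter tests show the
rules are implemented exactly as specified, not that the thresholds are
optimal on real alignments.

## Site and bin filters

Genotypes are called at sites with at least `min_depth` = 3 reads
passing base and mapping quality >= 20. The caller itself (unspecified
in the pileup-era tools this emulates) is a concrete stand-in: a site is
heterozygous when the minor allele has >= 2 passing reads and >= 20% of
them, else homozygous for the majority allele, with count ties broken
to the lexicographically smaller base for determinism.

Artifact rules, read literally and pinned by boundary tests:

- *SNP clusters*: any sliding window of 10 consecutive bp containing
  >= 3 SNP calls flags them all (positions 100, 105, 109 — span 10 bp —
  are all removed; 100, 105, 110 are kept).
- *Indel proximity*: SNPs within 3 bp of an indel position, in either
  direction (distance 3 removed, distance 4 kept).
- *Bin acceptance*: fixed 1-kbp bins pass iff mean raw depth is
  **strictly under** 2x the genome-wide mean and >= 90% of positions
  are callable. The final partial bin of a chromosome is excluded:
  fixed-size bin statistics are not comparable on truncated bins. The
  2x threshold uses the per-sample genome-wide mean (whether the
  original rule intended per-sample or cross-sample means is ambiguous;
  per-sample is self-contained).
- *Chaining* merges bins with exactly `end == start`; a 1-bp gap is
  never bridged.
- *Region selection* keeps chained regions of >= 5 kbp whose missing
  fraction is **strictly below** 10% in every sample. The strict
  inequality at exactly 10% is enforced with integer arithmetic, since
  450/5000 is not representable in binary floating point.

The effective-coverage filter for high-variance (mtDNA-like) contigs
weights each read by (1 − 10^(−m/10))(1 − 10^(−q/10)) — the probability
it is both correctly mapped and correctly called — sums per allele, and
keeps a site iff the major allele holds >= 70% of the total. C is
monotone in every read's qualities (property-tested), and zero-coverage
sites are flagged no-data rather than silently dropped.

Coordinates are 0-based half-open internally and in BED output, 1-based
in pileup and VCF I/O.

## D statistics

Sites are polarized on the outgroup: its haploid or homozygous allele is
the ancestral state A; sites with a heterozygous or missing outgroup
are dropped (judged on the raw genotypes, before any pseudo-haploid
resolution). For a quartet (P1, P2, P3, O), per-site weights are
(1−x1)·x2·x3 for ABBA and x1·(1−x2)·x3 for BABA with x the derived
fraction; in the default pseudo-haploid mode each heterozygote is first
resolved to one random allele with a seeded RNG, making the weights 0/1
indicators. A frequency-weighted mode keeps fractional dosages.
Pseudo-haploid is the default because it is deterministic given a seed
and matches how single-genome panels are usually analysed; which of the
two conventions the original analyses used is not documented, and both
are provided.

D = (nABBA − nBABA)/(nABBA + nBABA); it is NaN, never 0, without
informative sites. The standard error is a delete-one block jackknife
over contiguous genomic blocks — the simulation windows by default, or
a fixed bp size or explicit BED partition. The default treats each
block as one exchangeable unit. The choice of unit matters: the
informative-site-count-weighted variant (Busing, Meijer & van der
Leeden 1999; available as `weighting="sites"`) assumes sites within a
block are as exchangeable as sites across blocks, but a block's
informative sites typically descend from a single local genealogy and
swing together, and under that clustering the site-weighted SE
understates the replicate-to-replicate spread of D by 10–25% (measured
here across replicate genomes, and reproduced in a controlled
two-level experiment where the plain delete-one estimator stays
calibrated: SD(Z) 1.03 vs 1.13). The two estimators coincide exactly
for equal blocks (asserted in a test). When every informative site
shares one pattern (D = ±1) the jackknife has no resampling
variability and Z is flagged undefined rather than divided by a
floating-point zero. Z = D/SE; two-sided
p from the normal; Bonferroni correction multiplies p by the number of
D computations, and significance is called on the adjusted p at 0.01.
The enumeration produces one configuration per unordered {P1, P2} pair
(3·C(n,3) in total), since swapping P1 and P2 only flips D's sign;
optionally only configurations consistent with a supplied species tree
are kept — the null-calibration guarantees (Z ~ N(0,1) without gene
flow) apply to those, while tree-inconsistent configurations have
|D| >> 0 by topology alone.

The admixture fraction for donor → P2 flow is the excess-sharing ratio
f = S(P1, P2, P3a, O)/S(P1, P3b, P3a, O), S = nABBA − nBABA, with
P3a/P3b the donor's two lineages (phased haplotypes of a diploid donor,
or an explicit proxy pair); the denominator represents total
replacement of P2 by donor lineages. Its SE uses the same weighted
jackknife applied to the ratio. A non-positive denominator leaves f
undefined (NaN), flagged rather than clamped.

## Tree analytics

Per-window trees come from neighbor joining on Jukes-Cantor-corrected
distances — a deterministic stand-in for a maximum-likelihood search
(externally computed Newick trees drop in via `TreeSet.from_newick_file`,
and all downstream statistics are agnostic to the tree source). NJ ties
are broken lexicographically by the joined clusters' smallest leaf
labels so identical input yields an identical Newick string; negative
limb estimates are clipped to zero; a raw distance >= 0.75 makes the JC
correction undefined and raises an error naming the pair. Bootstrap
replicates resample alignment columns multinomially, counting the
implicit invariant columns.

Trees are treated as unrooted (bitmask bipartitions, normalized away
from a reference taxon) for Robinson-Foulds distances, bipartition
frequencies and consensus, and rooted for clade tables and STAR — each
procedure's own mathematical requirement. The consensus is
majority-rule-extended: bipartitions sorted by descending frequency
(ties by bitmask, for determinism) are added greedily while compatible,
and node support is the bipartition frequency, so the consensus's
support values reproduce the clade-frequency table exactly. STAR roots
every gene tree on the outgroup, assigns the root rank n (taxon count)
and each internal node its parent's rank minus one, averages the
2·rank-of-MRCA pair distances across trees, and runs NJ on the averaged
matrix. Gene trees lacking the outgroup are skipped with a count.

A supermatrix utility groups random bins into ~1-Mbp concatenations
without replacement (so the groups are disjoint); drawing with
replacement is available behind a flag since the original description
of "unique alignments" does not settle the question.

## Genome scans

Divergence to the outgroup per fixed-size window is differing sites /
callable sites, averaged over samples; heterozygous comparisons count
0.5 — the expectation for one sampled allele (the original convention
is unstated). The RF track averages pairwise Robinson-Foulds distances
over the trees whose provenance midpoint falls in the window; windows
with fewer than two trees are missing (NaN), never zero. Correlation
uses Kendall's tau-b with tie correction as implemented in scipy,
checked exactly against an O(n²) concordant/discordant pair-counting
oracle; missing and partial windows are excluded pairwise, and p-values
are reported raw, matching single-test usage. The final partial window
stays in the tracks but is flagged and excluded from correlations.

## Pipeline

One YAML config drives simulate → D statistics → tree analytics →
scans. The schema is validated before any stage runs and unknown keys
are rejected. A single global seed deterministically derives per-stage
seeds (SHA-256 of stage name + seed, reduced below 2³¹), so stages are
individually reproducible from one knob; the manifest records
parameters, seeds and SHA-256 checksums of every output, and a rerun
with the same config reproduces all checksums. On stage failure the
run aborts naming the stage, and outputs written so far get a
`.partial` suffix.

## Problem sizes in the test and acceptance runs

The statistical suites run at the following scales, chosen as the
package's own desk-scale study conditions: null calibration over 500
replicate genomes of 5,000 x 5-kbp windows (all 120 tree-consistent
quartets each); jackknife-vs-empirical-SD over 200 replicate genomes of
2,000 windows; admixture-fraction recovery over 100 diploid replicates
of 10,000 windows at gamma = 0.10; D-vs-gamma monotonicity over 60
replicates of 2,000 windows per gamma in {0, 0.05, 0.1, 0.2}; MSC
discordance at 10,000 draws per T in {0.5, 1, 2}; STAR consistency over
50 replicates of 1,000 gene trees with 1-coalescent-unit internodes;
RF oracle on all pairs of 500 random 6-taxon trees; correlation scans
on 200 windows. `scripts/acceptance.py` recomputes the same quantities
at moderately reduced replicate counts (150/100/40/30 replicates
respectively), which shifts only Monte-Carlo error, not expectations.

## Known limitations

- No intra-window linkage map, no continuous migration (pulses only),
  no selection, no sequence-level read simulation (no FASTQ or
  alignment step).
- The mutation model is infinite-sites 0/1; transition/transversion
  structure and triallelic sites exist only through the VCF import
  path, where non-biallelic records are skipped with a count.
- The simulator's Ne and split times are free parameters; nothing here
  estimates demographic history from data.
- The bitmask tree machinery supports at most 63 taxa; the jackknife
  requires at least two blocks with informative sites and flags, rather
  than fabricates, an SE otherwise.
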