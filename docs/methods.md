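# Methods

## Coverage model and island calling

**Input contract.** Per-base depth tracks (samtools-depth 3-column TSV or
bedGraph) on a reference replicon; positions absent from the input are depth
0. Internally everything is 0-based half-open; samtools-depth's 1-based
positions are converted on read.

**Mode-balanced normal fit.** The per-base depth histogram (default bin
width 1 depth unit — depths are integer read counts) is treated as a normal
background contaminated by a right tail (repeats, conserved mobile elements,
high-copy regions) and a left excess (genomic islands). The largest bin is
the primary mode, with ties broken toward lower depth (the conservative
choice: a lower mode gives a lower island cutoff). The fitting window is the
region around the mode over which counts decrease monotonically away from
it, truncated symmetrically to `w = min(left extent, right extent)` bins; μ
and σ are the plain Gaussian MLE (sample mean, 1/n SD) of the positions
whose depth falls in the window. No truncation correction is applied by
default: for the symmetric unimodal case the window covers essentially the
whole sample, and for contaminated cases the bias from symmetric truncation
is second-order relative to the contamination it removes.

*Monotonicity under sampling noise.* A literal per-bin "counts must not
increase" rule is ill-posed on real histograms: near the mode the expected
difference between adjacent bins is far smaller than its multinomial
sampling noise (for N(100, 10²) at n = 10⁵, adjacent expected counts differ
by ~18 while their noise SD is ~60), so the strict rule truncates after one
or two bins and collapses σ̂. The default therefore judges monotonicity
against noise: scanning outward, a side's extent ends at the first bin whose
count rises more than `z·√(running minimum)` above the running minimum on
that side (`noise_tolerance = z = 5`; `z = 0` recovers the strict rule).
This keeps expansion through noise-level wiggles but stops at a genuine
secondary mode: on a pure N(100, 10²) sample the fit equals the full-sample
MLE to three decimals, while with a 10% N(300, 20²) contaminant the window
closes before the contaminant mode and μ̂ matches the uncontaminated
component's MLE.

**Cutoff and islands.** The island threshold is `max(0, μ̂ − 3σ̂)`. Islands
are maximal runs of depth strictly below the cutoff, strictly longer than
`min_island_len` (default 1000 bp — "greater than 1 kb"). Degenerate fits
(σ̂ = 0 or fewer than `min_fit_positions = 100` window positions) never call
islands. Two optional structure parameters, both off by default:

- `smooth_window` — centred running median (odd width) applied before
  thresholding. At 50× background a true island at population fraction 0.3
  has λ ≈ 15 inside, and individual positions exceed the ≈29 cutoff with
  probability ~5·10⁻⁴ — enough to split a >1 kb run. A window of 101 bp
  (≪ the minimum island length, ≫ the per-base noise scale) removes both
  these splits and isolated sub-cutoff noise positions; the planted-truth
  recovery and null-calibration checks run with `smooth_window=101`, which
  is the recommended setting for per-base calling.
- `max_gap` — joins sub-cutoff runs separated by at most this many
  above-cutoff positions before the length filter (an alternative to
  smoothing; default 0).

Whether the fitting histogram should pool per-base depths or binned medians
is an open choice; the default is per-base (finer granularity, consistent
with the >1 kb rule being finer than the 5-kb abundance bins).

**Binned medians and heat-map scaling.** Abundance uses the per-bin median
depth (default 5 kb bins for primary replicons, 1 kb for secondaries; the
last partial bin uses the available positions). For display, each sample row
is centred and scaled to mean 0, SD 1 (population SD); all-constant rows
become zeros with a warning. Correlation between samples is computed on the
*unscaled* binned medians (scaling is display-only); Pearson by default,
Spearman by flag, distance `1 − r`.

**GC/coverage contig clustering.** Contigs are grouped on log2(depth) by an
exact dynamic-programme 1-D k-partition (minimum within-group sum of
squares); GC is carried for reporting only. Points further than 3 group SDs
from every group mean are labelled −1 (outliers: e.g. high-copy
transposase-bearing fragments).

## Homology analyses

**Aligner.** Seed–chain–extend: exact k-mer seeds on both strands (k = 21
for ~99%-identity HIR/allele searches, where long exact seeds are abundant;
k = 15 for 80%-identity recruitment), greedy colinear chaining with a 100-bp
gap/diagonal-drift bound, ungapped x-drop extension at chain ends (+1/−2,
drop 20), and per-chain global alignment of the spanned regions with edlib
(optimal unit-cost edit distance). Identity = matches / alignment columns,
counting gap columns in the denominator. Hits overlapping on both axes are
merged and re-aligned. Hyper-repetitive seeds (>100 occurrences) are
skipped. Precomputed hits (PAF or MUMmer show-coords) can be substituted for
the internal aligner anywhere downstream; all filters are applied
identically. On mutated pairs the reported identity matches an exhaustive
dynamic-programming oracle (Biopython's PairwiseAligner minimising edit
distance) to well within 0.5 percentage points.

**HIRs.** All qualifying hits across all record pairs of two genomes, with
overlapping hits per pair merged before the length filter; defaults
identity ≥ 0.99 and length ≥ 2000 bp (observed HIR spectra span ~2–14 kb; a
stricter >5 kb preset is a flag away). Sorted by length descending.

**Shared/unique partitioning.** Shared = union of query-contig intervals
covered by hits at ≥ 80% identity; unique = complement. The partition is
conservation-exact: shared + unique bp always equals total query bp.

**Recruitment.** Only hits spanning ≥ 5 kb at ≥ 80% identity qualify.
Replicon coverage is the qualifying-hit target-interval union cumulated over
the replicon; recruited reads are summed over contigs with ≥ 1 qualifying
hit and expressed as % of all mapped reads; mean identity is the unweighted
mean over qualifying hits.

**Allele screening.** Queries are a gene plus exactly 500 bp of flanking
context each side (truncated at replicon ends). Presence requires a single
contig alignment at ≥ 99% identity covering ≥ 90% of the query. The identity
rule alone would accept a 100-bp spurious match; the coverage guard is a
deliberate strengthening, exposed as `min_query_cov`.

## Biogeography

**Abundance.** Per filter fraction, a species' abundance is the sum of its
contigs' coverages (plain sums, per the field's convention; a
length-weighted option exists); per sample, fraction values are averaged,
then normalised to % of the sample total. Samples whose focus-group (e.g.
archaeal) percentage falls below a configurable floor are excluded from
clustering — a community where the focal group is negligible (fractions of a
percent) contributes only noise to resemblance patterns.

**Resemblance and trees.** Abundances are square-root transformed;
Bray–Curtis dissimilarity `Σ|x−y| / Σ(x+y)` (a semimetric: bounds, symmetry
and identity-of-indiscernibles hold, the triangle inequality is not
asserted); UPGMA (average linkage) trees with cophenetic heights — exact on
ultrametric input. Leaf ordering is the **exact** Bar-Joseph dynamic
programme minimising the sum of adjacent-leaf distances among all
2^(n−1) orders consistent with the topology. (scipy's
`optimal_leaf_ordering` was found to return suboptimal orders on random
matrices when validated against exhaustive enumeration, so the ordering is
implemented here; scipy still computes the linkage.) The DP is O(n³)-ish
and comfortable at the tens-of-samples scale this package targets.

**nMDS.** Kruskal stress-1 minimised by SMACOF majorization alternating
with isotonic regression of disparities (scikit-learn's PAVA); ties in the
input dissimilarities are handled by the primary approach (within tied
values, disparities follow the current configuration distances). Default 2
dimensions, 20 random restarts, best (lowest-stress) configuration kept;
deterministic given the seed; coordinates centred and rotated to principal
axes. Within a run the stress history is non-increasing (up to the
disparity-rescaling step's floating tolerance), and the implementation is
cross-checked against scikit-learn's non-metric MDS in the test suite.

**Replicon-structure regression.** Ordinary least squares of the % of the
primary replicon at low coverage on the % of the genome held in secondary
replicons, reporting R²; with ≥ 3 genomes.

## Synthetic data

The generator emulates the structure of multi-replicon haloarchaeal data:

- **Strain pair** — one ancestor primary replicon (default 200 kb, GC 0.67;
  a full-scale preset mirrors the published 2735/525/431-kb inventory);
  strain B diverges at a background rate of 5·10⁻⁴ per bp plus designated
  variable loci (default five 3-kb loci at 3% divergence — the
  cell-surface-like, <99%-identity regions); a 29-kb provirus is inserted
  into strain A only. Secondary replicons (default 40/20 kb, GC 0.57) share
  a 30% core, the remainder unique per strain.
- **HIR planting** — segments copied from strain A's unique secondary
  sequence into a partner-genome carrier replicon, with the requested number
  of substitutions placed ≥ 50 bp interior to the segment and a mismatching
  base forced at the first flanking position on each side. This makes the
  planted extent *well-defined and exactly recoverable*: without the forced
  boundary mismatch, a chance match in the flank leaves the true HIR
  boundary ambiguous at the bp level for any aligner.
- **Coverage** — expected depth λ = base_depth (50×) × species abundance ×
  replicon copy number, multiplied inside planted islands by the island's
  population fraction; depth ~ Poisson(λ), or Gamma-mixed Poisson when
  overdispersion is set. Islands are modelled as population-fraction mixing
  (the biological reading of islands as flexible content), not as mapping
  artefacts.
- **Metagenome assembly** — contigs are genome fragments with lognormal
  lengths (min 1 kb) tiling each replicon exactly (overlap off by default);
  per-contig coverage follows the same λ model with lognormal
  between-fraction dispersion across the configured filter fractions; taxon
  labels are carried as truth; read counts are Poisson(coverage ×
  length / read length).

Identical seeds give byte-identical sequences and tracks. Limitations the
generator does not model: dinucleotide/codon structure (base composition is
i.i.d. with a GC parameter — sufficient for seed statistics, not for
realistic repeat content), sequencing error, chimeric contigs, mapping
biases at island edges, and read-level artefacts. Passing planted-truth
tests therefore demonstrates correctness of the statistics under the stated
generative model, not robustness to assembler- or mapper-specific artefacts
in real data.

Aligner-oracle comparisons use mutated copies with intact 20-bp termini
(mutations drawn interior), so both the internal aligner and the global DP
oracle align end-to-end and the comparison isolates identity computation
from end-trimming ambiguity.

## Numerical and scale choices

- Interval coordinates 0-based half-open throughout; BED output sorted.
- The >1 kb island rule is strict (`length > min_island_len`).
- Histogram mode ties break toward lower depth; the island cutoff is floored
  at 0.
- Validation problem sizes: 1-Mb tracks for null calibration, 200-kb tracks
  with three planted islands per seed for recovery (20 seeds), 2–14 kb HIR
  spectra, ≤2-kb aligner-oracle pairs (100), n ≤ 8 leaf-ordering instances
  against 2^(n−1) enumeration, and nine-sample two-region communities on a
  100-kb replicon (10 seeds). These desk-scale sizes exercise every code
  path with comfortable statistical power; the generator's `full_scale()`
  preset produces published-inventory replicon sizes when heavier runs are
  wanted.
- The workflow layer writes all outputs via write-then-rename and records a
  JSON manifest (parameters, seed, version) for byte-identical reruns.

## Known limitations

- The greedy seed chainer can fragment hits in long low-identity (~80%)
  regions with dense substitutions; recruitment-scale analyses are tested at
  the span/identity thresholds above, not at the aligner's sensitivity
  floor.
- Bray–Curtis is a semimetric; nMDS embeds it without requiring the
  triangle inequality, but UPGMA heights on strongly non-ultrametric input
  are descriptive, not metric-consistent.
- The negative-binomial (Gamma-mixed) overdispersion option widens the
  fitted σ̂ and hence lowers the island cutoff; calibration targets are
  stated for the pure-Poisson model.
- ANI between genomes is approximated by mean qualifying-hit identity, not
  by reciprocal-best-hit gene ANI.
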