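# Methods

This note documents the models and procedures implemented in `allotetra`,
the defaults they run with, the design choices that were genuinely open, and
what the bundled synthetic data does and does not establish.

## Coordinates and data flow

Internal coordinates are 0-based half-open everywhere; VCF and SNP-table
positions are 1-based on disk and converted at the format boundary. The
pipeline's entry point for sequencing evidence is per-dataset coverage in
bedgraph form plus a manifest assigning each dataset to a clade (A-genome
progenitor, D-genome progenitor, or tetraploid AD). Read mapping, duplicate
marking (and the MAPQ < 20 filter recorded in `PipelineConfig.mapq_min`),
variant calling and effect annotation are upstream of this package: it
consumes coverage tracks, VCFs and annotation tables rather than BAMs, so no
aligner is required anywhere.

## Subgenome assignment

For each scaffold and dataset we compute the mean depth **averaged over all
bases, covered or not** (`sum(depth x length) / scaffold length`). "Average
base-pair coverage" is otherwise ambiguous; averaging over all bases makes
the A:D ratio robust to covered-fraction differences. Depths are then
library-size normalized by each dataset's genome-wide mean depth
(switchable via `normalize_depths`), so replicate lines sequenced to
different depths are comparable.

A scaffold is called At when all three criteria hold (Dt mirrors the ratio
sign):

1. union covered fraction over **all** diploid progenitor tracks (A- and
   D-clade pooled; fraction of bases at depth >= 1) > 0.40;
2. `log2((mean_A + eps)/(mean_D + eps)) > 2`, pooling all A-clade datasets
   equally (replicate progenitor lines are highly correlated, and pooling
   avoids an arbitrary choice among them), with pseudocount `eps = 0.01`
   normalized-depth units guarding zero denominators;
3. two-sample Student's t-test (classic equal-variance; Welch via
   `equal_var=False`) on the per-dataset normalized means gives p < 0.01.
   At least two replicate lines per diploid clade are required; with fewer,
   the call errors rather than silently skipping the test.

Everything else is "ungrouped". Tetraploid (AD) tracks are carried through
summaries for display but never classify. When both clades have zero depth
variance and equal means the t statistic is undefined; such scaffolds get
p = 1 (no evidence) and fall into "ungrouped" via the coverage criterion
anyway.

## Hybrid scaffolds and translocation sites

Whole-scaffold assignment cannot see a scaffold that is half At and half Dt
(its A:D ratio averages out), so hybrids are scanned per window: pooled
normalized A and D depths per window (default 10 kb), labelled A/D by the
same +-2 log2-ratio threshold, ambiguous otherwise. Same-label windows merge
into segments; ambiguous windows neither break nor extend a segment. A
junction is emitted between adjacent A and D segments when both flanks span
at least `hybrid_min_segment` (default 50 kb), reported as the interval
between the bounding unambiguous windows — an interval, not a point, because
the window resolution is the real uncertainty. Both window size and minimum
flank are explicit knobs; the defaults are this package's choice of a
conservative operating point, and scanning runs on all scaffolds while
annotating the "ungrouped" subset where true hybrids are expected.

Junction midpoints are projected onto reference chromosomes through a
scaffold-to-reference alignment interval table by strand-aware linear
interpolation; calls outside every interval are reported unprojected.
Sub-telomeric enrichment compares the fraction of projected sites within the
outer 10% of either chromosome end (uniform expectation 0.2) against
`n_permutations` uniform placements on the same chromosomes; the p-value
uses the add-one permutation estimator and is NaN when permutations are
disabled. Distinguishing biological translocation from assembly chimerism
requires orthogonal evidence (junction-spanning read pairs, PCR) and is out
of scope.

## Pseudochromosome anchoring

Genetic-map markers carry 201 bp segments (100 bp left of the SNP, the SNP
base, 100 bp right); segments extracted from a reference skip SNPs within
100 bp of a sequence end. Matching is **ungapped, substitutions only**: the
196/201 minimum match implies a budget of 5 mismatches, and indels are not
tolerated. The matcher is exact for that budget: a placement with at most m
mismatches must contain an exact seed of length `201 // (m+1)` = 33 at one
of six disjoint offsets (pigeonhole), so candidates come from rolling-hash
seed lookups over both strands and are verified by direct mismatch counting
(non-ACGT codes always mismatch). A marker with exactly one best placement
genome-wide is unique; unplaced and tied markers are dropped with a logged
count. The test suite cross-checks this against a brute-force all-positions
Hamming scan.

"At least 5 continuous SNP segments" is interpreted as **consecutive in
within-chromosome map order** (cM rank, stable on ties), not physical
distance; `max_run_gap` optionally tolerates missing markers inside a run
(default 0, strict). A scaffold anchors to the chromosome of its longest
qualifying run; qualifying runs on two chromosomes reject the scaffold.
Scaffolds are ordered by the run's median cM and oriented by the sign of the
correlation between map order and scaffold coordinate (zero or degenerate
correlation gives "unknown", treated as "+" when building sequences). The
published third criterion also allowed consistency with a second tetraploid
assembly; cross-assembly arbitration is reduced here to the
single-chromosome rule. Pseudochromosome sequences concatenate anchored
scaffolds in order, reverse-complemented on "-", separated by 100 N bases,
with an AGP-like layout table recording every placement.

## LTR insertion dating and families

For each intact element the 5' and 3' terminal repeats are compared under
the Kimura two-parameter model: with transition proportion P and
transversion proportion Q over comparable sites,
`K = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)`, and the insertion age is
`T = K/(2r)` at `r = 1.3e-8` substitutions/site/year. Columns containing a
gap or non-ACGT base are excluded (pairwise deletion) — the treatment of
gaps in the original workflow is unstated, so this choice is documented
rather than assumed. Equal-length input is taken as pre-aligned; otherwise a
bundled global aligner (match +1, mismatch -1, gap open -2, extend -0.5)
runs first, keeping the module self-contained. Saturated pairs
(`1-2P-Q <= 0` or `1-2Q <= 0`) are flagged `defined = False` and excluded
from age histograms instead of being clamped, which would silently bias the
distribution. Age histograms default to 0.5 Myr bins (the published
granularity is not stated numerically) and report each group's mode bin.

Family clustering keeps only reciprocal similarity edges (present in both
directions after re-applying the e-value <= 1e-5 filter defensively) and
takes connected components; elements seen only in non-reciprocal or
sub-threshold edges remain singletons, and family numbering is
deterministic by smallest member id. Solo/truncated-to-intact ratios are
computed from supplied counts only; identifying those element classes is
upstream.

## Lineage-specific SNPs and density scan

A site is lineage-L-specific iff the alternate allele is present in every
L-clade dataset covering the site (at least one) and absent from every
covering dataset of all other lineages. "Covering" means a called genotype
with depth >= `min_allele_depth` (default 3; depth-less calls are trusted);
uncovered datasets neither support nor veto — the published rule's exact
coverage requirements are unstated, so these are explicit assumptions.
Tetraploid genotypes are reduced to allele presence/absence; dosage is
ignored. The definition makes lineage sets pairwise disjoint by
construction. Effect summaries consume SnpEff-style annotations and count a
gene once per lineage regardless of its SNP count.

The density scan tiles contigs with 1 Mb windows (the last window may be
short), z-scores window counts against the genome-wide window distribution
and flags `z <= -2` low / `z >= +2` high. The z-score operationalization is
this package's; the original analysis identified low-density regions
descriptively. A degenerate count distribution suppresses all flags.

## Homoeolog expression

Profiles are normalized per gene as log2(FPKM+1) followed by a z-score
across tissues (zero-variance genes get flagged all-zero profiles), then
clustered with seeded k-means applied after sorting genes by id, making
results deterministic and permutation-invariant; k defaults to 8, one per
tissue column, since no k is published. "Highly and specifically expressed"
pairs are operationalized as combined (At+Dt) FPKM >= 5 in the focal tissue
and >= 2x every other tissue's combined FPKM; bias is
`log2((FPKM_At+1)/(FPKM_Dt+1))` with |ratio| >= 1 (two-fold) splitting
At-/Dt-biased from unbiased. All three knobs (floor, specificity factor,
bias threshold) are configurable and reported in output, because the
published "highly", "specifically" and "biased" are qualitative; published
percentages depend on the real data and those hidden thresholds. Matrices
are taken post-replicate-averaging. Group-summed profiles (e.g. totalling a
gene clade's members per tissue) are plain per-group FPKM sums and are
linear over partitions by construction.

## Synthetic data: what it emulates, and what it does not

The generator emits the exact on-disk formats the readers consume, each
object with exactly one truth record:

- **Coverage** is simulated directly as depth tracks, not reads — the
  classifier consumes coverage, and simulating reads would reintroduce the
  out-of-scope mapping stack. Subgenome divergence appears as
  clade-differential mappability: a progenitor's tracks cover its own
  subgenome's scaffolds at `depth_mean` (20x) and the other subgenome at a
  5% residual fraction and low depth; ungrouped-truth scaffolds are covered
  over only 20% of their bases in every clade; hybrids switch clade signal
  at a recorded junction. Depth noise per 1 kb bin is negative binomial
  (dispersion 10 by default; Poisson as the limit, or exact constant depth) —
  overdispersion is the realistic stress for the replicate t-test. The
  standard evaluation condition is 200 scaffolds of 30–80 kb, half At among
  grouped, 10% ungrouped, 3 A + 3 D + 1 AD datasets.
- **LTR pairs** start identical and evolve both copies for the true age
  under the exact K2P transition matrix (closed-form branch probabilities,
  so expected divergence is 2rT including multiple hits), ts:tv ratio 2,
  1 kb repeats, ages 1/2/3 Myr, 200 pairs per age.
- **Expression**: per-pair, per-tissue shared lognormal means with small
  per-gene lognormal noise (sigma 0.15 natural-log units); planted biased
  pairs (30% At, 20% Dt in the FE tissue) get a 4x effect on a
  well-expressed focal mean. Eight tissues mirror the panel shape.
- **Map and VCF**: 5 chromosomes x 200 markers at 1 kb spacing, shredded
  into 20 scaffolds each (~1 Mb total), 30% of scaffolds stored
  reverse-complemented; 2% of markers are mutated at 6 positions (below the
  196-base floor) and 2% get an exact second copy planted in a dead zone of
  another chromosome (dropped by uniqueness). Marker positions are nudged so
  segments never straddle a scaffold boundary. The VCF plants 1,000
  lineage-specific sites (half A, half D) and 1,000 shared sites at uniform
  depth 20.

Everything is deterministic under `rng_seed` (per-stage generators are
seeded as `[seed, stage-salt]`). What passing these tests does **not** show:
robustness to mapping artifacts, repeat-driven cross-mappability structure,
GC-dependent coverage bias, assembly gaps, indel divergence between LTR
copies or between map segments and scaffolds, genotyping error in the VCF,
or replicate-level expression noise — real data carry all of these, and the
thresholds above are the knobs to revisit when they bite.

## Problem sizes and numerical choices

The test suite and the acceptance script run the generator at the sizes
above (the package's standard evaluation conditions; everything completes in
well under a minute per stage on one CPU). Other numerical choices:
pseudocounts 0.01 (normalized depth) and 1.0 (FPKM); t statistics replaced
by (t=0, p=1) only when both clades are exactly constant and equal;
saturated K2P pairs excluded rather than clamped; k-means runs 10
initializations with a fixed `random_state` and relabels clusters by first
sorted member; permutation p-values use the add-one estimator; N50 of an
empty set is 0; the density scan suppresses flags when the window-count
distribution has zero spread.

## Known limitations

- Coverage-based assignment assumes progenitor reads were mapped
  competitively to the whole tetraploid assembly; tracks mapped per
  subgenome would violate the ratio criterion's premise.
- The hybrid scanner cannot see translocations shorter than
  `hybrid_min_segment` or within `hybrid_window` of a scaffold end.
- Anchoring tolerates no indels in segments and no map-order errors beyond
  `max_run_gap`; a genetic map with local order noise will fragment runs.
- K2P dating assumes a clock (`r` constant) and no gene conversion between
  LTR copies; conversion rejuvenates elements and biases ages downward.
- Lineage specificity is presence/absence only; allele dosage in the
  tetraploid is deliberately ignored.
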