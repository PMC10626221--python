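# Methods

This note documents the models, defaults, numerical choices and known
limitations behind each hemaseq component, in the package's own terms.

## Variable binning

Copy number from sparse coverage is estimated through bins constructed to
hold an equal *expected* number of uniquely mapped reads under a flat
diploid genome, so that observed read density per bin is directly
proportional to copy number. The expected-read surrogate is a per-window
(default 1 kbp) mappability weight track. Bins are apportioned to
chromosomes proportionally to total weight (largest-remainder rounding,
at least one bin per chromosome with positive weight); within a chromosome,
bin *k* closes at the first window where the cumulative weight reaches *k*
quanta, so boundaries snap to window edges, every bin's weight differs from
the quantum by less than one window's weight, and residual weight carries
into the next bin. This rule is deterministic and checkable against a
brute-force cumulative-sum search, which the tests do on small genomes.
The weight-ratio bound that follows is
`max/min ≤ (q + w_max)/(q − w_max)` with `q` the quantum and `w_max` the
largest window weight; for realistic `w_max ≪ q` the bins are equal-weight
to well under a percent. The default of 10,000 bins reflects the resolution
at which a human genome yields a median bin around 276 kbp; on synthetic
genomes bin size is whatever the weight track implies, and no particular
median is asserted. Per-bin GC is the window-length-weighted mean of window
GC. Reads are assigned to bins by start position (half-open intervals),
matching single-end density counting. Sex-chromosome or gap exclusion is
handled simply by not including such regions in the genome model.

## Synthetic data generator

The generator emulates the three data modalities the pipeline consumes; its
defaults are the study conditions under which the recovery experiments run.

* **Bin counts.** Expected count of bin *i* is proportional to
  `(CN_i / ploidy) · weight_i · max(0, b0 + b1·gc_i + b2·gc_i²)`,
  normalized to the requested total. Noise is negative binomial
  parameterized by mean and dispersion α (`var = μ + αμ²`), drawn as a
  gamma-mixed Poisson; α = 0 degenerates to exact Poisson. NB is the
  standard family for read counts; the dispersion appropriate to
  20–30-cell pools without pre-amplification is not established anywhere we
  know of, so α is a documented free knob with 0.02 used as the desk-scale
  recovery condition (bin-level CV ≈ 0.15 at 2,000 reads/bin, comfortably
  noisier than clean bulk WGS).
* **Locus reads.** Each read's true allele is alt with probability VAF;
  sequencing error flips the observed allele with probability `e`
  (ref ↔ alt, the worst case for presence calling). Base qualities are a
  clipped normal (mean 35, sd 4), so a `min_baseq` of 20 removes a small
  tail.
* **FISH tallies.** Cells are split multinomially into scoring classes
  (default 10% plasma cells / 90% non-PC, a marrow with a substantial PC
  clone), then into signal patterns multinomially within each class.

Every simulator takes one explicit seed and touches no global RNG state.
What the generator does **not** model: GC-dependent fragmentation
interactions, mappability artifacts near repeats, fixation damage,
amplification chimeras, or cell-to-cell heterogeneity within a pool.
Passing recovery tests therefore demonstrates correctness of the inference
chain under the stated noise family, not robustness to every artifact of
real slides.

## Copy-number calling

1. **GC normalization** divides counts by a lowess fit of count on GC
   (default span 0.3; a quadratic polynomial fit is the fallback method).
   Non-positive fitted values are replaced by the 1st percentile of the
   positive fits, guarding against division blow-ups without perturbing
   well-behaved fits; the result is rescaled to mean 1.
2. **Copy-number scale**: `cn_i = ploidy · density_i / median(density)`,
   the near-diploidy assumption that the median bin is at baseline ploidy.
   The transform is idempotent. It is wrong for genomes where more than
   half the bins are aberrant — a known limitation shared by any
   median-anchored scaler.
3. **Segmentation** is recursive binary splitting with the circular
   binary segmentation family's permutation calibration: at each segment
   the pooled two-sample t statistic is maximized over admissible
   breakpoints (both sides ≥ `min_width` = 3 bins), and the split is
   accepted iff its within-segment permutation p-value (default 1,000
   shuffles, seeded; early termination once significance is impossible)
   is below α = 0.01. Chromosomes are segmented independently. Maximizing
   over single breakpoints rather than two-ended arcs keeps the accepted
   breakpoint identical to the exhaustive max-t changepoint by
   construction — the property the oracle tests assert — at the cost of
   needing one extra recursion to resolve an interior event
   (gain-flanked-by-normal takes two splits instead of one); MergeLevels
   then re-unifies the flanks into one level.
4. **MergeLevels**: iteratively, the pair of distinct levels with the
   closest means is tested by the Wilcoxon rank-sum over their bins' CN
   ratios; if p exceeds the threshold (default 1e-4, the procedure's
   conventional default) they merge and means recompute, until no pair
   merges. Merging runs on CN ratios rather than log-ratios; at
   near-diploid amplitudes the two spaces order level pairs identically,
   and CN space keeps level means directly interpretable as copy numbers.
   Segment boundaries never change; only level ids coarsen, and the number
   of levels is non-increasing in the threshold.
5. **Integer calls** are round-half-even of the merged level mean
   (avoiding systematic upward bias at .5 ties), floored at 0.
6. **Aberration extraction**: a chromosome ≥ 90% of whose bins share one
   off-baseline integer CN is a whole-chromosome gain ("polysomy N") or
   loss ("monosomy N"); the same rule per p/q arm (given centromere
   positions) yields arm-level calls ("Nq deletion"); remaining
   off-baseline runs are focal. Without arm annotation only
   whole-chromosome and focal calls are made.

Desk-scale recovery conditions used throughout the tests: 500 bins over
five 20 Mbp chromosomes, 10⁶ reads, a linear GC gradient with a
multiplicative linear bias, dispersion 0.02, one whole-chromosome CN-3
gain and one arm-level CN-1 loss. Under these conditions the pipeline
recovers ≥ 95% of bins' integer CN and locates breakpoints within two bins.

## QC metrics

CV is the sample (n−1) standard deviation over the mean. MAPD operates on
mean-scaled adjacent differences `d_i = (x_{i+1} − x_i)/mean(x)` and is
reported in two non-equivalent readings: `Median(|d − Median(d)|)` (the
literal median absolute deviation of the steps; exactly zero for any
arithmetic progression) and `Median(|d_i|)` (the field-standard robust
noise measure). Both are always computed and reported; the MAD reading is
the default. A subtlety worth recording: on a strictly alternating series
of even length the steps are one more positive than negative, the median
step is the step itself, and the MAD reading is 0 while the standard
reading is |step|/mean; the two coincide only when the steps have zero
median (e.g. balanced up/down patterns). Both metrics are invariant under
positive rescaling of the input, and MAPD rises monotonically with
simulated overdispersion. Whether to feed raw counts, normalized densities
or CN ratios is left to the caller (`input_space` is echoed in the report);
counts are the default.

## Variant filtering

Annotation filters drop synonymous and non-coding variants and anything
with population MAF above 1% (missing MAF treated as 0 with a notice).
The somatic filter requires, per specimen, alt depth ≥ 10 **and**
VAF ≥ 5% **and** total depth ≥ 250. The rescue rule is read as: within one
case's serial specimens, a variant failing these thresholds somewhere is
retained everywhere if it **fully passes** them in at least one specimen.
This reading reproduces the retention of sub-threshold early timepoints of
a rising clone while keeping the filter meaningful; the permissive
alternative (any single threshold met qualifies a companion) is available
as `rescue_rule="any"`. Rescue never demotes a passing record, and the
filter is idempotent. Variant identity is genomic
(chrom, pos, ref, alt), never gene/HGVS text. VAFs are fractions
internally and one-decimal percentages in reports.

Read-level presence in pooled-cell libraries: after discarding bases below
`min_baseq` (default 20), a locus is *present* with ≥ `min_alt_reads`
(default 1) alt reads, *absent* with at least one surviving read otherwise,
and *uncallable* with none. At depth 30 and error rate 10⁻³, requiring two
alt reads bounds the false-presence rate below 10⁻³ (verified by
simulation).

Trajectory labels order specimens by days after diagnosis: *persisting*
(detected at the last timepoint, having been present at the first),
*emergent* (absent first, detected last), *cleared* (detected earlier,
absent last), *not detected*.

## Cytogenetics

The ISCN subset parsed is the one occurring in myeloid/plasma-cell clinical
reports of this kind: modal counts and ranges (hyphen or en-dash),
sex designations, ±N whole-chromosome events, `del(chr)(bands)`,
`?`-qualification, `xN` multipliers, `idem`/`sl` (first-clone) and `sdl`
(second-clone) stemline references, `slxN` doubling (aberration
multiplicities scale by N), `[n]` cell counts and `[cpN]` composites.
Unparseable tokens are preserved verbatim in an `unparsed` list with a
warning. Serialization expands stemline references, and round-trips
preserve resolved aberration multisets. Full ISCN 2016 (translocations,
derivatives, ring chromosomes, ...) is out of scope.

FISH percentages and non-PC:PC ratios are rounded half-up to one decimal,
matching clinical rendering in all but a few published cells where the
printed value disagrees with its own counts (the packaged fixtures flag
those as divergent; the package always computes the direct quotient).
Positivity is `percent ≥ cutoff` for the probe's cutoff at the scored-cell
bracket (100/200/300; nearest bracket with a notice otherwise). The
shipped cutoff table is reproduced as published, including one
probe whose printed cutoffs are not monotone in scored cells; the table is
treated as opaque clinical data and no monotonicity is enforced. Pattern
labels (e.g. a "tetrasomy" pattern reported under a polysomy heading) are
probe-specific opaque strings.

## Lineage inference

Characters are binary aberration groups; populations are rows. Under the
one-origin (infinite-sites) assumption a matrix is tree-compatible iff
character supports form a laminar family, which is checked pairwise
(nested-or-disjoint); all violating pairs are reported. Tree construction:
characters with identical supports merge onto one lexicographically ordered
multi-character edge; edges nest by strict support containment; each
population attaches below the deepest character it carries
(characterless populations sit at the root); sibling order is
lexicographic. For any compatible matrix the union of edge labels on a
population's root path equals its input row — the reconstruction property
the tests verify, including by full enumeration of all small matrices and
an independent per-row chain oracle (laminarity ⟺ every row's carried
supports form a containment chain).

Template mapping assigns each edge the deepest template compartment
ancestral to every cell type below it (LCA over leaf slots): a character
shared by plasma cells and myeloblasts lands at the LMPP split of the
classical scaffold; a character private to erythrocytes sits below MEP.
Mapping annotates, never rewires. The classical template encodes
HSC → MPP → {LMPP → {MLP, GMP}, CMP → MEP}; the composite template
removes CMP and branches MPP directly to MEP, the qualitative distinction
between the two models of hematopoiesis. Adding a population that carries
a character can only move that character's assignment rootward.

In the packaged worked-example matrix the granulocyte rows do not carry
character A; the source data leave this unresolved, and setting those
entries to 1 would keep the matrix laminar while moving group G's
placement rootward.

## Orchestration

`RunConfig` (pydantic, `extra="forbid"`) carries every stage parameter and
is echoed, with the package version, into every output file; identical
config + seed yields identical outputs. The CLI is a thin veneer:
subcommands simulate/bins/cna/qc/variants/fish/lineage/report call the same
library functions the examples use, log to stderr, and write results to
files only.

## Problem sizes

Default test and reproduction runs use 500-bin genomes, 10⁶ reads, 1,000
segmentation permutations, 10⁴-replicate presence simulations, and full
enumeration of character matrices up to 12 cells plus a seeded 6×6 random
sample — sizes chosen so the whole battery runs in well under a minute on
one core while keeping every statistical check adequately powered.
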