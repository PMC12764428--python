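# Methods

`mitolineage` implements clonal lineage tracing across tissues from somatic
mitochondrial variants, together with a permutation-based spatial
neighborhood analysis. This note describes the models, the statistics, the
synthetic data generator the package is validated on, and the design
decisions taken where the problem left genuine freedom.

## Tracing model

Somatic mitochondrial mutations accumulate per clone and are transmitted to
a cell's descendants, so a heteroplasmic variant acts as an endogenous
clonal barcode. A cell observed in the synovium that carries the variant
set of a skin-resident clone is evidence of skin-to-joint migration. The
pipeline has four stages.

**Informative variant selection.** Input is a sparse per-cell allele-count
tensor `(cell, position, base) -> count` over the 16,569 bp circular
mitochondrial reference (1-based positions, VCF convention). Per donor, a
candidate variant (any observed non-reference allele) is *detected* in a
cell when coverage ≥ `min_coverage` (default 5), alt reads ≥
`min_alt_reads` (2) and VAF = alt/coverage ≥ `min_vaf` (0.05); it is
retained when detected in ≥ `min_cells_detected` cells (3), its position is
not blacklisted (3107, the rCRS spacer), and it passes two specificity
caps: detected fraction ≤ `max_detected_fraction` (0.5) and mean VAF ≤
`max_mean_vaf` (0.35). The caps remove inherited haplogroup variants,
which sit near-homoplasmically (VAF ≈ 1) in essentially all cells of a
donor. All comparisons are inclusive; variants are never pooled across
donors. Defaults are declared, conservative values in line with common
single-cell mtDNA genotyping practice; every one of them is sweep-able.

*Numerical design choice.* The two specificity statistics are computed over
all cells with coverage ≥ 1 (detection there meaning ≥ 1 alt read), i.e.
they are properties of the data rather than of the threshold configuration.
If they were recomputed against the configurable evaluability floor,
raising `min_coverage` could lower the detected fraction below its cap and
re-admit a variant — the informative-set size would no longer be monotone
under threshold tightening, which the robustness sweep and its
interpretation rely on. With the fixed floor, monotonicity is provable:
the detection filters only shrink the detected set as thresholds rise, and
the caps act on fixed statistics.

**Sharing statistics.** A cluster *carries* a variant when ≥
`min_cells_per_side` (default 2) of its cells detect it. For each synovial
cluster the shared set is its carried set intersected with the union of
carried sets of lineage-matched skin clusters of the same donor
(lineage-matching can be disabled). The sharing proportion divides the
shared count by the cluster's carried count (default) or by the donor's
informative total (`denominator="donor_informative"`). Cluster enrichment
is tested one-versus-rest: each cluster's per-donor proportions against the
pooled values of all other clusters, with a two-sided Wilcoxon rank-sum
test and Benjamini–Hochberg correction across the family of clusters. The
statistical unit is the per-donor per-cluster value; no mixed-effects
modeling of donor structure is attempted (see *Calibration* below for the
consequence).

**Wilcoxon rank-sum.** The exact branch enumerates the permutation
distribution of the rank sum over midranks (ties included) by dynamic
programming on doubled midranks; the two-sided p counts rank sums at least
as far from the null mean as observed, which reduces to the classical
doubled tail when there are no ties. `mode="auto"` uses the exact branch
for n ≤ 12 and the normal approximation (tie and continuity corrected, via
`scipy.stats.mannwhitneyu`) above; `one_vs_rest_test` explicitly requests
the exact branch up to n = 24 because at the family sizes typical here
(3 donors × ~5 clusters) the normal approximation is measurably
anti-conservative. Identical samples return p = 1.

**Lineage graph and precursor ranking.** Synovial clusters are nodes; the
edge weight between two clusters is the number of informative variants
carried by both. In `exclude_skin` mode only variants carried by no skin
cluster enter the scoring sets, isolating within-joint sharing. The
precursor score of a cluster is the number of its (mode-filtered) variants
shared with at least one other synovial cluster, plus its skin-shared count
in `include_skin` mode. Ties are broken by containment fraction (the share
of all between-cluster shared variants the cluster carries), then by total
detecting-cell support, then lexicographically; tied clusters share the
best rank so that downstream tallies can count them fractionally.
Rankings are computed per donor and combined into a consensus by median
rank. The exact construction used by the original analysis is not public;
this scoring is a declared instantiation that uses only shared-variant
extents, supports the include/exclude-skin contrast, and is validated by
ground-truth recovery. Variants enter binarily; cell-support weighting is
available through the recorded support values.

**Robustness sweep.** Filtering → sharing → ranking is re-run over a grid
of filter thresholds (defaults: `min_coverage` {3, 5, 10}, `min_vaf`
{0.03, 0.05, 0.10}, `min_cells_detected` {2, 3, 5},
`max_detected_fraction` {0.3, 0.5, 0.7}; full cartesian product or a
seeded subsample). Iterations with an empty informative set are recorded
as degenerate and excluded from denominators. Summaries report, per
cluster, the fraction of iterations ranked first (ties counted 1/k), per
lineage the fraction with maximal skin-sharing, and per threshold the
fraction of rank-1 flips when that field varies with the others fixed.
Every iteration stores its full configuration and replays bit-identically.

## Spatial neighborhood analysis

Marker intensities, when present, are transformed elementwise by
asinh(x / cofactor) with cofactor 1 and z-scored per marker against the
entire dataset; constant markers get z = 0 with a warning. Neighbors are
cells whose centroids lie within 40 µm (inclusive, exact KD-tree radius
query) — "centroid extension" is read as centroid-to-centroid Euclidean
distance, the simplest consistent interpretation, and the radius is
configurable. For an ordered pair (A, B) the statistic is the mean number
of B neighbors per A cell; its null is generated by uniformly reshuffling
all labels of the sample (graph fixed, permutations never cross samples,
1,000 permutations by default). The two-sided p is
`(1 + #{|s_perm − μ| ≥ |s_obs − μ|}) / (n_perm + 1)`, with attraction
(avoidance) declared when p < 0.05 and the observed statistic lies above
(below) μ. The centring μ is the *closed-form* expectation under label
reshuffling — `2E·n_B/(n(n−1))` per source cell, with the within-type
analogue for A = B — rather than the Monte-Carlo mean of the permuted
statistics: with a Monte-Carlo centre, boundary membership of the discrete
null values flips with the centre's estimation error and the empirical p
fails to converge to the enumerated p. Ordered pairs are computed
separately (the statistic is not symmetrized). Interacting proportions
(fraction of source cells with ≥ 1 target neighbor) and nearest-neighbor
distances complete the per-sample report; cross-sample summaries report the
fraction of samples significant and per-sample classifications without
averaging mixed directions.

## The synthetic generator

The generator supplies ground-truthed inputs for every stage. Per donor it
emulates:

- **Germline haplogroup variants** (10 per donor) at true heteroplasmy
  0.98 in every cell — deliberately below 1 so the specificity caps, not an
  exact-1 shortcut, must remove them.
- **Clone pools** with rooted clone trees (depth 3): a child clone inherits
  its parent's variants plus `somatic_variants_per_clone` (3) of its own,
  with heteroplasmy drawn from Beta(2, 8) (right-skewed, low heteroplasmy —
  typical of somatic mtDNA variants; no distribution is published, so this
  is a declared stand-in). The migrating skin-myeloid pool holds
  `n_clones` = 8 expanded clones; resident pools are twice as polyclonal
  (`resident_polyclonality` = 2), reflecting that informative clonal
  barcodes come from expanded migrating clones while resident compartments
  are polyclonal.
- **Migration**: the synovial landing cluster receives
  `migration_fraction` (0.5) of its cells as migrants carrying skin
  precursor clones verbatim. Differentiated downstream clusters draw their
  migrant clones from the landing population through a clonal bottleneck
  (`bottleneck_fraction` = 0.5) and express them at attenuated
  heteroplasmy (`differentiation_retention` = 0.6): proliferation during
  differentiation lets heteroplasmy drift downward (vegetative
  segregation), which is why the landing precursors show the strongest
  conserved-variant signal. Migration is modeled as clone copying, not
  ongoing exchange — sufficient for the sharing statistic.
- **An independent-origin control**: S100A12+ monocytes draw from a
  cluster-private clone pool (blood-infiltrating cells share no clones with
  either tissue pool), mirroring their role as the negative control
  population.
- **Observation noise**: per cell-position depth ~ negative binomial
  (mean 20, dispersion 2; variance = mean + mean²/dispersion), read bases
  drawn multinomially from the cell's true allele mixture with a uniform
  base-error channel (`base_error_rate` = 0.002). Coverage always equals
  the sum of the four base counts. The reference genome is abstract:
  positions with uniformly assigned reference bases, consistent across
  donors; no sequence content is needed downstream.

The default scenario has 3 donors (matching the study's N = 3), skin
(precursors, T cells) and synovium (precursors, lining macrophages, HMOX1+
macrophages, S100A12+ monocytes, T cells), 60–80 cells per cluster. Under
these conditions the per-donor median shared-variant count lands around
10–15 — the magnitude the method is meant to operate at.

**What the generator does not emulate:** read-level artifacts (no FASTQ,
alignment or library chemistry), strand information (hence no
strand-concordance filter — the count tensor has no strands), doublets,
contamination, RNA-editing hotspots beyond the 3107 blacklist, donor-level
clinical covariates, and cell-type-specific coverage biases. Passing tests
therefore show the statistics and bookkeeping are correct and the signal is
recoverable under honest noise; they do not certify performance on real
libraries, where error structure is richer.

## Calibration design

The one-vs-rest rank-sum test pools per-donor per-cluster values. Its
exchangeability null holds exactly when each value comes from an
independent donor; the calibration experiment therefore simulates null
datasets (uniform, non-nested migration into equally sized, exchangeable
myeloid clusters; no retention gradient) and assembles each tested value
vector so that every cluster's values come from a different dataset. In
that regime the rejection rate sits at the nominal level (≈ 0.05, up to
the discreteness of the exact test). Two companion numbers are always
reported: the *donor-blocked* rate, where one dataset's three donors each
contribute a value to every cluster — positive within-donor correlation
(≈ 0.26 here) makes the pooled test conservative (≈ 0.03), never
anti-conservative — and the *no-migration* rate, where sharing values are
almost surely all zero, every p is 1 by the identical-samples contract and
the test never rejects. The spatial interaction test has no such block
structure and is calibrated directly on fully random point patterns.

## Problem sizes

Replicated experiments use 200 replicates for precursor recovery and
power, 500 for each calibration, 100 for monotonicity and spatial power,
and the 81-point default grid for the sweep; the acceptance script runs
the same sizes. These are the package's declared validation sizes; all
are parameters.

## Known limitations

- The precursor score is one declared member of a family of plausible
  graph scores; the module accepts any carriage map, so alternative scores
  can be ranked against the same ground truth.
- Sharing proportions are cluster-level; cells contribute only through
  carriage, so very small clusters (< `min_cells_per_side` detecting
  cells) drop out silently.
- The exact rank-sum branch is limited to n ≤ 30 (enumeration by DP);
  beyond that the tie-corrected normal approximation is used.
- With 3 donors the enrichment test's granularity is coarse
  (C(15,3) = 455 attainable configurations); single-donor datasets cannot
  be tested at all.
- The spatial null reshuffles labels uniformly; it conditions on the
  composition and geometry of the sample but not on local density
  gradients, so strong density confounds can masquerade as interactions —
  as in any label-permutation neighborhood test.
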