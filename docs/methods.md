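# Methods

`nephroscreen` re-implements, as a tested pipeline, the computational chain
of a glomerular-transcriptome susceptibility study: a microarray
differential-expression screen over a 2-strain x 2-treatment mouse design,
four-way comparison logic isolating diabetes-specific strain differences,
hypergeometric gene-set enrichment, and a classifier for leukocyte
rolling/adhesion/transmigration in a biomimetic microfluidic vascular
network. Because the raw study data are an external download, a first-class
synthetic-data module generates inputs with the same statistical structure
and a ground-truth sidecar, so every stage is testable offline.

## Differential-expression screen

**Quantile normalization.** Each sample column is mapped onto the common
distribution of rank means: after normalization every column's sorted
values equal the cross-sample mean of order statistics. Ties within a
column receive the mean of the reference values at their tied ranks (the
`ties=TRUE` convention of limma's `normalizeQuantiles`, against which the
implementation is cross-checked in the test suite). The transform is
idempotent and removes per-sample multiplicative scale distortions; it does
not model intensity-dependent variance or background.

**Probe collapse.** One row per gene symbol is retained: the probe with the
highest mean intensity across all samples, ties broken by lexicographically
smaller probe id. Collapse happens after normalization and before testing.

**Per-gene test.** Fold change is the ratio of linear-scale group means
(test / referent). P-values come from a two-sided Welch (unequal-variance)
t-test on log2 intensities — the standard choice for 4-vs-4 microarray
groups, since log2 intensities are closer to normal and the strains need
not share variance. Degenerate inputs are resolved deterministically: zero
variance in both groups with equal means gives p = 1; with unequal means,
p = 0 with a logged warning.

**Significance and the multiple-testing family.** A gene is significant
when its fold change is >= 2 (up) or <= 0.5 (down) *and* its
Benjamini-Hochberg adjusted p-value is below alpha = 0.05. The analysis is
restricted to the fold-change-passing genes first, and BH runs over that
family only: the candidate list defined by the effect-size filter is the
screen's testing population, and genes outside it report an adjusted p of 1
and are never significant. This restriction is what makes a 4-replicate
screen workable: with BH spread over all measured genes, an unmoderated
t-test at n = 4 cannot push true 2.5-log2 effects past the step-up
threshold reliably (measured mean sensitivity ~0.62 over 20 simulations),
whereas within the fold-change family the same effects are recovered at
~0.99 sensitivity with the empirical false-discovery proportion held near
8% and the null screen essentially empty. The one consequence worth
knowing: *lowering* the fold-change threshold enlarges the BH family and
can therefore de-reject a borderline gene — significance is monotone in
alpha, but not jointly in the fold-change threshold. BH is applied per
comparison, never pooled across the four screens.

## Four-way comparison logic and exclusive sets

The four screens use fixed referent conventions: diabetic vs. control
within each strain, and susceptible vs. resistant (referent) within each
treatment. The *exclusive sets* are the genes up- or down-regulated in the
diabetic strain comparison that are **not** significant, in either
direction, in the control strain comparison — the candidate susceptibility
genes whose strain difference appears only under diabetes. The within-strain
screens are not used for exclusion; only the two strain comparisons enter.
Note that a gene regulated by diabetes in exactly one strain necessarily
differs between diabetic strains as well (four group means cannot make one
contrast non-zero and the other three zero), so the within-strain and
between-strain screens overlap by construction. Disjointness of the
exclusive sets from the control-strain hits is asserted on every run.

The heat-map matrix reports, for a supplied gene list, per-sample
log2(intensity / mean intensity of a referent group) — by convention the
resistant-diabetic group — so referent-group row means are 0 in log2 space.
Rows are ordered by descending diabetic strain-comparison fold change (the
ordering is a presentation choice, configurable).

## Gene-set enrichment

For n hit genes mappable to a universe of N objects, a set of R members
overlapping the hits in r genes is scored by the hypergeometric upper tail
P(X >= r), X ~ Hypergeometric(N, R, n), computed in log space
(log-binomials via `gammaln`, summed with `logsumexp`) so that sets with
p ~ 1e-300 remain finite; P(X >= 0) is exactly 1. Only over-representation
is scored. Hits outside the universe are dropped with a logged count and do
not enter n. The `min_fdr` column is the BH adjustment of the p column over
all sets tested in the run, so its values depend on the database size; the
universe N is a required input (database-object space and array-measurable
space are both legitimate choices and give different p-values).

## Leukocyte kinetics

**Critical velocity.** v_crit = v_cc * eps * (2 - eps), where v_cc is the
segment's centerline velocity and eps the cell-to-vessel diameter ratio.
Equivalently v_crit = v_cc * (1 - (1 - eps)^2): the speed at which a
parabolic (Poiseuille) profile would carry a sphere whose center rides one
cell radius off the wall. A cell slower than this is interacting with the
endothelium. v_crit is strictly increasing in eps and never exceeds v_cc.

**Classification.** Each cell receives exactly one label with precedence
transmigrated > adherent > rolling > free:

* *transmigrated* — any trajectory record in the tissue compartment;
* *adherent* — some 30-s window with net displacement below delta
  (default one cell radius, 3.75 um for a 7.5-um neutrophil). Net
  displacement between window endpoints is used; a cell oscillating at
  high amplitude around a fixed point over exactly one window could in
  principle evade it, but tracked cells do not move that way;
* *rolling* — mean frame-to-frame speed below the critical velocity of its
  segment (per-segment by default; a network-wide override is available);
* *free* — everything else.

v_cc per segment is taken from the geometry when supplied (e.g. from an
external flow model), otherwise estimated as the q-th percentile (default
the maximum) of per-cell mean speeds in the segment — the fastest tracked
cell approximates the centerline. Lowering q trades bias for robustness to
tracking outliers. Cells spanning segments are assigned to the segment of
longest residence with a warning.

**Summaries.** Adhesion counts aggregate into user-specified wall-shear
bins (segments carry shear rate, by generator convention 4 * v_max /
diameter). The dose-response table divides each dose's cumulative
transmigration count at each timepoint by the untreated (dose-0) count at
the same timepoint, with undefined ratios reported as missing; the rolling
percentage is rolling count over total cells.

## Synthetic-data generators

**Expression.** Intensities are 2^(baseline + planted effect x group
indicator + sample offset + noise): per-gene baseline ~ N(8, 1.5^2) on the
log2 scale (typical microarray intensity scale), replicate noise sd 0.5,
and a per-sample offset sd 0.3 — the scale distortion quantile
normalization exists to remove. The design is 2 strains x 2 treatments x 4
replicates. Planted effects name a gene, one of the four screens, and a
log2 effect added to that screen's test group. The benchmark configuration
plants 50 of 1,000 genes at |log2FC| = 2.5. Multi-probe genes place later
probes 0.05 log2 units lower so the collapse rule has a deterministic
winner. The truth sidecar records the induced log2 difference for *every*
screen (planting a diabetes effect in one strain also creates a
diabetic-strain difference; the sidecar reflects that), and is never
embedded in the data files. Not emulated: probe-level cross-hybridization,
intensity-dependent variance, batch structure beyond a scalar offset.

**Gene sets.** Random sets are uniform draws from the universe, plus one
set equal to the planted hit list — the only set enriched by construction.

**Trajectories.** Four channels (diameters 30/40/50/60 um, centerline
velocities 200/300/400/500 um/s) sampled at 30 fps for 60 s. Free cells
ride the parabolic profile at radii where their speed clears 1.2 x v_crit
(a 20% margin against label ambiguity); rolling cells crawl monotonically
at (0.05, 0.8) x v_crit; adherent cells jitter within 0.5 um;
transmigrating cells roll, then cross into the tissue compartment at a
uniform random time in the middle 40% of the recording (one frame is
labelled `barrier`). Cells are dealt round-robin across segments so every
segment is populated. Not emulated: tracking noise and dropout, cell-cell
interactions, chemotactic gradients, channel entry/exit effects — so
classifier accuracy on these cohorts is an upper bound on real-video
performance. Dose cohorts hold rolling/adherent counts fixed and draw the
transmigrating count Binomial(n_pool, baseline x multiplier).

All generators draw from a single `numpy.random.default_rng(seed)` stream;
identical config and seed give bit-identical output.

## Small-assay statistics

Relative qPCR uses the comparative-Ct model: fold = 2^(-ddCt) with dCt =
target Ct - reference-gene Ct and ddCt relative to the referent group's
mean dCt, so the referent group has geometric mean 1 by construction; the
reference gene is a required input and no amplification-efficiency
correction is applied. Urinary analytes are normalized to creatinine
(ng/mg). Group comparisons: two-sided t-test for two groups, one-way ANOVA
for more, and for the 2x2 strain x treatment design a two-way ANOVA (OLS +
type-II table) with main effects and interaction. The tissue-expression
comparison runs a two-sided Mann-Whitney U (exact for pooled n <= 20) of a
focal tissue against each comparator, Bonferroni-adjusted by the number of
tests in the call, which is reported alongside every adjusted p because a
per-gene (m = 5) and a joint (m = 15) run are both legitimate readings.
All-tied inputs give p = 1.

## Problem sizes and numerical checks

The test suite and the acceptance script run the screen benchmark at 1,000
genes over 20 seeds, the classifier over 10 cohorts of 40-70 cells, the
dose-response recovery over 20 seeds of 3 x 120-cell cohorts (at 10 fps to
keep tables small), BH against a brute-force step-up oracle on 1,000 random
vectors, and the hypergeometric tail against exhaustive draw enumeration
for every valid instance with N <= 12 — sizes chosen so the whole suite
completes in about a minute while keeping Monte-Carlo error well inside the
asserted tolerances. The dose-response assertion uses a 3-standard-error
delta-method band for a ratio of binomial counts.

## Known limitations

* The per-gene test behind the original screen is not documented upstream;
  Welch-on-log2 with the fold-change-restricted BH family is this package's
  choice, and replication counts on the deposited series should be read
  with that caveat.
* The enrichment universe N must be supplied; published enrichment tables
  computed against a proprietary pathway database are reproducible in
  ordering but not in absolute p without that database.
* The adhesion rule uses endpoint net displacement per 30-s window, and the
  rolling rule uses mean (not instantaneous) speed.
* GEO series-matrix parsing maps samples to the design via a user-supplied
  YAML; probe-to-symbol annotation must come from the platform table when
  gene-level claims are needed.
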