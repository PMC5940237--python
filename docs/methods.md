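# Methods

## Percentile normalization

For each study and each feature, control abundances are converted to
percentiles of themselves and case abundances to percentiles of the same
control distribution, using the mean-of-strict-and-weak counting
convention: perc(x) = 100·(#{c < x} + #{c ≤ x}) / (2n). With n controls
and continuous values, control self-percentiles are exactly the grid
{100(k−½)/n}; a case value falling between control order statistics k and
k+1 maps to 100k/n. Percentiles are kept as reals in [0, 100] and never
rounded. The transform is invariant under any strictly increasing map
applied jointly to a feature's case and control values, so downstream
rank-based tests see only order information.

**Zero replacement.** Microbiome relative-abundance tables are
zero-inflated; tied zeros would pile up at a single midrank. Before
ranking, every zero is replaced by an independent draw from
Uniform(0, u] with u = 10⁻⁹ by default — chosen to sit below 1/depth for
any realistic sequencing depth, so replacement can never reorder a true
nonzero against a replaced zero. Draws come from one seeded stream per
table; the seed is a required parameter and is recorded in output
headers, because re-running with a different draw can move features near
the significance threshold across it. Case and control zeros are replaced
under the same policy, within each study, before any percentile
computation.

**Pooling.** Normalized studies are concatenated over the union of their
features. A feature never observed in a study carries no rank information
there, so by default its samples from that study are marked missing and
dropped pairwise by the tests; an `absent_as_zero` switch instead treats
absence as zero abundance (percentile of a zero), for users who consider
absence informative.

## Comparator corrections

Both model-based comparators operate on natural-log abundances after
replacing zeros with half the smallest positive value of the whole matrix
(applied to zeros only, not added everywhere), and are inverted by a
plain exponential without per-sample re-normalization. The log base is a
convention; rank-based tests downstream are unaffected by it.

*Empirical-Bayes location/scale adjustment* (the ComBat model): per
feature, batch means are fit by least squares, residuals standardized by
the pooled variance; per batch, feature-wise additive effects shrink
toward a normal prior and multiplicative effects toward an inverse-gamma
prior, with method-of-moments hyperparameters and the standard
fixed-point iteration (relative-change tolerance 10⁻⁶, max 500
iterations); shrunken effects are then subtracted/divided out and the
grand mean and scale restored. No biological covariates enter the design
(whole-dataset usage with batch only). Features with zero pooled variance
pass through unadjusted with a warning. The implementation agrees with
`sva::ComBat` elementwise to ≤10⁻³ on a shared fixture (the residual gap
comes from the tighter convergence tolerance); the test suite runs that
cross-check through `Rscript`. Two consequences worth knowing: scale
shrinkage perturbs values even when batches are identical (≈2% of the
data sd at 100 samples/batch), and pooled per-feature means shift
slightly (≈10⁻³ relative to unit sd) — the reference implementation
behaves the same way, so tests assert approximate rather than exact
preservation.

*Linear batch subtraction* (the limma model): per-feature OLS on batch
indicators with sum-to-zero contrasts; the fitted batch component is
subtracted and the intercept kept, leaving every batch with the same
per-feature mean (the unweighted mean of batch means) to 10⁻¹⁰. The
operation is idempotent and matches `limma::removeBatchEffect` to
machine precision.

## Differential testing and meta-analysis

Features enter a test only if they are present (abundance > 0, evaluated
*before* zero replacement) in at least one third of cases or one third of
controls — the filter trims the multiple-testing burden and is scoped to
the comparison being run (within-study groups for within-study tests,
pooled groups for pooled tests). Per feature, the two-sample Wilcoxon
rank-sum z uses midranks with no tie or continuity correction and a
two-sided normal p; BH step-up q-values control the FDR. Cross-study
combination uses Fisher's method (−2Σln p on χ² with 2k df) or Stouffer's
with weights √(n_case + n_control) per study, computed from the two-sided
p-values without sign restoration; as a guard against combining
contradictory evidence, features significant (within-study q ≤ 0.05) in
opposite directions in two or more studies are excluded first. The
threshold and measure of that screen are configurable (`q`, `p`, or any
sign conflict) because "significant responses in opposing directions" is
a convention, not a theorem. Community-level batch structure is measured
by Bray-Curtis dissimilarity and one-way PERMANOVA (pseudo-F from squared
distances, permutation p with a mandatory seed, R² = SS_among/SS_total;
999 permutations by default).

## Synthetic data

The generator draws feature abundances as exp(N(μ, σ)) per group. Batch
effects are study-wide shifts of (μ, σ) shared across features; disease
effects are feature-specific μ shifts applied to a configurable fraction
of features in both studies; zero inflation then zeroes each cell
independently with fixed probability (0.3 by default, a typical sparsity
for genus-level tables). The two-study defaults use the illustration
parameters μ = 0.1, σ = 0.7 (study A) against μ = 1.5, σ = 0.2 (study B)
— a location shift of 1.4 with a 0.3 σ ratio, a deliberately severe batch
difference — with 500 controls per study and case groups of 30 and 100.

Two deliberate choices behind those sizes. First, the case:control ratio
differs between the studies: when both studies contribute cases and
controls in the same proportion, a pooled group contrast weights the two
batches equally and the batch effect largely cancels — raw pooling then
looks spuriously safe. Unequal composition is both realistic and the
regime where raw pooling fails. Second, the control pools are large
relative to the case groups. All case percentiles of a study share that
study's control reference, so its sampling noise (variance ∝ 1/n_control
of the per-feature case-group mean) is common to the whole case block;
the pooled rank-sum variance formula does not account for this
clustering, and with small control pools plus strongly asymmetric
composition the pooled null test runs mildly hot (z sd up to ~1.2 at 71
controls vs 120 cases). With sizeable control pools the effect vanishes —
which is also the method's stated applicability condition: the control
distribution's density limits the resolution of the percentile transform.

What the generator does **not** emulate: compositional coupling between
features (each feature is drawn independently; real relative abundances
are constrained to a simplex), phylogenetic correlation, sequencing-depth
variation, and batch effects that hit only a subset of taxa. Passing
tests therefore show that the machinery behaves correctly under the
stated lognormal model, not that any particular real dataset is free of
artifacts.

## In-silico experiments

Treatments are applied to the full study pools once — percentile
normalization converts each study against its own complete control pool,
the model-based corrections fit the combined table with batch = source
study, raw data gets only zero replacement — and the experiments then
subsample treated columns. (Self-normalizing each drawn 40-sample subset
would be degenerate: both groups become identical uniform grids and every
z collapses to 0.) The *titration* experiment draws 40 cases and a
40-sample control group containing round(f·40) foreign controls per
iteration and fraction f ∈ {0, 0.2, …, 1}, filters on the pre-treatment
values of the drawn samples, and counts q ≤ 0.05 features; the *null
false-positive* experiment draws 40 + 40 cross-study control groups and
records the fraction of p ≤ 0.05. Both default to 20 iterations, sample
without replacement within an iteration, and are deterministic given
(seed, config). A `percentile_mode="after_mixing"` option demonstrates
misuse — normalizing cases against the already-mixed control group
reintroduces batch structure.

The meta-analysis pipeline reports, at q ≤ 0.05, the pooled significant
count alongside the union, intersection, and significant-in-≥2-studies
count of the within-study results, for any of the five treatments
(percentile pooling, Fisher, Stouffer, EB adjustment, linear removal).

## Numerical and scale choices

`scripts/acceptance.py` and the end-to-end tests use 2000-feature
two-study pairs, 40-sample groups with 20 iterations for the experiments,
and 500 null datasets × 199 permutations for the PERMANOVA calibration —
sizes at which every Monte-Carlo check has comfortable margin while the
whole suite stays interactive (tens of seconds). Percentile grids are
compared exactly; batch-mean equalization to 10⁻¹⁰; EB convergence to
10⁻⁶. Ties in ranks use midranks throughout; the rank-sum p deliberately
omits the tie correction to match the stated convention of the original
analyses (an exact-oracle comparison in the tests covers small samples).
Text output uses 17-significant-digit floats so written tables round-trip
bit-exactly.
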