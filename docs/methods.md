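# Methods

## Study design and models

The package analyses a paired design: each person contributes one tumor and
one matched normal methylation-array sample, and each person is either
microsatellite-unstable (MSI) or stable (MSS). The response at each CpG
locus is the beta value β = X/(X+Y) ∈ [0, 1], the methylated fraction of
probe intensity (no offset is added to the denominator by default; the
common stabilising constant can be passed explicitly).

Three per-locus models are fitted:

1. **Paired model** `Y = μ + Tumor + Person + ε`, Person a random
   intercept. This is the two-way layout without replication (one
   observation per tumor-state × person cell). The tumor effect estimate is
   the mean within-person tumor-minus-normal difference (Δβ); its F
   statistic on (1, n−1) df equals the squared paired-t statistic, an
   identity the tests verify to 1e-8 relative. The person variance
   component is estimated by the method of moments from the expected mean
   squares, `σ̂²_person = (MS_person − MS_error)/2`, truncated at zero (the
   pre-truncation value is kept as a diagnostic).
2. **Interaction model** `Y = μ + Tumor + MSI + Tumor×MSI + ε`, all fixed,
   fitted by least squares with sum-to-zero (effect) coding. Tests are
   Type III (marginal) sums of squares: for a single-df effect-coded
   column, SS = β̂²/[(X′X)⁻¹]ⱼⱼ, which equals the full-vs-reduced model
   comparison. In balanced designs Type I and Type III coincide.
3. **Location model** adds `Location + Tumor×Location`, giving the
   Tumor×MSI test adjusted for tumor side. Factors with one observed level
   are dropped (terms flagged `inestimable`); genuinely collinear designs
   (e.g. MSI coinciding with side) are flagged `collinear_design`.

### The person term and interaction-test calibration

The interaction and location models are written without a Person term, and
the DML pipeline uses that form by default. When person random intercepts
are present — and in this kind of data they dominate, with the person term
carrying over 60% of the paired-model sum of squares — the person-free
interaction F-test is *conservative*: the interaction contrast is a
difference of within-person differences, whose variance contains only the
residual σ²_e, while the model's MSE estimates σ²_p + σ²_e. Our null
simulations show a rejection rate near 2.5% at nominal 5%, and a unit test
asserts the rate stays at or below nominal.

For a correctly calibrated test under person heterogeneity the engine
offers `include_person=True`, a split-plot analysis stratifying by person:
within-person differences dᵢ = yᵢ,tumor − yᵢ,normal carry the Tumor,
Tumor×MSI and Tumor×Location tests (the Tumor×MSI F is then exactly the
squared two-sample t comparing dᵢ between MSI and MSS persons), and person
means carry the MSI and Location tests. The calibration acceptance test
uses this variant; the person-free default is kept for the DML pipeline
because it is the form the models above state.

p-values of exactly zero are floored at the smallest positive double when
a degenerate (zero-MSE) fit forces them, and such loci are flagged.

## DML calling and classification

A stratum DML passes both a Benjamini–Hochberg FDR threshold (default
q ≤ 0.001, computed per stratum across all scanned loci, NaNs propagated)
and a magnitude filter |Δβ| ≥ 0.2 on the stratum's paired mean difference;
direction is hyper (Δβ > 0) or hypo. The magnitude default resolves an
internal inconsistency in how such thresholds are sometimes printed
(0.02 vs 20%): we use 0.2, i.e. twenty percentage points of methylation,
and it is configurable. Interaction membership uses BH FDR ≤ 0.05 on the
Tumor×MSI p-value with *no* magnitude filter. The membership triple
(MSI-DML, MSS-DML, interaction) maps each locus to exactly one category:
A = both strata, no interaction; B = MSI-only with interaction; C = both
strata with interaction; D = MSS-only with interaction; none otherwise.

The promoter-island filter restricts to loci annotated Island *and*
promoter-associated, applies a Bonferroni threshold α/m with m the size of
that restricted universe, and reports surviving loci with gene symbols and
direction taken from the all-pairs Δβ.

Region tabulation reports hypo/hyper/total counts per CpG-island relation
band, percentages of the DML set and of the chip (half-up rounding to
2 dp); row conservation (hypo + hyper = total) is asserted in tests.

## Enrichment

Per category, a 2×2 Pearson chi-square (no continuity correction) compares
the category's share of significant genes with its share of the chip
universe; score = −log10 p. The background includes the significant genes
by default (a documented toggle excludes them). A gene is significant if
at least one of its loci is in the relevant DML list. Degenerate tables
(empty category, category spanning the chip, zero margins) are flagged with
score 0 rather than dropped.

## Cohort and expression statistics

Cohort proportions are reported at full precision with half-up integer
display rounding. Association tests: uncorrected Pearson chi-square
(default), Yates-corrected chi-square and Fisher's exact test (both 2×2
only) — all three are exposed because published cohort tables are often a
mixture. Age uses one-way ANOVA (two groups: F = pooled-t²).

Expression analysis assumes log2-scale input. Fold changes are
2^(mean paired log2 difference) with a t-based 95% CI on the log2
differences, reported with the signed convention fold = r if r ≥ 1 else
−1/r (applied to CI bounds, which the monotone transform preserves). The
CI method is a design choice; coverage is verified by simulation
(±3 points at n = 30 pairs). Gene-set average folds pool the per-probe,
per-pair log2 differences with equal weight; the pooled t-interval ignores
within-person correlation across probes, a known simplification. The
expression interaction scan reuses the interaction model on log2 values
and flags probes at unadjusted p < 0.05.

## Synthetic-data generator

The generator emulates the study conditions the analysis assumes, not raw
array chemistry (no IDAT, probe-type or batch structure):

* **Cohort**: 125 persons, 30 MSI by default; right-sided tumor probability
  13/30 given MSI and 11/95 given MSS; male fraction 72/125; age ~
  N(46, 14²) clipped to [20, 85]; stage probabilities 25/33/67 out of 125.
  Each person contributes one tumor and one normal sample.
* **Betas** are generated on the logit scale:
  `y = expit(logit(b) + tumor·shift(group) + b_person + ε)` with
  `b_person ~ N(0, σ²_p)` shared within person and `ε ~ N(0, σ²_e)` per
  sample. The group shift is `logit(b + δ) − logit(b)`, so at zero noise
  the realised beta-scale tumor−normal difference equals the planted δ
  exactly (≤1e-9, asserted); deltas are specified on the beta scale
  because the magnitude filter operates there. Values are strictly inside
  (0, 1) by construction.
* **Effect classes**: null (δ_MSI = δ_MSS = 0), shared (0.3, 0.3),
  msi_only (0.3, 0), mss_only (0, 0.3), both_diff (0.3, −0.3). The
  both_diff default plants equal magnitudes of opposite sign so both
  strata clear the 0.2 filter while the interaction contrast is 0.6.
  Baselines are drawn U(0.35, 0.65) so baseline ± 0.3 stays in (0, 1).
* **Noise defaults** σ_p = 0.20, σ_e = 0.35 (logit scale), which place the
  person term's share of the paired-model total SS near 62% at 125
  persons — the person-dominated regime this kind of data shows. The
  helper `sigma_person_for_ss_share` inverts the expected-mean-squares
  relation σ²_p = σ²_e(2f−1)/(2(1−f)) for a target share f ∈ (0.5, 1);
  recovery of a planted 0.62 share within ±0.05 is asserted over 2000 null
  loci. No per-locus variance parameters are published for this design, so
  these magnitudes are calibration choices of the generator, documented
  here once and not tuned per test.
* **Annotation**: region bands follow the 450K chip composition
  (Island 150,254; N/S shore 62,870/49,197; N/S shelf 24,844/22,300; open
  sea 176,112 of 485,577) by deterministic largest-remainder apportionment
  plus a seeded shuffle; "Deep Sea"/"DeepSea" is accepted as an input alias
  for OpenSea. Gene density targets ~17 loci per gene.
* **Expression**: log2-scale matrix with per-probe planted tumor/normal
  folds per MSI group, person intercepts and Gaussian residuals
  (σ_p = σ_e = 0.3 by default).

All randomness flows from a single seed expanded into independent
per-stage streams (`numpy` `SeedSequence.spawn`), making every output
byte-reproducible for a fixed seed.

What passing on synthetic data does **not** show: robustness to probe-type
chemistry bias, chip batch effects, cell-type composition, or non-Gaussian
person effects; the logit-normal noise model is an idealisation.

## Problem sizes

Simulation-based checks use 2000 loci for calibration/variance-share
recovery, 900 loci (600 null + 4×75 planted) for the demo, 900 for the
classification-accuracy check (500 null + 4×100), and 200 probes for
expression power — sizes at which Monte-Carlo error is well inside the
asserted tolerances while the full suite runs in seconds.

## Missing data and degenerate inputs

Pairwise deletion throughout: a pair with either half missing is dropped
for that locus and the effective n recorded; loci with <2 complete pairs,
empty design cells, constant responses or zero-MSE fits are flagged
(`insufficient_data`, `inestimable_interaction`, `degenerate`, …) and
excluded from DML calls with the reason preserved — never silently
dropped. Readers reject ragged rows, out-of-range betas (naming the cell)
and duplicate IDs; `NA` is the missing-value token.
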