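# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of the package. Nothing
here reports an empirical result that the test suite or the analysis
drivers do not themselves compute.

## Total-effect model and estimation

Each CpG's methylation fraction is modelled as

    beta_ij = b0 + b_age * age_ij + u_i + e_ij,

with a per-subject random intercept `u_i ~ N(0, s_u^2)` and residual
`e_ij ~ N(0, s_e^2)`. Age is coded numerically in years (2, 10, 16), so
`b_age` is the total effect (TE) in methylation-fraction change per year;
a categorical-time option (likelihood-ratio test with k−1 df) is exposed
for users who prefer an unordered-factor reading of the visits.

Fitting is maximum likelihood with the variance ratio
`theta = s_u^2 / s_e^2` profiled out (`methylaging.lmm`). For a
random-intercept model the marginal covariance is block
compound-symmetric, so each likelihood evaluation is closed-form and a
genome scan costs well under a millisecond per CpG. The profile is
maximized by bounded scalar search on log(theta) over [1e-8, 1e6], with
the theta = 0 boundary (pure OLS) evaluated explicitly and kept when it
wins; constant-response CpGs short-circuit to a flagged zero-slope
result so a scan never halts. The test suite verifies the solver against
statsmodels MixedLM (ML) on balanced and unbalanced data and against a
dense GLS solve.

P-values: likelihood-ratio chi-square (1 df) of the age term under ML by
default; a normal-theory Wald option is exposed. Simulation at cohort
scale (19 subjects, depth ≈ 30, null CpGs) puts the empirical type-I
rate of the LRT at roughly 0.05–0.07 at nominal 0.05 — the mild
anticonservatism expected of a 1-df LRT with 19 subjects — which the
acceptance suite asserts as a [0.03, 0.07] band. Benjamini–Hochberg
(statsmodels `multipletests`) adjusts genome-wide; missing p-values pass
through as missing and are excluded from the adjustment. Paired
per-interval tests are two-sided paired t-tests on within-subject
differences, restricted to CpGs with at least ten complete pairs and
strictly positive difference variance ("some variation" is read
minimally as nonzero variance).

## Cell-type proportions and the PC1 mediator

Differential cell counts for the five leukocyte types are converted to
proportions by dividing complete rows by their own sum. Incomplete rows
lack their true denominator; they are divided by the mean complete-row
sum of the same time point (falling back to the overall mean), which is
exact whenever entries share a common scale, e.g. percent-of-leukocytes
differentials, the form the synthetic generator emits. Imputation order
matters and is: (1) the complement rule — at the designated time point
(by default the youngest, where lymphocyte differentials are missing)
the missing cell type is set to 1 minus the sum of the other four; then
(2) stratum means — any remaining gap takes the mean of its (cell type,
time point) stratum, after which only those touched rows are
renormalized to sum to one (logged). An entirely missing stratum, or a
complement value outside [0, 1], is a hard error naming the offender.
Every entry carries a provenance flag (observed / complement /
stratum_mean).

PC1 is computed from the centered (not variance-scaled) proportion
matrix — all five columns already share the proportion scale — with
scaling available by flag. The sign is fixed so the neutrophil loading
is positive, making PC1 increase with age in cohorts where neutrophils
rise; mediation conclusions are invariant to this convention because IE
is the product alpha * b_M and sign flips cancel. The per-cell-type
"representation" statistic is defined as |corr(proportion column, PC1
score)| rather than a rescaled eigenvector entry, since correlation is
the quantity that can meaningfully approach 100 % for two dominant,
nearly collinear cell types.

## Mediation decomposition

With no exposure–mediator interaction, the causal mediation machinery
for linear models reduces to the product-of-coefficients identity, which
is what the package computes: DE = b_DE * Δ, IE = alpha * b_M * Δ,
TE = DE + IE, proportion mediated = IE / TE, for the age contrast
Δ = 16 − 2 = 14 years by default. The proportion is invariant to the
contrast length and left undefined when |TE| < 1e-8 on the fraction
scale. Both the mediator and outcome models include subject random
intercepts by default (an OLS option exists); the mediator model is
fitted once per dataset, the outcome model per CpG on its observed
samples.

On complete balanced data the separately fitted TE slope times Δ equals
DE + IE to machine precision regardless of noise: under a
compound-symmetric weighting the mediator-model residual is orthogonal
to the (intercept, age) design, so the omitted-variable term vanishes
and all three fits agree with their OLS counterparts for these
coefficients. With unbalanced or missing data the identity is only
approximate because each model estimates its own variance ratio.

Inference is quasi-Bayesian: (b_DE, b_M) are drawn jointly from the
outcome model's asymptotic normal (alpha independently from the
mediator model's), effects are recomputed per draw, and two-sided
p-values use the +1 continuity correction, so the smallest attainable p
is 2/(n_draws + 1). CIs are percentile intervals; everything is
reproducible under a seed (per-CpG generators are spawned from one root
so results are independent of scan order). Draw count defaults to 1000
for single-CpG use; the genome-scan drivers use 4000 so the p-value
floor (≈ 5e-4) sits below typical BH thresholds.

Proportion-mediated classes partition defined proportions into
inconsistent (< 0, the mediated path opposes the total effect), partial
([0, 1]) and amplified (> 1); boundary values are assigned to the
partial class so the classification is exhaustive and disjoint.

## Subgroup representativeness (confounding check)

For subgroup size k of n subjects, the null distribution of
mean(subgroup) − mean(all) is enumerated exactly over all C(n, k)
subsets when that count is at most 1e6 (the 8-of-19 case, 75,582
subsets, is exhaustive) and otherwise sampled uniformly with a seed
(1e5 subsets by default). Extremeness is two-sided — p = 2 · min(lower
tail, upper tail) of the empirical distribution with ties counted as
extreme, a conservative choice; a one-sided reading is available by
interpreting the per-site p-values directly. Subjects missing at a
CpG/time point are dropped from both the subgroup and the whole-group
mean, and the null is built on the reduced set (k and n shrink
together). Under exchangeability of the subgroup the positive rate at
level alpha is ≈ alpha, which the tests verify by simulation.

## Reporting

Interval mean differences pool subjects per time point (not paired) and
derive all three interval columns from the same per-time-point means, so
first→last is additive by construction; this is the only construction
consistent with an additive reporting table when different subjects are
missing at different visits. Report tables round to 4 decimals.
Direction is the sign of the end-point (2→16) difference. BED inputs are
0-based half-open and converted to the matrix's 1-based positions (a
site at 1-based p overlaps [start, end) iff start < p ≤ end); on
overlapping gene intervals the first by (start, end, name) sort order
wins, deterministically. Clustering is agglomerative with euclidean
distance and average linkage (both parameterized); remaining missing
values are mean-imputed per CpG for the distance computation only. The
ranked gene list takes unique genes of CpGs at q ≤ 0.25 (a deliberately
liberal screen for enrichment tools), each with its best q, over the
full annotated background.

A packaged reference table of 26 direct-effect aDMPs from a childhood
whole-blood cohort (ages 2/10/16) serves as a fixture for the reporting
summaries; three of its rows are exactly additive at printed precision
and anchor the additivity check.

## Synthetic-data generator

The generator emulates a longitudinal pediatric whole-blood RRBS cohort:
19 subjects × ages 2/10/16 (57 samples), five cell types with
lymphocytes declining (0.55 → 0.42 → 0.35) and neutrophils rising
(0.33 → 0.47 → 0.55) so the two jointly average ~89 % of leukocytes;
per-sample proportions are Dirichlet around the age profile
(concentration 200, i.e. inter-individual proportion SD ≈ 0.03–0.035,
the scale of healthy-cohort differentials; infinite concentration gives
the zero-variance limit exactly). Whole-blood methylation is the
proportion-weighted mixture of cell-type methylomes plus a per-subject
intercept (SD 0.02); read totals are negative binomial (mean 30, shape
8, floored at 1 read — depth filtering is the pipeline's job) with
binomially sampled methylated counts; observations drop out completely
at random (10 % by default). Cell-count tables are written as
one-decimal percent differentials, with all youngest-age lymphocyte
entries blanked (mirroring a differential column that was simply not
recorded at that visit) and a 5 % MCAR blanking at the later ages only,
so the complement rule stays well-posed.

CpGs belong to four classes (null 85 %, direct 5 %, mediated 7 %, mixed
3 %): null sites share one baseline across cell types with zero slopes;
direct sites add a common within-cell-type slope of |0.005–0.02| per
year (blood-level changes of 0.07–0.28 across the span, the range seen
in reported aDMP tables); mediated sites have zero slopes but a
lymphocyte-vs-neutrophil baseline gap of 0.2–0.5, so composition drift
alone moves their blood average; mixed sites carry both, exercising
partial mediation. Baselines are uniform on (0.1, 0.9) — the
intermediate-methylation regime where age-associated blood changes are
observed and binomial noise is well behaved — and slopes are clipped so
every cell type stays within [0.02, 0.98] across the age span. A single
integer seed drives all stages through spawned generators, so each stage
is independently reproducible and datasets regenerate bit-identically.

What the generator does **not** emulate: the bimodal genome-wide
methylation landscape (most real CpGs sit near 0 or 1; planted sites
here are intermediate), read-level artifacts (no FASTQ, fragment or
conversion-error simulation), informative missingness (real RRBS dropout
follows fragment size selection, not MCAR), correlated neighboring CpGs,
and cell-type-specific age slopes that differ across types. Passing
tests therefore demonstrate correct recovery of the planted mixture
mechanics, not performance on the full messiness of real libraries.

## Problem sizes in the test suite

The acceptance tests run the full chain at 19 subjects × 5000 CpGs,
type-I calibration at 2000 null CpGs, mediation recovery over 200
replicates of 200 subjects, BH against an independent step-up oracle on
500 random vectors, CTP row-stochasticity over 1000 random missingness
patterns, and the exhaustive 75,582-subset null — sizes chosen so the
whole suite completes in a couple of minutes on one CPU while leaving
Monte-Carlo margins (3 SE bands) wide enough to be stable across seeds.
The end-to-end recovery check plants *strong* direct effects
(within-cell-type slopes 0.025–0.035/year, blood changes ≈ 0.35–0.49
across the span, the top of the observed aDMP range): at 19 subjects the
direct-effect test pays a substantial collinearity penalty (age and PC1
are strongly correlated, VIF ≈ 5–7), and the check is designed to
measure pipeline correctness under clear signal rather than cohort
power.

## Known limitations

* The 1-df LRT under ML is mildly anticonservative at 19 subjects
  (empirically ~0.06 at nominal 0.05). A Satterthwaite or Kenward–Roger
  small-sample correction is not implemented; the Wald option is no
  better calibrated.
* Draw-based mediation p-values have a resolution floor of
  2/(n_draws + 1). Near that floor, Monte-Carlo luck can promote
  borderline sites (|z| ≈ 3) past a genome-wide BH threshold, so the
  realized false-discovery proportion of the DE-significant set can
  exceed the nominal level in any single run; raising n_draws pushes the
  floor down at linear cost.
* The TE = DE + IE identity with the separately fitted TE is exact only
  on complete balanced data; under missingness the models' separately
  estimated variance ratios introduce small discrepancies.
* Proportions mediated are ratio estimates and unstable when |TE| is
  small; they are reported as undefined below 1e-8 but remain noisy just
  above it.
* The complement imputation rule requires the other four cell types to
  be present in the row; richer missingness patterns at the complement
  time point are rejected rather than guessed.
* No strand merging of symmetric CpG pairs, no DMR/region testing, no
  reference-based cell-type deconvolution (measured counts are assumed),
  and no exposure–mediator interaction in the mediation models.
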