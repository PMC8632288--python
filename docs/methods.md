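# Methods

`preemiegut` implements a longitudinal analysis linking gut microbiome
succession in preterm infants to head-circumference-growth (HCG)
trajectories, together with a synthetic cohort generator that provides
data with the statistical structure the analysis assumes. This note
records the models, the defaults and why they were chosen, the numerical
decisions, and what the synthetic tests do and do not establish.

## Study design the package models

Infants are stratified into four ordered HCG groups by the loss in
Fenton head-circumference z-score from birth to 36 weeks postmenstrual
age (PMA): appropriate growth (AHCGT, loss <= 0.5), then mildly
(<= 1), moderately (<= 1.5) and severely (> 1.5) suboptimal (SHCGT).
Loss bins are right-closed; the bin edges are configurable. z-scores are
consumed as inputs — converting raw head circumference requires the
Fenton LMS reference tables, for which a pluggable hook
(`data_model.fenton_z_score`) is exposed but deliberately unimplemented.

Stool samples are indexed by completed PMA week. Analyses run overall
and in two windows: early (24–30, before growth-trajectory divergence)
and late (31–36, during divergence); both bounds inclusive. All
available in-range samples are used, including for infants discharged
between 34 and 36 weeks.

## Compositional preprocessing

Fixed order: (1) drop samples with total counts < 1000 (boundary
retained); (2) cull features with mean percent abundance < 0.1%
(means computed once, post-QC; boundary retained); (3) aggregate counts
to the requested rank, pooling features unclassified at that rank into
`unclassified@rank`. The centered log-ratio (CLR) transform is applied
per rank after aggregation (CLR values cannot be aggregated
meaningfully). Zeros are replaced by the multiplicative-simple rule:
delta = 0.65 x the sample's minimum nonzero proportion, nonzero parts
rescaled to preserve the unit sum; 0.65 is the conventional default and
is configurable. Alpha diversity is plain richness and Shannon entropy
(natural log); coverage-standardized rarefaction is out of scope, which
does not affect downstream logic because no alpha-diversity gate feeds
later stages.

## Per-taxon group statistics

Abundance contrasts use a linear mixed model on CLR values with a
patient random intercept; fixed effects are the group indicator (e.g.
any-SHCGT vs AHCGT, or vaginal vs cesarean) and standardized PMA
(overall window only). The indicator is left on its 0/1 scale so its
coefficient is the LS-mean difference; continuous covariates are
standardized. p-values are Wald z tests on the coefficient (recorded in
`LmmResult.p_method`); with ~58 patients the normal approximation is
adequate and calibrates at 0.048 empirical type-I error on null
cohorts. The marginal R^2 is the Nakagawa fixed-effect variance share
var(Xb) / (var(Xb) + sigma_re^2 + sigma_resid^2). Singular fits fall
back to OLS and are flagged `converged=False`.

Patient-level prevalence counts a taxon present when any in-window
sample has > 0 counts; denominators (patients with any in-window
sample) are always reported alongside. Group-by-presence tables are
tested with Fisher's exact test: 2x2 via the standard two-sided test,
r x c via the Freeman–Halton generalization (sum of probabilities of
margin-preserving tables with point probability <= observed, ties
within 1e-12 relative included). Enumeration is exact to 200 total
counts; beyond that a Monte-Carlo estimate (>= 1e6 margin-preserving
draws) is returned with its standard error.

Welch's ANOVA accepts raw observations or (n, mean, sd) summary
triples and gives identical answers for both; two groups reduce exactly
to Welch's t. Games–Howell post hoc uses the studentized range with
pairwise Welch degrees of freedom. Cohen's D uses the unequal-variance
form (mean difference over the root mean of the two variances).
Multiplicity control is Benjamini–Hochberg with flags at q < 0.01 by
default.

The redundancy-analysis screen projects the centered CLR matrix on the
design (group dummies + standardized PMA) by least squares; pseudo-F per
term uses the added-last (marginal) sum of squares, and both marginal
and sequential variance fractions are reported. Permutation p-values
shuffle response rows within patient blocks; this is informative for
within-patient terms (PMA) and conservative for patient-constant terms,
which is stated in the output rather than silently worked around.

## Succession timing (change-point tally)

Taxa are screened by the PMA fixed effect of the mixed model
(Benjamini–Hochberg, q < 0.01). For each selected taxon and each HCG
group, a weekly mean percent-abundance trajectory over PMA 24–36 is
built from the contributing patients (those with the taxon present in
at least one sample); weeks without samples are linearly interpolated
(edge weeks extended from the nearest observation) and masked as
imputed. Linear interpolation was chosen over model-based imputation
for determinism.

Change points are found by PELT under the empirical-distribution (ED)
nonparametric cost: the segment cost sums Bernoulli log-likelihood terms
of the segment's empirical CDF evaluated at K quantiles of the full
series (K = ceil(4 ln n) by default, quantiles placed by the
heavy-tailed spacing rule of the ED-PELT formulation, ties weighted
1/2), scaled by 2 ln(2n-1)/K. The dynamic program is exact; pruning
is safe because the cost is subadditive (Jensen on the binary entropy),
and tests verify exhaustive-search equality for n <= 12.

The penalty is selected automatically in the spirit of the manual
elbow diagnostic: the number of change points m and the unpenalized cost
J(m) are traced along a log-spaced penalty grid (default 25 points over
~3 orders of magnitude), J is normalized so the (m, J) curve has average
slope -1, and the selected model is the largest m whose discrete slope
change exceeds 2. Below that curvature the most parsimonious model on
the path is kept, so pure-noise trajectories select 0–1 change points
while a single clean step selects exactly one (both verified at 100%
over simulated series). The full path is always emitted so a human can
override with a fixed penalty.

A change point tau (observations left of the change) is tallied under
the first week of the new regime: a shift "at week 30" contributes a
tally at 30. Tallies accumulate over (taxon, group) pairs per rank; the
key succession week is the argmax, earliest on ties. On default
synthetic cohorts the planted week-30 change is recovered as the modal
key week at every rank in 20/20 seeds.

## Random-forest cascade

Patient-level feature tables hold the median in-window percent
abundance or the presence indicator per taxon. Classifiers are random
forests (500 trees) for AHCGT vs any SHCGT; the per-split candidate
count is tuned by randomized search over repeated stratified 10-fold
cross-validation (3 repeats; plain rather than adaptive resampling,
which affects only tuning efficiency). Accuracy is reported as 100
minus the out-of-bag error. Feature significance permutes the response
vector (1001 permutations by default), refits, and counts permutations
whose mean impurity-decrease importance falls below the observed one;
p = 1 - count/(n_perm + 1). The per-rank screen keeps features with
p < .05, presence in >= 3 patients, and a defined name at the rank.
After the multi-rank + clinical model, redundant descriptors of the
same lineage chain (ancestor/descendant at any rank or statistic) are
reduced to the best-ranked one, ties resolving to the more specific
rank; clinical features are never merged. The "same underlying taxon"
rule is one reading of an under-specified reduction step and is
isolated in `reduce_redundant` for easy replacement.

## Ordinal moderation analysis

The moderation model is a proportional-odds cumulative-logit regression
of the 4-level HCG group (repeated per sample) on standardized PMA,
delivery mode (+/-0.5, vaginal positive), a moderator (per-sample CLR
abundance or per-patient clinical factor, standardized; binaries
+/-0.5) and the delivery x moderator interaction, with a per-patient
normal random intercept. The linear predictor is oriented toward
less-severe outcomes, so a positive interaction means the moderator
strengthens the vaginal-delivery benefit. Thresholds are flexible
(monotone via a log-increment parameterization).

The random intercept is integrated by adaptive Gauss–Hermite quadrature
(9 nodes by default; the per-cluster mode is found by a vectorized
Newton search and the curvature rescales the nodes). Doubling the node
count moves coefficients by < 1e-3 on test fixtures. Two numerical
safeguards matter here because the outcome is constant within a
patient, which is intrinsic to this design:

- the random-intercept scale is bounded (sigma <= e^2 ~ 7.4); without
  the bound the variance drifts to infinity (quasi-separation between
  patient-constant outcomes and the intercept) and the quadrature
  degenerates;
- the Wald test uses a cluster-robust sandwich covariance (per-cluster
  scores by central differences, G/(G-1) correction). The model-based
  information counts each patient's repeated identical outcomes as
  replication and is badly anti-informative; the sandwich restores
  calibration (empirical type-I error 0.055 on null cohorts).

McFadden's R^2 is 1 - ll_model/ll_null with the null being the
thresholds-plus-random-intercept model. The consistency screen computes
unequal-variance Cohen's D of the moderator between vaginally delivered
AHCGT infants and each SHCGT severity; "consistent" means all three
share a sign. Note these three statistics share the AHCGT reference, so
under a pure-noise moderator their signs are equicorrelated and agree
about half the time at equal group sizes (an orthant probability, not
2/8); cells with fewer than two vaginal patients are flagged and
skipped, which at the cohort's delivery-mode rates is the common case
for the severer groups.

## Synthetic cohort generator

The generator is first-class, tested code that defines the conditions
every downstream claim is evaluated under. Defaults: four groups of
28/16/8/6 patients; entry at the week of birth (gestational age drawn
per group from the cohort's published means/sds, truncated to 23–33.9
weeks) and weekly samples until an absorbing dropout event (hazard 0.15
per week; the first week is never dropped), giving roughly 300 samples
over PMA 24–36. Counts follow a Dirichlet-multinomial: per sample,
composition ~ Dirichlet(50 x softmax(baseline + patient effect +
shift)), counts ~ Multinomial(depth, composition) with depth ~
lognormal(9.2, 0.5) on the natural-log scale. Patient effects are
i.i.d. N(0, 0.5^2) per (patient, leaf) on the log scale, motivating the
random-intercept models. The mock taxonomy has 24 species-like leaves
under 16 genera, 8 families and 4 phyla, including Bacteroidota,
Lachnospiraceae, Firmicutes and Actinobacteriota analogs; a few leaves
are unclassified at species rank to exercise pooling.

The planted signal is a per-group log-scale step: by default -2 on all
Bacteroidota and Lachnospiraceae leaves in the three SHCGT groups, from
week 30 onward (the change point is therefore tallied at week 30).
Head-circumference z-score trajectories are flat to week 30 and then
decline linearly to a per-group target loss drawn uniformly within the
group's stratification bin (kept 0.05 inside the edges, endpoints
noise-free), so stored records always map back to their generative
group. Clinical covariates are drawn independently per patient at the
cohort's published group rates (delivery mode, sex, six morbidities);
antibiotics and feeding variables use realistic gamma/normal draws
(e.g. total antibiotic days ~ Gamma(2, 4), enteral volume ~ N(120, 25)
mL/kg) since only their existence, not their distribution, matters for
the moderation panel. A `morbidity_microbiome_coupling` knob can link
morbidity burden to the planted taxa for confounding experiments; it is
off by default.

`simulate_null_cohort` forces all effects and z-decrements to zero and
equalizes clinical rates across groups; the group labels live only in
`ground_truth` and carry no signal, which is what the calibration tests
require. Note the expected CLR contrast implied by a planted logit
shift is not the raw shift: it is the shift minus its mean over the
rank's features, further modified by the log-curvature of the count
noise — `synthetic.expected_clr_shift` gives the noise-free part, and
the recovery tests use a direct Monte-Carlo oracle of the full
generative model for the true estimand.

What the generator does not emulate: week-to-week autocorrelation
beyond the patient intercept, gradual maturation trends (the planted
change is a clean step), sequencing error, strain dynamics, irregular
sampling cadence, and morbidity-microbiome coupling by default. Passing
tests therefore show that the machinery recovers the structure it
assumes at this cohort scale — not that the published effect estimates
from the real cohort are reproduced, which would require the deposited
raw reads.

## Problem sizes and determinism

All stochastic components take a seed and are bit-reproducible. The
test suite and the reproduction script use cohort-scale problems (58
patients, ~300 samples, 20 seeds for recovery rates, >= 200 simulated
tests for calibration, 100 simulations for CI coverage), chosen to make
Monte-Carlo error small relative to the asserted margins while keeping
a single-CPU run practical.
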