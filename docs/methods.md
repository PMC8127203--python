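# Methods

## The problem

Administrative health data (physician billing claims and hospital discharge
abstracts) are widely used to find chronic-disease cases without clinical
chart review. For juvenile arthritis (JA) — an episodic disease diagnosed
before the 16th birthday — the established approach is a *deterministic*
case definition: a fixed rule over diagnosis codes. This package implements
that rule together with a *model-based dynamic* alternative: group-specific
statistical models of annual healthcare use feed a longitudinal discriminant
analysis that classifies each child as case, control, or (for the time
being) indeterminate as their record accrues, freezing the first confident
decision. Because the linked registry/claims data the approach was developed
on are not public, the package ships a synthetic-data generator that
reproduces the statistical structure of such data, so every component can be
exercised and validated end to end.

## Observation grid

Follow-up runs from birth to the 16th birthday, divided into 15 measurement
occasions: occasion 1 spans ages [0, 2) (JA-specific healthcare use is too
sparse in the first year of life to support a separate period) and occasions
2–15 each span one year [j, j+1). A year is 365.25 days; claim days
(integers since birth) map to occasions by `floor(day / 365.25)`, with days
below 730.5 in occasion 1. The age covariate for occasion j is the single
representative year: 1 for occasion 1, otherwise j. No exposure offset is
used for the two-year first occasion: its longer span is absorbed by the
occasion's fitted mean, matching how the measures are modelled.

## Utilization measures and code sets

Four annual measures per child:

| measure | type | definition |
|---|---|---|
| `ja_contact` | binary | any record with a JA-related diagnosis (ICD-9-CM 696, 713, 714, 716, 720; ICD-10-CA M05–M09, M45) |
| `gp_visits` | count | ambulatory visits to a general practitioner |
| `specialist_visits` | count | ambulatory visits to a specialist |
| `hospitalization` | binary | any hospitalization, excluding the newborn (birth) record |

Code matching is prefix-based on the category (3-character ICD-9 root,
letter+2-digit ICD-10 root), since administrative systems record codes at
four or more characters. Physician claims carry exactly one ICD-9 code (the
claims system is ICD-9 only); hospital abstracts carry up to 25 codes in
either revision.

The deterministic definition uses a narrower set — rheumatoid arthritis and
ankylosing spondylitis codes (ICD-9 714, 720; ICD-10 M05, M06, M08, M45) —
and labels a child a case given one such hospitalization ever, or two
physician visits with such codes at least 56 days (eight weeks) and at most
730 days (two years) apart, both bounds inclusive; the pair may be any pair,
not consecutive visits, and any relevant code qualifies a visit (the rule
does not require the same code twice). Restricted-window variants apply the
same rule to data from ages [0, 2) or [14, 16) only, emulating short
administrative histories.

## The group models

For each group g (case / control) and marker r, the repeated measurements
follow a generalized linear mixed model: Bernoulli with logit link for the
binary markers, Poisson with log link for counts, with dispersion fixed at 1.
The linear predictor is

    eta_{i,r,j} = male_i * a_m + urban_i * a_u + age_j * a_t + b_{i,r},
    b_{i,r} ~ N(E_r, SD_r^2),

i.e. the intercept is entirely random with group-specific mean E_r and
standard deviation SD_r (one normal mixture component). Random intercepts
are independent across markers (the reported fits give only per-marker
intercept SDs, no correlations), so given the covariates the markers
factorize and each marker is fit on its own; the group model is their
product. Extending the random-effects distribution to a normal mixture is
reserved in the interface but not implemented.

### Priors

Weakly informative on the link scale: fixed effects and the intercept mean
~ Normal(0, 10²); the intercept SD ~ Half-Normal(5). With hundreds of
individuals these priors are dominated by the likelihood; with no data the
posterior reproduces them exactly (tested).

### Estimation

The random intercepts are integrated out of each marker's likelihood by
adaptive Gauss–Hermite quadrature (see below), leaving a 5-parameter
posterior per marker: (a_m, a_u, a_t, E, log SD). That posterior is sampled
by independence Metropolis–Hastings: a Laplace approximation at the
posterior mode supplies a multivariate-t proposal (df 20, covariance
inflated by 1.05²); the burn-in segment doubles as adaptation, after which
the proposal is rebuilt from the burn-in draws' mean and covariance and held
fixed, so the kept draws come from a fixed-kernel chain. At the cohort sizes
used here the marginalized posteriors are close to Gaussian and acceptance
rates run ≈0.85, giving near-iid draws. Defaults follow the reported
sampling plan: 10,000 iterations, 1,000 burn-in, 1:100 thinning, 2 chains
(so the Gelman–Rubin diagnostic is computable). Reduced settings
(2 × 3,000 iterations) are used throughout the test harness; the methods
and defaults are unchanged, only chain lengths are scaled to desk size.

Convergence is monitored with the Gelman–Rubin potential scale reduction
factor, including its degrees-of-freedom correction and 97.5% upper
confidence limit; the operational criterion is upper limit < 1.02.
`convergence_table` computes the diagnostic on split chains (each chain
halved) — the standard refinement that detects within-chain drift and
greatly stabilizes the upper limit, whose raw two-chain version is
chi-squared-with-1-df noisy even for iid draws. The `psrf` function itself
implements the classic two-sequence formula.

### Quadrature

Both the likelihood and all predictive densities require integrals
∫ L(b) φ(b; E, SD) db. When a child's accrued history is informative the
integrand is far narrower than the random-effects distribution, and
quadrature nodes placed on the prior miss it (errors up to order 1 in the
log-likelihood for count markers). Nodes are therefore centered at the mode
of log L + log φ with scale from its curvature (adaptive Gauss–Hermite).
Both integrands are strictly log-concave, so damped Newton iterations find
the mode reliably. Sufficient statistics keep this cheap: a Poisson unit's
likelihood depends on b only through its summed counts and summed rate
multipliers; a Bernoulli unit's through its event count and covariate
pattern, so units sharing both are collapsed to one integral. Fitting uses
15 nodes (agrees with a 41-node rule to ~1e-7); predictive densities
default to 31 nodes and match dense-grid integration to relative error
below 1e-6 (tested).

### Model fit

The penalized expected deviance is the expected (marginalized) deviance
plus an optimism penalty, taken as twice the effective number of parameters
p_D = E[D] − D(posterior mean) — the large-sample equivalent of the
cross-chain optimism estimator. With a single chain the penalty falls back
to p_D alone (DIC-style) with a logged warning. Lower is better; values are
comparable across model specifications on the same data.

## Group-membership probabilities

For an individual with history through occasion j, Bayes' theorem gives

    P_case = pi_case f_case / (pi_case f_case + pi_control f_control)

per posterior draw, with naive priors pi = 0.5/0.5 by default. The
predictive density f_g multiplies per-marker terms computed under one of
three approaches:

* **marginal** — intercepts integrated out (adaptive Gauss–Hermite);
* **conditional** — likelihood at b-hat, the estimated intercept given the
  accrued history under the draw's parameters: the conditional posterior
  mean by default, computed with the same quadrature rule (a `b_estimator`
  switch selects the conditional mode instead; the two differ only in the
  second or third decimal at these information levels);
* **random_effects** — the density φ(b-hat; E, SD) of the estimated
  intercepts under the group's random-effects distribution.

All work is in log space — fifteen occasions of Bernoulli/Poisson factors
underflow linear-scale arithmetic — and each draw uses its own parameters,
so the spread of the per-draw probabilities is a genuine credible interval.
Draws where both groups' densities vanish are skipped with a logged count.
Point estimate: mean over draws; CrI: equal-tailed quantiles, 99% by
default (the level previously found to perform best for this allocation
scheme).

## Dynamic classification

The cutoff c is the ROC threshold nearest the top-left corner, minimizing
d² = (1 − sensitivity)² + (1 − specificity)², searched over midpoints of
adjacent sorted unique probabilities plus {0, 1}; ties break toward 0.5.
Cutoff selection runs on the training folds only, using final-occasion
point-estimate probabilities (the occasion used for the ROC is not
prescribed; final-occasion is the default, exposed as config).

Allocation per occasion under the CrI scheme: case iff the CrI lies wholly
above c (lower bound > c), control iff wholly below (upper bound < c), else
indeterminate; intervals touching the cutoff stay indeterminate
(conservative reading of the scheme). The point scheme compares the point
estimate alone and never abstains. Scanning occasions in order, the first
non-indeterminate allocation freezes — probabilities are not updated after a
decision. The decision age is the upper age bound of the deciding occasion
(occasion 1 → 2 years, …, occasion 15 → 16 years), so the mean
classification time is a mean of decision ages; never-classified
individuals are excluded from that mean (and flagged via the indeterminate
proportion).

## Evaluation

Five-fold cross-validation with simple random, size-balanced,
non-stratified folds. Per fold: fit both group models on the training
folds, compute held-out probability series at all occasions, select the
cutoff on the training data, classify sequentially, and tabulate a
confusion matrix that keeps the indeterminate column after the last
occasion. Sensitivity and specificity are reported in two variants —
`all_data` (indeterminates count in the denominators) and `classified_only`
(they are removed); PPV = TP/(TP+FP) and NPV = TN/(TN+FN) never include
indeterminates. 95% CIs use Wilson score intervals (Wald intervals
degenerate at fold-level counts; the original report does not state its
interval method). The probability of correct classification uses the
variant-consistent denominator. AUC is the rank-based (Mann–Whitney,
tie-averaged) area using final-occasion point estimates for everyone,
including individuals frozen earlier (a frozen-probability variant is a
switch). Fold metrics are averaged unweighted; pooled-confusion metrics are
also reported. A per-occasion evolution table (proportion unclassified,
sensitivity, specificity, PPV) tracks the accuracy build-up; the
deterministic definition is scored through the identical confusion/accuracy
code path with an empty indeterminate column.

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions everything else is validated under.

Cohort structure: 797 children, 48.4% cases, 65% female, 57% urban —
the composition of the referral cohort being emulated. Income quintile is
simulated uniform on 1..5 and carried descriptively only (it is not a model
covariate). Group labels, covariates and per-marker latent intercepts are
drawn independently; measures come from the group models above with the
full-model posterior means as generating parameters. Under those defaults
the final-occasion contact prevalence is ≈72% among cases and ≈11% among
controls, bracketing the real cohort's 64.5% vs 9.0%.

Claims are then emitted to be *exactly* consistent with the measures
(round-tripping through `derive_annual_measures` is tested as an identity):
per occasion, GP/specialist ambulatory claim counts equal the recorded
visits with days uniform in the occasion span; a JA-contact year places
1 + Poisson(1) JA codes on physician claims (specialist visits preferred
with probability 0.8 — rheumatology contacts are specialist contacts), on
the hospital record (probability 0.5 when one exists), or, if the year has
no other contact, on an in-hospital/ER physician consult claim that does
not add to the ambulatory counts. Specific JA codes are drawn from
group-specific category mixes: cases mostly carry the definition-relevant
rheumatoid/ankylosing categories (weight 0.75), controls mostly other
arthropathy contact codes (relevant weight 0.10) — fixed a priori to
reflect that the deterministic definition was validated with high
sensitivity and PPV on the real registry. A newborn birth record
(probability 0.98, never JA-coded) exercises the newborn exclusion.
Physician claims are ICD-9; hospital records are ICD-9 or ICD-10 with
probability 0.5 each (the synthetic world has no calendar, so the revision
is carried per record rather than inferred from dates).

What the generator does *not* emulate: calendar/fiscal-year effects,
migration and loss to follow-up (the emulated cohort required continuous
coverage), within-year clustering of visits, diagnosis-date covariates, and
real ICD dictionaries beyond the listed categories. Passing tests therefore
demonstrate the correctness and internal consistency of the methods under
the assumed generating process — not the accuracy the methods would attain
on real administrative data.

## Problem sizes in the test harness

The package's own validation uses desk-scale runs chosen to exercise every
code path at meaningful precision: round-trip and deterministic-oracle
checks on 500-person cohorts; parameter recovery on 20 replicate cohorts of
800 cases with 2 × 3,000-iteration chains (overall 95%-CrI coverage ≥ 0.90
across the 400 coefficient-replicate checks, split-chain PSRF upper limits
below 1.02 throughout); an end-to-end cross-validated comparison on an
800-person cohort; and a null-calibration run (identical generating
parameters in both groups) whose cross-validated AUC must sit within
0.5 ± 0.1.

## Known limitations

* The random-effects-approach credible intervals come out consistently
  wider than the marginal ones here, at every occasion and sample size
  tried. This reproduces the approach's documented *behaviour* (more
  indeterminates, later decisions than the marginal approach) but not the
  reported ordering of predicted-probability standard deviations, which
  appears specific to the original data or software and is not asserted.
* The optimism penalty is the 2·p_D large-sample form, not a
  cross-chain importance-sampling estimator; PED differences between
  near-equivalent models smaller than a few units are not meaningful.
* The independence sampler is matched to the near-Gaussian marginalized
  posteriors of this design; strongly multimodal posteriors (e.g. mixture
  random effects, were they implemented) would need a different kernel.
* Five-fold metrics on a 797-person cohort carry fold-level Monte-Carlo
  noise of a few percentage points; seed-to-seed variation of that size in
  the reported accuracy measures is expected.
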