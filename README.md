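# dynacase

Model-based **dynamic classification** and **deterministic case
definitions** for ascertaining juvenile arthritis (JA) cases from
administrative health data — as a tested, reusable pipeline driven by a
synthetic claims/registry generator.

## Who this is for

Epidemiologists and health-services researchers who build chronic-disease
case definitions from physician claims and hospital discharge abstracts,
and methodologists studying longitudinal discriminant analysis (LoDA) for
disease ascertainment. The linked clinical-registry data this methodology
was developed on are not public, so the package includes a generator that
emulates their statistical structure: a two-group referral cohort (cases
and non-cases), four annual healthcare-utilization measures over 15
occasions from birth to the 16th birthday, and dated ICD-coded claims that
aggregate exactly to those measures.

## The methods

**Deterministic definition.** A child is a JA case if, before the 16th
birthday, they have ≥1 hospitalization with a rheumatoid arthritis /
ankylosing spondylitis code (ICD-9 714, 720; ICD-10 M05, M06, M08, M45), or
≥2 physician visits with such codes 56–730 days apart. Sensitivity-analysis
variants restrict the rule to ages 0–2 or 14–16.

**Dynamic classification.** For each group g ∈ {case, control} a
multivariate generalized linear mixed model describes the annual measures
Y_{i,r,j} (Bernoulli-logit / Poisson-log) with fixed effects for sex,
region and age and a random intercept b_{i,r} ~ N(E_r^g, (SD_r^g)²),
independent across markers:

    h_r⁻¹( E[Y_{i,r,j} | b, U_i = g] ) = x_{i,j}ᵀ α_r^g + b_{i,r}

Models are fit by MCMC under weakly informative priors. For a child with
history y_{1..j}, Bayes' theorem turns group-specific predictive densities
f_g (marginal, conditional, or random-effects form) into a membership
probability per posterior draw:

    P_case = π_case f_case / (π_case f_case + π_control f_control)

Scanning occasions in order, the child is called a case (control) once the
99% credible interval of P_case lies wholly above (below) a cutoff chosen
to minimize d² = (1−Sens)² + (1−Spec)² on training data; otherwise they
stay indeterminate, and the first decision freezes. Everything is scored by
five-fold cross-validation with sensitivity, specificity, PPV, NPV (Wilson
95% CIs), AUC, proportion indeterminate, and mean classification time.

See `docs/methods.md` for the full model, estimation, and design details.

## Worked example

```python
import dynacase as dc

# a synthetic cohort at the default study conditions
cfg = dc.GeneratorConfig(n_individuals=400, seed=21)
cohort = dc.generate_cohort(cfg)
claims = dc.generate_claims_for_cohort(cohort, cfg)

# cross-validated dynamic classification (JA-contact model,
# random-effects prediction, credible-interval allocation)
mcmc = dc.McmcConfig(n_iterations=2000, burn_in=500, thinning=15, seed=7)
cv = dc.run_cross_validation(cohort, dc.JA_UTILIZATION_MODEL, mcmc,
                             approach="random_effects", scheme="cri",
                             k=5, seed=3)
print(f"sensitivity {cv.pooled_all_data.sensitivity:.3f}  "
      f"specificity {cv.pooled_all_data.specificity:.3f}  "
      f"AUC {cv.auc:.3f}  mean time {cv.mean_classification_time:.2f} y")

# the deterministic comparator on the same children
truth = {ind.person_id: ind.group for ind in cohort}
det, _ = dc.evaluate_deterministic(claims, truth, dc.windowed_rules()[0])
print(f"deterministic sensitivity {det.sensitivity:.3f}  "
      f"PPV {det.ppv:.3f}")
```

Output (seed 21/7/3):

```
sensitivity 0.754  specificity 0.859  AUC 0.931  mean time 9.48 y
deterministic sensitivity 0.836  PPV 0.976
```

Reading: the dynamic classifier finds 75.4% of true cases (its credible
intervals left a few children permanently indeterminate) and commits, on
average, at age 9.5 — years before the end of follow-up — while the
deterministic rule, which needs the full 16-year record, is more sensitive
(83.6%). The per-occasion evolution (`cv.evolution`) shows the proportion
unclassified falling monotonically as histories accrue, with sensitivity
and specificity rising toward their final values.

The same workflow is available from the shell:

```bash
dynacase simulate --n 400 --seed 21 --out sim/
dynacase casedef --claims sim/claims.csv --window full --out labels.csv
dynacase evaluate --cohort sim/cohort.csv --claims sim/claims.csv \
    --model ja --approach ranef --scheme cri --seed 7 --out report.json
```

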