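# crmsm — cognitive reserve and multistate cognitive transitions

`crmsm` is a Python package for studying how **cognitive reserve (CR)** —
the latent capacity accumulated over the lifespan through education, work
complexity, leisure activity and social networks — shapes the movement of
older adults among four states: **normal cognition (1), CIND (2, cognitive
impairment no dementia), dementia (3) and death (4)**.  It is written for
epidemiologists and biostatisticians analyzing longitudinal aging cohorts
in which cognition is assessed only at periodic examinations (so cognitive
transitions are interval-censored) while death dates are exact.

The package implements the whole chain:

1. **Composite CR scoring** (`crmsm.cr`) — component scores for leisure
   (0–6) and social network (mean of standardized size and support blocks),
   z-standardization of the four indicators, a maximum-likelihood
   one-factor confirmatory factor model with χ²/CFI/RMSEA fit indices, and
   regression-method factor-score weights `w = Σ̂⁻¹λ̂` giving each person's
   composite score `Σ_j w_j z_j`.
2. **CIND classification** (`crmsm.cind`) — domain z-scores from a
   six-test battery and the rule *CIND ⇔ any of five domains ≥ 1.5 SD below
   its age-group mean*; state assembly with death > dementia > CIND
   precedence.
3. **Covariate preparation** (`crmsm.covariates`) — log transforms,
   ICV-adjustment of brain volumes by linear regression, presence/absence
   dichotomization, interaction products, complete-case policy.
4. **The Markov multistate model** (`crmsm.msm`) — a continuous-time
   four-state process with proportional transition intensities

       q_rs(x) = q⁰_rs · exp(β_rs′ x),

   panel likelihood `P_rs(dt) = [exp(Q dt)]_rs` for exam pairs and the
   absorption density `Σ_s P_rs(dt)·q_s4` for exactly observed deaths;
   BFGS maximum likelihood with analytic (spectral) gradients, Wald
   hazard-ratio tables `HR = exp(β̂)`, interaction tests, and stratified
   fits with automatic freezing of effects on sparse transitions.
5. **A synthetic cohort generator** (`crmsm.simulate`) — cohorts with the
   age-dependent exam design (6-year exams under attained age 78, 3-year
   exams after; 15-year censoring), latent CR driving an indicator battery
   and cognitive tests, and exact jump trajectories with full truth records
   for recovery testing.
6. **Pipeline and CLI** (`crmsm.pipeline`, console script `crmsm`) —
   simulate → score → classify → fit → report, driven by a YAML config.

## Worked example

Simulate a cohort, score CR from its raw indicator battery, fit the
four-state model adjusted for CR, centered age and sex, and print the
hazard-ratio table:

```bash
crmsm simulate --n 1200 --seed 4 --out demo
crmsm score-cr --indicators demo/indicators.csv --out demo/cr_scores.csv
crmsm fit --panel demo/panel.csv --covariates demo/covariates.csv \
          --covariate cr --covariate age_c --covariate female --out demo/results
crmsm report --bundle demo/results
```

The scoring step prints the CFA fit —

```
CFA fit: chi2=0.086 (df=2), CFI=1.00, RMSEA=0.000; scored 1200 subjects
```

— a near-perfect fit, as expected when the indicators really follow a
one-factor model.  The report prints one row per transition and covariate
(output abridged to the CR rows):

```
Hazard ratios (per 1-point CR unless noted):
    1->2 cr           0.82 (0.73-0.92) p=0.000735
    2->1 cr           1.16 (1.02-1.33) p=0.0246
    1->3 cr           0.80 (0.49-1.29) p=0.36
    2->3 cr           0.97 (0.76-1.24) p=0.815
    1->4 cr           0.85 (0.70-1.04) p=0.107
    2->4 cr           0.85 (0.71-1.01) p=0.0719
    3->4 cr           1.01 (0.88-1.16) p=0.887
loglik: -3837.7430729416546; convergence: True
```

Read: each 1-point increase in the composite CR score multiplies the
instantaneous rate of moving from normal cognition to CIND by 0.82
(18% lower risk), with a 95% Wald CI of 0.73–0.92 — close to this cohort's
generating value of 0.78, while transitions the generator left unaffected
(e.g. dementia → death) sit near 1.  At this cohort size the CIs are wide;
sparse transitions with very few events are frozen and reported as
"not estimated" rather than given spurious precision.

The same analysis runs as a library call:

```python
from crmsm import SimulationConfig, generate_cohort, fit_multistate, hazard_ratio_table

cohort, truth = generate_cohort(SimulationConfig(n=1200, seed=4))
fit = fit_multistate(cohort, covariates=["cr", "age_c", "female"])
print(hazard_ratio_table(fit))
```

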