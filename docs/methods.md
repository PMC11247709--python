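# Methods

## The scientific problem

Cognitive aging is not unidirectional: older adults move between normal
cognition and CIND (cognitive impairment, no dementia) in both directions,
progress to dementia, and die from any cognitive state.  `crmsm` implements
the full analysis chain for asking how *cognitive reserve* (CR) — the latent
capacity built up over the lifespan through education, occupational
complexity, leisure engagement and social networks — shifts the intensities
of these transitions, when cognition is only observed at periodic
examinations but death is known exactly.

## Composite CR score

Four indicators proxy the latent reserve:

* **education** — years of formal schooling;
* **work complexity** — substantive complexity of the longest-held
  occupations, a continuous score on [0.7, 10];
* **leisure activity** — an ordinal 0–6 score summing mental, social and
  physical components, each banded 0/1/2 (counts ≤1 / 2–3 / ≥4 for the
  mental and social components; participation frequency below weekly /
  weekly / above weekly for the physical component);
* **social network** — the average of a network-size block and a perceived-
  support block, each the mean of its z-standardized indicators.

The indicators are z-standardized and a one-factor confirmatory factor model

    Sigma(lambda, theta) = lambda lambda' + diag(theta),   Var(eta) = 1

is fitted by maximum likelihood to the complete-case sample covariance,
minimizing the Wishart discrepancy
`F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p`.  With four indicators the
model has 8 free parameters against 10 sample moments, leaving df = 2.
Fit indices use `chi2 = (n-1) F`, the independence model (free variances,
zero covariances) as the CFI baseline, and
`RMSEA = sqrt(max(chi2-df,0)/(df (n-1)))`.  Note that under a correctly
specified model `chi2` is approximately chi-square(2), so RMSEA has a
point mass at 0 of only ~0.63 and sampling quantiles up to ~0.03 even when
the model is exactly true; a near-zero *population* RMSEA does not make the
*sample* RMSEA collapse to zero.

Composite scores are regression-method weighted sums: `w = Sigma_hat^-1
lambda_hat`, score `= sum_j w_j z_j`.  Rows missing one indicator (at least
3 of 4 required by default) use the available weights rescaled to the
full-weight total.  Heywood cases are bounded at a uniqueness of 1e-6 and
flagged.  The first loading is constrained positive to fix the sign.

## CIND classification

Six raw tests map to five domains (episodic memory, executive function,
language, visuospatial ability, perceptual speed; the last has two tests).
Test scores are standardized against baseline means/SDs, timed tests
sign-flipped so higher is always better, and a domain z is the mean of its
available test z-scores.  CIND is called when any scoreable domain lies at
least 1.5 SD below its *age-band-specific* mean (inclusive threshold);
a negative call requires all five domains scoreable, otherwise the exam is
uninformative (missing).  Age bands follow the cohort's sampling ages
{60, 66, 72, 78, 81, 84, 87, 90}; a band too sparse to estimate an SD falls
back to the pooled all-ages reference.  State assembly gives death
precedence over dementia and dementia over CIND.

## The multistate model

States 1–4 are normal cognition, CIND, dementia, death.  The default
transition structure allows 1↔2, 1→3, 2→3, 1→4, 2→4, 3→4 — no recovery from
dementia, and a direct normal→dementia intensity because such transitions
are observed in practice.  Intensities are proportional in baseline
covariates and time-homogeneous on the follow-up-time scale:

    q_rs(x) = q0_rs exp(beta_rs' x),

so `exp(beta_rs)` is the hazard ratio of transition r→s per covariate unit.
Baseline age enters as a covariate, not as the time scale.

**Likelihood.** For consecutive exams in living states r (at t) and s (at
t+dt), the contribution is `P_rs(dt)` with `P = expm(Q dt)` — the state
path between exams is integrated out exactly, so multi-step paths within an
interval are fully accounted for.  An exactly observed death at t+dt after
a last living exam in state r contributes the absorption density
`sum_{s living} P_rs(dt) q_s4(x)`.  Subjects alive at their last exam are
right-censored there; single-observation subjects are retained but
contribute nothing.

**Estimation.** The total log-likelihood is maximized by BFGS.  All
subjects' generators are eigendecomposed in one batched call and the
gradient is analytic, using the spectral form of the directional derivative
of the matrix exponential (`dP = V (W ∘ (V^-1 dQ V)) V^-1`, with
`W_ab = (e^{la t}-e^{lb t})/(la-lb)` and `W_aa = t e^{la t}`); a dense
`expm` evaluation with central-difference gradients backs this up whenever
an eigenvector matrix is ill-conditioned, and is exposed as
`gradient="numeric"` for cross-checking.  The two paths agree to 1e-7 in
the test suite.  Starting values are occurrence/exposure rates
(counts / origin-state person-time, floored at 1e-4), which equal the exact
MLE for fully observed single-transition data.  The covariance is the
inverse observed information (central differences of the analytic
gradient); Wald CIs and p-values follow, with no multiplicity correction.

**Sparse transitions.**  Covariate effects on transitions supported by
fewer than 10 observed interval pairs (configurable) are frozen at zero and
reported as "not estimated"; a transition with no observed pairs at all has
its baseline rate frozen at the floor.  This mirrors how sparse transitions
are handled in applied reports and keeps stratified fits from crashing on
empty cells.

**Interactions and stratification.**  Effect modification is tested by a
single product term (e.g. CR × age-group) added to one transition, judged
by its Wald z; the pipeline follows up interactions with p < 0.10 with
per-stratum fits that drop the stratifying variable from the adjustment
set.

## Synthetic cohort generator

The generator reproduces the design features the estimators are sensitive
to, with defaults frozen once:

* cohort size 2631; baseline ages drawn from {60,…,90} with weights chosen
  to give mean age ≈ 72; 61% female; 27% APOE-ε4 carriers;
* latent CR ~ Normal(0, 1.26²) truncated to [−4.25, 3.46]; the four-
  indicator battery is generated from a one-factor model with loadings
  (0.7, 0.6, 0.5, 0.4) and then mapped onto raw scales (education mean
  12.32, SD 4.00; work complexity mean 5.0, SD 1.81 clipped to [0.7, 10];
  leisure counts and frequency discretized from the leisure factor;
  network indicators loading 0.6 on the network factor);
* six cognitive tests whose five domain abilities share a general factor at
  loading √0.4 (exchangeable cross-domain correlation ≈ 0.4) that itself
  loads 0.45 on CR; baseline state is *classified* from this battery with
  the CIND rule, which yields ≈ 23–24% baseline CIND and makes the
  scoring → classification → modelling chain testable end to end;
* true transition intensities: baseline rates (per year, at age 72, male,
  CR 0) of 0.090 (1→2), 0.200 (2→1), 0.006 (1→3), 0.050 (2→3), 0.020
  (1→4), 0.060 (2→4), 0.300 (3→4), calibrated once so that a 15-year
  follow-up of ~2500 subjects yields transition counts of the same order as
  published cohort reports (hundreds of 1→2 and 2→4 pairs, tens of direct
  1→3); log-linear age effects (0.04–0.09 per year), small female survival
  advantages, APOE effects on dementia transitions, and per-point CR log
  hazard ratios defaulting to the published estimates ln 0.78 (1→2),
  ln 0.85 (1→4), ln 0.82 (2→4);
* trajectories by competing exponentials; exams every 6 years while
  attained age < 78 and every 3 years from 78 (switching at the first exam
  past 78), administrative censoring at 15 years; death recorded at its
  exact time whenever it precedes censoring, even after (optional,
  default-off) permanent exam dropout.

What the generator does **not** emulate: per-wave attrition patterns,
learning/practice effects on cognitive tests, measurement error in the
observed states (no misclassification layer), time-varying covariates, and
secular trends.  Passing recovery tests therefore demonstrate correctness
of the estimators under the stated design, not robustness to those
real-data complications.

## Pre-specified experiments

`crmsm.experiments` fixes the recovery designs used by both the test suite
and `scripts/acceptance.py`:

* **HR recovery** — 20 cohorts (n = 2500) from the default design; refit
  with CR, centered age and sex on all transitions; report mean fitted HRs
  on 1→2, 1→4, 2→4.
* **Stratified recovery** — merged cohorts of 1600 young-old (60–72,
  6-year exams) and 1000 old-old (≥78, 3-year exams) subjects with
  stratum-specific CR effects on 2→4 (HR 0.65 vs 0.87); stratified refits
  and a pooled CR × age-group Wald test.
* **CFA behavior** — 50 draws of n = 2631 from the one-factor model;
  CFI/RMSEA distribution and the majority rounded CFI.
* **Interaction type-I error** — 400 null cohorts (n = 800; CR main effect
  only, no interaction) fitted with CR, age-group and their product on
  2→4; rejection count at the 5% level.

Problem sizes were chosen so the full suite and the reproduction script
each run in minutes on one CPU.

## Numerical choices and known limitations

* `expm` uses SciPy's scaling-and-squaring Padé implementation; the
  uniformization series lives in the test suite as an independent oracle
  (agreement to 1e-10 on random generators; Chapman–Kolmogorov to 1e-9).
* Probabilities are clipped only within 1e-12 slack; a structurally
  impossible observed pair yields −inf with a diagnostic naming the pair.
* BFGS stops at gradient norm 1e-4; the CFA at relative discrepancy change
  below 1e-8 (L-BFGS-B ftol 1e-14).
* Duplicate exam times are errors (panel intervals need positive length);
  gaps from missed exams are treated as one long panel interval, which the
  Markov assumption licenses.
* Finite-sample bias: with heavy competing mortality (old-old strata,
  n ≈ 1000) the per-transition CR effect on CIND→death carries a small
  upward finite-sample bias (~+0.04 on the HR at n = 1000, vanishing by
  n = 8000 in our checks) because deaths routed through dementia within an
  exam interval weaken identification of the direct effect.  Estimates on
  such strata should be read with their (wide) CIs, exactly as in applied
  reports.
* The observed information can be near-singular when a covariate effect
  sits on a sparsely supported transition; the fit then flags the
  covariance unavailable rather than reporting spurious precision.
* No semi-Markov or time-inhomogeneous intensities, no hidden-Markov
  misclassification layer, no frailties; covariates are baseline-fixed.
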