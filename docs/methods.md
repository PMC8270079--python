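# Methods

## The NTCP models

Each endpoint model is a binary logistic regression evaluated at fixed,
published coefficients: `NTCP = expit(LP)` with
`LP = β₀ + Σ βⱼ·D_mean,j + Σ γₖ·1[levelₖ]`. Doses are physical mean doses in
Gy read from the treatment plan's DVH; no EQD2 or fractionation conversion
is applied. The three shipped models are:

| model | grade | intercept | dose terms (per Gy) | clinical terms |
|---|---|---|---|---|
| xerostomia | 2 | −1.507 | contralateral parotid 0.052 | baseline xerostomia minor +0.525, moderate/severe +1.482 |
| dysphagia | 2 | −3.303 | oral cavity 0.024, superior PCM 0.024 | baseline dysphagia ≥2 +0.967 |
| tube feeding | 3 | −6.849 | superior PCM 0.030, inferior PCM 0.013, contralateral parotid 0.022, cricopharyngeal 0.008 | advanced T-stage (T3–T4) +0.680; weight loss 1–10% +0.317, >10% +1.178; accelerated RT +0.198, chemoradiation +1.101, RT+cetuximab +1.716 |

Coefficients live in `src/ntcp_select/data/default_models.json`, not in
code, and a load-time guard rejects any file whose dose coefficients are
non-positive or whose clinical coefficients are negative — in these models
every dose and risk-factor effect is harmful, so a sign flip can only be a
transcription error. Categorical reference levels (no baseline symptoms,
T1–T2, no weight loss, conventional RT alone) carry an implicit coefficient
of 0 and may not appear in a coefficient file. A predictor a model needs
that is absent from the input raises a `MissingPredictorError` naming model
and field; nothing is silently defaulted.

## Selection flowchart

Stage 1 is the eligibility gate: tumour site in {pharynx, larynx, oral
cavity}, no distant metastases, curative intent. Stage 2 computes, per
endpoint, `ΔNTCP_max = NTCP(photon doses) − NTCP(all model doses = 0)` with
clinical covariates unchanged — the largest benefit any proton plan could
deliver. A proton plan comparison is indicated only if the threshold rules
below could fire at this bound (the summed rule is mirrored at the
pre-screen for the same reason: a comparison is pointless if even the bound
cannot reach the summed threshold). Stage 3, given a real proton plan,
computes `ΔNTCP = NTCP_photon − NTCP_proton` per endpoint and applies:

- **single rule** — an endpoint of grade g qualifies at ΔNTCP ≥ 10 pp
  (g = 2), ≥ 5 pp (g = 3), ≥ 2 pp (g = 4);
- **summed rule** — any unordered pair of endpoints of the *same* grade
  qualifies at a joint ΔNTCP ≥ 15 / 7.5 / 3 pp. No summation across grades.

Numerical choices: comparisons are inclusive (≥) at full floating
precision; rounding to one decimal happens only in reports, never before a
decision. Pair sums use signed values, so an endpoint on which protons are
*worse* (negative ΔNTCP) reduces the pair sum — the conservative reading of
a case the national text does not address. With the three default models
the grade-2 summed rule has exactly one pair (xerostomia + dysphagia) and
grade 3 has none, but the engine implements the generic any-same-grade-pair
rule so additional models slot in unchanged; grade-4 thresholds are kept in
the default policy although no shipped model carries grade 4. Decisions
record every fired rule and satisfy `qualifies ⇒ comparison indicated ⇒
gate passed` by construction.

## External validation and model updating

Discrimination is the concordance statistic (probability that a random
event outscores a random non-event, ties ½), computed via
`sklearn.metrics.roc_auc_score`; tests check it against a brute-force
pairwise enumerator. Calibration regresses the observed outcomes on the
model's linear predictor LP: the **slope** is the LP coefficient of a
logistic refit (1 = spread of predictions is right), and the **intercept**
is fitted with LP as a fixed offset, so it is the additive logit correction
the new data ask for — positive when the model underpredicts. Validation
operates on complete cases; rows with missing predictors or outcomes must
be excluded (or imputed) upstream. The TRIPOD evaluation-stage label on a
report is user-declared metadata, not computed.

The closed-testing update fits the nested sequence

| level | model | free parameters |
|---|---|---|
| original | logit p = LP | 0 |
| intercept update | logit p = a + LP | 1 |
| recalibration | logit p = a + b·LP | 2 |
| revision | full refit of all coefficients | p + 1 |

and compares the *revision* against each simpler level in increasing
complexity by likelihood-ratio chi-square tests at level α, stopping at the
first non-rejection and selecting that level (all rejections ⇒ revision).
Under data truly generated by the original model the first test rejects
with probability α, so "original" is kept with probability 1 − α — the
closed-testing principle's overall type-I control. Log-likelihoods are
non-decreasing along the nesting and the selected level is monotone in α
(α → 0 always keeps the original, α = 1 always revises). The selected
level maps back to a coefficient set: an intercept update adds the fitted
offset to β₀; recalibration maps β₀ → a + b·β₀ and scales every other
coefficient by b; revision substitutes the refit.

Logistic fits are maximum likelihood via iteratively reweighted least
squares (statsmodels GLM, binomial family), converged when the relative
log-likelihood change falls below 1e-10 or after 100 iterations.
Rank-deficient designs raise; any |coefficient| > 15 flags probable
(quasi-)separation with a warning rather than failing, since the fit may
still be usable for likelihood comparison. `refit_model` optionally merges
a model's dose terms into a single summed-dose predictor — the standard
remedy when two organ doses are nearly collinear (oral cavity and superior
constrictor); the shipped dysphagia model keeps two equal-coefficient
terms, so merging is an analysis option, not the default.

## Synthetic cohorts

The generator emulates the statistical structure the protocol assumes, not
any real referral population. Photon-plan organ doses are multivariate
normal, truncated to [0, 80] Gy, with defaults (means 25/38/45/30/25 Gy,
SDs 10–12 Gy for contralateral parotid / oral cavity / superior PCM /
inferior PCM / cricopharyngeus) chosen once so that the latent event
fractions are of the same order as published validation cohorts (roughly
one half, one quarter and one tenth for the three endpoints). All dose
pairs share a 0.45 correlation; the oral-cavity/superior-PCM pair is set to
0.85 to reproduce the near-collinearity that motivated the merged-dose
option. Clinical factors are independent categorical draws with plausible
head-and-neck case-mix prevalences (e.g. 40% chemoradiation, 50% advanced
T-stage). Proton plans multiply each photon dose by a per-patient,
per-organ factor drawn as Normal(0.6, 0.15) clipped to [0, 1] — a mean 40%
dose reduction, consistent with reported proton-planning gains. Outcomes
are Bernoulli draws from the true models' NTCPs, so the simulation's truth
is exactly the model being tested.

One seed drives everything through `numpy.random.SeedSequence` spawned into
four independent streams (doses, clinical factors, proton reductions,
outcomes), so regenerating one table never shifts another. Limitations:
real dose distributions are not truncated normals, depend on tumour
subsite, and correlate with stage and treatment; clinical factors are not
independent of doses; proton benefit is not a homogeneous multiplicative
factor. Passing tests therefore demonstrate the *engine's* correctness and
the estimators' statistical properties, not the real-world qualification
rate — the cohort-level rates the tools report on synthetic data are
properties of these fixtures, not claims about any referral population.

## Problem sizes used in tests and the acceptance script

Property suites use 10,000 random patient/plan pairs and rule profiles;
parameter recovery uses one cohort of n = 50,000 (each coefficient within
3 SE of truth); closed-testing operating characteristics use 500 replicate
cohorts of n = 2,000 in the test suite and 200 in the acceptance script;
validation metrics use n = 5,000. These sizes make the stochastic checks
tight (binomial SE under 1 pp for the type-I rate) while keeping the whole
suite in the minutes range.
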