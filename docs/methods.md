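# Methods

## Diagnostic scoring

The IDQ/IAQ diagnostic algorithms are deterministic functions of the ordinal
responses and the impairment answer: endorsement means a rating of 3 or 4;
a case requires at least one core item endorsed (items 1–2), the minimum
total endorsed count (5 for the IDQ, 4 for the IAQ), and impairment answered
"Yes". Two policies are worth noting because they are choices, not forced:

* **Missingness is handled complete-case per scale.** A respondent missing
  any IDQ item is excluded from IDQ scoring, diagnosis and IRT, but still
  contributes to the IAQ and comparators. Out-of-range values in input files
  are treated as missing (with a logged count), not repaired.
* **A missing impairment answer with otherwise case-positive symptoms leaves
  caseness *undetermined*** (reported separately) rather than imputed as
  "no"; symptom-negative respondents are non-cases regardless.

Prevalence intervals use the **Wilson score interval**. The interval method
behind published prevalence CIs of this kind is rarely stated; Wilson is
preferred here because it behaves correctly for small proportions, and for
152/2058 it yields (6.3%, 8.6%) at one decimal, whereas a Wald interval
gives 8.5% at the upper end.

## IRT estimation

The binary endorsement recodes are modelled with the normal-ogive 2PL,
θ ~ N(0,1) fixed for identification. Estimation is marginal maximum
likelihood over response patterns:

* **2PL:** Bock–Aitkin EM — the E-step allocates each response pattern over
  a Gauss–Hermite grid (default 61 nodes, change of variable to N(0,1)) by
  its posterior trait density; the M-step refits each item's probit
  regression against the expected endorsement counts (weighted GLM). EM runs
  to a relative log-likelihood change below 1e-7 (default cap 200
  iterations), then an L-BFGS-B polish with the analytic score maximizes the
  marginal likelihood directly. The EM trajectory is retained and is
  non-decreasing by construction; tests assert it.
* **1PL:** the common slope couples the items, so the constrained likelihood
  is maximized directly by L-BFGS-B (same objective, analytic gradient) from
  a 2PL-style start. It remains the same marginal-likelihood estimator.
* **Starts** are deterministic: one-factor principal loadings of the
  tetrachoric matrix converted through λ = a/√(1+a²), thresholds from the
  margins. Seeds affect only data simulation, never estimation.
* **Bounds:** |a| is capped at 10; an item at the cap is flagged
  (Heywood-type). Items with zero endorsement variance are dropped with a
  warning. Standard errors come from the observed information (numerical
  Hessian of the marginal log-likelihood in the (a, b) metric).
* **Quadrature resolution matters for steep items.** With discriminations
  near 3, a 41-node grid leaves a visible negative bias in â at n = 5000;
  61 nodes reduce the recovery bias to ~0.02. The 61-node default is used
  throughout, including the validation studies.

**Model comparison** is a likelihood-ratio χ² between the nested MML fits
(df = number of items − 1). The original analyses used a weighted
least-squares categorical estimator with its own adjusted difference test;
that estimator's weight matrix is not reproduced here, so agreement is
expected in parameter values (approximately) and in the decision — reject
equal discriminations — not in the test statistic itself.

**Fit indices** are documented approximations, not the WLSMV values:
residuals of the tetrachoric matrix against the one-factor implied
correlations λλᵀ give SRMR (RMS of below-diagonal residuals) and an
unweighted-least-squares χ² analogue (n−1 times the summed squared
residuals), from which RMSEA/CFI/TLI follow with the zero-correlation
independence baseline. Degrees of freedom count distinct correlations minus
free loading parameters (2PL: p(p−1)/2 − p; 1PL: p(p−1)/2 − 1), matching the
published layout (27/35 for nine items).

**Tetrachorics** fix thresholds at the normal quantiles of the margins and
solve the bivariate-normal correlation reproducing the observed 2×2 cell
probabilities (the ML solution for a 2×2 table); a zero cell triggers a
0.5-per-cell continuity correction with a warning, a zero margin is an
error. Tests cross-check against a brute-force grid MLE of the orthant
likelihood.

## Reliability and descriptive statistics

McDonald's ω is computed from the 2PL loadings, ω = (Σλ)²/[(Σλ)²+Σ(1−λ²)],
and reported alongside Cronbach's α on the raw 0–4 items. Note the published
ω = 0.96 is not exactly recoverable from the published discrimination
parameters: the closed form over those loadings gives ≈ 0.98. The basis of
the printed value (binary vs. five-category loadings) is unstated, so the
package reports what it computes and documents the difference rather than
matching it. Item-total correlations are reported in both variants —
including the item (the magnitudes conventionally tabulated) and the
corrected rest-score form. Skewness is the adjusted Fisher–Pearson
statistic with se = √[6n(n−1)/((n−2)(n+1)(n+3))] (0.054 at n = 2058,
printing as 0.05). The t-test is the pooled-variance Student form (the
published df of 2050 equals n₁+n₂−2). One-way ANOVA accepts raw data or
per-group (n, mean, SD) triples; the summary form reconstructs SSB/SSW
exactly, so published tables reproduce F and η² without raw data. Scheffé
post hocs use the pooled MSE at α = 0.05.

## Synthetic cohort generator

The generator exists so the pipeline is testable end-to-end. Each respondent
carries correlated traits (θ_dep, θ_anx) composed of treatment-status
offsets, a sex shift, a linear age effect and a bivariate-normal residual,
standardized to unit variance; the residual correlation is solved so the
total trait correlation equals the configured value (default 0.75, a free
knob chosen to put disorder co-occurrence in the reported range, not a
published quantity). Ordinal items follow a graded probit: the standardized
latent response (a·θ+ε)/√(1+a²) is cut at four per-item thresholds
back-solved from the published response-category percentages, with the third
threshold tied to the binary 2PL threshold ab/√(1+a²) — so dichotomizing at
"Most days" recovers the 2PL and the published endorsement rates by
construction. Impairment is probit in θ; the two instruments' impairment
answers share one uniform draw so that impairment co-occurs across scales.
PHQ-9/GAD-7 analogue items are generated from the same traits with their own
loading and cutpoints.

Calibrated defaults (chosen once against the published summary statistics
and then frozen): treatment-group θ offsets reproducing the group score
means; sex shifts targeting d ≈ 0.09 (IDQ) / 0.19 (IAQ); an age slope
targeting r ≈ −0.33; impairment intercepts/slopes putting diagnostic
prevalence near 7–8%; comparator cutpoints putting PHQ-9/GAD-7 caseness near
25%/21%. Default n = 2058, default seed 20200323; identical configurations
give byte-identical CSVs.

**What the generator does not emulate.** Items are conditionally independent
given the trait, so symptom clustering beyond a single dimension is absent;
as a result the co-occurrence of the two diagnoses (~50% of depression cases
also anxiety cases) and the overlap of comparator cut-off cases with
algorithmic cases are weaker than observed in the real sample (64–67% and
86–95%). Quota sampling, panel attrition and survey weights are not
simulated. Passing tests therefore demonstrate that the *machinery* is
correct under the stated model, not that the model captures every dependency
of the real data.

## Problem sizes in the validation studies

Parameter recovery uses 10 replicates of n = 5000 (recovery is judged on the
per-item average across replicates and on mean bias, since a single
replicate's sampling SE for a steep item's â is ~0.17). The LR-test study
uses cohorts of n = 1000 — null regime with a common a = 2 and the published
difficulties (200 replicates), alternative regime with the published
heterogeneous discriminations (800 replicates: the rejection rate there is
~0.96 and needs a Monte-Carlo SE well below one percentage point to be a
stable two-digit estimate). The tetrachoric oracle checks 100 random tables
of n = 200–1500 against a two-stage grid MLE (resolution 2.5e-5).

## Known limitations

* Parameter values are expected to agree with the published categorical
  WLS estimates approximately, not digit-for-digit; fit indices are ULS
  analogues.
* The LR test's finite-sample size at n = 1000 sits slightly above nominal
  (~5–8% empirically at α = 0.05).
* The published "met requirements for both disorders" figure is reported
  inconsistently at 4.8% and 4.6% in different places of the original
  account; the pipeline simply reports its computed value.
* Graded *estimation* (polytomous IRT), multidimensional models and
  measurement invariance are out of scope.
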