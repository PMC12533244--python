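# Methods note

This note records what each stage of `msverse` computes and why the modelling
choices were made the way they were. It is written for a statistically
literate reader who has not seen the code.

## 1. Synthetic cohort generator

The generator (`msverse.cohort`) produces an RRMS-trial-like cohort: default
85 subjects, scheduled visits at months 0, 6, 12, 18, 24 and a long-term
follow-up at month 144, baseline demographics, serum markers, SF-36
quality-of-life items and MRI summaries.

**Membership model.** Each subject receives two latent binary risk labels
(disability decline, processing-speed decline) from a logistic model on
z-scored baseline predictors. The configurable coefficient dictionary is the
"planted truth"; the intercept is calibrated by bisection so that the mean
membership probability equals the configured prevalence (0.42 for disability,
23/85 for speed). Calibrating the intercept rather than thresholding keeps
labels stochastic, so downstream logistic fits face realistic label noise.

**Trajectories.** EDSS and PASAT follow linear subject trajectories:
baseline score + (base slope + excess slope × risk label + subject-level slope
deviation) × years + visit noise, then rounded and clipped to the instrument
grids (EDSS 0–10 in 0.5 steps, PASAT 0–60 integers). Default parameters were
fixed once, before any validation run:

- EDSS: visit noise SD 0.4 (≈ one rating step of short-term variability),
  slope heterogeneity SD 0.02/yr, base slope +0.02/yr, excess slope
  **+0.10/yr** — roughly one EDSS point over the 12-year follow-up, matching
  the magnitude the progression rule is designed to detect.
- PASAT: visit noise SD 3.0 (a few points of session-to-session variability,
  small relative to the 0–60 range), slope heterogeneity SD 0.15/yr, base
  slope −0.30/yr (mild practice/decline balance), excess slope **−0.52/yr** —
  ≈ 6 points lost by follow-up, near the 20 % relative-drop boundary for a
  typical baseline score.

Clipping to the PASAT grid produces a small, genuine attenuation of the
recovered excess slope (≈ −0.51 vs −0.52 configured). This is a property of
the measurement instrument, not an estimation bug, and is deliberately left
in place.

**Serum reliability.** Visit-level serum values are the subject's true
baseline value plus within-subject noise whose SD is a configurable fraction
of the between-subject SD. Defaults give test–retest ICC ≈ 0.92 for most
markers, ≈ 0.55 for vitamin D (seasonality-like instability) and ≈ 0 for
CHI3L1, so the reliability screen has a realistic positive control.

**Determinism.** All randomness flows from a master seed through named
substreams (`SeedSequence([seed, offset])`), so stages can be re-run
independently and reproduce byte-identical tables.

## 2. Screening

- **ICC**: one-way random-effects ICC(1,1), `(MSB − MSW)/(MSB + (k̄ − 1) MSW)`
  with k̄ the harmonic mean of per-subject repeat counts, which handles
  unbalanced designs and reduces to the classic estimator when balanced.
  Markers below the threshold (default 0.5) are excluded as `low_icc`.
- **Zero variance**: constant columns are excluded before VIF (a constant
  predictor makes VIF undefined and a logistic coefficient unidentified).
- **VIF**: `1/(1 − R²_j)` per predictor; the worst predictor with VIF ≥ 5 is
  removed and VIFs recomputed until the pool is clean. Ties break by pool
  order, making the screen deterministic. Exactly collinear columns are
  reported with infinite VIF rather than a numerical explosion.

## 3. Stratification and mixed-model validation

The EDSS and PASAT rules are implemented exactly as stated in the README. The
follow-up measurement is the visit inside a 128–156-month window closest to
month 144; subjects without a usable window (or with a zero PASAT anchor) are
returned as explicitly unclassifiable rather than dropped, so cohort
accounting stays visible. A baseline EDSS of 0.5 uses the 1.5-point
threshold (the "< 1.0" branch).

**Validation model.** Group labels should correspond to genuinely different
trajectories. This is checked with a random-intercept linear mixed model.
Fitting the naive `outcome ~ age × group + sex` pools two kinds of age
variation: within-subject aging (which carries the trajectory signal) and
between-subject baseline-age differences (which carry none, since baseline
scores are not age-graded in this design). The pooled estimator is therefore
attenuated. We use a Mundlak (within/between) decomposition,

```
outcome ~ age_within * group + age_mean + sex,   random intercept per subject
```

where `age_within` is age minus the subject's mean age and `age_mean` is that
mean. The `age_within:group` coefficient is the excess annual change of the
declining group, in outcome units per year — the quantity of scientific
interest — and recovers the configured excess slopes without bias (verified
at n = 3,000 and across seeds at n = 300).

## 4. Brain age

The brain-age model is an additive polynomial regression: each standardized
feature enters with its own degree (≤ 4), chosen by univariate validation MSE
on a 10 % split, and the joint model is then fitted by least squares. An
exactly rank-deficient design (duplicated or collinear features) is rejected
with the offending feature names.

**Age balancing.** Skewed reference age distributions bias brain-age models
toward the dense ages. `balance_age_distribution` equalizes equal-width age
bins (max/min occupied-bin ratio ≤ 1.2): rare bins are oversampled by convex
interpolation between a sampled member and its nearest same-bin age
neighbour (interpolated ages stay inside the observed span and receive no
noise; features receive small noise), and over-full bins are thinned —
without thinning, the ratio contract is unattainable whenever one bin holds
more than an equal share.

**Bias correction.** The usual regression-to-the-mean correction is
`Corrected BA = BA + (Age − (a + b·BA))`. Fitting `Age ~ a + b·BA` on
in-sample OLS training predictions is degenerate: OLS fitted values satisfy
cov(BA, Age) = var(BA), forcing a = 0, b = 1 and making the correction a
no-op. The slope and intercept are therefore estimated on 5-fold
out-of-fold predictions within the training split — still training-data
predictions, but carrying the realistic shrinkage the correction is meant to
undo. Corrected validation MAE beats raw MAE consistently on biased synthetic
reference data. The brain-age gap (BAG) is corrected BA minus chronological
age; groups are compared with Welch's t and Cohen's d (pooled SD) with a
normal-approximation CI.

## 5. Multiverse

The specification universe is every non-empty subset of the screened pool up
to `max_order`, crossed with the sex toggle; age and DMT-during-follow-up are
forced into every model. Enumeration order is deterministic (by subset size,
then lexicographic, sex off before on).

Each specification is fitted by maximum-likelihood logistic regression on the
specification's complete cases. Quasi-separation is flagged when a
standardized coefficient exceeds 15 in absolute value; non-converged or
separated fits are retained in the fit table (flagged) but excluded from
summaries.

Per-model panel:

- **McFadden pseudo-R²** = 1 − ℓ/ℓ₀, clipped to [0, 1].
- **AUC** via the midrank Mann-Whitney formula (ties count ½) — identical to
  pair counting but O(n log n), which matters at the robustness stage's 10⁵
  rows.
- **Brier score** = mean squared probability error.
- **Wald power** at the observed effect: per coefficient,
  Φ(−z₁₋α/₂ + |β̂|/SE) + Φ(−z₁₋α/₂ − |β̂|/SE); at the model level, a
  noncentral-χ² omnibus with noncentrality β̂ᵀV⁻¹β̂ (power = α when β̂ = 0).

Per-variable curve summaries: median OR, unscaled MAD of the ORs, median p,
and PORSD — the share of converged models containing the variable whose OR
lies on the same side of 1 as the median OR. Variables with PORSD ≥ 0.75 are
"reported". When the median OR is exactly 1 there is no modal side and PORSD
is 0.

## 6. Baseline tests

Group differences in baseline variables are estimated by OLS adjusted for age
and sex (sex only, when age itself is the outcome), with t-based CIs; ordinal
EDSS additionally gets median ± MAD and a Wilcoxon rank-sum test (exact for
small tie-free samples, midrank/continuity-corrected otherwise; the reported
W matches R's `wilcox.test`). Binary variables use Fisher's exact test with
the conditional-MLE odds ratio; tables with an empty margin are returned as
degenerate with p = 1 rather than erroring.

## 7. Robustness: CART synthesis and block comparison

Small cohorts cannot support saturated-vs-reduced model comparisons directly,
so the observed table is expanded by sequential CART synthesis (synthpop
style): variables are visited in order, the first resampled from its
marginal, each later one modelled by an unpruned decision tree (≥ 5
observations per leaf) on the previously synthesized variables, with synthetic
values drawn from the leaf's training donors. Without smoothing every
synthetic numeric value occurs in the training data — a deliberate property
that keeps values on instrument grids.

The default 100 iterations × 10,000 rows give Monte-Carlo error ≈ 0.3 % of a
standard deviation on marginal means. Note the method's intrinsic fidelity
limit: synthesized predecessor distributions shift leaf occupancy by
O(1/n_train), so with very small training samples the marginal reproduction
error is dominated by that method bias rather than sampling noise.

Four logistic models are compared on the synthetic sample: saturated, SF-36
block removed, MRI block removed, and forced covariates + consistently
significant variables only. Each reduced model is nested in the saturated
one, so likelihood-ratio tests are valid; AIC = 2k − 2ℓ and
BIC = k·ln n − 2ℓ with k counting the intercept.

## 8. Repository shape

Fit-shaped components are sklearn-style estimators with `fit`/`predict`/
`transform` and trailing-underscore fitted attributes (`BrainAgeRegressor`,
`SpecificationCurve`, `CartSynthesizer`, `ReliabilityScreen`, `VIFScreen`);
rule-like computations (stratification rules, tests, enumeration) are plain
functions, and thin module-level wrappers (`run_multiverse`,
`fit_brain_age`, …) cover the common one-shot paths. The CLI is a thin click
layer over the library; every run writes a manifest with the seed and
configuration needed to regenerate its outputs exactly.

## 9. Limitations

- Trajectories are linear with Gaussian noise; real EDSS dynamics are
  nonlinear and state-dependent. The generator aims at testability, not
  clinical realism.
- The PASAT excess slope is slightly attenuated by grid clipping (see §1).
- The LMM reports the within-subject age × group contrast; it is not
  comparable to a pooled cross-sectional age interaction.
- CART synthesis reproduces low-order structure well but is not a privacy
  mechanism and inherits small-sample leaf-occupancy bias.
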