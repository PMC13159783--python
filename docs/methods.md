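# Methods

This note documents the models implemented in `neomat`, the calibration of
the synthetic-data generator, the numerical choices, and the limits of
what the synthetic experiments demonstrate.

## Signal model and ingestion

A recording is a beat-interval series: beat times `t_i` (s, strictly
increasing) and cycle lengths `RR_i` (ms). Artifact cleaning flags beats
whose RR deviates from a centered 11-beat running median by more than 20%
(both thresholds configurable); this catches the doubled/halved intervals
produced by missed or spurious beat detections. Edge beats use shrinking
windows. Recordings are tiled into contiguous half-open windows of 30
minutes starting at the first beat; a window is retained when at least 80%
of its beats survive cleaning **and** at least 1000 clean beats remain.
The quality rule is a package definition — an explicit, testable stand-in
for "good-quality traces" — not a reproduction of any monitor vendor's
screening. Cleaning is idempotent in practice: after one pass the
remaining beats sit within the threshold of their local median.

## HRV feature bank

All variances use the population convention (denominator n), stated here
once so the identities below are exact.

* **Time domain** — mean_nn, sdnn, rmssd, sdsd, pnn20, pnn50 (pnnX =
  fraction of successive differences whose magnitude exceeds X ms).
* **Frequency domain** — Lomb–Scargle periodogram of the unevenly sampled
  RR series (no resampling), scaled so its integral over frequency equals
  signal variance in ms²; band powers by trapezoidal integration. Neonatal
  bands: LF 0.04–0.2 Hz, HF 0.2–2.0 Hz. Preterm infants breathe at
  ~40–80/min, so vagally mediated power sits far above the adult HF band;
  the bands are configurable. lf_hf_ratio is reported missing (with
  reason) when HF power is zero — never infinity.
* **Poincaré** — sd1² = ½⟨ΔRR²⟩ (second moment about zero), sd2² =
  2·sdnn² − sd1², floored at 0. With this convention sd1 = rmssd/√2 and
  sd1² + sd2² = 2·sdnn² hold exactly, which the tests assert at 1e-6.
* **Sample entropy** — m = 2, tolerance r = 0.2 × sd (absolute tolerance 0
  when the series is constant, where every template matches and the
  entropy is 0); Chebyshev distance, self-matches excluded,
  Richman–Moorman counting (N−m templates for both lengths). Verified
  exactly against an O(n²) brute-force counter.
* **DFA** — box ranges 4–11 (α1) and 12–64 beats (α2), linear detrending
  per non-overlapping box. Plain DFA overestimates α on the 4–11-beat
  range (uncorrelated noise reads ~0.62 rather than 0.5) because the
  expected detrended fluctuation deviates from the asymptotic power law in
  small boxes. We therefore apply the modified-DFA finite-size correction:
  F²(n) is divided by the *exact* white-noise response of the
  linear-detrend quadratic form, tr(MΣ)/n with Σ_jk = min(j,k)+1, and
  rescaled by n. The correction is analytic and data-independent;
  uncorrelated noise then scores α ≈ 0.5 and integrated noise α ≈ 1.5 at
  every box size.
* **Natural visibility graph** — nodes are beats placed at their beat
  *times* (not indices); two beats are linked when the chord between their
  RR values clears every intermediate value strictly. Strict inequality
  makes a constant series a path graph (ties block visibility). Segments
  longer than 1024 beats are subsampled deterministically (evenly spaced
  indices). Reported metrics: mean degree, degree SD, degree
  assortativity (undefined on degree-regular graphs, reported missing).

Every requested feature is always present in the output vector; degenerate
computations yield NaN plus a machine-readable reason code, so one bad
feature never drops a segment.

## FMA estimator

The target is PMA (weeks) at recording; the model fits on segment rows.

* **Sigmoid component** — "logistic regression" with a continuous age
  target is read as a generalized-logistic (bounded growth) regression:
  `FMA = A + (K − A)·expit(b₀ + wᵀz)` on standardized features, with the
  growth bounds A, K fitted inside the physiologic window [22, 45] weeks
  (trust-region least squares, analytic Jacobian, linear initialisation of
  the score through the logit link).
* **Forest component** — scikit-learn random forest (100 trees by
  default, fixed seed).
* **Ensemble** — equal-weight mean of the two components (configurable);
  predictions are convex combinations, hence bounded by the components and
  clipped to [22, 45]. Rows are sorted canonically before fitting so the
  model is invariant to input row order.
* **Feature selection** — a genetic algorithm over fixed-size feature
  subsets (tournament selection, union-resampling crossover, single-swap
  mutation, elitism). Fitness is the grouped 5-fold cross-validated MAE of
  the ensemble, computed with a reduced-size forest and memoized per
  subset for tractability; full grouped leave-one-patient-out CV is
  reserved for final evaluation. Both the "search 20, keep 15" and the
  direct fixed-size reading of the selection protocol are expressible via
  `subset_size`.
* **Aggregation** — per patient-week FMA is the median of that week's
  segment predictions, robust to unequal segment counts.

## ΔHRV trajectories and the mixed model

ΔHRV = PMA − FMA (positive = delay). Per patient, FMA outliers are removed
once with Tukey fences: [Q1 − 1.5·IQR, Q3 + 1.5·IQR], quartiles by linear
interpolation (type 7 — the most common default, stated for
reproducibility); fences are computed from the original values, so the
pass is idempotent by construction. Groups smaller than 4 pass through.

All retained observations with PMA in [32, 36] enter a linear
mixed-effects model (REML, statsmodels `MixedLM`):

```
delta_ij = β0 + β1·(PMA_ij − 34) + β2·IUGR_i + β3·BPD_i
           + β4·lesions_i + β5·PDA_i + b_i + ε_ij ,   b_i ~ N(0, σ_b²)
```

GA is deliberately not a covariate (it is already inside the FMA
estimate). Each patient's ΔHRV at 34 weeks is the conditional (BLUP)
prediction — fixed effects at the patient's covariates plus the estimated
random intercept; a marginal (population-line) prediction is available
behind a flag. Covariates are 0/1 indicators without centering. A singular
or non-converged fit falls back to fixed-effects OLS with an explicit
flag. Random slopes are available behind a flag but off by default, since
"patient as a random effect" identifies a random intercept.

## ASQ-3 scoring

Five domains of six items; yes = 10, sometimes = 5, not yet = 0 (domain
range 0–60). Domain abnormal iff score < 35 (communication) or < 25
(others). With one or two missing items the adjusted score is the mean of
answered items × 6 (the documented behaviour of the standard adjustment
tool); more than two missing items leave the domain unscored, which also
undefines the total. Total = sum of the five domains, abnormal iff ≤ 220.
Records completed outside 21–26 months of corrected age are flagged
non-analyzable. Scoring is monotone: upgrading any item response can never
lower a score or flip a flag from normal to abnormal (property-tested).

## Statistical tests and odds ratios

Because the biomarker is summarized as median (Q1; Q3), the default group
comparisons are rank tests — Mann–Whitney–Wilcoxon for two categories,
Kruskal–Wallis beyond — with Student's t / one-way ANOVA behind a
`parametric` flag. For combined sample sizes ≤ 20 the two-group test is an
exact permutation enumeration of the rank sum, which handles ties and
returns p = 1 for identical groups. Categorical associations dispatch to
Fisher's exact test on 2×2 tables with any expected count < 5, otherwise
chi-square (no continuity correction); the dispatch is a pure function of
the table and is recorded in the result. Outcome models are univariate
maximum-likelihood logistic regressions reported as OR with Wald 95% CI;
on a saturated 2×2 design the fitted OR equals the cross-product ratio.
Complete (or quasi-) separation is detected and returned as a flagged
infinite-OR sentinel. Multivariable adjustment is deliberately not the
default: with ~5% abnormal outcomes a multivariable fit would be anti-
conservative.

## Synthetic-data generator: what it emulates, and its calibration

The generator exists so that every stage is testable end to end without
monitor recordings. It emulates:

* **RR series** — baseline interval + LF and respiratory-band sinusoids +
  white Gaussian noise, with a configurable fraction of beats replaced by
  doubled/halved "ectopic" artifacts (simple, and detectable by the
  cleaning rule); `maturation_rr_config` makes baseline, overall
  variability, and both modulation amplitudes grow with PMA so the model
  stages can learn an age signal. No 1/f component by default (keeps
  analytic expectations for the feature tests; configurable).
* **Cohorts** — GA strata at 23.5 / 39.4 / 37.1% (<26, 26–<28, ≥28
  weeks), perinatal covariates as independent Bernoulli draws at published
  prevalences (male 0.515, BPD 0.34, PDA 0.652, lesions 0.28, tobacco
  0.106, …), ASQ follow-up at 66%.
* **Latent delay at 34 weeks** — per GA stratum, a quantile-pinned law
  through the published median and quartiles: 3.0 (2.3; 3.9), 2.3 (1.3;
  3.0), 1.3 (0.8; 2.4) weeks. The published quartiles are not
  log-symmetric, so the two log-scale spreads of the underlying two-piece
  log-normal are fitted separately below and above the median. The
  published stratum statistics and the published cohort median (2.3) are
  not jointly representable by smooth unimodal strata (see below), so the
  most mature stratum's quantile function carries one additional
  *derived* anchor — the probability level the cohort-median condition
  Σ w_s F_s(2.3) = ½ assigns to 2.3 within that stratum — with the
  two-piece shape kept as far above the median as possible and a short
  low-density segment just below the anchor. Every printed stratum
  quartile, every stratum median, and the cohort median are then exact
  simultaneously, with bounded log-normal tails. No distributional form
  is published; the construction is a package choice.
* **Complications and delay** — BPD and PDA are coupled to the delay as
  risk markers: P(complication | delay) = expit(a + slope·(delay − 2.3)),
  slopes 0.6 and 0.7 per week, with intercepts solved by quadrature over
  the delay mixture so the marginal prevalences (0.34, 0.652) are exact.
  Larger delays therefore carry higher complication probability,
  reproducing the observed delay differences by complication status
  (≈1-week median separation) without distorting the delay distribution.
  An additive-effect formulation (complication adds weeks of delay) was
  considered and rejected: any additive effect convolves the stratum laws
  and makes the printed quantiles unattainable exactly.
* **Trajectories** — delay(PMA) = delay34 · (1 + 0.15·(PMA − 34)): the
  delay grows with postnatal age, proportionally to its level (so a
  zero-delay infant stays on the identity line), plus white observation
  noise (default sd 0.3 weeks) on the delay scale.
* **ASQ outcomes** — per-domain logistic models in the latent delay.
  The personal-social domain carries tobacco and lesion effects at the
  published univariate ORs (9.57, 7.72) and a delay slope whose
  *conditional* value (0.862 per week) is calibrated so that the
  *marginal, univariate* per-week OR — the quantity actually reported by a
  univariate analysis — equals 2.05, and the marginal abnormality
  prevalence equals ~6.9%. The conditional slope exceeds ln(2.05) because
  odds ratios are non-collapsible: marginalizing over strong independent
  covariate effects attenuates a univariate slope. Other domains have no
  delay effect and intercepts at their observed prevalences. Item
  responses are synthesized to be consistent with the drawn domain score
  (full credit items first, one "sometimes" for a remainder of 5).

**The consistency anchor, and why it exists.** With the stratum medians
and quartiles pinned, the first stratum contributes F(2.3) = 0.25 (2.3 is
its printed Q1) and the middle stratum 0.5 (2.3 is its printed median),
so the cohort-median condition forces F(2.3) ≈ 0.66 in the ≥28-week
stratum — yet that stratum's printed Q3 is 2.4, so a smooth unimodal law
puts F(2.3) near 0.73–0.76 and the mixture median near 2.1–2.2 instead of
2.3. The published table is reconcilable only if ~9% of the most mature
stratum sits between 2.3 and 2.4 — a clustered subgroup the anchor
encodes explicitly. The anchor value is derived from the published
numbers, not fitted to any simulation output.

**Relative vs absolute delay in the end-to-end demo.** The study design
estimates FMA with a model trained on a *separate, uncomplicated*
reference population, so a cohort-wide maturation delay appears as a
positive ΔHRV offset. The bundled demo pipeline instead trains on the
same synthetic cohort it analyses (leave-one-patient-out); any
cohort-level mean delay is then absorbed into the regression target and
the resulting ΔHRV is centered near zero, measuring *relative* delay
only — between-infant contrasts (e.g. the PDA–delay association) remain.
The recovery studies therefore exercise the trajectory, mixed-model, and
outcome stages from generated FMA trajectories, which carry the absolute
calibration.

**What passing tests do not show.** The generator's RR series are
stationary within a recording, its covariates are mutually independent
given the stratum, ASQ responses have no reporting bias, and trajectories
are linear in PMA around 34 weeks. Real neonatal recordings are none of
these things; passing recovery tests demonstrates the *pipeline's*
correctness and calibration-recovery behaviour, not clinical validity.

## Problem sizes and numerics

The recovery studies use 200 cohorts × 500 infants for the odds-ratio
study and 1000 infants × 5 weekly visits for the trajectory study — large
enough that Monte-Carlo error (≈0.02 on the mean OR, ≈0.05 weeks on a
median) is small against the tolerances, and small enough to run in
minutes on one CPU. Demo pipeline runs use 30 infants. Other numerical
choices: RR intervals floored at 150 ms so beat times stay increasing;
sigmoid fit bounded in [22, 45] weeks with at most 80 Jacobian
evaluations; forest seeds fixed and rows canonically sorted for
order-invariance; GA fitness memoized per subset; derived seeds kept below
2³¹; the sample-entropy template distances and the Lomb–Scargle grid are
evaluated block-wise so memory stays bounded (a few hundred MB) on
30-minute segments.

## Known limitations

* The exact feature list, trained weights, and reported MAE of the
  original maturation model are out of scope; the package retrains on
  synthetic data, so absolute FMA accuracy is not comparable.
* Fisher's exact test is implemented for 2×2 tables only; larger sparse
  tables fall back to chi-square with a recorded note.
* BLUP interpolation assumes the random-intercept model; under strong
  per-patient slope heterogeneity the conditional prediction at 34 weeks
  absorbs slope misfit into the residual.
* The ASQ item synthesizer produces multiple-of-5 scores without missing
  items; missing-item adjustment paths are exercised by dedicated unit
  tests instead.
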