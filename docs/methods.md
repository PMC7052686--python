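# Methods

## Model and decision rule

The tool assumes that in healthy newborns the natural logs of IDUA activity
and heparan sulfate concentration are bivariate normal. The normative fit
estimates, with the usual sample moments (n−1 denominator), the log-scale
means and SDs of each analyte and the Pearson correlation ρ of the
standardized logs (equivalently, of the raw logs — standardization is
affine). The parameters are frozen at fit time: screening and simulation
never re-estimate them per batch, so a laboratory's decision boundary does
not drift with the composition of incoming batches.

A screened sample is standardized to (z₁, z₂) and called positive only if
z₁ < −3.62, z₂ > 1.90, and its squared Mahalanobis distance
(z₁² − 2ρz₁z₂ + z₂²)/(1 − ρ²) exceeds the squared radius of the
(1 − p)100% prediction ellipse. All three inequalities are strict: a point
exactly on a threshold or on the ellipse boundary is negative. This makes
boundary behaviour deterministic and matches the rule's "only if … falls
outside" phrasing. The three conditions are nested by construction — a BVNL
positive is always a joint-threshold positive, which is always positive
under each univariate rule — and the test suite asserts this nesting on
random point sweeps.

Normal probability plots (ordered values against standard-normal quantiles
at plotting positions (i − 0.5)/n, with the Pearson correlation of the
pairs as a straightness score) support the normality assumption on the log
scale. The (i − 0.5)/n positions are a common default; the choice is not
critical for a diagnostic plot.

## Ellipse radius: two variants

The prediction-region literature offers two radii for a future observation:

* `chi_square` (default): the (1 − p) quantile of χ² with 2 df, which for
  2 dimensions closed-forms to −2 ln p (≈ 32.236 at p = 10⁻⁷). This is the
  n → ∞ limit and the appropriate choice at n = 5000, where the
  small-sample correction changes the radius by ~0.4%.
* `f_prediction`: the exact bound for a future point given a normative
  sample of size n, 2(n² − 1)/(n(n − 2)) · F₂,ₙ₋₂(1 − p). It exceeds the
  χ² radius for every finite n and converges to it as n grows; the suite
  asserts the monotone gap shrinkage at n = 10, 100, 5000.

Which variant the original analysis used is not stated; both are provided
and selectable, and at the study's n they are operationally identical.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| z_idua_cut | −3.62 | standardized-log IDUA threshold (strict <) |
| z_hs_cut | +1.90 | standardized-log HS threshold (strict >) |
| ellipse_p | 10⁻⁷ | tail probability of the prediction ellipse |
| fp target | 10⁻⁸ | design false positive rate implied by the three conditions together |
| prevalence | 10⁻⁵ | MPS I incidence, ~1/100,000 live births |
| detection limits | 0.5 nmol/mg/hour, 1.0 ng/mL | assay floors; raw readings at or below are floored before the log transform so logs stay finite |

The standardized thresholds are taken as configuration: the raw-scale
protocol cut-offs (16.68 for IDUA, 90.00 for HS) cannot be converted to
standardized-log space without the source cohort's log-scale SDs, which are
not published. Values of exactly 0 or below are rejected rather than
floored — the floor is for small positive readings at the assay limit, not
for missing or negative data.

PPV is computed as Sens·Prev / (Sens·Prev + FP·(1 − Prev)). In the
rule-comparison table the PPV of a rule uses its empirical false positive
rate when false positives were observed, and otherwise the rate expected
under bivariate normality: the 10⁻⁸ design target for the BVNL rule, the
independence product Φ(z_idua_cut)·(1 − Φ(z_hs_cut)) for the joint rule
(justified by the near-zero measured correlation, r = 0.0934), and the
marginal normal tails for the single-analyte rules. The raw-scale Gifu
comparator has no normality-based fallback; a zero-false-positive rule with
no supplied theoretical rate is a configuration error. Sensitivity on a
cohort with no affected samples is reported as undefined (None), not 0
or 1. Percentages in exported tables are rounded to 2 decimals; raw
proportions are retained internally.

## Monte Carlo false-positive study

Healthy-newborn observations are simulated directly on the standardized
scale — a standard bivariate normal with correlation ρ (default 0.0934) —
which is mathematically identical to sampling the estimated raw-scale
log-normal and standardizing with the same frozen parameters, and
numerically cleaner. The default study size is 10⁸ draws, processed in
chunks (10⁶ by default) so the draws never materialize at once; a single
generator state carries across chunks, and because numpy's sequential
draws are independent of request partitioning, counts are identical for a
fixed seed whatever chunk size is used (asserted in the suite). All seeds
are explicit and recorded in outputs; there is no hidden global randomness.

Expected behaviour at the defaults: the IDUA-only rate estimates
Φ(−3.62) ≈ 1.473×10⁻⁴ (prints as 0.015%); the HS-only rate estimates
1 − Φ(1.90) ≈ 2.872×10⁻²; the joint rate estimates the bivariate orthant
probability ≈ 1.708×10⁻⁶, strictly below the independence product
4.230×10⁻⁶ because positive correlation penalizes the opposite-tail
quadrant; and the BVNL count at 10⁸ is Poisson with mean ≈ 1. One
published simulated rate (HS-only, 2.889%) differs from the exact normal
tail at 1.90 (2.872%) by more than Monte Carlo noise at n = 10⁸ — the
effective standardized threshold behind that figure evidently differed in
a late decimal. Thresholds here are treated as exact and the discrepancy
is documented rather than matched.

Affected-case distributions are not simulated: sensitivity is an empirical
proportion over the seven known cases, and no generative model for affected
biomarker pairs is warranted by seven points.

## Synthetic cohort generator

The source normative cohort (5000 newborns, Gifu Prefecture) is not
deposited; only raw means (IDUA 70.57 nmol/mg/hour, HS 45.12 ng/mL), raw
protocol cut-offs, the log-scale correlation and a scatter figure are
reported. The generator emulates that cohort:

* Logs are bivariate normal with correlation 0.0934; log-means are set to
  ln(target) − sd_log²/2 so the **raw arithmetic means** match the reported
  values.
* The log-scale SDs are calibration stand-ins, flagged as such in every
  manifest. sd_log_idua = 0.472 places the raw protocol cut 16.68 at the
  ≈ Φ⁻¹(12/5000) = −2.82 quantile, reproducing the observed ~12
  pseudo-deficiencies per 5000 from the distribution's own low tail — no
  mixture component is injected, mirroring the interpretation of
  pseudo-deficiency as the healthy distribution's tail rather than a
  separate population. sd_log_hs = 0.335 places the raw HS cut 90.00 at
  z ≈ +2.23, which keeps pseudo-deficient rows below the HS cut with
  per-row probability ≈ 99.4% (low IDUA pulls conditional HS slightly
  *down* under ρ > 0). A smaller HS spread relative to the cut is the
  feature that makes the second dimension discriminating; the exact SD is
  configurable and nothing downstream is tuned to it.
* Affected cases (default 7) have raw IDUA pinned exactly at the 0.5
  detection limit — where all confirmed cases sat — and raw HS drawn
  log-normally (log-mean ln 150, log-SD 0.3) truncated above the 90 ng/mL
  cut. Sub-floor jitter is not modelled. With the pin disabled, case IDUA
  is drawn uniformly between the detection limit and the protocol cut, a
  simple stand-in for non-floor-censored assays.

What passing tests on synthetic cohorts do **not** show: the generator is
exactly bivariate log-normal, so it cannot probe robustness to the heavier
empirical tails the real data show (the published IDUA-only rule saw 10
false positives among 5000 where normal theory predicts ~0.7, and three
real HS values sat above the ellipse). Results on synthetic cohorts
validate the decision machinery and its calibration under the model's own
assumptions, not the assumptions themselves. The seven real cases'
coordinates exist only as a figure and are not reproduced.

## Numerical and design notes

* Fitting requires ≥ 3 rows, strictly positive analytes and nonzero log
  variance in both columns; |ρ| ≥ 1 and invalid probabilities raise typed
  errors rather than propagating NaNs.
* The estimator surface follows scikit-learn: `BVNLScreen` exposes
  `fit`/`transform`/`predict`/`decision_function`/`get_params`, with fitted
  attributes trailing-underscored, so the screen composes with sklearn
  pipelines; `screen()` returns the full per-rule verdict table, and
  `BVNLScreen.from_model` rebuilds a fitted screen from a serialized model
  document.
* Verdict tables carry one positive/negative column per rule precisely so
  the nesting invariant is greppable in the artifact itself.
* Default problem sizes — 10⁸ simulation draws in the acceptance script
  and the large suite checks at 10⁶–10⁸ — match the published study scale
  while keeping a full run in the tens of seconds on one CPU.

## Known limitations

Two biomarkers only (no multi-analyte generalization); no genotype or
late-onset phenotype stratification; no assay-level modelling (batch
effects, measurement error, GAG assay variability); prevalence enters only
through the PPV formula, not as a decision input; the synthetic generator's
SDs are inferences from published tail counts, not measured values.
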