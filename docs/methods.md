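# Methods

## Scoring rubric

Raw attributes map to 1–5 scores by fixed bins (disease burden is a 0–5
count, one point per diagnosed condition among hypertension,
hyperlipidemia, diabetes, heart disease, head/ear trauma).  The bins are
left-closed/right-open on the real line; a rubric row ending in "more than
U" closes the preceding bin at U (e.g. occupational noise 86–90 dB(A)
scores 4, strictly above 90 scores 5).  This convention preserves the
integer labels of the source rubric while defining every real input.

Two rows need interpretation:

* **NRR.**  The printed rubric for the protector's noise-reduction rating
  is non-monotone (two bins score 4 and two score 5), which is internally
  inconsistent: more attenuation cannot mean more risk while non-use is
  also maximal risk.  The default is the monotone-decreasing correction —
  non-use 5, <5 dB 4, 5–10 dB 3, 10–15 dB 2, >15 dB 1 — with the printed
  mapping available via `nrr_rubric="as_printed"` for exact reproduction.
* **PPE use** is scored never=1 … always=5 exactly as printed, even though
  a protective behaviour scoring *up* with frequency is counter-intuitive;
  the positive published correlation of this item with hearing loss (0.374)
  indicates the original instrument was coded this way (plausibly because
  frequent users are those with the loudest jobs).  A `reverse_ppe_use`
  flag exists for sensitivity analyses.  PPE **awareness** is
  reverse-coded (very low awareness = 5), as printed.

Leisure noise level has no dB anchors and is accepted only as an ordinal
1–5 self-rating.  Missing raw fields are a hard error — the instrument has
no defined imputation.  Records with implausible tenure
(`work_experience > age − 10`) are scored but flagged with a warning.

## The index

OHLRA is the dot product of the nine item scores with positive weights; the
defaults are the indirect effects of the fitted path model (0.266, 0.227,
0.056, 0.064, 0.687, 0.660, 0.194, 0.147, 0.127), giving an attainable
range [1.2864, 12.14].  Weights are configuration, not constants: a
re-estimated set from `fit_path_model` can be supplied anywhere the
defaults are used.

Risk categories use half-open intervals with boundaries belonging to the
higher category: Low < 4.85 ≤ Moderate < 6.84 ≤ High < 7.59 ≤ Very high.
The published category table prints the directions inverted (e.g. "Low
≥ 4.85"), which contradicts its own ROC construction where higher scores
mean higher risk; the package follows the ROC logic, and assigns the
boundary to the upper class because the printed "Moderate 4.85 to 6.83"
places 4.85 in Moderate.

## Path model

Nine items load on three correlated latent factors — personal (A, WE, S,
D), noise exposure (ON, LN), protection (UPPE, NRR, APPE) — each with a
direct structural path to observed hearing loss.  This topology is implied
by the exact product relation between the published per-item "direct"
coefficients, per-group "total" coefficients, and per-item indirect
effects (indirect = loading × group path holds to 3 dp for all nine items).

Estimation is maximum likelihood on the covariance matrix: minimize
`F_ML = log|Σ| + tr(SΣ⁻¹) − log|S| − p` by L-BFGS-B with numerical
gradients.  Identification fixes latent variances at 1 (all loadings free,
as the source reports loadings for every item); latent correlations are
free.  Start values: loadings 0.7, paths 0.3, latent correlations 0.3,
residuals 0.5.  Residual variances are bounded below at 1e-6 (Heywood
cases clamp and warn rather than fail); convergence requires optimizer
success plus a small gradient norm, and failure sets a flag instead of
raising.  The model is fitted to the correlation matrix so the solution is
standardized directly; factors are oriented so outcome paths are
non-negative.  With p = 10 observed variables and 25 free parameters,
df = 30.  Fit indices follow the standard formulas (RMSEA, χ²/df, GFI,
AGFI, NFI, CFI, IFI) with the independence model (df = p(p−1)/2) as the
null.  The published χ² table cannot be reproduced exactly — it depends on
the raw records and the original software's model df, neither available —
so fit statistics are covered by formula-level tests and by structural
checks on the packaged correlation matrix (which in fact lands close to
the published values: RMSEA 0.085 vs 0.087, GFI 0.937 vs 0.942).

## ROC cut-offs

Positive class: hearing loss strictly above the threshold (25/40/60 dB HL).
The empirical ROC uses all distinct score thresholds with ties grouped.
The optimal cut-off minimizes the Euclidean distance to (FPR 0, TPR 1);
ties break toward the lower threshold, and the returned cut-off is the
midpoint between the adjacent distinct scores straddling the operating
point, so "score above cut-off" reproduces the chosen sensitivity and
specificity on the training data.  AUC is the Mann–Whitney pair statistic;
the 95% CI uses the Hanley–McNeil standard error (the original analysis
used SPSS's asymptotic nonparametric CI; the difference is immaterial at
these sample sizes).

## Synthetic cohorts

A Gaussian copula is the minimal model faithful to what was published:
only Pearson correlations plus a normality check, so the latent joint is
multivariate normal with the printed 10×10 correlation matrix (which is
positive definite as printed; a nearest-correlation repair via alternating
projections is available for user-supplied matrices).

* **Continuous mode** returns `z·sd + mean` per variable.  Hearing loss is
  clamped at ≥ 0 dB HL by default — audiometric thresholds below zero are
  not meaningful here — which shifts its mean/SD slightly (closed form:
  31.75/17.33 against latent 31.46/17.95) and attenuates its correlations
  by < 0.005.  The clamp can be disabled
  (`clamp_hearing_loss_at_zero=False`) when an exactly Gaussian outcome is
  required, e.g. for closed-form cross-checks; clamping to the observed
  range [10, 67.26] is off by default because it would bias the moments.
* **Discrete mode** thresholds each item's latent normal onto its
  rubric-legal grid (composites on {t·l/5}), shifting the thresholds by a
  common offset solved so the expected discretized mean matches the target
  mean.  The fidelity contract is the mean (within ±0.05), not the full
  marginal histogram, which was never published; correlations attenuate
  mildly under discretization and this is accepted, not corrected.
* **Raw records** invert the rubric: each discrete score samples a raw
  value uniformly inside its bin (values floored, not rounded, at the
  reported precision so they cannot cross a bin edge), composites sample a
  (duration, level) factor pair uniformly among those realizing the
  product.  Re-scoring a generated record reproduces its item scores
  exactly, which is the round-trip contract the tests enforce.

Synthetic cohorts reproduce second-order structure only.  They do not
emulate audiometric or dosimetry measurement error, non-Gaussian tail
behaviour, or any raw-data feature beyond the printed moments — so
passing replication on them validates the *machinery*, not the original
measurement campaign.  The default fixture seed is 20241117.

## Replication on synthetic cohorts: what matches and what does not

With the published weights and the packaged moments:

* the closed-form share of hearing-loss variance explained by the index is
  70.1%, agreeing with OLS on a 10⁶-worker simulated cohort to ~0.1 point;
  the original raw-data regression reported 74%.  The ~4-point gap is
  consistent with rounding of the printed moments and is surfaced, not
  hidden: both numbers appear in every validation report.
* ROC cut-offs on 10 replicate cohorts (n = 10,000, continuous mode)
  average ≈ 5.24 / 6.16 / 7.42 against the published 4.85 / 6.84 / 7.59,
  with AUCs ≈ 0.907 / 0.908 / 0.948 against 0.922 / 0.937 / 0.952.  The
  25 and 60 dB quantities and all three AUC levels replicate closely; the
  40 dB cut-off sits ≈ 0.7 low, and the 25-vs-40 dB AUC ordering is a coin
  flip because the two values are nearly equal under the Gaussian moment
  model.  Diagnostics (the printed AUCs match full-sample dichotomization,
  not alternative constructions) indicate this is a genuine limit of what
  the rounded printed moments determine, not an implementation artifact;
  the corresponding acceptance tests are left failing by design rather
  than loosened.

Problem sizes used throughout (10 seeds × 10,000 workers for ROC; 10⁵–10⁶
for moment checks; 20 replicates of n = 10,000 for path-model parameter
recovery) were chosen as the smallest that hold Monte-Carlo error well
below the comparison tolerances.

## Known limitations

* The rubric's NRR row is reconstructed (see above); exact-reproduction
  mode exists but is not the default.
* The path model treats ordinal item scores as continuous, as the original
  analysis did; no WLSMV/robust estimation is provided.
* p-values and bootstrap standard errors for the effect decomposition are
  out of scope — they depend on the raw sample.
* Real-data users must decide how to collapse per-ear audiometry into one
  hearing-loss value (the convention here is the mean across ears); the
  synthetic cohorts generate a single scalar and so do not exercise that
  choice.
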