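# Methods

## The measurement model: from chromogens to a MetaSite score

A triple-immunostained section shows three chromogens: blue (CD31,
endothelium), brown (CD68, macrophages) and red (Mena, tumor cells).
Under the Beer–Lambert law a pixel with chromogen concentrations
`c ∈ R³` transmits intensity `I = I₀ exp(−c·B)` per RGB channel, where
`B` is the 3×3 stain matrix (unit-norm optical-density row per
chromogen).  The default `B` uses published-style vectors
(hematoxylin-like blue, DAB-like brown, AEC-like red; condition number
≈ 21); any nonsingular matrix below a configurable condition-number
bound is accepted.

Unmixing inverts this: `OD = −log((I+1)/256)`, `c = OD·B⁻¹`, negatives
clipped to zero with a QC counter.  The synthetic renderer emits both the
8-bit image and the exact float transmission `I = 256·exp(−OD) − 1`, so
on the float path mix→unmix is an exact linear inversion (max error at
machine precision); on the quantised 8-bit path the OD error is ~1/255,
far below the segmentation threshold.

Segmentation is deliberately classical and deterministic: Gaussian
smoothing (0.75 µm SD), fixed OD threshold (0.25), morphological opening
(1 px), connected components, minimum area 10 µm².  A TMEM is any
(tumor, macrophage, endothelial) triple whose three masks are pairwise
within the contact radius (default 2 µm, as nearest mask-pixel
distance); every distinct qualifying triple counts once, with an
optional cluster mode that merges triples sharing two member cells.  The
MetaSite score is the sum of the three largest per-field counts (all
counts if fewer than three fields; rank ties break by field id and never
affect the sum).

The synthetic slide generator plants TMEM triples with pairwise boundary
gaps of a quarter contact radius and keeps every other structure at
≥ 40 µm separation (> 2× contact radius), so planted truth is
unambiguous by construction: planted triples must satisfy the contact
predicate, isolated cells cannot.  Fields default to 665×500 µm at
0.5 µm/px — a configurable stand-in for a 20X field of view, not an
inferred value.  What the generator does *not* emulate: tissue texture,
nuclear counterstain, stain heterogeneity, out-of-focus blur, section
artifacts, or learned cell classification.  Passing recovery tests
therefore show the pipeline is correct under its own imaging model, not
that it reproduces a commercial assay on real tissue.

## The survival model

The analysis sample is a case-enriched two-phase subsample: strata are
recurrence status (optionally crossed with covariates), each stratum is
sampled without replacement at a known fraction `f`, and each selected
patient carries weight `1/f`.  Sampling is fixed-size (`round(f·N)` per
stratum) rather than Bernoulli so weighted totals reproduce stratum
sizes exactly.

Estimation follows the standard weighted-partial-likelihood approach for
such designs:

* **Weighted Kaplan–Meier**: `S(t) = Π (1 − d_w(t)/n_w(t))` with
  weighted event and at-risk totals; supports delayed entry.
* **Weighted Cox** over counting-process episodes `(start, stop]`,
  Newton–Raphson with step halving on internally standardised
  covariates; convergence at max |score| < 1e−8 or relative
  log-likelihood change < 1e−10; Efron ties by default (Breslow
  available).  Estimates diverging beyond 8 log hazard ratios per
  covariate SD raise a separation error rather than returning a
  plateau artifact.
* **Corrected variance**: per-episode score residuals (martingale
  integral of `x − x̄(t)` with the weighted risk-set mean and weighted
  baseline-hazard increment, Efron-adjusted within tied blocks) are
  summed within subject, so episode splitting never inflates the
  variance; the sandwich is `D'D`, `D = (w ⊙ U) I⁻¹`.  No
  finite-population correction is applied.  The implementation matches
  `survival::coxph` (coefficients, naive SE, robust SE, score
  residuals) to ~1e−10 on weighted, tied data.
* **Time-varying coefficients**: episodes are split at every event time
  and the interaction `t·x` (with `t` the stop of each risk interval)
  is added; the 2-df robust Wald on `(β_x, β_{t·x})` is the overall
  association test and the 1-df Wald on the interaction is the
  proportionality test.  Wald (not likelihood-ratio) forms are used
  throughout, consistent with the robust covariance.
* **Windows**: years 0–5 = administrative censoring at 5; years 5–10 =
  delayed entry at 5 among subjects still at risk.
* **Group-difference p-values for KM displays** come from robust Wald
  tests of group indicators in a weighted Cox model; the classical
  log-rank is not valid under outcome-dependent weighting.

Risk-set sums use difference arrays over the sorted event times, so one
likelihood evaluation is O(n·p² + T·p²); the large episode-split fits in
the calibration studies run in milliseconds.

## The cohort generator

Defaults emulate the structure of an adjuvant-chemotherapy trial cohort:

* n = 2952; subtypes HR+/HER2− 65%, triple-negative 20%, HER2+ 15%.
* MetaSite score: zero-inflated negative binomial (inflation 0.12, size
  0.8, capped at 199) with subtype means 16.1 / 23.8 / 26.2 — integer,
  heavy right tail.
* Recurrence Score: gamma marginals per subtype (HR+ centered low,
  triple-negative almost entirely > 30, HER2+ high), linked to the
  MetaSite score through a Gaussian copula.  The latent correlation
  (0.33) was calibrated once by large-n simulation so the raw Pearson
  correlation in the HR+/HER2− subset is ≈ 0.29.
* First recurrence from a piecewise-exponential proportional-hazards
  model by exact inverse-CDF sampling: the score's log hazard is
  `β_early` up to year 5 (default 0.015, HR+/HER2− only) and `β_late`
  after (default 0); baseline hazards 0.004 / 0.014 / 0.009 per year
  give ≈ 18% 10-year recurrence overall; covariate effects (nodal
  status 0.4, size > 2 cm 0.4, grade 0.5/1.0) on the same hazard.
* 70% of first recurrences are distant; breast-cancer death follows a
  distant recurrence with an exponential lag (rate 0.35/y);
  other-cause death is an independent exponential (0.012/y);
  administrative censoring at 10 years.
* Endpoints follow STEEP conventions: DRFI is censored at a first
  locoregional recurrence (later distant events are not recorded), RFI
  counts any first recurrence, BCSS censors other-cause death.

Limitations of the emulation: no treatment-arm effect, no delayed-entry
accrual patterns, no dependence between censoring and covariates, no
recording of post-locoregional distant events, and the real trial's
sampling strata and fractions are not public — the sampling design
object is generic.

## Study-level analyses

* **Weighted tertiles**: cutpoints are the smallest integers whose
  weighted CDF reaches 1/3 and 2/3 (reproducing integer-boundary groups);
  heavy ties collapse with a warning instead of splitting a tied value.
* **Group comparisons**: design-based Wald chi-square on weighted means
  or proportions with Horvitz–Thompson linearization variances.
* **Correlation**: raw Pearson on untruncated, unweighted values;
  truncation at 50 affects only scatter plots (a weighted variant exists
  behind a flag).
* **Recurrence-Score categories**: classical < 18 / 18–30 / > 30 and
  TAILORx < 11 / 11–25 / > 25, boundary values inclusive in the middle
  band.
* **Multivariate models** (HR+/HER2−, 0–5-year window): all include
  nodal status, tumor size coded as an indicator for > 2 cm, and grade
  (two dummies vs low, joint 2-df p); model 1 adds continuous MetaSite
  score, model 2 continuous RS, model 3 continuous MetaSite score plus
  categorical RS (joint 2-df p).  No multiplicity adjustment; all tests
  two-sided at 0.05.
* **Subgroup hazard ratios**: high- vs low-tertile weighted Cox within
  each RS category; cells with a zero-event arm return a flagged
  "too few recurrences" row.
* **Power by simulation**: cohorts are generated with the target
  high-vs-low tertile log hazard ratio applied log-linearly across
  tertile groups, subsampled per design, and tested with the robust
  Wald at α.

Report tables round only at serialization (`%.10g`), never internally;
rerunning with one config and seed is byte-identical.

## Validation experiment sizes and observed behavior

The acceptance experiments use: 50 random layouts for detector-oracle
agreement; 50 fields / 20 slides for planted-truth recovery; 50 random
≤ 30-row weighted instances for the likelihood-maximiser oracle; 500
subsample redraws for Horvitz–Thompson unbiasedness; 200 cohorts of
n = 600 (all HR+, baseline hazard 0.03 so each fit has ~100 events, no
covariate effects) for early/late effect recovery; 1000 null cohorts of
n = 800 for Wald-test size; 1000 simulations for power at the null.

Two small-sample properties are worth knowing.  The robust sandwich CI
runs slightly below nominal coverage with this heavy-tailed score
covariate (true coverage ≈ 0.94 at ~100 events; the same behavior is
obtained from R's implementation), and the 2-df robust Wald is
anticonservative in small samples (size ≈ 0.09–0.11 at n = 250,
≈ 0.06 at n = 800).  The calibration experiments therefore use cohort
sizes where the asymptotics hold; at very low event counts the tertile
power test is conservative instead (size ≈ 0.02 with ~25 events).
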