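# tmemscore

Tumor MicroEnvironment of Metastasis (TMEM) scoring of triple-chromogen
IHC images, and the weighted two-phase survival analysis that links that
score to breast-cancer recurrence — implemented end to end on synthetic
slides and synthetic cohorts with known ground truth.

TMEM are microanatomic structures in which a Mena-expressing tumor cell, a
CD68⁺ macrophage and a CD31⁺ endothelial cell are in direct mutual
contact; they act as intravasation doorways for tumor cells and their
density in a primary tumor is a candidate metastasis biomarker.  The
slide-level **MetaSite score** is the sum of TMEM counts from the three
highest-count fields of view.  Cohort studies of such biomarkers are
typically run on a *case-enriched* subsample of a trial (every relapsing
patient, a fraction of the others), so estimation must weight each patient
by the inverse of their sampling fraction and replace the naive Cox model
variance with a score-residual sandwich.

## What is inside

| module | contents |
| --- | --- |
| `tmemscore.slide_sim` | synthetic 20X fields with planted cells and TMEM triples, Beer–Lambert rendering, TIFF/PNG + ground-truth JSON output |
| `tmemscore.imaging` | chromogen unmixing (`c = OD·B⁻¹`), cell segmentation, triple-contact detection, top-3-field MetaSite scoring |
| `tmemscore.cohort_sim` | trial-like cohorts: subtype mixture, zero-inflated negative-binomial scores, copula-linked Recurrence Score, piecewise-hazard recurrence, STEEP endpoints (DRFI/RFI/OS/BCSS), stratified case-enriched subsampling |
| `tmemscore.survival` | `WeightedCoxPH` / `WeightedCoxResults`: weighted partial likelihood (Efron/Breslow), score residuals, robust sandwich covariance, episode splitting, follow-up windows, time-varying coefficient tests, weighted Kaplan–Meier |
| `tmemscore.analysis` | weighted tertiles, design-based group comparisons, score–RS correlation, the three multivariate model specifications, subgroup hazard ratios by RS category, power by simulation, full report |
| `tmemscore.cli` | `tmemscore simulate-slide / simulate-cohort / score / fit / report / power` |

The statistical model at the core is the weighted Cox proportional-hazards
model over counting-process episodes `(start, stop]`: coefficients maximise

```
ℓ(β) = Σ_events w_i [ x_i'β − log Σ_{j ∈ R(t_i)} w_j exp(x_j'β) ]
```

and the reported ("corrected") covariance is the sandwich
`D'D` with `D = (w ⊙ U) I⁻¹`, where `U` holds subject-level score
residuals and `I` the weighted information.  The implementation is
validated against R's `survival::coxph(..., weights, robust=TRUE)` to
~1e−10 and against brute-force likelihood maximisation.

## Worked example

Score a synthetic slide with known planted truth:

```bash
$ tmemscore simulate-slide --fields 4 --triples-per-field 5,3,7,2 --seed 7 --out slide/
wrote 4 fields to slide/; true counts [5, 3, 7, 2]
$ tmemscore score --manifest slide/manifest.csv --out scored/
MetaSite score 15
```

15 is the sum of the three highest per-field TMEM counts (7 + 5 + 3); the
detector recovered every planted count exactly.

Run the full synthetic study (generate a 2952-patient cohort, draw the
case-enriched weighted sample, run every analysis):

```python
from tmemscore import AnalysisConfig, run_full_analysis
report = run_full_analysis(AnalysisConfig(seed=5))
print(report.window_fits.round(4))
```

```
            subset endpoint  early_coef  early_p  late_coef  late_p  tv_overall_p  tv_proportionality_p
0          overall     drfi      0.0059   0.0122     0.0035  0.2502        0.0456                0.4777
...
4       hr_her2neg     drfi      0.0128   0.0061     0.0093  0.1815        0.0256                0.7528
5       hr_her2neg      rfi      0.0116   0.0060     0.0064  0.3189        0.0433                0.8974
```

The generator plants a positive log hazard per score unit only in years
0–5 and only in the HR+/HER2− subtype; the weighted analysis recovers
exactly that pattern — a significant early-window coefficient in
HR+/HER2− (0.0128, p = 0.006 for DRFI), nothing significant late, and a
significant 2-df time-varying association test.  The same report carries
the weighted tertile cutpoints, descriptive tables, the raw score–RS
Pearson correlation (≈ 0.28–0.30 by construction of the copula), the
three multivariate Cox specifications and the subgroup hazard-ratio
tables; sparse subgroup cells are flagged "too few recurrences" rather
than fitted.

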