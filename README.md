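# ibris

Image-based risk score (IbRiS) for estrogen-receptor-positive,
lymph-node-negative invasive breast cancer: quantitative histomorphometry of
segmented H&E tumor tiles, LASSO-Cox survival modeling, and optimal-cutpoint
risk stratification — with a synthetic phantom-cohort generator so the whole
pipeline can be exercised end to end without whole-slide images.

## Who this is for

Computational-pathology researchers who have (or can emulate) per-patient
tumor tiles with nuclei label masks, mitosis detections, tubule and
epithelium masks, plus a cohort table with disease-free survival (DFS), and
who want an auditable, lockable prognostic model built from interpretable
morphology rather than a black box.

## The method

The pipeline measures the three Nottingham grading axes computationally:

1. **343 patient-level features** — 242 nuclear morphology (shape,
   Voronoi/Delaunay/MST architecture, cell cluster graph, cell orientation
   entropy, Haralick chromatin texture), 45 mitotic activity (counts,
   count-to-nuclei ratios, density bins, a proliferation hotspot score) and
   56 tubule formation (tubule-nuclei ratios, area fractions, interval
   histograms), aggregated from tiles to patients by nine statistics
   (mean, median, max, sum, SD, skewness, kurtosis, histogram entropy,
   approximate entropy).
2. **Screening** — a univariable Cox model per feature; the top four by
   Wald p within each of the three families give 12 candidate features.
3. **Ensembling** — a LASSO-regularized Cox model over the z-scored 12,
   with the penalty chosen by 5-fold cross-validated partial likelihood,
   yields the continuous risk score s = Σ β_j z_j.
4. **Dichotomization** — a training-derived cutpoint θ_opt (maximal
   log-rank separation within the 20th–80th percentile band) splits
   patients into high (s > θ_opt) and low (s ≤ θ_opt) risk.
5. **Evaluation** — Kaplan-Meier curves, two-sided log-rank tests, uni- and
   multivariable Cox hazard ratios with Wald 95% CIs, Lin's concordance,
   and subgroup analyses within recurrence-score categories (low < 18,
   intermediate 18–30, high > 30) and histologic grades.

See `docs/methods.md` for every definition, default, and design choice.

## Worked example

```python
import numpy as np
from ibris import PhantomConfig, simulate_cohort, extract_features, IbrisModel

cfg = PhantomConfig(n_patients=120, tiles_per_patient=1, tile_side_px=112,
                    nuclei_density=25, nucleus_radius_px=5.0,
                    planted_effect={"mitotic": 1.0}, censor_rate=0.2, seed=7)
train = simulate_cohort(cfg)                      # tiles + masks + DFS outcomes
fm = extract_features(train)                      # 120 x 343 feature matrix
t = np.array([c.dfs_time for c in train])
e = np.array([c.event for c in train])
res = IbrisModel(fm, t, e).fit(seed=0)            # screen -> LASSO-Cox -> theta_opt
print(res.summary())
```

```
Image-based risk score (LASSO-Cox)
==========================================================
n = 120    events = 92    lambda = 0.06808    folds = 5
theta_opt = 0.2989   (high risk iff score > theta_opt)
----------------------------------------------------------
feature                               family         coef
nuc:shape_fsd5_minmax_ratio           nuclear      0.0514
nuc:arch_density_quadrant_disorder    nuclear     -0.1378
...
mit:count_max                         mitotic      0.5240
...
6 non-zero of 12 selected features
```

The cohort plants a log-hazard of 1.0 on the latent mitotic phenotype, and
the fitted model finds it: the dominant coefficient sits on a mitotic-count
aggregate. Scoring an independent 60-patient phantom cohort:

```
held-out: n_high=13, HR=3.33 (95% CI 1.62-6.85), log-rank p=0.00055
```

so held-out patients called high-risk recur about three times faster, and
the separation is far beyond chance. `res.save(path)` locks the model
(features, coefficients, standardization, θ_opt, catalog hash) as JSON;
`ibris.io.load_model` refuses matrices built from a different catalog
version.

The same workflow is available from the shell:

```sh
ibris simulate --config cfg.yaml --out cohort/ --seed 7
ibris extract cohort/ --out features.csv
ibris fit features.csv cohort/manifest.csv --out model.json --seed 0
ibris predict model.json features.csv --out preds.csv
ibris evaluate preds.csv cohort/manifest.csv --by odx
```

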