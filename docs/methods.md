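# Methods

## Scope and model

`ibris` implements a quantitative-histomorphometry prognostic pipeline for
estrogen-receptor-positive, lymph-node-negative invasive breast cancer. The
inputs are per-patient sets of H&E tumor tiles with companion segmentation
products (a nuclei label mask, a mitosis point list, a tubule mask, an
epithelium mask) and a cohort table with disease-free survival (DFS) and
clinical covariates. The pipeline measures the three Nottingham axes
computationally — nuclear pleomorphism, mitotic activity, tubule formation —
as 343 patient-level features, screens the four most prognostic features per
axis with univariable Cox regression, ensembles the resulting 12 features in
a LASSO-regularized Cox model into a continuous image-based risk score
(IbRiS), and dichotomizes the score at a training-derived optimal cutpoint
θ_opt into high (score > θ_opt) and low (score ≤ θ_opt) risk groups. The
package does not perform segmentation itself; upstream deep-learning
detectors are out of scope, and the phantom generator stands in for them.

## The 343-feature catalog

The catalog is frozen, ordered, and versioned by a content hash recorded in
every locked model. Family allocation:

* **Nuclear (242).** 25 per-nucleus shape descriptors (area, perimeter,
  equivalent diameter, major/minor axis, elongation, eccentricity,
  solidity, extent, convexity, circularity, bending energy, radial-distance
  mean/SD/ratio, boundary smoothness, and the first nine non-DC Fourier
  magnitudes of the radial signature normalized by the DC term) × four
  across-nucleus statistics {mean, SD, median, min/max ratio} = 100;
  51 architecture statistics of the centroid point pattern (Voronoi cell
  area/perimeter/chord, Delaunay side/area, MST edge length, k-NN distances
  for k ∈ {3,5,7}, neighbor counts within 10–50 µm, density and quadrant
  density); 26 cell-cluster-graph (CCG) metrics; 39 cell-orientation-entropy
  (CORE) statistics (13 co-occurrence statistics × {mean, SD, disorder});
  26 Haralick chromatin statistics (13 × {mean, SD}). The per-family counts
  within the 242 are a reconstruction consistent with the published totals;
  the source publications of each family guided the descriptor lists.
* **Mitotic (45).** Nine aggregators of the per-tile mitotic count (9);
  nine aggregators × three ratios (mitoses/epithelial nuclei, mitoses/
  blue-ratio nuclei, mitoses/all nuclei) (27); the proportion of tiles in
  eight mitotic-count bins {0}, [1,2], [3,5], [6,10], [11,20], [21,50],
  [51,100], >100 (8); a proliferation score (1).
* **Tubule (56).** Nine aggregators × three tubule-nuclei ratios (27); nine
  aggregators of the tubule area fraction (9); proportions of tiles in ten
  equal-width intervals of the tubule/all ratio and of the area fraction
  (10 + 10). Tile counts are normalized to proportions so patients with
  different numbers of tiles are comparable.

The nine aggregators are mean, median, max, sum, SD, skewness, kurtosis,
histogram entropy (Shannon entropy, natural log, of a 10-bin histogram over
[min, max]) and approximate entropy (Pincus, m = 2, r = 0.2·SD, computed on
the row-major tile ordering so it is deterministic and spatially
meaningful). Applying all nine aggregators to every base descriptor would
overshoot the published total, so nuclear tile descriptors are aggregated
across tiles by the mean only, while the full nine-statistic scheme is
applied within the mitotic and tubule families, whose base-descriptor
arithmetic (9+27+8+1 and 27+9+20) reproduces the printed family totals
exactly. This is the central reconstruction assumption of the catalog.
Moments are population moments; n = 1 falls back to 0 for SD, skewness,
kurtosis and both entropies. Families undefined on a degenerate tile (fewer
than 4 nuclei, no CCG edges) are flagged NA and excluded from that
patient's aggregation rather than zero-filled.

## Feature definitions and numerical choices

* Geometry is computed from central second moments of pixel coordinates
  (with the 1/12 per-pixel correction); axis lengths are 4·√eigenvalue,
  matching the filled-ellipse convention. Orientation is the major-axis
  angle in [0, π) in the rotation sense of (row, col) rasterization;
  circular nuclei get orientation 0. Boundaries are 0.5-level
  marching-squares contours; the radial signature is resampled to 32 points
  by arc length before Fourier analysis and curvature estimation. Labels
  smaller than 3 px are discarded.
* Pixel pitch is fixed at 0.25 µm/px (×40); all architecture/CCG distances
  are in µm. The disorder statistic is SD/(mean+SD) throughout.
* The CCG is deterministic: edge (u,v) iff d(u,v)^(−α) > r with α = 0.5 and
  default r = 0.16 µm^(−0.5), i.e. nuclei closer than ≈39 µm are linked.
  The threshold was chosen so that tiles at the canonical density yield
  sparse graphs with a non-trivial component structure; both parameters are
  configurable. Metrics with no defined value on an empty edge set
  (clustering, path lengths, spectral quantities, …) are 0 by convention;
  an all-identical point pattern is an error. Diameter, radius and path
  statistics are measured on the giant component, eccentricities within
  each node's own component; betweenness is normalized by pair count.
* CORE builds, for each CCG node's closed neighborhood, an 18-bin (10°)
  co-occurrence matrix of edge-endpoint orientations expressed relative to
  the central nucleus, so rotating all nuclei together is a no-op. The 13
  second-order statistics are the Haralick set (energy, entropy, contrast,
  inverse difference moment, difference average/variance/entropy, sum
  average/variance/entropy, correlation, and the two information measures
  of correlation), evaluated with natural logarithms; they are shared with
  the chromatin-texture family.
* Haralick chromatin texture uses ITU-R 601 luminance quantized to 32 gray
  levels on a fixed 0–255 scale, a symmetric GLCM averaged over the four
  offsets (0,1), (1,0), (1,1), (1,−1), restricted to pixels inside the
  nucleus; nuclei with fewer than 9 interior pixels are skipped.
* The blue-ratio transform is BR = (100·B/(1+R+G)) · (256/(1+R+G+B)),
  thresholded by Otsu, with nucleus-sized components (3 px to 5000 px)
  counted. Ratios with a zero denominator are 0 when the numerator is 0 and
  NA otherwise; NA tiles are excluded from aggregation.
* The proliferation hotspot is the contiguous 2×2 block of tiles with the
  largest mitosis total (exhaustive block scan; a slide smaller than one
  block uses its covered area). The summed count is rescaled to the
  reference block area (2×2 tiles of 2000 px ≈ 1 mm², roughly ten
  high-power fields) and mapped through Nottingham-style cutoffs ≤7 → 1,
  8–14 → 2, ≥15 → 3. Bin edges and cutoffs are configurable; they are a
  plausible reconstruction, not published values.

## Model fitting

Screening fits a univariable Cox model per z-scored feature (custom
vectorized Newton solver, Breslow ties; ties are measure-zero in the
simulated data) and ranks by Wald p, breaking ties by |z| then name;
constant features are skipped and at least 10 events are required. The
LASSO-Cox ensemble (scikit-survival's coxnet path) z-scores the 12 screened
features with training statistics that are stored in the locked model; the
penalty is chosen by 5-fold cross-validated held-out Breslow partial
likelihood over the path, restricted to penalties retaining at least one
non-zero coefficient so the locked model always scores (an all-empty path
is an error). Zero coefficients are retained in the model record. θ_opt
maximizes the two-group log-rank chi-square over midpoints of consecutive
unique training scores inside the [20th, 80th] percentile band, preferring
the more balanced split and then the smaller cutpoint on ties. The true
cutpoint criterion of the original method is unpublished; this maximal
log-rank rule is this package's design choice and is stated prominently
here for that reason. Prediction is the linear score under training
standardization; the high-risk group requires a strict score > θ_opt.

Survival statistics: Kaplan-Meier with events processed before censorings
at ties; two-sided two-group log-rank with the hypergeometric variance;
Cox fits (lifelines, Efron ties) reported as hazard ratios with Wald 95%
CIs on the log scale; Lin's concordance correlation coefficient with a
Fisher-z interval using Lin's asymptotic variance; recurrence-score
categories low < 18, intermediate 18–30, high > 30. Multivariable models
are complete-case per model. Subgroup analyses stratify by recurrence-score
category, histologic grade, or a HER2-negative filter; strata with fewer
than two patients, no events, or a single risk group are reported
non-evaluable rather than erroring.

## The phantom generator

The phantom emulates the pipeline's inputs, not H&E appearance. Nuclei are
hard-core ellipses (minimum center distance equal to the mean minor axis;
infeasible packings raise an error naming the density); per-patient
pleomorphism scales axis and orientation variance. Tubules are annular
rings whose rim nuclei are tangentially oriented and flagged; the
epithelium is a dilated nuclei neighborhood; mitoses are Poisson-distributed
uniformly over the epithelium. Rendering uses a pale eosin-like background
with darker basophilic nuclei plus per-nucleus and per-pixel noise so
texture features are non-degenerate. Three standard-normal latents per
patient (mitotic, nuclear disorder, tubule) drive the image phenotypes —
the mitotic latent via a lognormal link exp(0.6·u) on the Poisson mean —
and the survival hazard: DFS is exponential (optionally Weibull) with
log-hazard Σ planted_effect[k]·u_k on a baseline of 0.005/month. Censoring
is independent exponential with its rate solved so the expected censored
fraction matches `censor_rate`; the default 0.8 mirrors the heavy
administrative censoring of real adjuvant cohorts. A noisy monotone
transform of the latent hazard yields a plausible recurrence score so
ODx-style subgroup analyses can be exercised. Randomness is organized as
counter-based substreams keyed by (seed, patient, tile), so identical
configurations are bit-identical and changing `tiles_per_patient` does not
reshuffle other draws.

What the phantom does not emulate: stain variation, segmentation errors,
spatially correlated tumor microenvironments, non-proportional hazards, or
informative censoring. Passing tests therefore demonstrate the pipeline's
internal correctness and statistical calibration under its own assumptions,
not clinical performance on real slides.

## Validation studies and problem sizes

`ibris.validate` runs the end-to-end cycle (simulate, extract, screen, fit,
lock, score an independent phantom cohort). The replicated studies use
small tiles (112 px, ~25 nuclei, one tile per patient) so that a 25-seed
parameter-recovery study (n = 300 training / 150 held-out patients, planted
mitotic log-hazard 1.0, 20% censoring) and a 50-seed null-calibration study
(no planted effect) complete on a single CPU; single demonstration runs use
richer 512-px tiles. The recovery criterion is a held-out hazard ratio
above 1 with two-sided log-rank p < 0.05; the null criterion is
Kolmogorov-Smirnov uniformity of held-out p-values, which also guards
against optimism leaking from the θ_opt search into evaluation.
`scripts/acceptance.py` reruns the same studies at reduced replicate counts
and writes the measured quantities as JSON.

## Known limitations

* The per-family descriptor allocation inside the 242 nuclear features and
  the mitosis bin edges/proliferation cutoffs are reconstructions
  constrained by the published totals, frozen in the versioned catalog.
* The penalized Cox path uses Breslow tie handling (continuous simulated
  times make the distinction moot); unpenalized cross-checks agree with an
  Efron-based solver on tie-free data.
* Voronoi statistics exclude boundary-open cells, so very sparse tiles can
  leave few closed cells; with fewer than four nuclei the whole
  architecture family is NA.
* The CLI reads whole cohort directories into memory; it targets phantom
  scale, not WSI production scale.
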