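# Methods

This note records the models, conventions and numerical choices behind
`immunorad`, and what the synthetic experiments do and do not demonstrate.

## Region geometry

Volumes and masks are `(z, y, x)` grids with physical spacing in mm;
voxel positions are voxel centres and masks are inclusive voxel sets.
Resampling to an isotropic grid (default 1 mm) uses SimpleITK — linear
interpolation for intensities, nearest-neighbor for masks.

The peritumoral band is defined in millimetres via Euclidean distance
transforms rather than iterated structuring elements, so its semantics do
not depend on voxel spacing: band = background voxels within `outer_mm`
(default 2) of a tumor voxel centre, plus tumor voxels within `inner_mm`
(default 1) of a background voxel centre — a 3 mm radial span. Under these
voxel-centre semantics a single-voxel tumor's band is the 33-voxel
Euclidean ball of radius 2, and the band of a digital sphere stays inside
the analytic [r−1, r+2] shell while covering ≳ 85% of its volume (the
digital outer reach is ≈ r+1.6, so the band's voxel count sits a stable
~15% below the continuum shell volume — a discretization property, not an
error). Exclusion masks (air, vessels, adjacent organs) are caller inputs
subtracted from the band; an emptied band is flagged, not fatal.

The intratumoral region defaults to the **full** tumor mask (the "center"
region of the study design), so the band overlaps the tumor's inner 1 mm;
`intratumoral="eroded"` yields strictly disjoint regions, and
`validate_region_pair` enforces disjointness only in that mode.

## Feature inventory

292 features per region, 584 per patient:

* **8 shape**: volume, surface area (marching-cubes mesh of the mask
  lightly smoothed with a 0.8-voxel Gaussian, which removes the staircase
  overestimate — a digital sphere meshes within ~2% of 4πr²),
  surface/volume, sphericity, maximum 3D diameter (convex-hull pairwise
  distance), major axis length (4√λ₁ of the voxel-coordinate covariance),
  elongation √(λ₂/λ₁), flatness √(λ₃/λ₁).
* **14 first-order**: mean, median, min, max, range, IQR, variance
  (population), skewness, kurtosis (Pearson), energy, entropy and
  uniformity on a fixed 32-bin min–max histogram, robust mean absolute
  deviation (10–90 percentile band), RMS. Zero-variance conventions:
  skewness = kurtosis = 0, entropy = 0, uniformity = 1.
* **270 texture**: 90 statistics × bin counts {16, 32, 64} with
  fixed-bin-count, equal-width min–max discretization (robust to intensity
  scale and shift). The 90 statistics: GLCM 39 (13 Haralick-type
  statistics × {direction mean, direction range, merged matrix} over the
  13 unique distance-1 3D directions, symmetric), GLRLM 16 (runs merged
  across the 13 directions), GLSZM 16 (26-connected zones), GLDM 14
  (26-neighborhood, dependence threshold α = 0), NGTDM 5
  (26-neighborhood restricted to the mask).

Matrices are built over masked voxels only; pairs/runs/neighborhoods never
cross the mask boundary. Degenerate cases are defined, not NaN: constant
regions give GLCM contrast 0 / joint energy 1 / joint entropy 0 /
correlation 1; a single-voxel region returns all texture features as 0
with a warning. Every matrix statistic is verified against brute-force
enumeration oracles (explicit voxel loops, flood fills and run walks) to
1e-10 on random grids.

Reproducibility uses ICC(2,1) — two-way random effects, absolute
agreement, single rater — from ANOVA mean squares, with an acceptance
threshold of 0.75 for the downstream filter; zero-variance features return
0 with a degeneracy flag.

## Signature construction

The cascade, run against the binary IHC status (LIS high/low for the
lymphoid target, MIS for myeloid):

1. z-scoring with training means and population SDs (zero-variance columns
   dropped);
2. mRMR ranking, quotient criterion MI(f; y) / mean MI(f; selected), with
   plug-in MI on 3-bin equal-frequency feature discretization; k = 30
   retained (the source design does not state k);
3. collinearity pruning in rank order at |Pearson r| > 0.9;
4. LASSO logistic over a 100-point log-spaced penalty grid (C ∈ [1e−3,
   1e2]), penalty chosen by mean stratified 5-fold CV AUC, ties toward the
   stronger penalty; and linear SVM-RFE (cost 1, 10% of features with the
   smallest squared weight removed per step), subset size chosen by CV
   AUC;
5. the LASSO ∩ SVM-RFE overlap feeds an unpenalized multivariate logistic
   fit. If the overlap has < 2 features the LASSO set is used (logged) —
   with a 30-feature pool the intersection is legitimately small at desk
   scale. Perfect separation is stabilized by a vanishing ridge (C = 1e6)
   and flagged.

The score is the logistic linear predictor including the intercept (a pure
location shift absorbed by the cutoff). The Youden cutoff is the observed
score maximizing sensitivity + specificity − 1 under the rule
`high iff score ≥ cutoff`, smallest maximizer on ties; median and quartile
cutoffs are reported for comparison. Subtypes: (low,low)→1, (high,low)→2,
(low,high)→3, (high,high)→4. Features from both regions enter one pooled
cascade (the printed intratumoral/peritumoral splits of the original
signatures are outcomes, not constraints).

## Immune context scoring

Marker-region medians are fitted once on the training cohort (midpoint for
even n) and frozen. A count **at or equal to** its median scores 1. LIS =
sum over {CD3, CD8} × {intra, peri} ∈ 0–4, low = 0–1; MIS = sum over
CD66b × {intra, peri} ∈ 0–2, low = 0. Counts are treated as already
comparable across patients (field-of-view normalization is out of scope).

## Outcome statistics

Kaplan–Meier (Greenwood bands) and the k-sample log-rank test go through
lifelines. Cox regression is an in-package Newton maximizer of the partial
likelihood (gradient norm < 1e−8, step halving), **Breslow** tie handling
by default with Efron as an option; it agrees with lifelines to 1e−5 on
tie-free data, where the two tie conventions coincide. The PH diagnostic
is the Grambsch–Therneau correlation test of scaled Schoenfeld residuals
against Kaplan–Meier-transformed event times (global statistic
d·uᵀI⁻¹u / Σ(g−ḡ)²); it reproduces lifelines' statistic exactly on shared
data and rejects at ~2.5–5% under proportional hazards. Verdict strings
follow the rule: global p < 0.05 ⇒ "violated".

Harrell's C counts predictor ties 1/2 (lifelines implementation, audited
against an all-pairs enumeration); in the binary-outcome, no-censoring
limit it equals the Mann–Whitney AUC. The nomogram is implemented as its
scoring mathematics only: per-covariate points
100·β(x − x_ref)/max_j |β_j|·range_j, total points an increasing affine map
of the linear predictor (hence identical C-index); graphical rendering is
out of scope.

ORR = (CR+PR)/n per group; group tests use Pearson chi-square, with
Fisher's exact substituted for 2×2 tables with any expected cell < 5.
SciPy provides no r×c exact test, so larger sparse tables fall back to the
chi-square and are flagged `chi_square_small_expected`. AUC comparisons
use DeLong structural components for correlated curves; the "combined" and
"integrative" markers are in-sample logistic combinations of (LRS, MRS)
and (CPS, LRS, MRS).

Shapley attribution is interventional and exact for ≤ 15 features
(enumeration over all coalitions against a background sample; efficiency
Σφ = f(x) − E_bg[f] holds to 1e−10), with a seeded permutation estimator
beyond that. The intended inputs — two radiomics scores plus a handful of
clinical covariates — sit inside the exact regime.

No multiple-testing correction is applied across subgroup analyses,
matching the source study's practice; p-values should be read accordingly.

## Synthetic cohort generator

The generator defines the study conditions for every test:

* **Latent context**: (lymphoid, myeloid) ~ bivariate standard normal,
  correlation ρ = 0.2 by default (the joint distribution is not
  characterized in the source; ρ is exposed in config).
* **Phantoms**: ellipsoids (semi-axes uniform in 8–25 mm by default,
  1 mm isotropic) on a constant-baseline background (60 intensity units).
  Interior = baseline + correlated Gaussian noise, normalized to unit
  in-mask variance before scaling, so the noise SD is exactly
  max(0, 10 + 4·lymphoid) intensity units — texture variance rises
  linearly with the lymphoid latent — and the smoothing length
  max(0.2, 1.5 + 0.5·myeloid) mm grows with the myeloid latent. The
  background equals the interior baseline so that a small segmentation
  disagreement perturbs intensity statistics mildly, as in soft tissue;
  with a one-voxel-shifted second segmentation the feature ICC
  distribution is realistic (median ≈ 0.86, ~70% ≥ 0.75) rather than
  collapsed. This is a texture phantom, not a CT simulator: no organs,
  partial volume, beam hardening or scanner variation — passing tests
  show the pipeline recovers planted statistical structure, not clinical
  performance.
* **IHC counts**: negative binomial (dispersion 2.0; Poisson at ∞) with
  log-mean log(base) + 0.7·latent (CD3/CD8 ← lymphoid, CD66b ← myeloid;
  base means 50/30/20 intratumoral, ×0.8 peritumoral).
* **Survival**: Weibull baseline (shape 1.2, scale 49 months ⇒ baseline
  median ≈ 36 months), proportional hazards
  log h = log(0.25)·1[LIS high] + log(3.0)·1[MIS high] — inside the
  reported multivariate ranges (0.183–0.362 and 1.971–6.014) — with
  independent uniform censoring on (0, 60] months.
* **Response**: Bernoulli per subtype with probabilities
  (0.273, 0.533, 0.102, 0.300), the reported subtype response rates;
  responders split CR/PR with CR fraction 0.15; PD-L1 CPS is lognormal
  with a 0.5 log-unit shift for responders (a deliberately modest AUC,
  matching the reported weakness of CPS).
* Covariates (age, sex, location, differentiation, Lauren type, size,
  CEA/CA19-9, chemotherapy, TNM stage) are drawn independently of the
  latent context by default, so "independent predictor" claims are
  testable under a known truth; a confounding switch tilts stage with the
  myeloid latent.

Cohorts are pure functions of (config, seed): per-patient child seeds are
drawn once from the master generator, so identical configs reproduce
bitwise-identical cohorts.

## Problem sizes

Simulations are sized for a single CPU: the analysis scripts use an
80-patient cohort with 8–12 mm tumors at 1 mm spacing and the full
584-feature inventory; the end-to-end signature-recovery test uses n = 150
(100 train / 50 test) with 2 mm phantoms and a single-bin (16-level)
texture configuration; calibration suites use 100–200 replicates
(log-rank/PH type-I error, Cox coverage at n = 1000 with ~30% censoring,
LASSO support recovery at n = 300 with 3 informative of 30 features).
These sizes are the package's own desk-scale choices; the selection
cascade and all statistics are unchanged by them.

## Known limitations

* The phantom's constant background makes peritumoral intensity features
  depend only on the band's tumor-side voxels; at spacings coarser than
  the 1 mm inner margin the band contains no tumor voxels and peritumoral
  texture degenerates (the default 1 mm spacing avoids this).
* Cutoffs (−0.1293 / −0.2604 in the source) and selected feature
  identities are cohort-specific and not reproducible without the original
  data; only the construction procedure is.
* The Efron option shares the Breslow risk-set machinery but is loop-based
  and slower on heavily tied data.
* Exact Shapley cost grows as 2^p × background size; beyond 15 features
  only the Monte-Carlo permutation estimator is practical.
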