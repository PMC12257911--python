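# Methods

This note documents the models, conventions and parameter choices behind
`brachymetrics`, and what the synthetic validation does and does not show.

## Grid model

All computations live on a 3D voxel grid with anisotropic spacing
(sx, sy, sz) in mm.  Voxel indices are 0-based and the physical position of
a voxel centre is `index * spacing`; orientation and affine information
beyond spacing are ignored (a warning is logged for non-diagonal NIfTI
affines), because every in-scope quantity depends only on relative
distances.  Grids must match exactly between compared volumes (shapes equal,
spacings within 1e-6 mm); no resampling is offered, since resampling changes
metric values and belongs upstream.  Structure sets are stored as one integer
label map with mutually exclusive labels; clinical contours that genuinely
overlap must be supplied as separate single-label files.  This exclusivity is
a real limitation for some clinical data, accepted to keep the phantom
generator and the per-organ evaluation simple.

## Distance-penalty map

The distance map assigns each voxel the exact anisotropic Euclidean distance
R (mm) to the nearest *voxel* of the target structure — not to its surface —
so R = 0 inside the target.  The penalty is the inverse-square law
P = 1/R², motivated by the first-order falloff of photon fluence from a
brachytherapy source, normalized into (0, 1].  1/R² diverges at R = 0, and
how target-interior voxels should be handled before normalization is a
genuinely open choice; we clamp R at a radius `r_min` before inversion and
divide by the resulting maximum 1/r_min²:

    penalty(v) = (r_min / max(R(v), r_min))²

so target voxels get penalty exactly 1 and weights stay bounded.  `r_min`
defaults to the smallest voxel spacing — the finest distance the grid can
represent — and the map is invariant under jointly rescaling spacing and
r_min.

## Weighted Dice (wDSC)

The grid is divided into N crops from the distance map: crop i keeps voxels
with R ≤ cᵢ, where cᵢ = R_max (N−i+1)/N shrinks linearly from the grid-wide
maximum distance and c₁ is extended to +∞ so the outermost crop misses
nothing (R_max is taken over the whole grid, so the scheme is
prediction-independent and stable across predictions of the same case).
Crop i carries weight wᵢ = i/N, and

    wDSC = 1 − Σᵢ wᵢ (1 − vDSCᵢ) / N.

Two design points were open and are settled here:

* **Nested crops, not disjoint shells.**  Cropping "from the outer boundary
  toward the centre" is read as progressively restricting the field of view,
  so crop i ⊇ crop i+1.  A disjoint-shell variant is available behind the
  `shells=True` flag for sensitivity analysis.
* **Thresholds uniform in R, not in the penalty value.**  Equal bins of the
  inverse-square value would collapse nearly the whole grid into one bin;
  uniform distance bins give the spatially regular concentric crops the
  construction intends.

Per-crop conventions: a crop empty in both masks contributes vDSCᵢ = 1 (a
crop with no voxels of the organ in either mask carries no discrepancy); a
crop empty in exactly one mask contributes 0.  The default N = 100 makes the
weighting effectively continuous.  The implementation bins voxels once and
uses cumulative counts (O(grid + N)); the tests verify it against explicit
materialization of every crop.

## Standard metrics

Surfaces are sets of boundary faces between a true voxel and a false or
out-of-grid voxel; each face contributes a surface element at its centre
with its physical area as weight.  HD95 is the max of the two directed 95th
percentiles of nearest-surface distance, with a linear-interpolation
percentile of the area-weighted distance distribution (tied distances are
collapsed with summed weights so the percentile is order-independent).  ASSD
pools the directed distances from both surfaces, area-weighted.  sDSC uses a
1 mm tolerance by default.  APL follows its slice-wise editing-effort
origin: per axial slice, ground-truth contour pixels (8-connected boundary)
absent from the prediction's contour are counted and scaled by the mean
in-plane pixel size, reported in cm.  The 8-connectivity and in-plane
scaling are documented choices, not forced by the definition.  Empty-mask
conventions: one-empty gives vDSC = sDSC = 0 and APL = full ground-truth
contour length; HD95/ASSD are undefined and raise.

## Losses

CE, pooled soft Dice (background included; `foreground_only` available),
DiceCE, and the distance-penalized DPCE / DPDiceCE.  The printed form of the
penalized losses places the penalty term outside the voxel sum, which is
dimensionally inconsistent for a per-voxel map; they are implemented as
voxel-wise weighting with a single target-derived map shared across classes,
consistent with the stated intent that voxels closer to the target carry
higher error penalties.  The CE term inside DPDiceCE is left unweighted,
exactly as printed.  Probabilities are clamped to [1e-7, 1] before logs so
hard one-hot predictions stay finite.  Analytic gradients with respect to
the probabilities are provided and tested against central finite differences
(simplex-preserving perturbations, agreement to 1e-5) — the contract any
training-framework port must satisfy.  Training itself (networks,
optimizers, augmentation) is out of scope.

## Dose surrogate

The clinical treatment-planning dose engine is deliberately not reproduced.
Instead, dwell positions are isotropic point sources with
dose = strength / max(r, r_clamp)² (strength in Gy·mm², r_clamp default
2 mm), superposed linearly.  This keeps the D2cc machinery transparent and
oracle-testable while preserving the property that matters for the analysis:
dose is a steep, monotone function of distance to the dwell line, so contour
errors near the target move D2cc and distant errors do not.  D2cc is
extracted at voxel resolution (sorted organ doses accumulated to 2000 mm³,
no sub-voxel interpolation); organs smaller than 2 cm³ fall back to their
minimum dose with a warning.  TG-43 anisotropy, dwell-time optimization and
EQD2 conversion are out of scope, and no clinical dosimetric value should be
expected from the surrogate.

## Synthetic phantoms

Phantoms provide controllable distance structure, not anatomy: a central
ellipsoidal target (semi-axes ≈ 12×12×16 mm), a spherical bladder analogue
and a tubular rectum analogue placed in contact with the target, a curved
tubular sigmoid analogue a few mm away, and a distant blob-chain small-bowel
analogue, on an 80×80×24 grid at 1×1×3 mm spacing (echoing the strong slice
anisotropy of pelvic MR while keeping the grid desk-sized).  Abutting organs
are sized to reach ~1.5 mm into the target, with the overlap trimmed at
rasterization, so contact survives the per-seed jitter (centres ±2 mm, radii
±8%) that differentiates cases.  Five dwells span the central 75% of the
target's long axis at 800 Gy·mm² each, which puts near-organ D2cc values in
the several-Gy range typical of HDR fractions.  Predictions are made by
flipping a controlled fraction of an organ's voxels (default modes: dilate =
false positives around the boundary, erode = false negatives, transfer =
volume-preserving boundary shift), chosen from the near or far end of the
organ's distance-to-target distribution or uniformly.  Everything is
deterministic per seed.

What the phantoms do **not** emulate: image intensities, inter-observer
contour style, deformable anatomy, applicator geometry, or realistic organ
shapes.  Passing tests therefore demonstrate the correctness and the
qualitative behaviour of the metrics and losses — not clinical performance
numbers, which depend on real patient data and a real planning system.

## Correlation study

The study driver generates a seeded cohort (default 50 cases), perturbs each
of the four organs once per condition (near-band and far-band errors of
equal, randomly drawn volume fraction in [0.04, 0.25]), and records the six
metrics plus |ΔD2cc| per (case, organ, condition) — 400 records at the
default size.  Pearson correlations and OLS fits of each metric against
|ΔD2cc| are computed over the pooled records, mirroring an analysis that
pools across trained models; here the perturbation condition supplies the
variation instead.  Paired Wilcoxon signed-rank tests compare wDSC and vDSC
between conditions per organ (8 tests) against a Bonferroni-adjusted
threshold of 0.05/8 = 0.00625.  The Wilcoxon test drops zero differences,
uses mid-ranks for ties, enumerates the exact null for n ≤ 12 and uses a
continuity- and tie-corrected normal approximation above.

Only the *sign* and *ordering* of the correlations are claims of this
package: wDSC correlates negatively with |ΔD2cc| and more strongly than
vDSC, because only near-to-target errors move D2cc and only wDSC weights
them accordingly.  The correlation magnitudes depend on the phantom and
perturbation distributions and carry no clinical meaning.  (By construction
the near/far dilate conditions have identical vDSC within a case pair, so
the per-organ paired vDSC test has no information and is reported as
missing.)

## Numerical notes

* The Euclidean distance transform is scipy's exact anisotropic EDT;
  verified against an all-pairs brute force.
* Crop membership uses R ≤ cᵢ with thresholds computed in float64; crop
  counts come from a single binning pass verified against explicit masking.
* Weighted percentiles collapse tied values before interpolation; q = 100
  recovers the maximum.
* Dose grids are clamped at r_clamp to stay finite at dwell positions.
* All randomness flows through `numpy.random.default_rng` seeds; identical
  seeds give byte-identical study reports.
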