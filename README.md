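# brachymetrics

Geometrically focused evaluation of organ-at-risk (OAR) auto-segmentation for
high-dose-rate (HDR) brachytherapy and other near-to-target radiotherapy
settings.

## The problem

In cervical HDR brachytherapy, treatment planning is driven by the dose to
the hottest 2 cm³ of each OAR (D2cm³, "D2cc") — bladder, rectum, sigmoid and
small bowel — adjacent to the high-risk clinical target volume (CTV_HR).
Standard segmentation metrics (volumetric Dice, HD95, surface Dice, added
path length, average symmetric surface distance) treat every part of an organ
equally, so a contouring error 5 cm from the target counts the same as one
touching it, even though only the latter moves D2cc.  This package implements
evaluation and training machinery that weights segmentation accuracy by
proximity to the target:

* **Distance-penalty (DP) map** — the anisotropic Euclidean distance R (mm)
  from every voxel to the CTV_HR, turned into an inverse-square penalty
  P = 1/R² (dose falls off as 1/r² to first approximation), normalized to
  (0, 1] with a clamp radius so target voxels score exactly 1.
* **Weighted Dice (wDSC)** — the grid is cropped into N nested volumes by
  distance to the target; crop i gets weight wᵢ = i/N (1/N at the boundary,
  1 at the centre) and

  wDSC = 1 − Σᵢ wᵢ (1 − vDSCᵢ) / N

  where vDSCᵢ is the volumetric Dice restricted to crop i.  Near-to-target
  errors fall in many high-weight crops; distant errors in few low-weight
  ones.  Default N = 100.
* **Distance-penalized losses** — reference (array-level) implementations of
  CE, soft Dice, DiceCE and their DP-weighted variants DPCE / DPDiceCE, with
  analytic gradients, for validating training-framework ports.
* **Standard metrics** — vDSC, HD95, sDSC (1 mm tolerance), APL (cm), ASSD,
  on boundary-face surfaces with area weighting.
* **Dose surrogate** — inverse-square point-source dwells, cumulative DVH,
  voxel-resolution D2cc, and the absolute D2cc difference
  |D2cc(prediction) − D2cc(reference)| between contour pairs.
* **Synthetic phantoms and study driver** — seeded pelvic-like phantoms
  (target ellipsoid + four organ analogues) with controllable contour errors
  (volume and distance band), and a cohort driver that reproduces the
  metric-vs-dosimetry correlation analysis end to end.

## Worked example

```python
import brachymetrics as bm

gt, dwells = bm.generate_phantom(bm.default_phantom_spec(seed=7))
dist = bm.euclidean_distance_map(bm.extract_binary(gt, 1))   # 1 = CTV_HR
dose = bm.compute_dose(dwells, gt.shape, gt.spacing)

# two predictions with the SAME error volume, placed near vs far from the target
for band in ("near", "far"):
    res = bm.perturb_prediction(gt, "rectum",
                                bm.PerturbSpec(0.1, band, "dilate", seed=7),
                                dist=dist)
    G = bm.extract_binary(gt, 3)
    P = bm.extract_binary(res.prediction, 3)
    print(band, round(bm.vdsc(G, P), 4), round(bm.wdsc(G, P, dist).wdsc, 4),
          round(bm.abs_d2cc_diff(P, G, dose).abs_diff, 2))
```

prints

```
near 0.9524 0.9271 2.18
far 0.9524 0.9949 0.0
```

Volumetric Dice is identical for both predictions (same error volume), but
the near-to-target error drops wDSC by ~0.07 and shifts the rectum D2cc by
2.18 Gy, while the far error leaves both nearly untouched — wDSC tracks the
dosimetric consequence that vDSC cannot see.

The same workflows are available from a shell:

```bash
brachymetrics synth --seed 5 --out-dir phantom        # gt/pred NIfTI + dwells
brachymetrics compare --gt phantom/gt.nii.gz --pred phantom/pred.nii.gz \
    --dwells phantom/dwells.json --out report.json
brachymetrics study --n-cases 50 --seed 0 --out-dir study_out
```

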