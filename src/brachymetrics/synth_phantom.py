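"""Seeded pelvic-like phantom generator and contour perturbation.

The phantom emulates the geometry that matters for near-to-target evaluation
in cervical brachytherapy: a small central target (CTV analogue, an
ellipsoid), an abutting bladder analogue (sphere), an abutting rectum
analogue (straight tube), a nearby sigmoid analogue (curved tube) and a
distant small-bowel analogue (blob chain), rasterized into one mutually
exclusive integer label map on an anisotropic grid (default 1 x 1 x 3 mm,
echoing the strong slice anisotropy of pelvic MR).  Dwell positions for the
dose surrogate are placed along the target's long (z) axis, mimicking an
intracavitary tandem.

"Predicted" contours are produced by flipping a controlled number of voxels
of one organ, placed in a chosen distance band relative to the target
(near / far / uniform), so the error volume and the error's
distance-to-target are independently controllable — the two knobs the
weighted-Dice and distance-penalized-loss machinery is designed to separate.

Everything is deterministic per seed.  No anatomy, intensities or applicator
geometry are modelled: the phantoms provide controllable distance structure,
nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .dpmap import DistanceMap, euclidean_distance_map
from .dose_surrogate import SourceDwell
from .volumes import BinaryMask, LabeledVolume, extract_binary

DEFAULT_LABELS = {1: "CTV_HR", 2: "bladder", 3: "rectum", 4: "sigmoid", 5: "small_bowel"}

# rasterized organ volume may lose at most this fraction to overlap trimming
MAX_TRIM_FRAC = 0.20


@dataclass(frozen=True)
class OrganSpec:
    """One organ analogue: a geometric primitive plus its distance role."""

    name: str
    label: int
    primitive: str  # sphere | tube | curved_tube | blob_chain
    params: dict
    abutting: bool = False


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom description; deterministic per seed."""

    grid_shape: tuple[int, int, int] = (80, 80, 24)
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    ctv_center: tuple[float, float, float] = (40.0, 40.0, 36.0)
    ctv_semiaxes: tuple[float, float, float] = (12.0, 12.0, 16.0)
    organs: tuple[OrganSpec, ...] = ()
    n_dwells: int = 5
    dwell_strength: float = 800.0  # Gy*mm^2
    seed: int = 0


def default_phantom_spec(seed: int = 0, jitter: bool = True) -> PhantomSpec:
    """The default five-structure phantom, with per-seed geometric jitter.

    Jitter moves organ centres by up to ±2 mm and scales radii by ±8%, so
    distinct seeds give distinct but comparable cases.
    """
    rng = np.random.default_rng(seed)

    def j(v: float, mm: float = 2.0) -> float:
        return v + (rng.uniform(-mm, mm) if jitter else 0.0)

    def s(v: float, frac: float = 0.08) -> float:
        return v * (1.0 + (rng.uniform(-frac, frac) if jitter else 0.0))

    ctv_center = np.array([40.0, 40.0, 36.0])
    semi = np.array([s(12.0), s(12.0), s(16.0)])

    def ellipsoid_radius(direction: np.ndarray, axes: np.ndarray) -> float:
        u = direction / np.linalg.norm(direction)
        return 1.0 / np.sqrt(((u / axes) ** 2).sum())

    # abutting organs are sized to reach ~1.5 mm into the target, so contact
    # survives any jitter (the overlap is trimmed away at rasterization)
    overlap = 1.5
    bladder_c = np.array([j(40.0), j(15.0), j(36.0)])
    gap_b = np.linalg.norm(ctv_center - bladder_c)
    bladder_r = gap_b - ellipsoid_radius(ctv_center - bladder_c, semi) + overlap

    rectum_c2d = np.array([j(40.0), j(61.0)])
    d2d = ctv_center[:2] - rectum_c2d
    gap_r = np.linalg.norm(d2d)
    rectum_r = gap_r - ellipsoid_radius(d2d, semi[:2]) + overlap

    organs = (
        OrganSpec("bladder", 2, "sphere",
                  {"center": tuple(bladder_c), "radius": float(bladder_r)},
                  abutting=True),
        OrganSpec("rectum", 3, "tube",
                  {"cx": float(rectum_c2d[0]), "cy": float(rectum_c2d[1]),
                   "radius": float(rectum_r), "z_range": (0.0, 69.0)},
                  abutting=True),
        OrganSpec("sigmoid", 4, "curved_tube",
                  {"arc_center": (40.0, j(40.0), 36.0), "arc_radius": s(22.0),
                   "tube_radius": s(5.0), "angles_deg": (-55.0, 55.0)},
                  abutting=False),
        OrganSpec("small_bowel", 5, "blob_chain",
                  {"centers": [(j(13.0), j(18.0), j(15.0)),
                               (j(17.0), j(26.0), j(30.0)),
                               (j(13.0), j(32.0), j(45.0)),
                               (j(17.0), j(38.0), j(57.0))],
                   "radius": s(6.0)},
                  abutting=False),
    )
    return PhantomSpec(
        ctv_semiaxes=tuple(float(a) for a in semi),
        organs=organs,
        seed=seed,
    )


def _coord_grids(shape: tuple[int, int, int], spacing: tuple[float, float, float]):
    x = np.arange(shape[0]) * spacing[0]
    y = np.arange(shape[1]) * spacing[1]
    z = np.arange(shape[2]) * spacing[2]
    return x[:, None, None], y[None, :, None], z[None, None, :]


def _rasterize_ellipsoid(shape, spacing, center, semiaxes) -> np.ndarray:
    x, y, z = _coord_grids(shape, spacing)
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _rasterize_primitive(spec: OrganSpec, shape, spacing) -> np.ndarray:
    x, y, z = _coord_grids(shape, spacing)
    p = spec.params
    if spec.primitive == "sphere":
        cx, cy, cz = p["center"]
        r = p["radius"]
        return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r**2
    if spec.primitive == "tube":
        z0, z1 = p["z_range"]
        radial = (x - p["cx"]) ** 2 + (y - p["cy"]) ** 2 <= p["radius"] ** 2
        return radial & (z >= z0) & (z <= z1)
    if spec.primitive == "curved_tube":
        acx, acy, acz = p["arc_center"]
        t = np.deg2rad(np.linspace(*p["angles_deg"], 60))
        pts = np.stack([acx + p["arc_radius"] * np.cos(t),
                        np.full_like(t, acy),
                        acz + p["arc_radius"] * np.sin(t)], axis=1)
        mask = np.zeros(shape, dtype=bool)
        for px, py, pz in pts:  # union of spheres along the arc
            mask |= (x - px) ** 2 + (y - py) ** 2 + (z - pz) ** 2 <= p["tube_radius"] ** 2
        return mask
    if spec.primitive == "blob_chain":
        r = p["radius"]
        mask = np.zeros(shape, dtype=bool)
        for cx, cy, cz in p["centers"]:
            mask |= (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r**2
        return mask
    raise ValueError(f"unknown primitive {spec.primitive!r}")


def generate_phantom(spec: PhantomSpec) -> tuple[LabeledVolume, list[SourceDwell]]:
    """Rasterize the phantom into one label map plus dwell positions.

    Labels are claimed in order (target first), so a small designed overlap of
    an abutting organ with the target is trimmed to keep labels exclusive; an
    organ losing more than 20% of its voxels to previously placed structures
    is an error naming the offending pair.
    """
    shape, spacing = spec.grid_shape, spec.spacing
    labels = np.zeros(shape, dtype=np.int32)
    ctv = _rasterize_ellipsoid(shape, spacing, spec.ctv_center, spec.ctv_semiaxes)
    if not ctv.any():
        raise ValueError("CTV ellipsoid does not intersect the grid")
    labels[ctv] = 1
    names = {1: "CTV_HR"}
    for organ in spec.organs:
        raw = _rasterize_primitive(organ, shape, spacing)
        n_raw = int(raw.sum())
        if n_raw == 0:
            raise ValueError(f"organ {organ.name!r} rasterizes to zero voxels")
        free = raw & (labels == 0)
        if int(free.sum()) < (1.0 - MAX_TRIM_FRAC) * n_raw:
            prev = np.unique(labels[raw & (labels != 0)])
            prev_names = [names.get(int(v), str(v)) for v in prev]
            raise ValueError(
                f"organ {organ.name!r} overlaps {prev_names} by more than "
                f"{MAX_TRIM_FRAC:.0%}; overlap cannot be resolved by trimming")
        labels[free] = organ.label
        names[organ.label] = organ.name

    cx, cy, cz = spec.ctv_center
    az = spec.ctv_semiaxes[2]
    # dwell line spans the central 75% of the CTV long axis
    zs = np.linspace(cz - 0.75 * az, cz + 0.75 * az, spec.n_dwells)
    dwells = [SourceDwell(position=(cx, cy, float(zk)), strength=spec.dwell_strength)
              for zk in zs]
    return LabeledVolume(labels=labels, spacing=spacing, label_names=names), dwells


# ---------------------------------------------------------------------------
# Prediction perturbation


@dataclass(frozen=True)
class PerturbSpec:
    """How to corrupt one organ's contour.

    error_volume_frac: fraction of the organ's voxel count to flip.
    band: where (in distance-to-target) the flipped voxels go —
        "near" takes the candidates closest to the target, "far" the
        farthest, "uniform" a random subset.
    mode: "dilate" adds false positives around the organ, "erode" removes
        boundary voxels, "transfer" moves the boundary within the band
        (removes k and adds k, preserving volume).
    """

    error_volume_frac: float = 0.1
    band: str = "uniform"   # near | far | uniform
    mode: str = "dilate"    # dilate | erode | transfer
    seed: int = 0
    dilate_iters: int = 3


@dataclass(frozen=True)
class PerturbResult:
    prediction: LabeledVolume
    n_flipped: int
    n_requested: int
    mean_error_dist: float  # mm, mean distance-to-target of flipped voxels


def _pick(candidates: np.ndarray, dist: np.ndarray, k: int, band: str,
          rng: np.random.Generator) -> np.ndarray:
    """Choose k candidate voxels by distance band; returns flat indices."""
    flat = np.flatnonzero(candidates)
    if len(flat) < k:
        raise ValueError(
            f"band has only {len(flat)} candidate voxels, {k} requested; "
            f"achievable maximum is {len(flat)}")
    d = dist.ravel()[flat]
    if band == "near":
        order = np.lexsort((flat, d))
        return flat[order[:k]]
    if band == "far":
        order = np.lexsort((flat, -d))
        return flat[order[:k]]
    if band == "uniform":
        return rng.choice(flat, size=k, replace=False)
    raise ValueError(f"unknown band {band!r}")


def perturb_prediction(gt: LabeledVolume, organ: str | int, p: PerturbSpec,
                       dist: DistanceMap | None = None,
                       target_label: int = 1) -> PerturbResult:
    """Build a predicted label map by flipping voxels of one organ.

    The organ may be given by name (via the label-name map) or label value.
    Flipped voxels are chosen from the organ's boundary neighbourhood by
    their distance to the target structure.
    """
    if isinstance(organ, str):
        matches = [k for k, v in gt.label_names.items() if v == organ]
        if not matches:
            raise KeyError(f"organ {organ!r} not in {sorted(gt.label_names.values())}")
        label = matches[0]
    else:
        label = int(organ)
    organ_mask = extract_binary(gt, label).mask
    if dist is None:
        dist = euclidean_distance_map(extract_binary(gt, target_label),
                                      target_label=target_label)
    d = dist.dist
    rng = np.random.default_rng(p.seed)
    n_organ = int(organ_mask.sum())
    k = int(round(p.error_volume_frac * n_organ))

    labels = gt.labels.copy()
    flipped: list[np.ndarray] = []
    if k > 0:
        struct = ndimage.generate_binary_structure(3, 1)
        grow = ndimage.binary_dilation(organ_mask, structure=struct,
                                       iterations=p.dilate_iters)
        add_cand = grow & (gt.labels == 0)
        shrink = ndimage.binary_erosion(organ_mask, structure=struct,
                                        iterations=p.dilate_iters, border_value=1)
        del_cand = organ_mask & ~shrink
        if p.mode == "dilate":
            idx = _pick(add_cand, d, k, p.band, rng)
            labels.ravel()[idx] = label
            flipped.append(idx)
        elif p.mode == "erode":
            idx = _pick(del_cand, d, k, p.band, rng)
            labels.ravel()[idx] = 0
            flipped.append(idx)
        elif p.mode == "transfer":
            k_half = max(1, k // 2)  # k_half removed and k_half added: volume preserved
            idx_del = _pick(del_cand, d, k_half, p.band, rng)
            idx_add = _pick(add_cand, d, k_half, p.band, rng)
            labels.ravel()[idx_del] = 0
            labels.ravel()[idx_add] = label
            flipped.extend([idx_del, idx_add])
        else:
            raise ValueError(f"unknown mode {p.mode!r}")
    all_idx = np.concatenate(flipped) if flipped else np.empty(0, dtype=np.intp)
    mean_dist = float(d.ravel()[all_idx].mean()) if len(all_idx) else 0.0
    pred = LabeledVolume(labels=labels, spacing=gt.spacing, label_names=gt.label_names)
    return PerturbResult(prediction=pred, n_flipped=len(all_idx),
                         n_requested=k, mean_error_dist=mean_dist)
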