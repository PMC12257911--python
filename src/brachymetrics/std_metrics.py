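"""The five standard geometric segmentation metrics.

vDSC (volumetric Dice), HD95 (95th-percentile Hausdorff distance), sDSC
(surface Dice at a 1 mm tolerance), APL (added path length) and ASSD (average
symmetric surface distance), computed between a ground-truth and a predicted
binary mask on a common anisotropic grid.

Surfaces are represented as boundary faces: every face between a true voxel
and a false (or out-of-grid) voxel contributes one surface element at the
face centre, weighted by its physical area.  Surface-to-surface distances are
nearest-neighbour distances between face centres; HD95 uses a
linear-interpolation percentile of the area-weighted distance distribution and
symmetrizes by taking the max of the two directed percentiles.

APL follows its slice-wise editing-effort origin: per axial slice, ground-truth
contour pixels (true pixels with an 8-connected background neighbour) whose
(row, col, slice) position is not a prediction contour pixel are counted and
scaled by the mean in-plane pixel size; the result is reported in cm.

Empty-mask conventions: with exactly one empty mask, vDSC = sDSC = 0 and APL
falls back to the full ground-truth contour length, while HD95/ASSD are
genuinely undefined and raise.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volumes import BinaryMask, validate_pair


@dataclass(frozen=True)
class SurfaceSet:
    """Boundary-face surface elements of a binary mask.

    ``points`` are face centres in physical mm, ``areas`` the face areas in
    mm^2 (a face is weighted by the product of the two spacings orthogonal to
    its normal).
    """

    points: np.ndarray  # (M, 3) mm
    areas: np.ndarray   # (M,) mm^2
    spacing: tuple[float, float, float]

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class MetricReport:
    """All five standard metrics for one (ground truth, prediction) pair."""

    organ: str
    vdsc: float        # unitless, [0, 1]
    hd95: float        # mm
    sdsc: float        # unitless, [0, 1]
    apl: float         # cm
    assd: float        # mm

    def to_dict(self) -> dict:
        return asdict(self)


def vdsc(G: BinaryMask, P: BinaryMask) -> float:
    """Volumetric Dice 2|G∩P| / (|G| + |P|) from voxel counts.

    Both masks empty is undefined and raises; exactly one empty gives 0.
    """
    validate_pair(G, P)
    n_g, n_p = G.n_voxels, P.n_voxels
    if n_g == 0 and n_p == 0:
        raise ValueError("vDSC undefined: both masks are empty")
    inter = int(np.count_nonzero(G.mask & P.mask))
    return 2.0 * inter / (n_g + n_p)


_FACE_AXES = ((0, +1), (0, -1), (1, +1), (1, -1), (2, +1), (2, -1))


def extract_surface(M: BinaryMask) -> SurfaceSet:
    """Boundary faces of a mask, with face-centre positions and areas."""
    if M.is_empty():
        raise ValueError("cannot extract the surface of an empty mask")
    spacing = np.asarray(M.spacing)
    mask = M.mask
    pts, areas = [], []
    for axis, sign in _FACE_AXES:
        # neighbour in direction sign along axis; out-of-grid counts as background
        shifted = np.zeros_like(mask)
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        if sign > 0:
            src[axis] = slice(1, None)
            dst[axis] = slice(None, -1)
        else:
            src[axis] = slice(None, -1)
            dst[axis] = slice(1, None)
        shifted[tuple(dst)] = mask[tuple(src)]
        boundary = mask & ~shifted
        idx = np.argwhere(boundary).astype(np.float64)
        if idx.size == 0:
            continue
        centers = idx * spacing
        centers[:, axis] += sign * spacing[axis] / 2.0
        pts.append(centers)
        area = spacing[(axis + 1) % 3] * spacing[(axis + 2) % 3]
        areas.append(np.full(len(centers), area))
    points = np.concatenate(pts, axis=0)
    return SurfaceSet(points=points, areas=np.concatenate(areas), spacing=M.spacing)


def _directed_nn_distances(src: SurfaceSet, dst: SurfaceSet) -> np.ndarray:
    tree = cKDTree(dst.points)
    d, _ = tree.query(src.points, k=1)
    return np.asarray(d, dtype=np.float64)


def _weighted_percentile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Linear-interpolation percentile of a weighted distribution.

    Tied values are collapsed (their weights summed) so the result does not
    depend on sort order.  With F_k = cw_k / W the cumulative weight fraction
    at the k-th distinct sorted value, the q-th percentile interpolates
    linearly between successive (F_k, v_k), returning the smallest value for
    q below F_1 (so q=100 gives the max).
    """
    v, inverse = np.unique(values, return_inverse=True)
    w = np.bincount(inverse, weights=weights, minlength=len(v))
    cw = np.cumsum(w)
    frac = cw / cw[-1]
    return float(np.interp(q / 100.0, frac, v, left=v[0]))


def hd95(G: BinaryMask, P: BinaryMask, q: float = 95.0) -> float:
    """95th-percentile Hausdorff distance (mm): max of the two directed
    area-weighted percentile nearest-surface distances."""
    validate_pair(G, P)
    if G.is_empty() or P.is_empty():
        raise ValueError("HD95 undefined for an empty mask")
    sg, sp = extract_surface(G), extract_surface(P)
    d_gp = _directed_nn_distances(sg, sp)
    d_pg = _directed_nn_distances(sp, sg)
    return max(_weighted_percentile(d_gp, sg.areas, q),
               _weighted_percentile(d_pg, sp.areas, q))


def assd(G: BinaryMask, P: BinaryMask) -> float:
    """Average symmetric surface distance (mm): area-weighted mean of all
    directed nearest-surface distances pooled over both directions."""
    validate_pair(G, P)
    if G.is_empty() or P.is_empty():
        raise ValueError("ASSD undefined for an empty mask")
    sg, sp = extract_surface(G), extract_surface(P)
    d_gp = _directed_nn_distances(sg, sp)
    d_pg = _directed_nn_distances(sp, sg)
    num = float(np.dot(d_gp, sg.areas) + np.dot(d_pg, sp.areas))
    return num / (sg.total_area + sp.total_area)


def sdsc(G: BinaryMask, P: BinaryMask, tol: float = 1.0) -> float:
    """Surface Dice: fraction of the combined boundary area lying within
    ``tol`` mm of the other boundary (default tolerance 1 mm)."""
    validate_pair(G, P)
    if tol <= 0:
        raise ValueError(f"tolerance must be > 0 mm, got {tol}")
    if G.is_empty() or P.is_empty():
        raise ValueError("sDSC undefined for an empty mask")
    sg, sp = extract_surface(G), extract_surface(P)
    d_gp = _directed_nn_distances(sg, sp)
    d_pg = _directed_nn_distances(sp, sg)
    close = float(sg.areas[d_gp <= tol].sum() + sp.areas[d_pg <= tol].sum())
    return close / (sg.total_area + sp.total_area)


def _slice_contour(slice2d: np.ndarray) -> np.ndarray:
    """8-connected contour pixels of a 2D mask (out-of-grid = background)."""
    if not slice2d.any():
        return np.zeros_like(slice2d)
    eroded = ndimage.binary_erosion(slice2d, structure=np.ones((3, 3), bool),
                                    border_value=0)
    return slice2d & ~eroded


def apl(G: BinaryMask, P: BinaryMask) -> float:
    """Added path length (cm): ground-truth contour pixels absent from the
    prediction contour, counted per axial slice and scaled by the mean
    in-plane pixel size.  Asymmetric by design (ground-truth referenced)."""
    validate_pair(G, P)
    if G.is_empty():
        raise ValueError("APL undefined for an empty ground truth")
    sx, sy, _ = G.spacing
    pixel_mm = (sx + sy) / 2.0
    n_added = 0
    for k in range(G.shape[2]):
        cg = _slice_contour(G.mask[:, :, k])
        if not cg.any():
            continue
        cp = _slice_contour(P.mask[:, :, k])
        n_added += int(np.count_nonzero(cg & ~cp))
    return n_added * pixel_mm / 10.0  # mm -> cm


def all_metrics(G: BinaryMask, P: BinaryMask, organ: str = "",
                sdsc_tol: float = 1.0) -> MetricReport:
    """Compute the full five-metric report for one organ."""
    return MetricReport(
        organ=organ,
        vdsc=vdsc(G, P),
        hd95=hd95(G, P),
        sdsc=sdsc(G, P, tol=sdsc_tol),
        apl=apl(G, P),
        assd=assd(G, P),
    )
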