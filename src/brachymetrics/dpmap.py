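"""Distance maps and inverse-square distance-penalty (DP) maps.

The target structure (the high-risk clinical target volume, CTV_HR, in
cervical brachytherapy) defines a per-voxel Euclidean distance field R in mm.
Photon fluence from a brachytherapy source falls off as 1/R^2 to first
approximation, so the penalty map P = 1/R^2, normalized into [0, 1], encodes
how dosimetrically consequential a segmentation error at each voxel is.  The
same map serves as the voxel weight of the distance-penalized losses and as
the cropping field of the weighted Dice coefficient.

R = 0 inside the target would make 1/R^2 diverge; distances are clamped at a
radius ``r_min`` (default: the smallest voxel spacing) before inversion, and
the result is divided by its maximum 1/r_min^2 so target voxels get penalty
exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask


@dataclass(frozen=True)
class DistanceMap:
    """Per-voxel anisotropic Euclidean distance (mm) to the nearest target voxel."""

    dist: np.ndarray
    spacing: tuple[float, float, float]
    target_label: int = 1

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dist.shape

    @property
    def r_max(self) -> float:
        """Largest distance on the grid, mm."""
        return float(self.dist.max())


@dataclass(frozen=True)
class DPMap:
    """Normalized inverse-square penalty in (0, 1]; 1 on (and within r_min of) the target."""

    penalty: np.ndarray
    r_min: float
    spacing: tuple[float, float, float]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.penalty.shape


def euclidean_distance_map(target: BinaryMask, target_label: int = 1) -> DistanceMap:
    """Exact anisotropic Euclidean distance transform of the target mask.

    Every voxel gets the centre-to-centre physical distance (mm) to its
    nearest target voxel; distance is 0 inside the target.

    Raises
    ------
    ValueError
        If the target mask is empty (distance undefined).
    """
    if target.is_empty():
        raise ValueError("target mask is empty: distance map undefined")
    dist = ndimage.distance_transform_edt(~target.mask, sampling=target.spacing)
    return DistanceMap(dist=np.asarray(dist, dtype=np.float64), spacing=target.spacing,
                       target_label=target_label)


def inverse_square_map(dist: DistanceMap, r_min: float | None = None) -> DPMap:
    """Build the normalized inverse-square penalty map from a distance map.

    ``penalty(v) = (r_min / max(dist(v), r_min))**2`` — i.e. 1/R'^2 with the
    clamped distance R' = max(R, r_min), normalized by its maximum 1/r_min^2.

    Parameters
    ----------
    dist
        Distance map from :func:`euclidean_distance_map`.
    r_min
        Clamp radius in mm, > 0.  Defaults to the smallest voxel spacing.
    """
    if r_min is None:
        r_min = float(min(dist.spacing))
    if r_min <= 0:
        raise ValueError(f"r_min must be > 0 mm, got {r_min}")
    clamped = np.maximum(dist.dist, r_min)
    penalty = (r_min / clamped) ** 2
    return DPMap(penalty=penalty, r_min=float(r_min), spacing=dist.spacing)
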