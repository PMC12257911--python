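"""Desk-scale dose surrogate: inverse-square point sources, DVH, D2cc.

A clinical treatment-planning system computes brachytherapy dose with TG-43
source models; here a transparent stand-in is used so the dosimetric
machinery — cumulative dose-volume histograms, the D2cm^3 organ constraint,
and the absolute D2cm^3 difference between predicted and reference contours —
can be exercised end to end on synthetic phantoms.  Each dwell position is an
isotropic point source with dose = strength / r^2 (strength in Gy*mm^2),
clamped at a small radius so the grid stays finite; doses from multiple
dwells superpose linearly.

D2cm^3 (D2cc) is the minimum dose in the most irradiated 2 cm^3 of an organ,
extracted at voxel resolution with no sub-voxel interpolation: organ voxel
doses are sorted descending and accumulated until 2000 mm^3 is reached; the
dose of the crossing voxel is returned.  An organ smaller than 2 cm^3 falls
back to its minimum dose with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volumes import BinaryMask, validate_pair

D2CC_MM3 = 2000.0


@dataclass(frozen=True)
class SourceDwell:
    """Point source: position in physical mm, strength in Gy*mm^2."""

    position: tuple[float, float, float]
    strength: float

    def __post_init__(self) -> None:
        if self.strength <= 0:
            raise ValueError(f"source strength must be > 0, got {self.strength}")


@dataclass(frozen=True)
class DoseGrid:
    """Per-voxel dose in Gy on the same grid as the label maps."""

    dose: np.ndarray
    spacing: tuple[float, float, float]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dose.shape


@dataclass(frozen=True)
class DoseReport:
    """D2cc on the predicted and reference contour of one organ, and |diff|."""

    organ: str
    d2cc_pred: float  # Gy
    d2cc_ref: float   # Gy
    abs_diff: float   # Gy


def compute_dose(sources: list[SourceDwell], shape: tuple[int, int, int],
                 spacing: tuple[float, float, float], r_clamp: float = 2.0) -> DoseGrid:
    """Superpose inverse-square point-source doses on a voxel grid.

    dose(v) = sum_k strength_k / max(r_vk, r_clamp)^2 with r_vk the physical
    distance from the voxel centre to source k (voxel centre = index*spacing).
    """
    if not sources:
        raise ValueError("at least one source dwell is required")
    if r_clamp <= 0:
        raise ValueError(f"r_clamp must be > 0 mm, got {r_clamp}")
    sx, sy, sz = spacing
    x = np.arange(shape[0]) * sx
    y = np.arange(shape[1]) * sy
    z = np.arange(shape[2]) * sz
    dose = np.zeros(shape, dtype=np.float64)
    for src in sources:
        px, py, pz = src.position
        r2 = ((x - px) ** 2)[:, None, None] + ((y - py) ** 2)[None, :, None] \
            + ((z - pz) ** 2)[None, None, :]
        dose += src.strength / np.maximum(r2, r_clamp**2)
    return DoseGrid(dose=dose, spacing=tuple(float(s) for s in spacing))


def cumulative_dvh(dose: DoseGrid, organ: BinaryMask, n_bins: int = 100) -> pd.DataFrame:
    """Cumulative dose-volume histogram of one organ.

    Returns a DataFrame with columns ``dose_gy`` (bin edges from 0 to the
    organ's maximum dose) and ``volume_cm3`` (organ volume receiving at least
    that dose).  Volume at dose 0 is the full organ volume; the curve is
    monotone non-increasing.
    """
    if organ.is_empty():
        raise ValueError("DVH undefined for an empty organ")
    if dose.shape != organ.shape:
        raise ValueError(f"dose grid shape {dose.shape} != organ shape {organ.shape}")
    organ_dose = dose.dose[organ.mask]
    vox_cm3 = organ.voxel_volume / 1000.0
    edges = np.linspace(0.0, float(organ_dose.max()), n_bins + 1)
    volume = np.array([(organ_dose >= d).sum() * vox_cm3 for d in edges])
    return pd.DataFrame({"dose_gy": edges, "volume_cm3": volume})


def d2cc(dose: DoseGrid, organ: BinaryMask) -> float:
    """Minimum dose (Gy) in the most irradiated 2 cm^3 of the organ."""
    if organ.is_empty():
        raise ValueError("D2cc undefined for an empty organ")
    if dose.shape != organ.shape:
        raise ValueError(f"dose grid shape {dose.shape} != organ shape {organ.shape}")
    organ_dose = np.sort(dose.dose[organ.mask])[::-1]
    vol = organ.voxel_volume
    if len(organ_dose) * vol < D2CC_MM3:
        warnings.warn(
            f"organ volume {len(organ_dose) * vol / 1000.0:.2f} cm^3 < 2 cm^3; "
            "returning the organ's minimum dose", stacklevel=2)
        return float(organ_dose[-1])
    # index of the voxel whose cumulative volume first reaches 2 cm^3
    idx = int(np.ceil(D2CC_MM3 / vol)) - 1
    return float(organ_dose[idx])


def abs_d2cc_diff(pred_organ: BinaryMask, ref_organ: BinaryMask,
                  dose: DoseGrid, organ: str = "") -> DoseReport:
    """|D2cc(prediction) - D2cc(reference)| on a shared dose grid.

    A value closer to zero means the auto-contour meets the dosimetric
    requirement as well as the reference contour does.
    """
    validate_pair(pred_organ, ref_organ)
    dp = d2cc(dose, pred_organ)
    dr = d2cc(dose, ref_organ)
    return DoseReport(organ=organ, d2cc_pred=dp, d2cc_ref=dr, abs_diff=abs(dp - dr))
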