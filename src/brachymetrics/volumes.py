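"""Typed containers for 3D label maps and binary masks on a physical grid.

All downstream computations (distance maps, metrics, losses, dose) operate on
these two containers.  A :class:`LabeledVolume` holds one integer label map per
case with mutually exclusive structure labels (0 = background); a
:class:`BinaryMask` is one structure extracted from it.  Grids carry anisotropic
voxel spacing in millimetres; the physical position of a voxel centre is
``index * spacing``.  Orientation information beyond spacing is deliberately
ignored — every in-scope quantity depends only on relative distances.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

SPACING_ATOL_MM = 1e-6


class FormatError(ValueError):
    """Raised when an on-disk image cannot be interpreted as a label map."""


class GridMismatchError(ValueError):
    """Raised when two volumes do not share a common voxel grid."""


def _check_spacing(spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 strictly positive values in mm, got {spacing}")
    return spacing


@dataclass(frozen=True)
class LabeledVolume:
    """A 3D integer label map on a physical grid.

    Parameters
    ----------
    labels
        3D integer array; 0 is background, 1..C are structures.
    spacing
        Voxel spacing ``(sx, sy, sz)`` in mm, each strictly positive.
    label_names
        Optional mapping label value -> structure name
        (e.g. ``{1: "CTV_HR", 2: "bladder"}``).
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3 or min(labels.shape) < 1:
            raise ValueError(f"labels must be a 3D array, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError(f"labels must be integer-typed, got {labels.dtype}")
        if labels.min(initial=0) < 0:
            raise ValueError("negative label values are not allowed")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))
        object.__setattr__(self, "label_names", dict(self.label_names))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def present_labels(self) -> list[int]:
        """Sorted nonzero label values present in the map."""
        return [int(v) for v in np.unique(self.labels) if v != 0]

    def name_of(self, label: int) -> str:
        return self.label_names.get(label, str(label))


@dataclass(frozen=True)
class BinaryMask:
    """A single structure as a boolean mask on the parent grid."""

    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {mask.shape}")
        if mask.dtype != bool:
            mask = mask.astype(bool)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def voxel_volume(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume

    def is_empty(self) -> bool:
        return not self.mask.any()


def extract_binary(vol: LabeledVolume, label: int, strict: bool = True) -> BinaryMask:
    """Extract one structure as a :class:`BinaryMask`.

    With ``strict=True`` (default) an absent nonzero label is an error listing
    the labels that are present; with ``strict=False`` it yields an all-false
    mask.
    """
    label = int(label)
    mask = vol.labels == label
    if strict and label != 0 and not mask.any():
        raise KeyError(
            f"label {label} not present in volume; available labels: {vol.present_labels()}"
        )
    return BinaryMask(mask=mask, spacing=vol.spacing)


def validate_pair(a: LabeledVolume | BinaryMask, b: LabeledVolume | BinaryMask) -> None:
    """Check that two volumes/masks live on the same grid.

    Shapes must match exactly; spacings must agree within 1e-6 mm.  Every
    metric, loss and dose operation calls this before computing anything.
    """
    if a.shape != b.shape:
        raise GridMismatchError(f"grid shape mismatch: {a.shape} vs {b.shape}")
    sa, sb = np.asarray(a.spacing), np.asarray(b.spacing)
    if not np.allclose(sa, sb, rtol=0.0, atol=SPACING_ATOL_MM):
        raise GridMismatchError(f"voxel spacing mismatch: {tuple(sa)} vs {tuple(sb)} mm")


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_labelmap(path: str | Path, names_sidecar: str | Path | None = None) -> LabeledVolume:
    """Read a 3D integer NIfTI label map.

    Spacing is taken from the header zooms.  The affine is otherwise ignored;
    a non-diagonal affine triggers a warning because in-plane orientation does
    not affect any distance-based quantity but users may expect it preserved.
    An optional JSON sidecar maps label values to structure names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D image, got {data.ndim} dimensions")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.array_equal(rounded, data):
            raise FormatError(f"{path}: voxel data is not integer-valued")
        data = rounded.astype(np.int32)
    affine = img.affine
    if affine is not None:
        rot = affine[:3, :3]
        if not np.allclose(rot, np.diag(np.diagonal(rot)), atol=1e-4):
            logger.warning("%s: non-diagonal affine; orientation ignored, using header zooms", path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])

    names: dict[int, str] = {}
    if names_sidecar is not None:
        with open(names_sidecar) as fh:
            names = {int(k): str(v) for k, v in json.load(fh).items()}
    return LabeledVolume(labels=data.astype(np.int32), spacing=spacing, label_names=names)


def write_labelmap(vol: LabeledVolume, path: str | Path,
                   names_sidecar: str | Path | None = None) -> None:
    """Write a label map as NIfTI; re-reading recovers labels and spacing."""
    path = Path(path)
    affine = np.diag([*vol.spacing, 1.0])
    img = nib.Nifti1Image(vol.labels.astype(np.int16), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    if names_sidecar is not None and vol.label_names:
        with open(names_sidecar, "w") as fh:
            json.dump({str(k): v for k, v in vol.label_names.items()}, fh, indent=1)


def write_float_volume(data: np.ndarray, spacing: tuple[float, float, float],
                       path: str | Path) -> None:
    """Write a 3D float field (distance map, penalty map, dose) as NIfTI."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 3:
        raise ValueError("expected a 3D array")
    img = nib.Nifti1Image(data, np.diag([*spacing, 1.0]))
    img.header.set_zooms(spacing)
    nib.save(img, str(path))
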