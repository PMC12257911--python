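"""Reference implementations of the segmentation training losses.

Cross-entropy (CE), soft Dice, their sum (DiceCE), and the distance-penalized
variants DPCE and DPDiceCE, evaluated as pure array computations.  These are
oracle-grade references: any training-framework port (e.g. inside an nnU-Net
pipeline) can be validated against them, and analytic gradients with respect
to the predicted probabilities are provided for the same purpose.

Shapes: probabilities ``p`` and one-hot labels ``g`` are ``(C, X, Y, Z)``
(class-first); the distance-penalty map ``D`` is ``(X, Y, Z)`` and is shared
across classes — it is derived from the single target structure, and weighting
is applied voxel-wise:

    L_DPCE     = -(1/N) sum_c sum_i D_i g_ic log p_ic
    L_DPDiceCE = 1 - 2 sum_c sum_i D_i g_ic p_ic / (sum g + sum p) + L_CE

With D == 1 both reduce exactly to their unpenalized counterparts.  The Dice
term is pooled over all classes including background (under the per-voxel
simplex constraint the pooled denominator is always 2N); a ``foreground_only``
flag drops the background class for users porting to frameworks that do.
The CE term inside DPDiceCE is deliberately unweighted.

Probabilities are clamped to [eps, 1] with eps = 1e-7 before the log so that
hard one-hot predictions give a finite loss.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-7
SIMPLEX_ATOL = 1e-6


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """One-hot encode an integer label map to shape (C, *grid)."""
    labels = np.asarray(labels)
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= n_classes:
        raise ValueError(f"labels outside 0..{n_classes - 1}")
    g = np.zeros((n_classes, *labels.shape), dtype=np.float64)
    for c in range(n_classes):
        g[c] = labels == c
    return g


def _validate(g: np.ndarray, p: np.ndarray, D: np.ndarray | None = None) -> None:
    if g.shape != p.shape:
        raise ValueError(f"label/probability shape mismatch: {g.shape} vs {p.shape}")
    if g.ndim != 4 or g.shape[0] < 2:
        raise ValueError("expected (C, X, Y, Z) arrays with C >= 2")
    s = p.sum(axis=0)
    if np.abs(s - 1.0).max() > SIMPLEX_ATOL:
        raise ValueError("probabilities violate the per-voxel simplex constraint")
    if D is not None and D.shape != g.shape[1:]:
        raise ValueError(f"penalty map shape {D.shape} != grid shape {g.shape[1:]}")


def _n_vox(g: np.ndarray) -> int:
    return int(np.prod(g.shape[1:]))


def ce_loss(g: np.ndarray, p: np.ndarray) -> float:
    """Cross-entropy: -(1/N) sum_c sum_i g_ic log p_ic."""
    _validate(g, p)
    logp = np.log(np.clip(p, EPS, 1.0))
    return float(-(g * logp).sum() / _n_vox(g))


def dice_loss(g: np.ndarray, p: np.ndarray, foreground_only: bool = False) -> float:
    """Soft Dice pooled over classes: 1 - 2 sum(g p) / (sum g + sum p)."""
    _validate(g, p)
    if foreground_only:
        g, p = g[1:], p[1:]
    num = 2.0 * (g * p).sum()
    den = g.sum() + p.sum()
    return float(1.0 - num / den)


def dicece_loss(g: np.ndarray, p: np.ndarray, foreground_only: bool = False) -> float:
    """Combo loss: Dice + CE."""
    return dice_loss(g, p, foreground_only=foreground_only) + ce_loss(g, p)


def dpce_loss(g: np.ndarray, p: np.ndarray, D: np.ndarray) -> float:
    """Distance-penalized CE: the per-voxel CE term weighted by the penalty map."""
    _validate(g, p, D)
    logp = np.log(np.clip(p, EPS, 1.0))
    return float(-(D[None] * g * logp).sum() / _n_vox(g))


def dpdicece_loss(g: np.ndarray, p: np.ndarray, D: np.ndarray,
                  foreground_only: bool = False) -> float:
    """Distance-penalized DiceCE: Dice numerator weighted by the penalty map,
    denominator unweighted, plus an unweighted CE term."""
    _validate(g, p, D)
    gs, ps = (g[1:], p[1:]) if foreground_only else (g, p)
    num = 2.0 * (D[None] * gs * ps).sum()
    den = gs.sum() + ps.sum()
    return float(1.0 - num / den) + ce_loss(g, p)


# ---------------------------------------------------------------------------
# Analytic gradients w.r.t. p — the contract a training-framework port must
# satisfy.  The probability clamp is inactive for p in (eps, 1), which is
# where gradient checks should be run.


def ce_grad(g: np.ndarray, p: np.ndarray) -> np.ndarray:
    _validate(g, p)
    return -g / np.clip(p, EPS, 1.0) / _n_vox(g)


def dice_grad(g: np.ndarray, p: np.ndarray) -> np.ndarray:
    _validate(g, p)
    A = (g * p).sum()
    B = g.sum() + p.sum()
    return (-2.0 * g * B + 2.0 * A) / B**2


def dicece_grad(g: np.ndarray, p: np.ndarray) -> np.ndarray:
    return dice_grad(g, p) + ce_grad(g, p)


def dpce_grad(g: np.ndarray, p: np.ndarray, D: np.ndarray) -> np.ndarray:
    _validate(g, p, D)
    return -D[None] * g / np.clip(p, EPS, 1.0) / _n_vox(g)


def dpdicece_grad(g: np.ndarray, p: np.ndarray, D: np.ndarray) -> np.ndarray:
    _validate(g, p, D)
    A = (D[None] * g * p).sum()
    B = g.sum() + p.sum()
    return (-2.0 * D[None] * g * B + 2.0 * A) / B**2 + ce_grad(g, p)
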