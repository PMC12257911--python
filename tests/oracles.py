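"""Independent brute-force reference implementations used only by the tests.

Everything here is written with explicit loops / set arithmetic, independent
of the library's vectorized code paths, so the two can be compared on small
random fixtures.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.spatial.distance import cdist


def brute_edt(target: np.ndarray, spacing) -> np.ndarray:
    """All-pairs minimum centre-to-centre distance to the target set."""
    sx, sy, sz = spacing
    tgt = [(i * sx, j * sy, k * sz) for i, j, k in np.argwhere(target)]
    out = np.zeros(target.shape)
    for i in range(target.shape[0]):
        for j in range(target.shape[1]):
            for k in range(target.shape[2]):
                p = (i * sx, j * sy, k * sz)
                out[i, j, k] = min(
                    math.dist(p, t) for t in tgt)
    return out


def vdsc_sets(G: np.ndarray, P: np.ndarray) -> float:
    g = {tuple(v) for v in np.argwhere(G)}
    p = {tuple(v) for v in np.argwhere(P)}
    return 2.0 * len(g & p) / (len(g) + len(p))


def surface_faces(mask: np.ndarray, spacing):
    """Enumerate boundary faces voxel by voxel; returns (points, areas)."""
    sx, sy, sz = spacing
    steps = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    face_area = {0: sy * sz, 1: sx * sz, 2: sx * sy}
    pts, areas = [], []
    for i, j, k in np.argwhere(mask):
        for di, dj, dk in steps:
            ni, nj, nk = i + di, j + dj, k + dk
            outside = not (0 <= ni < mask.shape[0] and 0 <= nj < mask.shape[1]
                           and 0 <= nk < mask.shape[2])
            if outside or not mask[ni, nj, nk]:
                axis = 0 if di else (1 if dj else 2)
                c = [i * sx, j * sy, k * sz]
                c[axis] += (di + dj + dk) * (sx, sy, sz)[axis] / 2.0
                pts.append(c)
                areas.append(face_area[axis])
    return np.array(pts), np.array(areas)


def weighted_percentile(values, weights, q) -> float:
    # collapse tied values, summing their weights, so order cannot matter
    grouped: dict[float, float] = {}
    for val, wt in zip(values, weights):
        grouped[float(val)] = grouped.get(float(val), 0.0) + float(wt)
    v = np.array(sorted(grouped))
    w = np.array([grouped[val] for val in v])
    frac = np.cumsum(w) / w.sum()
    target = q / 100.0
    if target <= frac[0]:
        return float(v[0])
    for a in range(1, len(v)):
        if frac[a] >= target:
            f0, f1 = frac[a - 1], frac[a]
            if f1 == f0:
                return float(v[a])
            return float(v[a - 1] + (v[a] - v[a - 1]) * (target - f0) / (f1 - f0))
    return float(v[-1])


def _surface_dists(G, P, spacing):
    pg, ag = surface_faces(G, spacing)
    pp, ap_ = surface_faces(P, spacing)
    D = cdist(pg, pp)
    return D.min(axis=1), ag, D.min(axis=0), ap_


def hd95_brute(G, P, spacing, q=95.0) -> float:
    d_gp, ag, d_pg, ap_ = _surface_dists(G, P, spacing)
    return max(weighted_percentile(d_gp, ag, q), weighted_percentile(d_pg, ap_, q))


def assd_brute(G, P, spacing) -> float:
    d_gp, ag, d_pg, ap_ = _surface_dists(G, P, spacing)
    return (float(d_gp @ ag) + float(d_pg @ ap_)) / (ag.sum() + ap_.sum())


def sdsc_brute(G, P, spacing, tol=1.0) -> float:
    d_gp, ag, d_pg, ap_ = _surface_dists(G, P, spacing)
    return (ag[d_gp <= tol].sum() + ap_[d_pg <= tol].sum()) / (ag.sum() + ap_.sum())


def slice_contour_pixels(slice2d: np.ndarray) -> set:
    """True pixels with a false/out-of-grid neighbour in 8-connectivity."""
    out = set()
    nx, ny = slice2d.shape
    for i, j in np.argwhere(slice2d):
        for di, dj in itertools.product((-1, 0, 1), repeat=2):
            if di == dj == 0:
                continue
            ni, nj = i + di, j + dj
            if not (0 <= ni < nx and 0 <= nj < ny) or not slice2d[ni, nj]:
                out.add((i, j))
                break
    return out


def apl_brute(G, P, spacing) -> float:
    sx, sy, _ = spacing
    n = 0
    for k in range(G.shape[2]):
        cg = slice_contour_pixels(G[:, :, k])
        cp = slice_contour_pixels(P[:, :, k])
        n += len(cg - cp)
    return n * (sx + sy) / 2.0 / 10.0


def wdsc_brute(G, P, dist, n_crops) -> float:
    """Materialize every nested crop explicitly and aggregate."""
    r_max = dist.max()
    total = 0.0
    for i in range(1, n_crops + 1):
        c_i = math.inf if i == 1 else r_max * (n_crops - i + 1) / n_crops
        sel = dist <= c_i
        g, p = G & sel, P & sel
        if not g.any() and not p.any():
            v = 1.0
        else:
            v = 2.0 * np.count_nonzero(g & p) / (np.count_nonzero(g) + np.count_nonzero(p))
        total += (i / n_crops) * (1.0 - v)
    return 1.0 - total / n_crops


def d2cc_brute(organ_doses: np.ndarray, voxel_mm3: float) -> float:
    """Max threshold t among organ doses with volume{dose >= t} >= 2000 mm^3."""
    best = None
    for t in np.unique(organ_doses):
        if np.count_nonzero(organ_doses >= t) * voxel_mm3 >= 2000.0:
            best = t
    return float(best)


def pearson_brute(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))


def ols_brute(x, y):
    """Normal equations for [intercept, slope]."""
    X = np.stack([np.ones_like(x, dtype=float), np.asarray(x, float)], axis=1)
    beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(y, float))
    yhat = X @ beta
    ss_res = ((y - yhat) ** 2).sum()
    ss_tot = ((y - np.mean(y)) ** 2).sum()
    return float(beta[1]), float(beta[0]), float(1.0 - ss_res / ss_tot)


def wilcoxon_exact_brute(a, b) -> tuple[float, float]:
    """Two-sided exact signed-rank p by full sign enumeration (with mid-ranks)."""
    d = [ai - bi for ai, bi in zip(a, b) if ai != bi]
    n = len(d)
    absd = sorted((abs(v), idx) for idx, v in enumerate(d))
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and absd[j + 1][0] == absd[i][0]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[absd[t][1]] = mid
        i = j + 1
    w_plus = sum(r for r, v in zip(ranks, d) if v > 0)
    sums = []
    for signs in itertools.product((0, 1), repeat=n):
        sums.append(sum(r for s, r in zip(signs, ranks) if s))
    ge = sum(1 for s in sums if s >= w_plus - 1e-9) / len(sums)
    le = sum(1 for s in sums if s <= w_plus + 1e-9) / len(sums)
    return w_plus, min(1.0, 2.0 * min(ge, le))


def random_blob_mask(rng: np.random.Generator, shape, p_seed=0.08,
                     smooth_iters=1) -> np.ndarray:
    """Random connected-ish non-empty mask: scattered seeds, then majority growth."""
    from scipy import ndimage
    m = rng.random(shape) < p_seed
    for _ in range(smooth_iters):
        m = ndimage.binary_dilation(m)
    if not m.any():
        m[tuple(rng.integers(0, s) for s in shape)] = True
    return m
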