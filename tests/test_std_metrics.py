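import numpy as np
import pytest

from brachymetrics import (GridMismatchError, apl, assd, extract_surface, hd95,
                           sdsc, vdsc)
from conftest import make_mask
import oracles


def pair(rng, shape=(8, 8, 4), spacing=(1.0, 1.0, 2.0)):
    G = oracles.random_blob_mask(rng, shape)
    P = oracles.random_blob_mask(rng, shape)
    return make_mask(G, spacing), make_mask(P, spacing)


class TestVdsc:
    def test_identical_masks_give_one(self, rng):
        G, _ = pair(rng)
        assert vdsc(G, G) == 1.0

    def test_half_overlap(self):
        g = np.zeros((4, 4, 1), bool); g[0, 0] = g[0, 1] = True
        p = np.zeros((4, 4, 1), bool); p[0, 1] = p[0, 2] = True
        assert vdsc(make_mask(g), make_mask(p)) == pytest.approx(0.5)

    def test_both_empty_raises_one_empty_zero(self):
        e = make_mask(np.zeros((3, 3, 3)))
        full = np.zeros((3, 3, 3)); full[1, 1, 1] = 1
        f = make_mask(full)
        with pytest.raises(ValueError):
            vdsc(e, e)
        assert vdsc(f, e) == 0.0

    def test_symmetry_and_oracle(self, rng):
        for _ in range(20):
            G, P = pair(rng)
            expected = oracles.vdsc_sets(G.mask, P.mask)
            assert vdsc(G, P) == pytest.approx(expected)
            assert vdsc(P, G) == pytest.approx(vdsc(G, P))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(GridMismatchError):
            vdsc(make_mask(np.ones((3, 3, 3))), make_mask(np.ones((3, 3, 4))))


class TestSurface:
    def test_single_voxel_cube(self):
        m = np.zeros((3, 3, 3), bool); m[1, 1, 1] = True
        s = extract_surface(make_mask(m))
        assert len(s) == 6
        assert s.total_area == pytest.approx(6.0)

    def test_two_voxel_bar_has_ten_faces(self):
        m = np.zeros((4, 3, 3), bool); m[1:3, 1, 1] = True
        assert len(extract_surface(make_mask(m))) == 10

    def test_solid_block_has_no_interior_faces(self):
        m = np.ones((3, 3, 3), bool)
        s = extract_surface(make_mask(m, (1, 1, 1)))
        assert len(s) == 6 * 9  # only the outer shell
        assert s.total_area == pytest.approx(54.0)

    def test_anisotropic_face_areas(self):
        m = np.zeros((3, 3, 3), bool); m[1, 1, 1] = True
        s = extract_surface(make_mask(m, (1.0, 2.0, 3.0)))
        # 2 faces each of area 6, 3, 2
        assert sorted(s.areas) == pytest.approx([2, 2, 3, 3, 6, 6])

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            G, _ = pair(rng)
            s = extract_surface(G)
            pts, areas = oracles.surface_faces(G.mask, G.spacing)
            assert len(s) == len(pts)
            assert s.total_area == pytest.approx(areas.sum())
            got = sorted(map(tuple, np.round(s.points, 6)))
            exp = sorted(map(tuple, np.round(pts, 6)))
            assert got == exp


class TestSurfaceDistances:
    def test_identical_masks(self, rng):
        G, _ = pair(rng)
        assert hd95(G, G) == 0.0
        assert assd(G, G) == 0.0
        assert sdsc(G, G) == 1.0

    def test_two_voxels_five_mm_apart(self):
        g = np.zeros((8, 3, 3), bool); g[0, 1, 1] = True
        p = np.zeros((8, 3, 3), bool); p[5, 1, 1] = True
        assert hd95(make_mask(g), make_mask(p), q=100.0) == pytest.approx(5.0)

    def test_hd95_below_full_hausdorff(self, rng):
        for _ in range(10):
            G, P = pair(rng)
            assert hd95(G, P) <= hd95(G, P, q=100.0) + 1e-12

    def test_translation_bounds_assd(self):
        g = np.zeros((6, 6, 6), bool); g[1:4, 1:4, 1:4] = True
        p = np.roll(g, 1, axis=0)
        assert assd(make_mask(g), make_mask(p)) <= 1.0 + 1e-12

    def test_sdsc_zero_when_far_one_when_tol_large(self):
        g = np.zeros((10, 3, 3), bool); g[0, 1, 1] = True
        p = np.zeros((10, 3, 3), bool); p[8, 1, 1] = True
        G, P = make_mask(g), make_mask(p)
        assert sdsc(G, P, tol=1.0) == 0.0
        assert sdsc(G, P, tol=100.0) == 1.0

    def test_empty_mask_raises(self):
        e = make_mask(np.zeros((3, 3, 3)))
        f = make_mask(np.eye(3)[..., None] > 0)
        for fn in (hd95, assd, sdsc):
            with pytest.raises(ValueError):
                fn(f, e)

    def test_against_brute_force(self, rng):
        for _ in range(15):
            G, P = pair(rng, shape=(7, 7, 3))
            sp = G.spacing
            assert hd95(G, P) == pytest.approx(
                oracles.hd95_brute(G.mask, P.mask, sp), abs=1e-9)
            assert assd(G, P) == pytest.approx(
                oracles.assd_brute(G.mask, P.mask, sp), abs=1e-9)
            assert sdsc(G, P) == pytest.approx(
                oracles.sdsc_brute(G.mask, P.mask, sp), abs=1e-12)

    def test_symmetry(self, rng):
        for _ in range(5):
            G, P = pair(rng)
            assert hd95(G, P) == pytest.approx(hd95(P, G))
            assert assd(G, P) == pytest.approx(assd(P, G))
            assert sdsc(G, P) == pytest.approx(sdsc(P, G))


class TestApl:
    def test_identical_masks_give_zero(self, rng):
        G, _ = pair(rng)
        assert apl(G, G) == 0.0

    def test_empty_prediction_gives_full_contour(self):
        g = np.zeros((5, 5, 1), bool); g[1:4, 1:4, 0] = True
        G = make_mask(g, (1, 1, 3))
        P = make_mask(np.zeros_like(g), (1, 1, 3))
        # 3x3 square: 8 contour pixels (8-connectivity), 1 mm pixels -> 0.8 cm
        assert apl(G, P) == pytest.approx(0.8)

    def test_single_slice_shift_matches_set_difference(self):
        g = np.zeros((6, 6, 1), bool); g[1:4, 1:4, 0] = True
        p = np.roll(g, 1, axis=1)
        G, P = make_mask(g), make_mask(p)
        cg = oracles.slice_contour_pixels(g[:, :, 0])
        cp = oracles.slice_contour_pixels(p[:, :, 0])
        assert apl(G, P) == pytest.approx(len(cg - cp) / 10.0)

    def test_asymmetric_by_design(self, rng):
        vals = []
        for _ in range(20):
            G, P = pair(rng)
            vals.append(abs(apl(G, P) - apl(P, G)))
        assert max(vals) > 0  # GT-referenced: direction matters

    def test_against_brute_force(self, rng):
        for _ in range(15):
            G, P = pair(rng, spacing=(0.8, 1.2, 3.0))
            assert apl(G, P) == pytest.approx(
                oracles.apl_brute(G.mask, P.mask, G.spacing), abs=1e-12)


class TestMonotonicDegradation:
    def test_growing_error_never_helps(self, rng):
        """Nested dilations of the prediction: overlap metrics never increase,
        ASSD never decreases."""
        from scipy import ndimage
        g = np.zeros((10, 10, 6), bool); g[3:7, 3:7, 2:4] = True
        G = make_mask(g, (1, 1, 2))
        prev_v, prev_s, prev_a = 1.0, 1.0, 0.0
        p = g.copy()
        for _ in range(3):
            p = ndimage.binary_dilation(p)
            P = make_mask(p, (1, 1, 2))
            v, s, a = vdsc(G, P), sdsc(G, P), assd(G, P)
            assert v <= prev_v + 1e-12
            assert s <= prev_s + 1e-12
            assert a >= prev_a - 1e-12
            prev_v, prev_s, prev_a = v, s, a
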