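import numpy as np
import pytest

from brachymetrics import (SourceDwell, abs_d2cc_diff, compute_dose,
                           cumulative_dvh, d2cc)
from brachymetrics.dose_surrogate import DoseGrid
from conftest import make_mask
from oracles import d2cc_brute


def uniform_dose(value, shape=(10, 10, 10), spacing=(5.0, 5.0, 8.0)):
    return DoseGrid(dose=np.full(shape, float(value)), spacing=spacing)


class TestComputeDose:
    def test_inverse_square_point_value(self):
        src = SourceDwell(position=(0.0, 0.0, 0.0), strength=100.0)
        dg = compute_dose([src], (12, 1, 1), (1.0, 1.0, 1.0), r_clamp=0.5)
        assert dg.dose[10, 0, 0] == pytest.approx(1.0)

    def test_superposition(self):
        s1 = SourceDwell((0.0, 0.0, 0.0), 50.0)
        s2 = SourceDwell((4.0, 0.0, 0.0), 80.0)
        a = compute_dose([s1], (8, 2, 2), (1, 1, 1)).dose
        b = compute_dose([s2], (8, 2, 2), (1, 1, 1)).dose
        both = compute_dose([s1, s2], (8, 2, 2), (1, 1, 1)).dose
        np.testing.assert_allclose(both, a + b, rtol=1e-12)

    def test_clamp_saturates_near_source(self):
        src = SourceDwell((1.0, 1.0, 1.0), 100.0)
        dg = compute_dose([src], (3, 3, 3), (1, 1, 1), r_clamp=10.0)
        np.testing.assert_allclose(dg.dose, 1.0)

    def test_falls_off_monotonically_beyond_clamp(self):
        src = SourceDwell((0.0, 0.0, 0.0), 100.0)
        line = compute_dose([src], (30, 1, 1), (1, 1, 1), r_clamp=2.0).dose[:, 0, 0]
        assert (np.diff(line[2:]) < 0).all()

    def test_no_sources_rejected(self):
        with pytest.raises(ValueError):
            compute_dose([], (3, 3, 3), (1, 1, 1))

    def test_nonpositive_strength_rejected(self):
        with pytest.raises(ValueError):
            SourceDwell((0, 0, 0), 0.0)


class TestDvh:
    def test_uniform_dose_step_function(self):
        organ = make_mask(np.ones((2, 2, 1)), (5.0, 5.0, 40.0))  # 4 cm^3 organ
        assert organ.volume_mm3 == pytest.approx(4000.0)
        dvh = cumulative_dvh(uniform_dose(10.0, (2, 2, 1), (5, 5, 40)), organ, n_bins=5)
        np.testing.assert_allclose(dvh["volume_cm3"], 4.0)  # all bins <= max dose

    def test_volume_at_zero_dose_is_organ_volume(self, rng):
        organ = make_mask(rng.random((6, 6, 6)) > 0.5, (2.0, 2.0, 5.0))
        dose = DoseGrid(rng.uniform(0, 20, (6, 6, 6)), (2.0, 2.0, 5.0))
        dvh = cumulative_dvh(dose, organ)
        assert dvh["volume_cm3"].iloc[0] == pytest.approx(organ.volume_mm3 / 1000.0)

    def test_monotone_nonincreasing_and_counting_oracle(self, rng):
        organ = make_mask(rng.random((6, 6, 6)) > 0.4, (3.0, 3.0, 6.0))
        dose = DoseGrid(rng.uniform(0, 15, (6, 6, 6)), (3.0, 3.0, 6.0))
        dvh = cumulative_dvh(dose, organ, n_bins=20)
        vols = dvh["volume_cm3"].to_numpy()
        assert (np.diff(vols) <= 1e-12).all()
        organ_doses = dose.dose[organ.mask]
        for d, v in zip(dvh["dose_gy"], vols):
            expected = (organ_doses >= d).sum() * organ.voxel_volume / 1000.0
            assert v == pytest.approx(expected)

    def test_empty_organ_rejected(self):
        with pytest.raises(ValueError):
            cumulative_dvh(uniform_dose(1.0), make_mask(np.zeros((10, 10, 10)),
                                                        (5, 5, 8)))


class TestD2cc:
    def test_uniform_dose(self):
        organ = make_mask(np.ones((2, 2, 5)), (5.0, 5.0, 40.0))
        assert d2cc(uniform_dose(10.0, (2, 2, 5), (5, 5, 40)), organ) == 10.0

    def test_four_voxel_hand_example(self):
        # 4 voxels of 1 cm^3 with doses 8, 6, 4, 2: hottest 2 cm^3 = {8, 6}
        dose = DoseGrid(np.array([8.0, 6.0, 4.0, 2.0]).reshape(4, 1, 1),
                        (10.0, 10.0, 10.0))
        organ = make_mask(np.ones((4, 1, 1)), (10.0, 10.0, 10.0))
        assert d2cc(dose, organ) == pytest.approx(6.0)

    def test_shrinking_to_hottest_2cc_preserves_value(self):
        dose = DoseGrid(np.array([8.0, 6.0, 4.0, 2.0]).reshape(4, 1, 1),
                        (10.0, 10.0, 10.0))
        hottest = make_mask(np.array([1, 1, 0, 0]).reshape(4, 1, 1),
                            (10.0, 10.0, 10.0))
        assert d2cc(dose, hottest) == pytest.approx(6.0)

    def test_small_organ_warns_and_returns_min(self):
        dose = DoseGrid(np.array([9.0, 3.0]).reshape(2, 1, 1), (8.0, 8.0, 8.0))
        organ = make_mask(np.ones((2, 1, 1)), (8.0, 8.0, 8.0))  # ~1 cm^3
        with pytest.warns(UserWarning, match="2 cm"):
            assert d2cc(dose, organ) == pytest.approx(3.0)

    def test_between_min_and_max_and_shift_equivariant(self, rng):
        organ = make_mask(rng.random((8, 8, 8)) > 0.3, (4.0, 4.0, 4.0))
        vals = rng.uniform(0, 30, (8, 8, 8))
        d0 = d2cc(DoseGrid(vals, (4, 4, 4)), organ)
        organ_doses = vals[organ.mask]
        assert organ_doses.min() <= d0 <= organ_doses.max()
        d5 = d2cc(DoseGrid(vals + 5.0, (4, 4, 4)), organ)
        assert d5 == pytest.approx(d0 + 5.0)

    def test_matches_threshold_oracle(self, rng):
        for _ in range(20):
            organ = make_mask(rng.random((6, 6, 6)) > 0.4, (4.0, 4.0, 7.0))
            vals = rng.uniform(0, 12, (6, 6, 6))
            got = d2cc(DoseGrid(vals, (4.0, 4.0, 7.0)), organ)
            exp = d2cc_brute(vals[organ.mask], organ.voxel_volume)
            assert got == pytest.approx(exp)

    def test_dvh_consistency(self, rng):
        """d2cc equals the highest DVH sample dose whose volume still
        reaches 2 cm^3 (voxel-resolution agreement)."""
        organ = make_mask(rng.random((8, 8, 8)) > 0.3, (4.0, 4.0, 4.0))
        dose = DoseGrid(rng.uniform(0, 30, (8, 8, 8)), (4.0, 4.0, 4.0))
        val = d2cc(dose, organ)
        dvh = cumulative_dvh(dose, organ, n_bins=400)
        crossing = dvh[dvh["volume_cm3"] >= 2.0]["dose_gy"].max()
        assert abs(val - crossing) <= dvh["dose_gy"].iloc[1] + 1e-9


class TestAbsD2ccDiff:
    def test_identical_contours_give_zero(self, rng):
        organ = make_mask(rng.random((8, 8, 8)) > 0.3, (4.0, 4.0, 4.0))
        dose = DoseGrid(rng.uniform(0, 30, (8, 8, 8)), (4.0, 4.0, 4.0))
        assert abs_d2cc_diff(organ, organ, dose).abs_diff == 0.0

    def test_symmetric_under_swap(self, rng):
        a = make_mask(rng.random((8, 8, 8)) > 0.3, (4.0, 4.0, 4.0))
        b = make_mask(rng.random((8, 8, 8)) > 0.3, (4.0, 4.0, 4.0))
        dose = DoseGrid(rng.uniform(0, 30, (8, 8, 8)), (4.0, 4.0, 4.0))
        assert abs_d2cc_diff(a, b, dose).abs_diff == pytest.approx(
            abs_d2cc_diff(b, a, dose).abs_diff)

    def test_missing_hottest_voxel_hand_example(self):
        dose = DoseGrid(np.array([8.0, 6.0, 4.0, 2.0]).reshape(4, 1, 1),
                        (10.0, 10.0, 10.0))
        pred = make_mask(np.ones((4, 1, 1)), (10.0, 10.0, 10.0))
        ref = make_mask(np.array([0, 1, 1, 1]).reshape(4, 1, 1),
                        (10.0, 10.0, 10.0))  # lost the 8 Gy voxel
        rep = abs_d2cc_diff(pred, ref, dose)
        assert rep.d2cc_pred == pytest.approx(6.0)
        assert rep.d2cc_ref == pytest.approx(4.0)
        assert rep.abs_diff == pytest.approx(2.0)
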