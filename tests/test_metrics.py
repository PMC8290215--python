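"""Surface distances, volume decomposition, dose coverage, recurrence overlap."""

import numpy as np
import pytest

from aminopet import (
    ImageVolume,
    Unit,
    UnitError,
    dice,
    dose_coverage,
    hd95_directed,
    overlap_decomposition,
    recurrence_analysis,
    surface_voxels,
    svc_distances,
)
from helpers import brute_hd95, brute_surface, brute_svc, make_mask, random_blob


class TestSurfaceVoxels:
    def test_single_voxel_is_its_own_surface(self):
        data = np.zeros((5, 5, 5), dtype=bool)
        data[2, 2, 2] = True
        out = surface_voxels(make_mask(data))
        np.testing.assert_array_equal(out.data, data)

    def test_solid_block_surface_count(self):
        data = np.zeros((5, 5, 5), dtype=bool)
        data[1:4, 1:4, 1:4] = True
        assert surface_voxels(make_mask(data)).voxel_count == 26

    def test_grid_edge_counts_as_outside(self):
        out = surface_voxels(make_mask(np.ones((3, 3, 3))))
        assert out.voxel_count == 26  # all but the centre

    def test_matches_bruteforce(self, rng):
        for _ in range(5):
            blob = random_blob(rng, (9, 10, 8))
            np.testing.assert_array_equal(surface_voxels(blob).data, brute_surface(blob.data))

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            surface_voxels(make_mask(np.zeros((3, 3, 3))))


class TestHd95:
    def test_self_distance_zero(self, rng):
        blob = random_blob(rng)
        assert hd95_directed(blob, blob) == 0.0

    def test_two_point_case(self):
        a = np.zeros((8, 8, 8), dtype=bool)
        b = np.zeros((8, 8, 8), dtype=bool)
        a[2, 2, 2] = True
        b[2, 2, 5] = True
        assert hd95_directed(make_mask(a), make_mask(b)) == pytest.approx(3.0)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(10):
            a = random_blob(rng, (12, 11, 10), spacing=(1.0, 1.5, 2.0))
            b = random_blob(rng, (12, 11, 10), spacing=(1.0, 1.5, 2.0))
            assert hd95_directed(a, b) == pytest.approx(brute_hd95(a, b), abs=1e-9)

    def test_asymmetric_in_general(self):
        a = np.zeros((20, 6, 6), dtype=bool)
        b = np.zeros((20, 6, 6), dtype=bool)
        a[2:4, 2:4, 2:4] = True
        b[2:16, 2:4, 2:4] = True
        assert hd95_directed(make_mask(b), make_mask(a)) > hd95_directed(make_mask(a), make_mask(b))

    def test_monotone_in_percentile(self, rng):
        a = random_blob(rng)
        b = random_blob(rng)
        assert hd95_directed(a, b, 100.0) >= hd95_directed(a, b, 95.0)

    def test_translation_invariance(self, rng):
        a = np.zeros((16, 16, 16), dtype=bool)
        b = np.zeros((16, 16, 16), dtype=bool)
        a[4:7, 4:7, 4:7] = True
        b[5:10, 5:8, 4:7] = True
        shifted = (np.roll(a, (3, 2, 1), axis=(0, 1, 2)), np.roll(b, (3, 2, 1), axis=(0, 1, 2)))
        d0 = hd95_directed(make_mask(a), make_mask(b))
        d1 = hd95_directed(make_mask(shifted[0]), make_mask(shifted[1]))
        assert d0 == pytest.approx(d1, abs=1e-12)

    def test_empty_inputs_rejected(self, rng):
        blob = random_blob(rng)
        empty = make_mask(np.zeros(blob.grid.shape))
        with pytest.raises(ValueError):
            hd95_directed(blob, empty)
        with pytest.raises(ValueError):
            hd95_directed(empty, blob)


class TestSvcDistances:
    def test_subset_btv_gives_zero(self, rng):
        gtv = random_blob(rng)
        assert svc_distances(gtv, gtv) == (0.0, 0.0)

    def test_one_voxel_svc(self):
        gtv = np.zeros((8, 8, 8), dtype=bool)
        gtv[3, 3, 3] = True
        btv = gtv.copy()
        btv[3, 3, 7] = True
        mx, mn = svc_distances(make_mask(gtv), make_mask(btv))
        assert mx == pytest.approx(4.0) and mn == pytest.approx(4.0)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(10):
            gtv = random_blob(rng, (11, 10, 12), spacing=(2.0, 1.0, 1.0))
            btv = random_blob(rng, (11, 10, 12), spacing=(2.0, 1.0, 1.0), threshold_pct=60.0)
            got = svc_distances(gtv, btv)
            want = brute_svc(gtv, btv)
            assert got[0] == pytest.approx(want[0], abs=1e-9)
            assert got[1] == pytest.approx(want[1], abs=1e-9)

    def test_empty_gtv_rejected(self, rng):
        blob = random_blob(rng)
        with pytest.raises(ValueError):
            svc_distances(make_mask(np.zeros(blob.grid.shape)), blob)


class TestOverlapDecomposition:
    def test_identical_masks(self, rng):
        blob = random_blob(rng)
        total, within, outside, frac = overlap_decomposition(blob, blob)
        assert outside == 0.0 and frac == 0.0 and within == total

    def test_disjoint_masks(self):
        a = np.zeros((8, 8, 8), dtype=bool)
        b = np.zeros((8, 8, 8), dtype=bool)
        a[:2], b[6:] = True, True
        total, within, outside, frac = overlap_decomposition(make_mask(a), make_mask(b))
        assert frac == 1.0 and within == 0.0 and outside == total

    def test_volume_conservation_exact(self, rng):
        for _ in range(10):
            a = random_blob(rng, threshold_pct=60.0)
            b = random_blob(rng, threshold_pct=60.0)
            total, within, outside, _ = overlap_decomposition(a, b)
            assert within + outside == total

    def test_printed_table_style_fraction(self):
        # a BTV of 96.7 cm³ with 68.1 cm³ outside the GTV -> fraction 68.1/96.7
        btv = np.zeros((100, 100, 12), dtype=bool)
        gtv = np.zeros((100, 100, 12), dtype=bool)
        btv.ravel()[:96700] = True
        gtv.ravel()[68100:96700] = True  # overlap of 28600 voxels
        total, within, outside, frac = overlap_decomposition(make_mask(btv), make_mask(gtv))
        assert total == pytest.approx(96.7)
        assert outside == pytest.approx(68.1)
        assert frac == pytest.approx(68.1 / 96.7, abs=1e-12)

    def test_empty_btv_fraction_zero(self, rng):
        blob = random_blob(rng)
        empty = make_mask(np.zeros(blob.grid.shape))
        assert overlap_decomposition(empty, blob)[3] == 0.0


class TestDoseCoverage:
    def dose(self, data):
        return ImageVolume.from_array(data, (1, 1, 1), unit=Unit.GY)

    def test_uniform_prescription_fully_covers(self):
        mask = make_mask(np.ones((4, 4, 4)))
        rep = dose_coverage(self.dose(np.full((4, 4, 4), 60.0)), mask, 60.0)
        assert rep.covered_fraction == 1.0
        assert rep.iso_level_Gy == pytest.approx(57.0)

    def test_zero_dose_covers_nothing(self):
        mask = make_mask(np.ones((4, 4, 4)))
        assert dose_coverage(self.dose(np.zeros((4, 4, 4))), mask, 60.0).covered_fraction == 0.0

    def test_half_covered_inclusive_comparison(self):
        data = np.full((4, 4, 4), 50.0)
        data[:2] = 57.0  # exactly the 95% level of 60 Gy
        mask = make_mask(np.ones((4, 4, 4)))
        assert dose_coverage(self.dose(data), mask, 60.0).covered_fraction == 0.5

    def test_rejects_wrong_unit_and_empty_mask(self):
        good = self.dose(np.ones((3, 3, 3)))
        with pytest.raises(UnitError):
            dose_coverage(ImageVolume.from_array(np.ones((3, 3, 3)), (1, 1, 1),
                                                 unit=Unit.SUV), make_mask(np.ones((3, 3, 3))), 60.0)
        with pytest.raises(ValueError):
            dose_coverage(good, make_mask(np.zeros((3, 3, 3))), 60.0)


class TestRecurrenceAnalysis:
    def test_inside_and_disjoint(self):
        rec = np.zeros((10, 10, 10), dtype=bool)
        rec[4:6, 4:6, 4:6] = True
        ptv = np.zeros((10, 10, 10), dtype=bool)
        ptv[2:8, 2:8, 2:8] = True
        gtv = np.zeros((10, 10, 10), dtype=bool)
        gtv[8:, 8:, 8:] = True
        out = recurrence_analysis(make_mask(rec), {"PTV": make_mask(ptv), "GTV": make_mask(gtv)})
        assert out == {"PTV": 0.0, "GTV": 1.0}

    def test_empty_recurrence_rejected(self, rng):
        blob = random_blob(rng)
        with pytest.raises(ValueError):
            recurrence_analysis(make_mask(np.zeros(blob.grid.shape)), {"GTV": blob})


class TestDice:
    def test_identical_and_disjoint(self, rng):
        blob = random_blob(rng)
        assert dice(blob, blob) == 1.0
        a = np.zeros((6, 6, 6), dtype=bool)
        b = np.zeros((6, 6, 6), dtype=bool)
        a[0], b[5] = True, True
        assert dice(make_mask(a), make_mask(b)) == 0.0
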