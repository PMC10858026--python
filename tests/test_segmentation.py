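"""Fiber segmentation, stroma partition, cell/vessel detection."""

import numpy as np
import pytest

from imcfiber.matching import match_labels
from imcfiber.roi import mask_area
from imcfiber.segment import (
    CellObject,
    SegmentationParams,
    VesselObject,
    classify_macrophages,
    detect_capillaries,
    detect_cells,
    nearest_structure_distance,
    segment_fibers,
    stroma_mask,
)
from imcfiber.synth import generate_lattice


@pytest.fixture(scope="module")
def lattice_noisy():
    stack, gt = generate_lattice(seed=3)
    return stack, gt


class TestSegmentFibers:
    def test_clean_lattice_recovers_16_fibers(self):
        stack, gt = generate_lattice(seed=0, poisson_noise=False)
        labels = segment_fibers(
            stack.plane("Laminin"), np.ones(stack.shape, bool), SegmentationParams()
        )
        assert labels.max() == 16
        areas = np.bincount(labels.ravel())[1:]
        assert np.all(np.abs(areas - 1600) <= 160)  # each within ±10% of 1600 µm²

    def test_noisy_lattice_iou_recovery(self, lattice_noisy):
        stack, gt = lattice_noisy
        labels = segment_fibers(
            stack.plane("Laminin"), np.ones(stack.shape, bool), SegmentationParams()
        )
        matches, frac = match_labels(gt.fiber_labels, labels, iou_min=0.7)
        assert frac >= 0.95

    def test_all_zero_laminin_gives_no_fibers(self):
        roi = np.ones((60, 60), bool)
        with pytest.warns(UserWarning, match="no fibers"):
            labels = segment_fibers(
                np.zeros((60, 60)), roi,
                SegmentationParams(exclude_border=True, max_fiber_area_um2=10000.0),
            )
        assert labels.max() == 0

    def test_deterministic_and_canonically_labeled(self, lattice_noisy):
        stack, _ = lattice_noisy
        roi = np.ones(stack.shape, bool)
        a = segment_fibers(stack.plane("Laminin"), roi, SegmentationParams())
        b = segment_fibers(stack.plane("Laminin"), roi, SegmentationParams())
        np.testing.assert_array_equal(a, b)
        present = np.unique(a)
        np.testing.assert_array_equal(present, np.arange(a.max() + 1))
        # raster-order canonicalization: first occurrences appear in order
        firsts = [np.flatnonzero(a.ravel() == k)[0] for k in range(1, a.max() + 1)]
        assert firsts == sorted(firsts)

    def test_max_area_gate_drops_giant_components(self):
        stack, _ = generate_lattice(seed=0, poisson_noise=False)
        labels = segment_fibers(
            stack.plane("Laminin"), np.ones(stack.shape, bool),
            SegmentationParams(max_fiber_area_um2=1000.0),
        )
        assert labels.max() == 0  # every 1600 µm² fiber exceeds the gate

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            segment_fibers(np.zeros((8, 8)), np.zeros((8, 8), bool))


class TestStromaMask:
    def test_empty_labelmap_gives_whole_roi(self):
        roi = np.ones((10, 10), bool)
        np.testing.assert_array_equal(stroma_mask(roi, np.zeros((10, 10), int)), roi)

    def test_partition_identity_on_lattice(self, lattice_noisy):
        stack, _ = lattice_noisy
        roi = np.ones(stack.shape, bool)
        labels = segment_fibers(stack.plane("Laminin"), roi, SegmentationParams())
        stroma = stroma_mask(roi, labels)
        assert mask_area(stroma) + mask_area(labels > 0) == mask_area(roi)
        assert not (stroma & (labels > 0)).any()

    def test_fully_tiled_roi_leaves_only_boundary(self):
        # on the clean lattice the stroma is exactly the wall network
        stack, gt = generate_lattice(seed=0, poisson_noise=False)
        roi = np.ones(stack.shape, bool)
        labels = segment_fibers(stack.plane("Laminin"), roi, SegmentationParams())
        stroma = stroma_mask(roi, labels)
        wall_area = mask_area(gt.stroma_mask)
        assert abs(mask_area(stroma) - wall_area) / wall_area < 0.15


def _blob_masks(shape, centers, radius, with_nuclei=True):
    from skimage.draw import disk

    marker = np.zeros(shape, bool)
    nuclei = np.zeros(shape, bool)
    for r, c in centers:
        rr, cc = disk((r, c), radius, shape=shape)
        marker[rr, cc] = True
        if with_nuclei:
            rr, cc = disk((r, c), 2, shape=shape)
            nuclei[rr, cc] = True
    return marker, nuclei


class TestDetectCells:
    def test_planted_blobs_with_nuclei(self):
        marker, nuclei = _blob_masks((60, 60), [(10, 10), (30, 30), (50, 15)], 4.4)
        cells = detect_cells(marker, nuclei, SegmentationParams(), "CD68")
        assert len(cells) == 3
        for cell in cells:
            assert 25 <= cell.area_um2 <= 500
            assert cell.has_nucleus

    def test_nucleus_gate(self):
        marker, _ = _blob_masks((60, 60), [(10, 10), (30, 30)], 4.4)
        assert detect_cells(marker, np.zeros((60, 60), bool), SegmentationParams(), "CD68") == []

    def test_diffuse_smear_rejected(self):
        marker = np.zeros((120, 120), bool)
        marker[10:110, 10:110] = True  # 10,000 µm² smear
        nuclei = np.ones((120, 120), bool)
        with pytest.warns(UserWarning, match="diffuse"):
            cells = detect_cells(marker, nuclei, SegmentationParams(), "CD56")
        assert cells == []

    def test_empty_masks(self):
        empty = np.zeros((10, 10), bool)
        assert detect_cells(empty, empty, SegmentationParams(), "CD68") == []


class TestClassifyMacrophages:
    def test_constructed_overlap(self):
        shape = (80, 80)
        centers = [(10, 10), (10, 40), (40, 10), (40, 40), (70, 40)]
        marker, nuclei = _blob_masks(shape, centers, 4)
        cells = detect_cells(marker, nuclei, SegmentationParams(), "CD68")
        assert len(cells) == 5
        cd206, _ = _blob_masks(shape, centers[:2], 4, with_nuclei=False)
        counts = classify_macrophages(cells, cd206)
        assert counts == {"m2": 2, "non_m2": 3}

    def test_empty_and_full_cd206(self):
        marker, nuclei = _blob_masks((50, 50), [(10, 10), (30, 30)], 4)
        cells = detect_cells(marker, nuclei, SegmentationParams(), "CD68")
        assert classify_macrophages(cells, np.zeros((50, 50), bool)) == {
            "m2": 0,
            "non_m2": 2,
        }
        assert classify_macrophages(cells, np.ones((50, 50), bool)) == {
            "m2": 2,
            "non_m2": 0,
        }


class TestDetectCapillaries:
    def test_planted_capillaries(self):
        centers = [(10 + 15 * i, 10 + 7 * (i % 3)) for i in range(10)]
        mask, _ = _blob_masks((170, 60), centers, 3.1, with_nuclei=False)
        vessels = detect_capillaries(mask)
        assert len(vessels) == 10
        assert all(v.kind == "capillary" for v in vessels)

    def test_large_vessel_partition(self):
        mask = np.zeros((100, 100), bool)
        from skimage.draw import disk

        rr, cc = disk((50, 50), 40, shape=mask.shape)
        mask[rr, cc] = True  # ~5000 µm²
        vessels = detect_capillaries(mask)
        assert [v.kind for v in vessels] == ["large_vessel"]

    def test_subthreshold_noise_discarded_and_empty(self):
        mask = np.zeros((20, 20), bool)
        mask[3, 3] = True  # 1 µm² speck < capillary_min
        assert detect_capillaries(mask) == []
        assert detect_capillaries(np.zeros((5, 5), bool)) == []


class TestNearestStructureDistance:
    def test_three_four_five(self):
        cells = [CellObject((0.0, 0.0), 30, "CD56", True)]
        vessels = [
            VesselObject((3.0, 4.0), 30, "capillary"),
            VesselObject((10.0, 0.0), 30, "capillary"),
        ]
        assert nearest_structure_distance(cells, vessels)[0] == 5.0

    def test_coincident_is_zero(self):
        cells = [CellObject((2.0, 2.0), 30, "CD56", True)]
        vessels = [VesselObject((2.0, 2.0), 30, "capillary")]
        assert nearest_structure_distance(cells, vessels)[0] == 0.0

    def test_matches_all_pairs_minimum(self, rng):
        cells = [CellObject(tuple(p), 30, "CD56", True) for p in rng.uniform(0, 100, (15, 2))]
        vessels = [VesselObject(tuple(p), 30, "capillary") for p in rng.uniform(0, 100, (7, 2))]
        got = nearest_structure_distance(cells, vessels)
        for i, cell in enumerate(cells):
            brute = min(
                np.hypot(cell.centroid[0] - v.centroid[0], cell.centroid[1] - v.centroid[1])
                for v in vessels
            )
            assert got[i] == pytest.approx(brute, abs=1e-9)

    def test_no_vessels_is_error(self):
        cells = [CellObject((0.0, 0.0), 30, "CD56", True)]
        with pytest.raises(ValueError, match="undefined"):
            nearest_structure_distance(cells, [])
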