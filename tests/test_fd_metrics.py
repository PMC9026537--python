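import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ccflow import BinaryDeficitMask, average_eye_metrics, compute_fd_metrics, extract_corner_rois, label_components
from ccflow.fd_metrics import CORNERS, ROISpec, corner_metrics, roi_side_px

from oracles import flood_fill_components


def roi(side_px=10, pitch=10.0, corner="superonasal", size_mm=None):
    size_mm = size_mm if size_mm is not None else side_px * pitch / 1000.0
    return ROISpec(corner=corner, size_mm=size_mm, side_px=side_px, pixel_pitch_um=pitch)


class TestRoiExtraction:
    def test_overlapping_rois_rejected(self, image_factory):
        img = image_factory(np.zeros((100, 100)), pitch=10.0)
        with pytest.raises(ValueError, match="overlap"):
            extract_corner_rois(img, size_mm=1.0)  # 100 px ROI on a 100 px image

    def test_quarter_mm_rois_fit(self, image_factory):
        img = image_factory(np.zeros((100, 100)), pitch=10.0)
        rois = extract_corner_rois(img, size_mm=0.25)
        assert set(rois) == set(CORNERS)
        for spec, crop in rois.values():
            assert spec.side_px == 25
            assert crop.pixels.shape == (25, 25)

    def test_rounding_follows_physical_side(self):
        # 1 mm at 6.5925 um/px -> 151.69 px -> 152
        assert roi_side_px(1.0, 6.5925) == 152
        assert roi_side_px(1.0, 6.225) == 161
        assert roi_side_px(0.25, 10.0) == 25

    def test_superonasal_roi_is_flush_with_top_left_for_od(self, rng, image_factory):
        img = image_factory(rng.uniform(0, 1, (910, 910)), pitch=6.5925)
        spec, crop = extract_corner_rois(img, size_mm=1.0, laterality="OD")["superonasal"]
        assert spec.side_px == 152
        assert np.array_equal(crop.pixels[:3, :3], img.pixels[:3, :3])

    def test_mirroring_with_laterality_flip_preserves_corner_metrics(self, rng):
        mask = BinaryDeficitMask(rng.random((128, 128)) < 0.4, pixel_pitch_um=10.0)
        mirrored = BinaryDeficitMask(mask.pixels[:, ::-1], pixel_pitch_um=10.0)
        od = corner_metrics(mask, size_mm=0.5, laterality="OD")
        os_ = corner_metrics(mirrored, size_mm=0.5, laterality="OS")
        for corner in CORNERS:
            assert od[corner].fd_percent == os_[corner].fd_percent
            assert od[corner].n_fd == os_[corner].n_fd


class TestComponents:
    def test_diagonal_touch_is_one_component(self):
        mask = BinaryDeficitMask(np.eye(2, dtype=bool), 10.0)
        comps = label_components(mask)
        assert comps.n_components == 1
        assert comps.sizes_px.tolist() == [2]

    def test_separated_blocks_are_two_components(self):
        pixels = np.zeros((8, 8), dtype=bool)
        pixels[0:2, 0:2] = True
        pixels[5:7, 5:7] = True
        comps = label_components(BinaryDeficitMask(pixels, 10.0))
        assert comps.n_components == 2
        assert sorted(comps.sizes_px.tolist()) == [4, 4]

    def test_matches_flood_fill_oracle_on_random_masks(self, rng):
        for _ in range(5):
            pixels = rng.random((64, 64)) < 0.4
            comps = label_components(BinaryDeficitMask(pixels, 10.0))
            assert sorted(comps.sizes_px.tolist()) == flood_fill_components(pixels)
            assert comps.sizes_px.sum() == pixels.sum()


class TestFdMetrics:
    def test_single_block_hand_computed(self):
        pixels = np.zeros((10, 10), dtype=bool)
        pixels[2:7, 2:7] = True
        m = compute_fd_metrics(BinaryDeficitMask(pixels, 10.0), roi(10, 10.0))
        assert m.fd_percent == 25.0
        assert m.n_fd == 1
        assert m.mean_fd_size_um2 == 2500.0
        assert m.total_fd_area_mm2 == pytest.approx(0.0025)

    def test_empty_and_full_masks(self):
        spec = roi(10, 10.0)
        empty = compute_fd_metrics(BinaryDeficitMask(np.zeros((10, 10), bool), 10.0), spec)
        assert (empty.fd_percent, empty.n_fd, empty.mean_fd_size_um2, empty.total_fd_area_mm2) == (0, 0, 0, 0)
        full = compute_fd_metrics(BinaryDeficitMask(np.ones((10, 10), bool), 10.0), spec)
        assert full.fd_percent == 100.0
        assert full.n_fd == 1
        assert full.total_fd_area_mm2 == pytest.approx(spec.area_mm2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.floats(0.05, 0.95))
    def test_consistency_invariants_on_fuzzed_masks(self, seed, fill):
        rng = np.random.default_rng(seed)
        pixels = rng.random((24, 24)) < fill
        mask = BinaryDeficitMask(pixels, 7.5)
        m = compute_fd_metrics(mask, roi(24, 7.5))
        # area <-> percentage
        roi_area_mm2 = (24 * 7.5 / 1000.0) ** 2
        assert m.total_fd_area_mm2 == pytest.approx(m.fd_percent / 100.0 * roi_area_mm2, abs=1e-12)
        # count x mean size <-> total area
        if m.n_fd:
            assert m.n_fd * m.mean_fd_size_um2 == pytest.approx(m.total_fd_area_mm2 * 1e6, rel=1e-12)
        # complement percentages sum to 100 exactly
        mc = compute_fd_metrics(mask.complement(), roi(24, 7.5))
        assert m.fd_percent + mc.fd_percent == 100.0


class TestEyeAverages:
    def _metrics(self, fd_percent):
        pixels = np.zeros((10, 10), dtype=bool)
        pixels[: int(fd_percent / 10), :] = True
        return compute_fd_metrics(BinaryDeficitMask(pixels, 10.0), roi(10, 10.0))

    def test_identical_corners_are_idempotent(self):
        m = self._metrics(40)
        avg = average_eye_metrics([m, m, m, m])
        assert avg.fd_percent == m.fd_percent
        assert avg.n_fd == m.n_fd

    def test_arithmetic_mean_and_permutation_invariance(self):
        metrics = [self._metrics(v) for v in (40, 40, 50, 50)]
        avg = average_eye_metrics(metrics)
        assert avg.fd_percent == 45.0
        shuffled = average_eye_metrics(metrics[::-1])
        assert shuffled == avg

    def test_wrong_cardinality_rejected(self):
        m = self._metrics(40)
        with pytest.raises(ValueError, match="4"):
            average_eye_metrics([m, m, m])
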