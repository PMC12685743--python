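"""Detection, patch extraction, background-median dAFAI and unmixing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sargassum as sg
from sargassum.afai import AfaiGrid, MaskGrid, PixelStatus
from sargassum.constants import AFAI_FULL_COVERAGE
from sargassum.detection import DetectionResult, patches_to_table
from sargassum.synthetic import CloudSpec

from conftest import bfs_label, make_scene, oracle_background_median


def grids(values, valid=None):
    values = np.asarray(values, float)
    valid = np.ones(values.shape, bool) if valid is None else valid
    afai = AfaiGrid(values=values, valid_mask=np.isfinite(values))
    prov = np.where(valid, PixelStatus.OK, PixelStatus.CLOUD).astype(np.uint8)
    return afai, MaskGrid(valid=valid, provenance=prov)


class TestDetectPixels:
    def test_uniform_field_no_detections(self):
        afai, mask = grids(np.full((32, 32), 0.001))
        det = sg.detect_pixels(afai, mask, threshold=1e-4)
        assert not det.sargassum_mask.any()

    def test_single_anomalous_pixel_detected(self):
        values = np.full((32, 32), 0.001)
        values[10, 10] += 2e-4
        afai, mask = grids(values)
        det = sg.detect_pixels(afai, mask, threshold=1e-4)
        assert det.sargassum_mask[10, 10]
        assert det.sargassum_mask.sum() == 1

    def test_anomaly_under_mask_never_detected(self):
        values = np.full((32, 32), 0.001)
        values[10:13, 10:13] += 1e-2
        valid = np.ones((32, 32), bool)
        valid[8:15, 8:15] = False
        afai, mask = grids(values, valid)
        det = sg.detect_pixels(afai, mask, threshold=1e-4)
        assert not det.sargassum_mask.any()

    def test_nonpositive_threshold_rejected(self):
        afai, mask = grids(np.full((8, 8), 0.001))
        with pytest.raises(ValueError, match="threshold"):
            sg.detect_pixels(afai, mask, threshold=0.0)

    def test_custom_detector_slots_in(self):
        afai, mask = grids(np.full((8, 8), 0.001))

        def everything(values, valid):
            return np.ones_like(valid)

        det = sg.detect_pixels(afai, mask, detector=everything)
        assert det.sargassum_mask.all()
        assert det.detector_id == "everything"


class TestExtractPatches:
    def _det(self, mask):
        return DetectionResult(sargassum_mask=np.asarray(mask, bool), detector_id="t")

    def test_empty_mask_empty_list(self):
        assert sg.extract_patches(self._det(np.zeros((8, 8)))) == []

    def test_two_pixel_component_excluded(self):
        m = np.zeros((8, 8), bool)
        m[2, 2] = m[2, 3] = True
        assert sg.extract_patches(self._det(m)) == []

    def test_diagonal_contact_is_contiguous(self):
        """Two diagonal pixels plus an orthogonal neighbour form one patch."""
        m = np.zeros((8, 8), bool)
        m[2, 2] = m[3, 3] = m[3, 4] = True
        patches = sg.extract_patches(self._det(m))
        assert len(patches) == 1
        assert sorted(patches[0].pixels) == [(2, 2), (3, 3), (3, 4)]

    def test_matches_bfs_oracle_on_random_masks(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            m = rng.random((24, 24)) < 0.15
            patches = sg.extract_patches(self._det(m))
            labels = bfs_label(m)
            expected = [sorted(zip(*np.nonzero(labels == k)))
                        for k in range(1, labels.max() + 1)]
            expected = sorted([c for c in expected if len(c) >= 3])
            got = sorted([sorted(p.pixels) for p in patches])
            assert got == expected

    def test_order_invariance_and_min_size(self):
        rng = np.random.default_rng(2)
        m = rng.random((32, 32)) < 0.2
        p1 = sg.extract_patches(self._det(m))
        p2 = sg.extract_patches(self._det(m[::-1, ::-1].copy()))
        n_rows, n_cols = m.shape
        flipped = sorted(sorted((n_rows - 1 - r, n_cols - 1 - c) for r, c in p.pixels)
                         for p in p2)
        assert sorted(sorted(p.pixels) for p in p1) == flipped
        assert all(len(p) >= 3 for p in p1)


class TestDeltaAfai:
    def test_constant_background_subtraction(self):
        values = np.full((40, 40), 0.002)
        pix = [(20, 20), (20, 21), (20, 22)]
        for p in pix:
            values[p] = 0.03
        afai, mask = grids(values)
        det = DetectionResult(np.zeros((40, 40), bool), "t")
        for p in pix:
            det.sargassum_mask[p] = True
        patch = sg.SargassumPatch(pixels=pix)
        sg.compute_delta_afai(patch, afai, det, mask)
        assert patch.background_median == pytest.approx(0.002)
        np.testing.assert_allclose(patch.delta_afai, 0.03 - 0.002)

    def test_median_robust_to_background_outlier(self):
        values = np.full((30, 30), 0.000)
        values[0, 0] = 0.010  # lone bright background pixel inside the window
        values[14, 14] = 0.02
        afai, mask = grids(values)
        det = DetectionResult(np.zeros((30, 30), bool), "t")
        det.sargassum_mask[14, 14] = True
        patch = sg.SargassumPatch(pixels=[(14, 14)])
        sg.compute_delta_afai(patch, afai, det, mask)
        assert patch.background_median == pytest.approx(0.0)

    def test_neighbouring_patch_excluded_from_background(self):
        values = np.full((40, 40), 0.001)
        a = [(20, 20), (20, 21), (20, 22)]
        b = [(22, 20), (22, 21), (22, 22)]
        for p in a + b:
            values[p] = 0.05
        afai, mask = grids(values)
        det = DetectionResult(np.zeros((40, 40), bool), "t")
        for p in a + b:
            det.sargassum_mask[p] = True
        patch = sg.SargassumPatch(pixels=a)
        sg.compute_delta_afai(patch, afai, det, mask)
        # bright pixels of patch b are Sargassum-flagged, so the median
        # stays at the clean background level
        assert patch.background_median == pytest.approx(0.001)

    def test_matches_enumeration_oracle_on_random_grids(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            values = rng.normal(0.001, 2e-4, size=(40, 40))
            detected = rng.random((40, 40)) < 0.1
            valid = rng.random((40, 40)) < 0.9
            det = DetectionResult(detected & valid, "t")
            afai, mask = grids(values, valid)
            labels = bfs_label(det.sargassum_mask)
            for k in range(1, labels.max() + 1):
                pix = sorted(zip(*np.nonzero(labels == k)))
                if len(pix) < 3:
                    continue
                patch = sg.SargassumPatch(pixels=[(int(r), int(c)) for r, c in pix])
                sg.compute_delta_afai(patch, afai, det, mask, dilation_radius=5)
                expected = oracle_background_median(
                    patch.pixels, values, det.sargassum_mask, valid, radius=5)
                if expected is None:
                    assert patch.no_background
                else:
                    assert patch.background_median == pytest.approx(expected, abs=1e-12)

    def test_no_background_flagged(self):
        values = np.full((5, 5), 0.02)
        afai, mask = grids(values)
        det = DetectionResult(np.ones((5, 5), bool), "t")
        patch = sg.SargassumPatch(pixels=[(r, c) for r in range(5) for c in range(5)])
        sg.compute_delta_afai(patch, afai, det, mask, dilation_radius=2)
        assert patch.no_background


class TestFractionalDensity:
    @pytest.mark.parametrize("delta,frac", [
        (AFAI_FULL_COVERAGE, 1.0),     # 100% coverage constant
        (0.0, 0.0),
        (2.205e-2, 0.5),
        (-1e-3, 0.0),                  # negative dAFAI clamps to 0
        (1.0, 1.0),                    # above full coverage clips to 1
    ])
    def test_linear_unmixing(self, delta, frac):
        assert sg.fractional_density(delta) == pytest.approx(frac)

    @given(st.lists(st.floats(-0.1, 0.1), min_size=2, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, deltas):
        deltas = np.sort(np.asarray(deltas))
        f = sg.fractional_density(deltas)
        assert ((f >= 0) & (f <= 1)).all()
        assert (np.diff(f) >= -1e-15).all()


class TestQuantifyScene:
    def test_noiseless_recovery_is_exact(self):
        """Known injected fractions come back bit-for-bit on a clean scene."""
        fracs = [0.05, 0.2, 0.5, 0.75, 1.0]
        patches_spec = [sg.PatchSpec(row=10 + 12 * i, col=30, footprint=2, fraction=f)
                        for i, f in enumerate(fracs)]
        scene, truth = make_scene(grid_rows=80, grid_cols=80, patch_spec=patches_spec)
        grid = sg.compute_afai(scene)
        mask = sg.build_valid_mask(scene)
        patches, fraction = sg.quantify_scene(grid, mask, threshold=1e-4)
        assert len(patches) == len(fracs)
        np.testing.assert_allclose(fraction[np.isfinite(fraction)].sum(),
                                   truth.fraction.sum(), rtol=1e-12)
        got = np.where(np.isnan(fraction), 0.0, fraction)
        np.testing.assert_allclose(got, truth.fraction, atol=1e-12)

    def test_masked_pixels_never_quantified(self):
        scene, _ = make_scene(
            grid_rows=64, grid_cols=64, seed=8,
            cloud_spec=CloudSpec(n_blobs=4, radius_px=3.0),
            patch_spec=[sg.PatchSpec(row=30, col=30, footprint=3, fraction=0.8)],
        )
        grid = sg.compute_afai(scene)
        mask = sg.build_valid_mask(scene)
        _, fraction = sg.quantify_scene(grid, mask, threshold=1e-4)
        assert np.isnan(fraction[~mask.valid]).all()

    def test_patch_table_schema(self):
        scene, _ = make_scene(grid_rows=32, grid_cols=32,
                              patch_spec=[sg.PatchSpec(row=10, col=10, footprint=2,
                                                       fraction=0.5)])
        grid = sg.compute_afai(scene)
        mask = sg.build_valid_mask(scene)
        patches, _ = sg.quantify_scene(grid, mask, threshold=1e-4)
        table = patches_to_table(patches, grid)
        assert list(table.columns) == ["patch_id", "row", "col", "afai",
                                       "delta_afai", "fraction"]
        assert len(table) == 4
        np.testing.assert_allclose(table["fraction"], 0.5, atol=1e-12)
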