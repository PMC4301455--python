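import numpy as np
import pytest

import fogbank as fb
from fogbank.geodesic import GeodesicMask
from fogbank.segment import (
    FogBankParams,
    detect_mitotic,
    fogbank_grow,
    fogbank_segment,
    merge_mitotic,
)


def labels_of(seg):
    return set(np.unique(seg[seg > 0]).tolist())


def connected(mask, connectivity=8):
    from scipy import ndimage as ndi

    struct = np.ones((3, 3), bool) if connectivity == 8 else None
    _, n = ndi.label(mask, structure=struct)
    return n <= 1


class TestFogbankGrow:
    def test_single_seed_floods_roi(self):
        img = np.full((20, 20), 5.0)
        roi = np.zeros((20, 20), bool)
        roi[3:17, 3:17] = True
        seeds = np.zeros((20, 20), dtype=np.int64)
        seeds[10, 10] = 1
        geo = GeodesicMask(traversable=roi.copy(), roi=roi)
        out = fogbank_grow(img, seeds, geo)
        np.testing.assert_array_equal(out > 0, roi)
        assert labels_of(out) == {1}

    def test_bright_ridge_is_cell_interface(self):
        img = np.full((21, 21), 10.0)
        img[:, 10] = 200.0  # impassable bright ridge
        roi = np.ones((21, 21), bool)
        trav = roi & (img < 100)
        seeds = np.zeros((21, 21), dtype=np.int64)
        seeds[10, 3] = 1
        seeds[10, 17] = 2
        geo = GeodesicMask(traversable=trav, roi=roi)
        out = fogbank_grow(img, seeds, geo)
        # no pixel across the ridge joins the geodesically farther seed
        assert (out[:, :10] == 1).all()
        assert (out[:, 11:] == 2).all()
        # the ridge line itself is assigned in the final pass, split at the interface
        assert set(np.unique(out[:, 10])) <= {1, 2}

    def test_seed_conservation(self, sheet5):
        img, truth, _ = sheet5
        roi = truth > 0
        geo = fb.build_geodesic_mask(img, roi, 85.0)
        seeds = fb.histogram_quantization_seeds(img, roi, fb.HistogramSeedParams(S_T=25), geo)
        out = fogbank_grow(img, seeds, geo)
        assert labels_of(out) == labels_of(seeds)

    def test_partition_of_roi(self, sheet5):
        img, truth, _ = sheet5
        roi = truth > 0
        geo = fb.build_geodesic_mask(img, roi, 85.0)
        seeds = fb.histogram_quantization_seeds(img, roi, fb.HistogramSeedParams(S_T=25), geo)
        out = fogbank_grow(img, seeds, geo)
        assert (out[roi] > 0).all()
        assert (out[~roi] == 0).all()

    def test_cells_connected(self, sheet5):
        img, truth, _ = sheet5
        roi = truth > 0
        geo = fb.build_geodesic_mask(img, roi, 85.0)
        seeds = fb.histogram_quantization_seeds(img, roi, fb.HistogramSeedParams(S_T=25), geo)
        out = fogbank_grow(img, seeds, geo)
        for lab in labels_of(out):
            assert connected(out == lab)

    def test_five_cell_sheet_recovery(self, sheet5):
        img, truth, _ = sheet5
        roi = truth > 0
        geo = fb.build_geodesic_mask(img, roi, 85.0)
        seeds = fb.histogram_quantization_seeds(img, roi, fb.HistogramSeedParams(S_T=25), geo)
        out = fogbank_grow(img, seeds, geo)
        assert len(labels_of(out)) == 5
        assert fb.adjusted_rand_index(truth, out) >= 0.8

    def test_no_seeds_rejected(self):
        img = np.zeros((10, 10))
        roi = np.ones((10, 10), bool)
        geo = GeodesicMask(traversable=roi.copy(), roi=roi)
        with pytest.raises(ValueError, match="no seeds"):
            fogbank_grow(img, np.zeros((10, 10), np.int64), geo)

    def test_quantized_equals_unquantized_on_few_levels(self):
        # image with <= 100 distinct intensities, every level carrying
        # equal mass: the percentile bins then reproduce the value cuts
        rng = np.random.default_rng(3)
        img = rng.permutation(np.repeat(np.arange(50.0), 8)).reshape(20, 20)
        roi = np.ones((20, 20), bool)
        geo = GeodesicMask(traversable=roi.copy(), roi=roi)
        seeds = np.zeros((20, 20), dtype=np.int64)
        seeds[4, 4] = 1
        seeds[15, 15] = 2
        a = fogbank_grow(img, seeds, geo, FogBankParams(quantize=True))
        b = fogbank_grow(img, seeds, geo, FogBankParams(quantize=False))
        np.testing.assert_array_equal(a, b)


class TestDetectMitotic:
    def make(self, blob=True, elongated=False):
        rng = np.random.default_rng(7)
        img = rng.normal(100.0, 2.0, size=(60, 60))
        roi = np.ones((60, 60), bool)
        if blob:
            img[fb.make_disk(5, (20, 20), (60, 60))] = 250.0
        if elongated:
            img[45, 10:50] = 250.0
        return img, roi

    def test_bright_round_blob_detected(self):
        img, roi = self.make(blob=True)
        out = detect_mitotic(img, roi, FogBankParams(mitotic_min_size=20))
        assert labels_of(out) == {1}

    def test_elongated_streak_rejected(self):
        img, roi = self.make(blob=False, elongated=True)
        out = detect_mitotic(img, roi, FogBankParams(mitotic_min_size=20))
        assert labels_of(out) == set()

    def test_noise_specks_below_min_size_rejected(self):
        img, roi = self.make(blob=False)
        out = detect_mitotic(img, roi, FogBankParams(mitotic_min_size=30))
        assert labels_of(out) == set()


class TestMergeMitotic:
    def test_empty_mitotic_identity(self):
        cells = np.zeros((8, 8), dtype=np.int64)
        cells[:4] = 1
        cells[4:] = 2
        out = merge_mitotic(cells, np.zeros_like(cells))
        np.testing.assert_array_equal(out, cells)

    def test_object_inside_one_cell(self):
        cells = np.zeros((20, 20), dtype=np.int64)
        cells[:, :10] = 1
        cells[:, 10:] = 2
        mit = np.zeros_like(cells)
        mit[5:8, 2:5] = 1
        out = merge_mitotic(cells, mit)
        assert len(labels_of(out)) == 3
        new_label = out[6, 3]
        assert new_label not in (out[0, 0], out[0, 19])
        # host cell keeps its remaining pixels
        assert out[0, 0] == out[19, 9]

    def test_object_overlapping_two_cells(self):
        cells = np.zeros((20, 20), dtype=np.int64)
        cells[:, :10] = 1
        cells[:, 10:] = 2
        mit = np.zeros_like(cells)
        mit[8:12, 8:12] = 1
        out = merge_mitotic(cells, mit)
        assert len(labels_of(out)) == 3
        assert len(set(out[mit > 0].tolist())) == 1  # one new label spans the overlap
        assert (out[mit > 0] != out[0, 0]).all()
        assert (out[mit > 0] != out[0, 19]).all()

    def test_labels_contiguous(self):
        cells = np.zeros((10, 10), dtype=np.int64)
        cells[:5] = 4
        cells[5:] = 9
        mit = np.zeros_like(cells)
        mit[4:6, 4:6] = 2
        out = merge_mitotic(cells, mit)
        assert labels_of(out) == {1, 2, 3}

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            merge_mitotic(np.zeros((4, 4), np.int64), np.zeros((5, 5), np.int64))


class TestFogbankSegment:
    def test_blank_image_all_zero(self):
        out = fogbank_segment(np.full((40, 40), 12.0))
        assert (out == 0).all()

    def test_sheet_ground_truth_count(self, sheet5):
        img, truth, _ = sheet5
        params = FogBankParams(histogram_params=fb.HistogramSeedParams(S_T=25))
        out = fogbank_segment(img, params)
        assert len(labels_of(out)) == 5
        assert fb.adjusted_rand_index(truth, out) >= 0.8

    def test_determinism(self, sheet5):
        img, _, _ = sheet5
        params = FogBankParams(histogram_params=fb.HistogramSeedParams(S_T=25))
        a = fogbank_segment(img, params)
        b = fogbank_segment(img, params)
        np.testing.assert_array_equal(a, b)

    def test_wopg_ablation_runs_and_not_better(self):
        # noisy ridge-bounded sheet: quantization is what suppresses the
        # noise-induced over-segmentation, so wopg must not come out ahead
        spec = fb.SheetSpec(n_cells=8, rng_seed=103, shape=(150, 150), noise_std=3.0)
        img, truth, _ = fb.make_confluent_sheet(spec)
        hp = fb.HistogramSeedParams(S_T=25)
        default = fogbank_segment(img, FogBankParams(histogram_params=hp))
        wopg = fogbank_segment(
            img, FogBankParams(histogram_params=hp, quantize=False, grow_metric="euclidean")
        )
        assert fb.adjusted_rand_index(truth, wopg) <= fb.adjusted_rand_index(truth, default) + 1e-9

    def test_mitotic_merge_end_to_end(self):
        spec = fb.SheetSpec(n_cells=4, rng_seed=5, shape=(128, 128), n_mitotic=1,
                            mitotic_radius=4.0)
        img, truth, _ = fb.make_confluent_sheet(spec)
        params = FogBankParams(
            histogram_params=fb.HistogramSeedParams(S_T=25),
            mitotic=True, mitotic_min_size=20, mitotic_circularity=0.4,
        )
        out = fogbank_segment(img, params)
        assert len(labels_of(out)) == 5  # 4 cells + 1 mitotic body

    def test_zero_seed_fallback_one_label_per_component(self):
        # sharply bounded flat plateau: foreground found, no seeds inside
        img = np.full((60, 60), 10.0)
        img[15:45, 15:45] = 120.0
        params = FogBankParams(
            histogram_params=fb.HistogramSeedParams(S_T=10**6)
        )
        out = fogbank_segment(img, params)
        assert len(labels_of(out)) == 1

    def test_nucleoli_method_end_to_end(self, sheet5):
        img, truth, _ = sheet5
        params = FogBankParams(
            seed_method="nucleoli",
            nucleoli_params=fb.NucleoliSeedParams(t=6, S_T=15, C_T=0.4, D_N=8.0),
        )
        out = fogbank_segment(img, params)
        assert len(labels_of(out)) == 5

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            FogBankParams(mitotic_percentile=40.0)
        with pytest.raises(ValueError):
            FogBankParams(boundary_percentile=150.0)
        with pytest.raises(ValueError):
            FogBankParams(connectivity=6)
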