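"""Fuzzy c-means recovery, region growing, brain-extraction pipeline."""

import numpy as np
import pytest

from voxelpipe import Image, StoragePool, run_chain
from voxelpipe import filters as flt
from voxelpipe import segmentation as seg
from voxelpipe import synth
from voxelpipe.errors import DegenerateInputError, ParameterError
from voxelpipe.filters import shape_from_name

import oracles


class TestFuzzyCMeans:
    def test_two_separable_values_recovered_exactly(self):
        data = np.full((4, 10), 100.0, dtype=np.float32)
        data[:, 5:] = 200.0
        result = seg.fuzzy_cmeans(Image(data), K=2, gain=False)
        np.testing.assert_allclose(result.centroids, [100.0, 200.0], atol=0.5)
        hard = np.argmax(np.stack([m.data for m in result.memberships]), axis=0)
        assert (hard[:, :5] == 0).all() and (hard[:, 5:] == 1).all()
        top = np.max(np.stack([m.data for m in result.memberships]), axis=0)
        assert top.min() > 0.99

    def test_phantom_centroid_recovery_without_bias(self, three_class_nobias):
        phantom, result = three_class_nobias
        assert result.converged
        np.testing.assert_allclose(result.centroids, [50, 125, 200], atol=3)

    def test_membership_normalization(self, three_class_nobias):
        _, result = three_class_nobias
        total = np.stack([m.data for m in result.memberships]).sum(axis=0)
        assert np.abs(total - 1.0).max() <= 1e-5

    def test_centroids_strictly_ascending(self, three_class_biased):
        _, result = three_class_biased
        assert (np.diff(result.centroids) > 0).all()

    def test_gain_correction_recovers_class_means(self, three_class_biased):
        phantom, result = three_class_biased
        for name, mean in zip(["outer", "middle", "core"], [50, 125, 200]):
            mask = phantom.truth_masks[name].data
            assert abs(float(result.corrected.data[mask].mean()) - mean) <= 5

    def test_gain_correction_reduces_within_class_cov(self, three_class_biased):
        phantom, result = three_class_biased
        for name in ("outer", "middle", "core"):
            mask = phantom.truth_masks[name].data
            corr = result.corrected.data[mask].astype(np.float64)
            unc = phantom.image.data[mask].astype(np.float64)
            assert corr.std() / corr.mean() < unc.std() / unc.mean()

    def test_gain_near_one_on_unbiased_image(self, three_class_nobias_gain):
        phantom, result = three_class_nobias_gain
        fg = phantom.image.data > 0
        assert np.abs(result.gain.data[fg] - 1.0).max() <= 0.05

    def test_gain_positive_and_mean_one_over_foreground(self, three_class_biased):
        phantom, result = three_class_biased
        assert (result.gain.data > 0).all()
        fg = phantom.image.data > 0
        assert abs(float(result.gain.data[fg].mean()) - 1.0) < 1e-3

    def test_objective_monotone_descent(self, three_class_nobias,
                                         three_class_biased):
        _, plain = three_class_nobias
        diffs = np.diff(plain.objective)
        assert (diffs <= 1e-9 * np.abs(plain.objective[:-1])).all()
        # with the smoothed gain step the descent is only approximate
        _, gained = three_class_biased
        diffs = np.diff(gained.objective)
        assert (diffs <= 1e-2 * np.abs(gained.objective[:-1])).all()

    def test_degenerate_input_rejected(self):
        img = Image(np.full((3, 3), 7.0, dtype=np.float32))
        with pytest.raises(DegenerateInputError):
            seg.fuzzy_cmeans(img, K=3)

    def test_corrected_is_input_over_gain(self, three_class_biased):
        phantom, result = three_class_biased
        np.testing.assert_allclose(
            result.corrected.data,
            phantom.image.data / result.gain.data, rtol=1e-4)


class TestSelectClass:
    def test_brightest_darkest_and_index(self, three_class_nobias):
        _, result = three_class_nobias
        assert np.array_equal(seg.select_class(result, "brightest").data,
                              result.memberships[2].data)
        assert np.array_equal(seg.select_class(result, "darkest").data,
                              seg.select_class(result, 0).data)

    def test_selected_classes_resum_to_one(self, three_class_nobias):
        _, result = three_class_nobias
        total = sum(seg.select_class(result, k).data.astype(np.float64)
                    for k in range(3))
        assert np.abs(total - 1.0).max() <= 1e-5

    def test_index_out_of_range(self, three_class_nobias):
        _, result = three_class_nobias
        with pytest.raises(ParameterError):
            seg.select_class(result, 3)


class TestRegionGrow:
    def test_empty_seeds_empty_result(self, rng):
        img = Image(rng.random((5, 5)).astype(np.float32))
        seeds = Image(np.zeros((5, 5), dtype=bool))
        assert not seg.region_grow(img, seeds, "4n", thresh=0.5).data.any()

    def test_vacuous_threshold_floods_everything(self, rng):
        img = Image(rng.random((6, 6)).astype(np.float32))
        seeds = np.zeros((6, 6), dtype=bool)
        seeds[3, 3] = True
        out = seg.region_grow(img, Image(seeds), "4n",
                              thresh=float(img.data.min()))
        assert out.data.all()

    @pytest.mark.parametrize("mode", ["threshold", "downhill"])
    @pytest.mark.parametrize("shape_name,img_shape", [
        ("4n", (9, 10)), ("8n", (9, 10)), ("6n", (5, 6, 7)),
    ])
    def test_matches_fixed_point_oracle(self, mode, shape_name, img_shape, rng):
        shape = shape_from_name(shape_name, len(img_shape))
        data = rng.integers(0, 8, img_shape).astype(np.float32)
        seeds = rng.random(img_shape) < 0.05
        thresh = 4.0 if mode == "threshold" else None
        got = seg.region_grow(Image(data), Image(seeds), shape, thresh).data
        expected = oracles.region_grow_oracle(data, seeds,
                                              shape.neighbor_offsets, thresh)
        assert np.array_equal(got, expected)

    def test_monotone_in_threshold(self, rng):
        data = rng.integers(0, 100, (8, 8)).astype(np.float32)
        seeds = np.zeros((8, 8), dtype=bool)
        seeds[4, 4] = True
        low = seg.region_grow(Image(data), Image(seeds), "8n", thresh=20.0).data
        high = seg.region_grow(Image(data), Image(seeds), "8n", thresh=60.0).data
        assert not (high & ~low).any()  # higher threshold grows a subset

    def test_result_contains_seeds(self, rng):
        data = rng.random((6, 6)).astype(np.float32)
        seeds = rng.random((6, 6)) < 0.2
        out = seg.region_grow(Image(data), Image(seeds), "4n", thresh=2.0)
        assert (out.data | ~seeds).all()


class TestBrainExtract:
    def test_phantom_dice_at_default_parameters(self, head_extraction):
        phantom, result = head_extraction
        score = seg.dice(result.mask, phantom.truth_masks["brain"])
        assert score >= 0.95

    def test_stage_trace_lists_all_stages_in_order(self, head_extraction):
        _, result = head_extraction
        assert result.trace == (
            "fuzzy_cmeans", "select_class", "binarize", "erode", "label",
            "select_biggest", "region_grow", "close", "open", "mask_apply")

    def test_mask_is_single_connected_component(self, head_extraction):
        _, result = head_extraction
        labels = flt.label(result.mask, "6n")
        assert labels.data.max() == 1

    def test_masked_output_zero_outside_mask(self, head_extraction):
        _, result = head_extraction
        assert not result.image.data[~result.mask.data].any()

    def test_impossible_probability_threshold_gives_empty_mask(self):
        phantom = synth.head_phantom(32, seed=3)
        result = seg.brain_extract(phantom.image, pthresh=1.01)
        assert not result.mask.data.any()
        assert not result.image.data.any()


class TestDescriptorPlugins:
    def test_fuzzycm_filter_populates_the_pool(self):
        phantom = synth.three_class_phantom(24, noise_sigma=2.0, seed=4)
        pool = StoragePool()
        out = run_chain(phantom.image, ["fuzzycm:k=3,gain=0"],
                        flt.FILTERS_3D, pool)
        for key in ("class0", "class1", "class2", "gain", "corrected"):
            assert key in pool
        assert np.array_equal(out.data, pool.get("corrected").data)

    def test_regiongrow_filter_reads_seeds_from_pool(self):
        data = np.zeros((4, 4), dtype=np.float32)
        data[:2] = 10.0
        seeds = np.zeros((4, 4), dtype=bool)
        seeds[0, 0] = True
        pool = StoragePool()
        pool.store("s", Image(seeds))
        out = run_chain(Image(data), ["regiongrow:seed=s,thresh=5"],
                        flt.FILTERS_2D, pool)
        assert out.data[:2].all() and not out.data[2:].any()
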