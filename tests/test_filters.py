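"""Filters against brute-force oracles, plus their algebraic invariants."""

import numpy as np
import pytest

from voxelpipe import Image, filter_registry, run_chain
from voxelpipe.errors import DegenerateInputError, ParameterError
from voxelpipe.filters import (
    binarize,
    combine,
    distance_transform,
    gauss,
    binomial_kernel,
    intensity_bandpass,
    invert,
    label,
    mask_apply,
    mlv,
    morph,
    neighborhood_filter,
    select_biggest,
    shape_from_name,
)

import oracles


def _rand_image(rng, shape, kind=np.uint16, high=1000):
    if kind is bool:
        return Image(rng.random(shape) < 0.5)
    if np.dtype(kind).kind == "f":
        return Image((rng.random(shape) * high).astype(kind))
    return Image(rng.integers(0, high, shape).astype(kind))


SMALL_SHAPES = [(7, 9), (5, 6, 7)]


class TestShapes:
    @pytest.mark.parametrize("name,rank,count", [
        ("4n", 2, 5), ("8n", 2, 9), ("6n", 3, 7), ("18n", 3, 19), ("26n", 3, 27),
    ])
    def test_offset_counts(self, name, rank, count):
        shape = shape_from_name(name, rank)
        assert len(shape.offsets) == count
        assert (0,) * rank in shape.offsets

    def test_offsets_symmetric_under_negation(self):
        for name, rank in [("8n", 2), ("18n", 3), ("sphere:r=2", 3)]:
            offs = set(shape_from_name(name, rank).offsets)
            assert {tuple(-o for o in off) for off in offs} == offs

    def test_sphere_radius_is_euclidean(self):
        offs = shape_from_name("sphere:r=2", 2).offsets
        assert (2, 0) in offs and (1, 1) in offs and (2, 2) not in offs


class TestPointOps:
    def test_binarize_predicate(self):
        img = Image(np.array([[0.2, 0.6], [0.5, 0.9]], dtype=np.float32))
        out = binarize(img, 0.5, float("inf"))
        assert out.data.tolist() == [[False, True], [True, True]]

    def test_binarize_full_range_all_true(self, rng):
        img = _rand_image(rng, (4, 4))
        assert binarize(img, float("-inf"), float("inf")).data.all()

    def test_binarize_tooth_intensity_band(self):
        # discarding intensities outside [46, 90] keeps exactly the band
        img = Image(np.array([[40, 46, 90, 100]], dtype=np.uint8))
        out = binarize(img, 46, 90)
        assert out.data.tolist() == [[False, True, True, False]]

    def test_binarize_min_above_max_rejected(self):
        with pytest.raises(ParameterError):
            binarize(Image(np.zeros((2, 2), np.uint8)), 2, 1)

    def test_invert_unsigned_and_float(self):
        u = Image(np.array([[0, 255, 10]], dtype=np.uint8))
        assert invert(u).data.tolist() == [[255, 0, 245]]
        f = Image(np.array([[-1.5]], dtype=np.float32))
        assert invert(f).data.tolist() == [[1.5]]
        b = Image(np.array([[True, False]]))
        assert invert(b).data.tolist() == [[False, True]]

    def test_bandpass_clamps_to_floor(self):
        img = Image(np.array([[40, 60, 120]], dtype=np.uint8))
        out = intensity_bandpass(img, 50, 100)
        assert out.data.tolist() == [[50, 60, 50]]


class TestMorphology:
    def test_lonely_center_erodes_away_and_dilates_to_cross(self):
        center = np.zeros((3, 3), dtype=bool)
        center[1, 1] = True
        img = Image(center)
        assert not morph(img, "erode", "4n").data.any()
        dil = morph(img, "dilate", "4n").data
        cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
        assert np.array_equal(dil, cross)

    @pytest.mark.parametrize("shape_name,img_shape", [
        ("4n", (8, 9)), ("8n", (8, 9)), ("6n", (5, 6, 7)),
        ("26n", (5, 6, 7)), ("sphere:r=2", (8, 9)),
    ])
    @pytest.mark.parametrize("op", ["erode", "dilate", "open", "close"])
    def test_matches_double_loop_oracle(self, shape_name, img_shape, op, rng):
        rank = len(img_shape)
        shape = shape_from_name(shape_name, rank)
        img = _rand_image(rng, img_shape, np.uint16, 100)
        expected = oracles.morph_oracle(img.data, shape.offsets, op)
        assert np.array_equal(morph(img, op, shape).data, expected)

    def test_open_idempotent_and_duality_on_bit_masks(self, rng):
        mask = _rand_image(rng, (9, 8), bool)
        opened = morph(mask, "open", "8n")
        assert np.array_equal(morph(opened, "open", "8n").data, opened.data)
        # erode(m) == not dilate(not m), borders clipped symmetrically
        er = morph(mask, "erode", "4n").data
        dual = ~morph(Image(~mask.data), "dilate", "4n").data
        assert np.array_equal(er, dual)

    def test_open_below_identity_below_close(self, rng):
        mask = _rand_image(rng, (4, 9, 8), bool)
        opened = morph(mask, "open", "6n").data
        closed = morph(mask, "close", "6n").data
        assert not (opened & ~mask.data).any()
        assert not (mask.data & ~closed).any()


class TestNeighborhood:
    def test_median_row_example(self):
        img = Image(np.array([[1, 9, 1]], dtype=np.uint8))
        # clipped windows {1,9},{1,9,1},{9,1}; lower medians 1,1,1
        assert neighborhood_filter(img, "median", 1).data.tolist() == [[1, 1, 1]]

    @pytest.mark.parametrize("shape", SMALL_SHAPES)
    @pytest.mark.parametrize("mode", ["median", "mean"])
    @pytest.mark.parametrize("w", [1, 2])
    def test_matches_sliding_window_oracle(self, shape, mode, w, rng):
        img = _rand_image(rng, shape, np.uint16)
        out = neighborhood_filter(img, mode, w)
        expected = oracles.window_oracle(img.data, w, mode)
        if mode == "median":
            assert out.pixel_kind == img.pixel_kind
            assert np.array_equal(out.data, expected)
        else:
            assert out.pixel_kind.tag == "f32"
            np.testing.assert_allclose(out.data, expected, rtol=1e-6)

    @pytest.mark.parametrize("mode", ["median", "mean"])
    def test_constant_preserved(self, mode):
        img = Image(np.full((5, 5), 42, dtype=np.uint8))
        out = neighborhood_filter(img, mode, 2)
        np.testing.assert_allclose(np.asarray(out.data, dtype=float), 42.0,
                                   rtol=1e-6)


class TestGauss:
    def test_w1_kernel_is_quarter_half_quarter(self):
        np.testing.assert_allclose(binomial_kernel(1), [0.25, 0.5, 0.25])

    def test_constant_preserved_including_borders(self):
        img = Image(np.full((4, 5, 6), 7.0, dtype=np.float32))
        np.testing.assert_allclose(gauss(img, 2).data, 7.0, rtol=1e-6)

    @pytest.mark.parametrize("shape", SMALL_SHAPES)
    @pytest.mark.parametrize("w", [1, 2])
    def test_matches_dense_convolution_oracle(self, shape, w, rng):
        img = _rand_image(rng, shape, np.float32, 100)
        expected = oracles.gauss_dense_oracle(img.data, w)
        np.testing.assert_allclose(gauss(img, w).data, expected, rtol=1e-6)

    def test_shift_equivariance_on_floats(self, rng):
        img = _rand_image(rng, (8, 9), np.float64, 10)
        shifted = Image(img.data + 5.0)
        for fn in (lambda im: gauss(im, 2),
                   lambda im: neighborhood_filter(im, "mean", 2)):
            np.testing.assert_allclose(fn(shifted).data, fn(img).data + 5.0,
                                       rtol=1e-6)


class TestMlv:
    def test_constant_preserved(self):
        img = Image(np.full((6, 6), 3.0, dtype=np.float32))
        np.testing.assert_allclose(mlv(img, 1).data, 3.0)

    def test_step_edge_preserved_away_from_corners(self):
        data = np.zeros((9, 9), dtype=np.float32)
        data[:, 5:] = 10.0
        out = mlv(Image(data), 1).data
        interior = out[2:-2, :]
        np.testing.assert_allclose(interior, data[2:-2, :])

    @pytest.mark.parametrize("shape", [(9, 9), (5, 6, 7)])
    def test_matches_window_enumeration_oracle(self, shape, rng):
        img = _rand_image(rng, shape, np.float32, 50)
        expected = oracles.mlv_oracle(img.data, 1)
        np.testing.assert_allclose(mlv(img, 1).data, expected, rtol=1e-5)

    def test_width_below_one_rejected(self):
        with pytest.raises(ParameterError):
            mlv(Image(np.zeros((3, 3), np.float32)), 0)


class TestLabel:
    def test_empty_mask_gives_empty_labeling(self):
        out = label(Image(np.zeros((4, 4), dtype=bool)), "4n")
        assert out.data.max() == 0

    def test_first_encountered_component_gets_label_one(self):
        mask = np.zeros((3, 5), dtype=bool)
        mask[2, 0] = True   # later in scan order
        mask[0, 4] = True   # first in scan order
        out = label(Image(mask), "4n").data
        assert out[0, 4] == 1 and out[2, 0] == 2

    @pytest.mark.parametrize("shape_name,img_shape", [
        ("4n", (10, 11)), ("8n", (10, 11)), ("6n", (6, 7, 8)), ("26n", (6, 7, 8)),
    ])
    def test_matches_flood_fill_oracle(self, shape_name, img_shape, rng):
        shape = shape_from_name(shape_name, len(img_shape))
        mask = _rand_image(rng, img_shape, bool)
        got = label(mask, shape).data
        # the oracle labels in scan order of first encounter too
        expected = oracles.label_oracle(mask.data, shape.neighbor_offsets)
        assert np.array_equal(got, expected)

    def test_non_bit_input_rejected(self):
        with pytest.raises(ParameterError):
            label(Image(np.zeros((3, 3), dtype=np.uint8)), "4n")


class TestSelectBiggest:
    def test_picks_largest_and_breaks_ties_low(self):
        labels = Image(np.array([[1, 1, 0, 2], [1, 0, 2, 2]], dtype=np.int32))
        assert select_biggest(labels).data.sum() == 3  # label 1 has 3 voxels
        tie = Image(np.array([[1, 1, 2, 2]], dtype=np.int32))
        out = select_biggest(tie).data
        assert out.tolist() == [[True, True, False, False]]

    def test_empty_labeling_yields_all_false(self):
        out = select_biggest(Image(np.zeros((3, 3), dtype=np.int32)))
        assert not out.data.any()

    def test_selected_size_equals_histogram_max(self, rng):
        mask = _rand_image(rng, (12, 12), bool)
        labs = label(mask, "4n")
        sizes = np.bincount(labs.data.ravel())[1:]
        if sizes.size:
            assert select_biggest(labs).data.sum() == sizes.max()


class TestCombineAndMask:
    def test_self_difference_is_zero(self, rng):
        a = _rand_image(rng, (5, 5))
        assert not combine(a, a, "sub").data.any()

    def test_logical_identities(self, rng):
        m = _rand_image(rng, (6, 6), bool)
        notm = Image(~m.data)
        assert not combine(m, m, "xor").data.any()
        assert combine(m, notm, "or").data.all()

    @pytest.mark.parametrize("op,fn", [
        ("add", np.add), ("sub", np.subtract), ("mul", np.multiply),
        ("absdiff", lambda x, y: np.abs(x - y)),
    ])
    def test_arithmetic_matches_elementwise_oracle(self, op, fn, rng):
        a = _rand_image(rng, (5, 6), np.float32, 10)
        b = _rand_image(rng, (5, 6), np.float32, 10)
        expected = fn(a.data.astype(np.float64), b.data.astype(np.float64))
        np.testing.assert_allclose(combine(a, b, op).data, expected, rtol=1e-6)

    def test_extent_mismatch_names_both_shapes(self, rng):
        a = _rand_image(rng, (5, 6))
        b = _rand_image(rng, (6, 5))
        with pytest.raises(ParameterError, match=r"6, 5.*5, 6"):
            combine(a, b, "add")

    def test_mask_apply_full_empty_and_random(self, rng):
        img = _rand_image(rng, (5, 5))
        full = Image(np.ones((5, 5), dtype=bool))
        none = Image(np.zeros((5, 5), dtype=bool))
        assert np.array_equal(mask_apply(img, full).data, img.data)
        assert (mask_apply(img, none, outside=7).data == 7).all()
        m = _rand_image(rng, (5, 5), bool)
        out = mask_apply(img, m, outside=3)
        assert np.array_equal(out.data, np.where(m.data, img.data, 3))


class TestDistanceTransform:
    def test_single_source_is_euclidean_norm(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[0, 0, 0] = True
        out = distance_transform(Image(mask)).data
        z, y, x = np.meshgrid(*(np.arange(5),) * 3, indexing="ij")
        np.testing.assert_allclose(out, np.sqrt(z**2 + y**2 + x**2), rtol=1e-6)

    def test_matches_brute_force_search(self, rng):
        mask = Image(rng.random((12, 12, 12)) < 0.02)
        if not mask.data.any():
            mask = Image(np.eye(12, dtype=bool)[None].repeat(12, 0))
        expected = oracles.distance_oracle(mask.data)
        np.testing.assert_allclose(distance_transform(mask).data, expected,
                                   atol=1e-5)

    def test_spacing_aware_scales_isotropically(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0, 0, 0] = True
        img = Image(mask, spacing=(0.028,) * 3)
        vox = distance_transform(img, spacing_aware=False).data
        mm = distance_transform(img, spacing_aware=True).data
        np.testing.assert_allclose(mm, vox * 0.028, rtol=1e-6)

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateInputError):
            distance_transform(Image(np.zeros((3, 3), dtype=bool)))


class TestFilterInvariants:
    CHAINS = ["invert", "binarize:min=100", "median:w=1", "mean:w=1",
              "gauss:w=1", "mlv:w=1", "erode", "close"]

    @pytest.mark.parametrize("chain", CHAINS)
    def test_extents_spacing_metadata_preserved_and_input_untouched(
            self, chain, rng):
        data = rng.integers(0, 1000, (6, 7)).astype(np.uint16)
        img = Image(data, spacing=(0.5, 2.0), attributes={"k": "v"})
        out = run_chain(img, [chain], filter_registry(2))
        assert out.shape == img.shape
        assert out.spacing == img.spacing
        assert out.attributes == img.attributes
        assert np.array_equal(img.data, data)  # input raster bit-identical
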