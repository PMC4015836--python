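"""In-core 2D/3D gray-scale filters.

Border policy is window clipping throughout: every neighborhood operation
uses only the in-volume part of its window (for the separable Gaussian the
truncated kernel is renormalized to sum 1).  This keeps in-core results
identical to what the streaming slice pipeline produces at stack ends.

All filters return fresh images, preserve extents, spacing and metadata,
and never touch their input raster.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import ndimage

from .core import Image, PIXEL_KINDS, StoragePool, convert_pixel_kind
from .errors import DegenerateInputError, ParameterError
from .pipeline import (
    FilterDescriptor,
    Filter,
    ParamDecl,
    Registry,
    parse_chain,
    parse_descriptor,
)

__all__ = [
    "NeighborhoodShape",
    "shape_from_name",
    "binarize",
    "invert",
    "intensity_bandpass",
    "morph",
    "neighborhood_filter",
    "gauss",
    "binomial_kernel",
    "mlv",
    "label",
    "select_biggest",
    "combine",
    "mask_apply",
    "distance_transform",
    "FILTERS_2D",
    "FILTERS_3D",
    "SHAPES",
    "filter_registry",
]


# ---------------------------------------------------------------------------
# neighborhood shapes

@dataclass(frozen=True)
class NeighborhoodShape:
    """A symmetric set of integer voxel offsets, including the zero offset.

    The standard names are ``4n``/``8n`` in 2D, ``6n``/``18n``/``26n`` in
    3D, and ``sphere:r=k`` (all offsets with Euclidean norm <= k) in either
    rank.  Offsets are in NumPy axis order (``(dy, dx)`` / ``(dz, dy, dx)``).
    """

    name: str
    rank: int
    offsets: tuple[tuple[int, ...], ...]

    @property
    def footprint(self) -> np.ndarray:
        """Boolean structuring element centered on the zero offset."""
        r = max(max(abs(o) for o in off) for off in self.offsets)
        size = 2 * r + 1
        fp = np.zeros((size,) * self.rank, dtype=bool)
        for off in self.offsets:
            fp[tuple(o + r for o in off)] = True
        return fp

    @property
    def neighbor_offsets(self) -> tuple[tuple[int, ...], ...]:
        """Offsets without the center, in scan order."""
        return tuple(o for o in self.offsets if any(o))


def _ball_offsets(rank: int, radius: float) -> list[tuple[int, ...]]:
    r = int(np.floor(radius))
    out = []
    for off in itertools.product(range(-r, r + 1), repeat=rank):
        if sum(o * o for o in off) <= radius * radius:
            out.append(off)
    return out


def shape_from_name(name: str, rank: int) -> NeighborhoodShape:
    """Build a shape from its descriptor name for a given image rank."""
    name = name.strip()
    if name.startswith("sphere"):
        desc = parse_descriptor(name)
        params = desc.param_map
        try:
            radius = float(params.get("r", "1"))
        except ValueError:
            raise ParameterError(f"sphere radius {params.get('r')!r} is not a number")
        if radius < 1:
            raise ParameterError(f"sphere radius must be >= 1, got {radius}")
        offsets = _ball_offsets(rank, radius)
    elif rank == 2 and name == "4n":
        offsets = [(0, 0), (-1, 0), (1, 0), (0, -1), (0, 1)]
    elif rank == 2 and name == "8n":
        offsets = list(itertools.product((-1, 0, 1), repeat=2))
    elif rank == 3 and name in ("6n", "18n", "26n"):
        limit = {"6n": 1, "18n": 2, "26n": 3}[name]
        offsets = [o for o in itertools.product((-1, 0, 1), repeat=3)
                   if sum(abs(v) for v in o) <= limit]
    else:
        valid = "4n, 8n (2D); 6n, 18n, 26n (3D); sphere:r=k"
        raise ParameterError(
            f"unknown neighborhood shape {name!r} for rank {rank}; valid: {valid}")
    offsets.sort()  # scan order
    return NeighborhoodShape(name, rank, tuple(tuple(o) for o in offsets))


def _as_shape(shape, rank: int) -> NeighborhoodShape:
    if isinstance(shape, NeighborhoodShape):
        if shape.rank != rank:
            raise ParameterError(
                f"shape {shape.name!r} has rank {shape.rank}, image rank {rank}")
        return shape
    return shape_from_name(str(shape), rank)


# ---------------------------------------------------------------------------
# point operations

def binarize(image: Image, min: float, max: float) -> Image:
    """Bit mask of voxels with ``min <= value <= max`` (inclusive)."""
    if min > max:
        raise ParameterError(f"binarize: min {min} > max {max}")
    data = image.data
    return image.with_data((data >= min) & (data <= max))


def invert(image: Image) -> Image:
    """``v -> kind_max - v`` for unsigned/bit kinds, ``v -> -v`` for signed/float."""
    kind = image.pixel_kind
    data = image.data
    if kind.is_bit:
        return image.with_data(~data)
    if kind.is_float or kind.dtype.kind == "i":
        return image.with_data(-data)
    return image.with_data(kind.dtype.type(kind.max) - data)


def intensity_bandpass(image: Image, min: float, max: float) -> Image:
    """Values outside ``[min, max]`` are set to ``min``; inside unchanged."""
    if min > max:
        raise ParameterError(f"bandpass: min {min} > max {max}")
    data = image.data
    floor = np.asarray(min, dtype=data.dtype)
    out = np.where((data >= min) & (data <= max), data, floor)
    return image.with_data(out.astype(data.dtype, copy=False))


# ---------------------------------------------------------------------------
# morphology

def _flat_minmax(data: np.ndarray, footprint: np.ndarray, take_min: bool) -> np.ndarray:
    """Flat min/max over a footprint, ignoring out-of-bounds offsets."""
    if data.dtype == np.bool_:
        work = data.astype(np.uint8)
        out = _flat_minmax(work, footprint, take_min)
        return out.astype(np.bool_)
    if data.dtype.kind == "f":
        cval = np.inf if take_min else -np.inf
    else:
        info = np.iinfo(data.dtype)
        cval = info.max if take_min else info.min
    fn = ndimage.minimum_filter if take_min else ndimage.maximum_filter
    return fn(data, footprint=footprint, mode="constant", cval=cval)


def morph(image: Image, op: str, shape) -> Image:
    """Flat gray-scale morphology (erode/dilate/open/close) over a shape.

    On bit images this reduces to Boolean erosion/dilation.  Out-of-bounds
    offsets are ignored (the window is clipped at the borders).
    """
    shape = _as_shape(shape, image.rank)
    fp = shape.footprint
    data = image.data
    if op == "erode":
        out = _flat_minmax(data, fp, True)
    elif op == "dilate":
        out = _flat_minmax(data, fp, False)
    elif op == "open":
        out = _flat_minmax(_flat_minmax(data, fp, True), fp, False)
    elif op == "close":
        out = _flat_minmax(_flat_minmax(data, fp, False), fp, True)
    else:
        raise ParameterError(f"unknown morphological op {op!r}")
    return image.with_data(out)


# ---------------------------------------------------------------------------
# smoothing

def _box_sum(arr: np.ndarray, w: int) -> np.ndarray:
    """Sum over the (2w+1)^rank box with zero padding (clipped window sum)."""
    out = arr.astype(np.float64, copy=True)
    size = 2 * w + 1
    for axis in range(arr.ndim):
        out = ndimage.uniform_filter1d(out, size=size, axis=axis,
                                       mode="constant", cval=0.0) * size
    return out


def _box_count(shape: tuple[int, ...], w: int) -> np.ndarray:
    return _box_sum(np.ones(shape), w)


def neighborhood_filter(image: Image, mode: str, w: int) -> Image:
    """Median or mean over the clipped ``(2w+1)^rank`` window.

    The median of an even-count window is the lower median, which keeps
    integer images integer-exact.  Mean output is f32 (f64 stays f64).
    """
    if w < 0:
        raise ParameterError(f"window half-width must be >= 0, got {w}")
    data = image.data
    if w == 0:
        if mode == "median":
            return image.copy()
        if mode == "mean":
            tgt = np.float64 if data.dtype == np.float64 else np.float32
            return image.with_data(data.astype(tgt))
    if mode == "mean":
        cnt = _box_count(data.shape, w)
        out = _box_sum(data, w) / cnt
        tgt = np.float64 if data.dtype == np.float64 else np.float32
        return image.with_data(out.astype(tgt))
    if mode != "median":
        raise ParameterError(f"unknown neighborhood mode {mode!r}")

    was_bit = data.dtype == np.bool_
    work = data.astype(np.uint8) if was_bit else data
    if work.dtype.kind == "f":
        pad_value = np.inf
    else:
        pad_value = np.iinfo(work.dtype).max
    padded = np.pad(work, w, mode="constant", constant_values=pad_value)
    windows = np.lib.stride_tricks.sliding_window_view(
        padded, (2 * w + 1,) * work.ndim)
    flat = windows.reshape(work.shape + (-1,))
    flat = np.sort(flat, axis=-1)
    cnt = np.rint(_box_count(work.shape, w)).astype(np.intp)
    idx = (cnt - 1) // 2  # lower median among the valid (non-pad) samples
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    out = out.astype(work.dtype, copy=False)
    if was_bit:
        out = out.astype(np.bool_)
    return image.with_data(out)


def binomial_kernel(w: int) -> np.ndarray:
    """The 1D binomial smoothing kernel of half-width ``w``: C(2w,k)/4**w."""
    if w < 0:
        raise ParameterError(f"gauss width must be >= 0, got {w}")
    return np.array([comb(2 * w, k) for k in range(2 * w + 1)],
                    dtype=np.float64) / 4.0 ** w


def _gauss_axis(data: np.ndarray, kernel: np.ndarray, axis: int) -> np.ndarray:
    num = ndimage.correlate1d(data, kernel, axis=axis, mode="constant", cval=0.0)
    den = ndimage.correlate1d(np.ones(data.shape), kernel, axis=axis,
                              mode="constant", cval=0.0)
    return num / den


def gauss(image: Image, w: int) -> Image:
    """Separable binomial (discrete Gaussian) smoothing of half-width ``w``.

    At the borders the kernel is truncated to the valid samples and
    renormalized to sum 1, so constants stay constant everywhere.
    """
    kernel = binomial_kernel(w)
    data = image.data.astype(np.float64)
    for axis in range(data.ndim - 1, -1, -1):  # x, then y, then z
        data = _gauss_axis(data, kernel, axis)
    tgt = np.float64 if image.data.dtype == np.float64 else np.float32
    return image.with_data(data.astype(tgt))


def mlv(image: Image, w: int) -> Image:
    """Mean-of-least-variance edge-preserving smoother.

    For each voxel, among all clipped ``(2w+1)^rank`` windows whose center
    lies within Chebyshev distance ``w`` of the voxel, the window with the
    least population variance wins and its mean is the output.  Ties go to
    the smallest center in (z, y, x) scan order.
    """
    if w < 1:
        raise ParameterError(f"mlv width must be >= 1, got {w}")
    data = image.data.astype(np.float64)
    cnt = _box_count(data.shape, w)
    s1 = _box_sum(data, w)
    s2 = _box_sum(data * data, w)
    mean_c = s1 / cnt
    var_c = np.maximum(s2 / cnt - mean_c * mean_c, 0.0)

    shape = data.shape
    flat_index = np.arange(data.size, dtype=np.int64).reshape(shape)
    best_var = np.full(shape, np.inf)
    best_key = np.full(shape, np.iinfo(np.int64).max, dtype=np.int64)
    best_mean = np.zeros(shape)

    for off in itertools.product(range(-w, w + 1), repeat=data.ndim):
        # candidate center u = v + off; build aligned views
        src = tuple(slice(max(o, 0), n + min(o, 0)) for o, n in zip(off, shape))
        dst = tuple(slice(max(-o, 0), n + min(-o, 0)) for o, n in zip(off, shape))
        cand_var = var_c[src]
        cand_key = flat_index[src]
        cand_mean = mean_c[src]
        bv = best_var[dst]
        bk = best_key[dst]
        take = (cand_var < bv) | ((cand_var == bv) & (cand_key < bk))
        best_var[dst] = np.where(take, cand_var, bv)
        best_key[dst] = np.where(take, cand_key, bk)
        best_mean[dst] = np.where(take, cand_mean, best_mean[dst])
    tgt = np.float64 if image.data.dtype == np.float64 else np.float32
    return image.with_data(best_mean.astype(tgt))


# ---------------------------------------------------------------------------
# labeling and selection

def _connectivity_structure(shape: NeighborhoodShape) -> np.ndarray:
    fp = shape.footprint
    if any(s > 3 for s in fp.shape):
        raise ParameterError(
            f"shape {shape.name!r} exceeds the 3^rank structuring element "
            "supported for connectivity labeling")
    full = np.zeros((3,) * shape.rank, dtype=bool)
    sl = tuple(slice(1 - s // 2, 2 + s // 2) for s in fp.shape)
    full[sl] = fp
    full[(1,) * shape.rank] = True
    return full


def label(mask: Image, shape) -> Image:
    """Connected-component labeling of a bit mask.

    Components get labels 1..L in first-encounter (z, y, x) scan order;
    background stays 0.  Output pixel kind is s32.
    """
    if not mask.pixel_kind.is_bit:
        raise ParameterError("label expects a bit image")
    shape = _as_shape(shape, mask.rank)
    structure = _connectivity_structure(shape)
    raw, n = ndimage.label(mask.data, structure=structure)
    if n > 0:
        flat = raw.ravel()
        nz = flat[flat > 0]
        _, first = np.unique(nz, return_index=True)
        order = np.argsort(first, kind="stable")
        remap = np.zeros(n + 1, dtype=np.int32)
        labels_sorted_by_first = np.unique(nz)[order]
        remap[labels_sorted_by_first] = np.arange(1, n + 1, dtype=np.int32)
        raw = remap[raw]
    return mask.with_data(raw.astype(np.int32))


def select_biggest(labels: Image) -> Image:
    """Bit mask of the label with the most voxels (ties: smallest label).

    An empty labeling (no components) yields an all-false mask.
    """
    data = labels.data
    if data.dtype.kind not in "iu":
        raise ParameterError("select_biggest expects an integer label map")
    counts = np.bincount(data.ravel())
    if len(counts) <= 1:
        return labels.with_data(np.zeros(data.shape, dtype=bool))
    counts = counts[1:]
    winner = int(np.argmax(counts)) + 1  # argmax returns the smallest tie
    if counts[winner - 1] == 0:
        return labels.with_data(np.zeros(data.shape, dtype=bool))
    return labels.with_data(data == winner)


# ---------------------------------------------------------------------------
# combination, masking, distance

_LOGICAL = {"and": np.logical_and, "or": np.logical_or, "xor": np.logical_xor}


def combine(a: Image, b: Image, op: str) -> Image:
    """Pixel-wise combination of two images of equal extents.

    Arithmetic ops work in f64 and emit f32; logical ops require bit
    inputs and emit bit.
    """
    if a.shape != b.shape:
        raise ParameterError(
            f"combine: extent mismatch {a.extents} vs {b.extents}")
    if op in _LOGICAL:
        if not (a.pixel_kind.is_bit and b.pixel_kind.is_bit):
            raise ParameterError(f"combine {op!r} requires bit images")
        return a.with_data(_LOGICAL[op](a.data, b.data))
    x = a.data.astype(np.float64)
    y = b.data.astype(np.float64)
    if op == "add":
        out = x + y
    elif op == "sub":
        out = x - y
    elif op == "mul":
        out = x * y
    elif op == "absdiff":
        out = np.abs(x - y)
    else:
        raise ParameterError(
            f"unknown combine op {op!r}; valid: add, sub, mul, absdiff, "
            "and, or, xor")
    return a.with_data(out.astype(np.float32))


def mask_apply(image: Image, mask: Image, outside: float = 0) -> Image:
    """Keep the image where the mask is true; set ``outside`` elsewhere."""
    if image.shape != mask.shape:
        raise ParameterError(
            f"mask: extent mismatch {image.extents} vs {mask.extents}")
    if not mask.pixel_kind.is_bit:
        raise ParameterError("mask must be a bit image")
    fill = np.asarray(outside).astype(image.data.dtype)
    out = np.where(mask.data, image.data, fill)
    return image.with_data(out.astype(image.data.dtype, copy=False))


def distance_transform(mask: Image, spacing_aware: bool = False) -> Image:
    """Exact Euclidean distance to the nearest true voxel (f32).

    With ``spacing_aware`` the per-axis spacing (mm) is applied, otherwise
    distances are in voxel units.  True voxels map to 0.
    """
    if not mask.pixel_kind.is_bit:
        raise ParameterError("distance_transform expects a bit image")
    if not mask.data.any():
        raise DegenerateInputError("distance transform of an empty mask")
    sampling = mask.spacing_numpy if spacing_aware else None
    dist = ndimage.distance_transform_edt(~mask.data, sampling=sampling)
    return mask.with_data(np.asarray(dist, dtype=np.float32))


# ---------------------------------------------------------------------------
# registries

SHAPES = Registry("shape")
for _name in ("4n", "8n", "6n", "18n", "26n"):
    SHAPES.add(_name,
               lambda context, _n=_name: _n,
               help=f"fixed neighborhood {_name}")
SHAPES.add("sphere",
           lambda context, r: f"sphere:r={r}",
           params=[ParamDecl("r", "float", default=1.0, min=1.0,
                             help="Euclidean radius in voxels")],
           help="all offsets with Euclidean norm <= r")


def _register_common(reg: Registry, rank: int) -> None:
    default_shape = "4n" if rank == 2 else "6n"
    shape_decl = ParamDecl("shape", "shape", default=default_shape,
                           help="neighborhood shape descriptor")

    @reg.register("binarize",
                  params=[ParamDecl("min", "float", default=float("-inf"),
                                    help="lower inclusive bound"),
                          ParamDecl("max", "float", default=float("inf"),
                                    help="upper inclusive bound")],
                  help="bit mask of values inside [min, max]")
    def _binarize(context, min, max):
        if min > max:
            raise ParameterError(f"binarize: min {min} > max {max}")
        return lambda img: binarize(img, min, max)

    @reg.register("invert", help="intensity inversion (max-v / -v)")
    def _invert(context):
        return invert

    @reg.register("bandpass",
                  params=[ParamDecl("min", "float", required=True,
                                    help="lower bound / replacement value"),
                          ParamDecl("max", "float", required=True,
                                    help="upper bound")],
                  help="clamp values outside [min, max] to min")
    def _bandpass(context, min, max):
        if min > max:
            raise ParameterError(f"bandpass: min {min} > max {max}")
        return lambda img: intensity_bandpass(img, min, max)

    for _op in ("erode", "dilate", "open", "close"):
        @reg.register(_op, params=[shape_decl],
                      help=f"morphological {_op} over the shape")
        def _morph(context, shape, _op=_op):
            resolved = shape_from_name(shape, rank)
            return lambda img: morph(img, _op, resolved)

    @reg.register("median",
                  params=[ParamDecl("w", "int", default=1, min=0,
                                    help="window half-width")],
                  help="median of the clipped (2w+1)^rank window")
    def _median(context, w):
        return lambda img: neighborhood_filter(img, "median", w)

    @reg.register("mean",
                  params=[ParamDecl("w", "int", default=1, min=0,
                                    help="window half-width")],
                  help="mean of the clipped (2w+1)^rank window")
    def _mean(context, w):
        return lambda img: neighborhood_filter(img, "mean", w)

    @reg.register("gauss",
                  params=[ParamDecl("w", "int", default=1, min=0,
                                    help="kernel half-width")],
                  help="separable binomial smoothing")
    def _gauss(context, w):
        return lambda img: gauss(img, w)

    @reg.register("mlv",
                  params=[ParamDecl("w", "int", default=1, min=1,
                                    help="window half-width")],
                  help="mean-of-least-variance edge-preserving smoother")
    def _mlv(context, w):
        return lambda img: mlv(img, w)

    @reg.register("label", params=[shape_decl],
                  help="connected-component labeling of a bit mask")
    def _label(context, shape):
        resolved = shape_from_name(shape, rank)
        return lambda img: label(img, resolved)

    @reg.register("selectbig", help="keep the largest labeled component")
    def _selectbig(context):
        return select_biggest

    @reg.register("mask",
                  params=[ParamDecl("src", "str", required=True,
                                    help="pool key of the bit mask"),
                          ParamDecl("outside", "float", default=0.0,
                                    help="value outside the mask")],
                  help="apply a bit mask stored in the virtual storage")
    def _mask(context, src, outside):
        pool = context.pool
        return lambda img: mask_apply(img, binarize_mask(pool.get(src)), outside)

    @reg.register("tee",
                  params=[ParamDecl("target", "str", required=True,
                                    help="pool key to store under")],
                  help="store a copy of the current image in the pool")
    def _tee(context, target):
        if not target:
            raise ParameterError("tee: target key must be non-empty")
        pool = context.pool

        def apply(img):
            pool.store(target, img)
            return img.copy()
        return apply

    @reg.register("load",
                  params=[ParamDecl("key", "str", required=True,
                                    help="pool key to load")],
                  help="replace the current image by a pool entry")
    def _load(context, key):
        pool = context.pool
        return lambda img: pool.get(key)

    @reg.register("convert",
                  params=[ParamDecl("repn", "enum", default="u8",
                                    choices=tuple(PIXEL_KINDS),
                                    help="target pixel kind"),
                          ParamDecl("mode", "enum", default="copy",
                                    choices=("copy", "clamp", "rescale"),
                                    help="conversion mode")],
                  help="pixel-kind conversion")
    def _convert(context, repn, mode):
        return lambda img: convert_pixel_kind(img, repn, mode)


def binarize_mask(image: Image) -> Image:
    """Coerce a pool entry to a bit mask (non-zero -> true)."""
    if image.pixel_kind.is_bit:
        return image
    return image.with_data(image.data != 0)


FILTERS_2D = Registry("filter2d")
FILTERS_3D = Registry("filter3d")
_register_common(FILTERS_2D, 2)
_register_common(FILTERS_3D, 3)


def filter_registry(rank: int) -> Registry:
    """The default filter registry for a given image rank."""
    if rank == 2:
        return FILTERS_2D
    if rank == 3:
        return FILTERS_3D
    raise ParameterError(f"no filter registry for rank {rank}")
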