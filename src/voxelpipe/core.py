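"""Typed raster images, pixel-kind dispatch and conversion, virtual storage.

An :class:`Image` is the single value type every filter consumes and
produces: a dense 2D or 3D gray-scale raster with a pixel-kind tag,
per-axis spacing in millimetres, and a flat string metadata map.  Data is
stored C-contiguous with the x axis fastest, so a 3D array is indexed
``data[z, y, x]`` while user-facing ``extents``/``spacing`` are given in
``(x, y[, z])`` order to match how slice stacks are laid out on disk.

Images have value semantics: filters never mutate their input, and the
:class:`StoragePool` (the "virtual storage" that the ``tee``/``load``
pipeline elements talk to) stores and hands out independent copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Mapping

import numpy as np

from .errors import (
    MissingPoolEntryError,
    ParameterError,
    PixelRangeError,
    UnsupportedPixelKindError,
)

__all__ = [
    "PixelKind",
    "PIXEL_KINDS",
    "Image",
    "StoragePool",
    "dispatch_by_pixel_kind",
    "convert_pixel_kind",
    "images_equal",
]


@dataclass(frozen=True)
class PixelKind:
    """One of the eleven supported pixel kinds.

    ``bit`` images hold only {False, True}; the integer kinds map to the
    fixed-width NumPy integers and ``f32``/``f64`` to IEEE floats.
    """

    tag: str

    @property
    def dtype(self) -> np.dtype:
        return _DTYPES[self.tag]

    @property
    def is_float(self) -> bool:
        return self.tag in ("f32", "f64")

    @property
    def is_bit(self) -> bool:
        return self.tag == "bit"

    @property
    def min(self):
        if self.is_bit:
            return 0
        if self.is_float:
            return float(np.finfo(self.dtype).min)
        return int(np.iinfo(self.dtype).min)

    @property
    def max(self):
        if self.is_bit:
            return 1
        if self.is_float:
            return float(np.finfo(self.dtype).max)
        return int(np.iinfo(self.dtype).max)

    def __str__(self) -> str:
        return self.tag


_DTYPES = {
    "bit": np.dtype(np.bool_),
    "u8": np.dtype(np.uint8),
    "s8": np.dtype(np.int8),
    "u16": np.dtype(np.uint16),
    "s16": np.dtype(np.int16),
    "u32": np.dtype(np.uint32),
    "s32": np.dtype(np.int32),
    "u64": np.dtype(np.uint64),
    "s64": np.dtype(np.int64),
    "f32": np.dtype(np.float32),
    "f64": np.dtype(np.float64),
}

PIXEL_KINDS: dict[str, PixelKind] = {tag: PixelKind(tag) for tag in _DTYPES}

_KIND_BY_DTYPE = {dt: PIXEL_KINDS[tag] for tag, dt in _DTYPES.items()}


def _as_kind(kind: "PixelKind | str") -> PixelKind:
    if isinstance(kind, PixelKind):
        return kind
    try:
        return PIXEL_KINDS[kind]
    except KeyError:
        raise UnsupportedPixelKindError(
            f"unknown pixel kind {kind!r}; supported: {', '.join(_DTYPES)}"
        ) from None


def kind_of_dtype(dtype) -> PixelKind:
    """Map a NumPy dtype to its pixel kind (bool -> bit)."""
    try:
        return _KIND_BY_DTYPE[np.dtype(dtype)]
    except KeyError:
        raise UnsupportedPixelKindError(f"no pixel kind for dtype {dtype!r}") from None


class Image:
    """A typed 2D/3D gray-scale raster with spacing and metadata.

    Parameters
    ----------
    data:
        Array of rank 2 or 3, indexed ``[y, x]`` / ``[z, y, x]``.  Copied
        unless ``copy=False`` (internal use for freshly built arrays).
    spacing:
        Per-axis voxel size in mm, ``(x, y[, z])`` order; defaults to 1.0.
    attributes:
        Flat string-to-string metadata map, carried through filters.
    """

    __slots__ = ("_data", "_spacing", "attributes")

    def __init__(self, data, spacing=None, attributes: Mapping[str, str] | None = None,
                 *, copy: bool = True):
        arr = np.array(data, copy=copy)
        if arr.ndim not in (2, 3):
            raise ValueError(f"image rank must be 2 or 3, got {arr.ndim}")
        kind_of_dtype(arr.dtype)  # validate supported dtype
        arr = np.ascontiguousarray(arr)
        arr.setflags(write=False)
        self._data = arr
        if spacing is None:
            spacing = (1.0,) * arr.ndim
        spacing = tuple(float(s) for s in spacing)
        if len(spacing) != arr.ndim:
            raise ValueError(f"spacing has {len(spacing)} entries for rank {arr.ndim}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be positive, got {spacing}")
        self._spacing = spacing
        self.attributes: dict[str, str] = dict(attributes or {})

    # -- geometry -----------------------------------------------------------
    @property
    def data(self) -> np.ndarray:
        """Read-only view of the raster (``[z, y, x]`` indexing)."""
        return self._data

    @property
    def rank(self) -> int:
        return self._data.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        """NumPy-order shape (``(y, x)`` or ``(z, y, x)``)."""
        return self._data.shape

    @property
    def extents(self) -> tuple[int, ...]:
        """Voxel counts in ``(x, y[, z])`` order."""
        return tuple(reversed(self._data.shape))

    @property
    def spacing(self) -> tuple[float, ...]:
        """Voxel size in mm, ``(x, y[, z])`` order."""
        return self._spacing

    @property
    def spacing_numpy(self) -> tuple[float, ...]:
        """Spacing reordered to match NumPy axis order."""
        return tuple(reversed(self._spacing))

    @property
    def pixel_kind(self) -> PixelKind:
        return kind_of_dtype(self._data.dtype)

    # -- value semantics ----------------------------------------------------
    def copy(self) -> "Image":
        return Image(self._data, self._spacing, self.attributes)

    def with_data(self, data, *, copy: bool = False) -> "Image":
        """A new image with fresh pixel data but this image's metadata."""
        return Image(data, self._spacing, self.attributes, copy=copy)

    def __repr__(self) -> str:
        return (f"Image(kind={self.pixel_kind}, extents={self.extents}, "
                f"spacing={self._spacing})")


def images_equal(a: Image, b: Image) -> bool:
    """Value equality: pixel kind, extents, spacing, attributes and raster."""
    return (a.pixel_kind == b.pixel_kind
            and a.shape == b.shape
            and a.spacing == b.spacing
            and a.attributes == b.attributes
            and np.array_equal(a.data, b.data))


def dispatch_by_pixel_kind(image: Image, handlers: Mapping[Any, Callable[[Image], Any]]):
    """Invoke the handler registered for the image's pixel kind.

    ``handlers`` maps pixel-kind tags (or :class:`PixelKind` values) to
    callables; the key ``"*"`` acts as a generic fallback.  Exactly one
    handler is invoked, with the image as its argument.
    """
    kind = image.pixel_kind
    for key in (kind, kind.tag):
        if key in handlers:
            return handlers[key](image)
    if "*" in handlers:
        return handlers["*"](image)
    raise UnsupportedPixelKindError(
        f"no handler for pixel kind '{kind.tag}' and no '*' fallback")


def _float_target_range(target: PixelKind) -> tuple[float, float]:
    # rescale maps onto [0, 1] for float targets: the full representable
    # float range is useless as an intensity scale
    return (0.0, 1.0)


def convert_pixel_kind(image: Image, target: "PixelKind | str",
                       mode: str = "copy") -> Image:
    """Convert an image to another pixel kind.

    ``copy`` requires every value to be exactly representable in the
    target kind; ``clamp`` saturates to the target range (rounding to
    nearest for integer targets); ``rescale`` maps the observed
    ``[min, max]`` affinely onto the target's full range ([0, 1] for float
    targets), producing all zeros when the image is constant.
    """
    target = _as_kind(target)
    if mode not in ("copy", "clamp", "rescale"):
        raise ParameterError(
            f"unknown conversion mode {mode!r}; expected copy|clamp|rescale")
    src = image.data

    if mode == "copy":
        if target.is_bit:
            bad = (src != 0) & (src != 1)
            if bad.any():
                v = src[bad][0]
                raise PixelRangeError(f"value {v} not representable as bit")
            out = src.astype(np.bool_)
        else:
            out = src.astype(target.dtype)
            back = out.astype(src.dtype)
            if src.dtype.kind == "f" and target.is_float:
                ok = np.array_equal(back, src, equal_nan=True)
            else:
                ok = np.array_equal(back, src)
            if not ok:
                if src.dtype.kind == "f":
                    bad = ~(np.isclose(back, src, rtol=0, atol=0) | (np.isnan(back) & np.isnan(src)))
                else:
                    bad = back != src
                v = src[bad][0]
                raise PixelRangeError(
                    f"value {v} not representable in {target.tag} (copy mode)")
        return image.with_data(out)

    if mode == "clamp":
        work = src.astype(np.float64)
        lo, hi = (0.0, 1.0) if target.is_bit else (target.min, target.max)
        if target.is_float:
            # avoid inf from out-of-range f64 -> f32
            work = np.clip(work, lo, hi)
            out = work.astype(target.dtype)
        else:
            work = np.clip(np.rint(work), lo, hi)
            out = work.astype(np.bool_ if target.is_bit else target.dtype)
        return image.with_data(out)

    # rescale
    work = src.astype(np.float64)
    vmin, vmax = float(work.min()), float(work.max())
    if target.is_float:
        tmin, tmax = _float_target_range(target)
    else:
        tmin, tmax = float(target.min), float(target.max)
    if vmin == vmax:
        out = np.zeros(src.shape, dtype=target.dtype)
        return image.with_data(out)
    scaled = (work - vmin) * ((tmax - tmin) / (vmax - vmin)) + tmin
    if target.is_bit:
        out = np.rint(scaled).astype(np.bool_)
    elif target.is_float:
        out = scaled.astype(target.dtype)
    else:
        out = np.rint(scaled).astype(target.dtype)
    return image.with_data(out)


class StoragePool:
    """In-memory virtual storage for pipeline intermediates.

    One pool per pipeline run.  ``store`` overwrites silently and keeps an
    independent copy; ``get`` returns a copy, so pool contents can never be
    aliased by later pipeline stages.
    """

    def __init__(self):
        self._entries: dict[str, Image] = {}

    def store(self, key: str, image: Image) -> None:
        if not key:
            raise ValueError("pool key must be non-empty")
        self._entries[key] = image.copy()

    def get(self, key: str) -> Image:
        try:
            return self._entries[key].copy()
        except KeyError:
            raise MissingPoolEntryError(
                f"no pool entry named {key!r} (have: {sorted(self._entries) or 'none'})"
            ) from None

    def __contains__(self, key: str) -> bool:
        return key in self._entries

    def keys(self):
        return self._entries.keys()

    def __len__(self) -> int:
        return len(self._entries)
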