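"""Readers and writers for PNG, TIFF and NIfTI-1, plus slice-stack IO.

Supported combinations (gray-scale only):

* ``.png`` — 2D bit, u8, u16; no spacing (PNG carries none we honor).
* ``.tif``/``.tiff`` — 2D u8, u16, u32, f32; in-plane spacing via the
  TIFF resolution tags (resolution unit centimeter).
* ``.nii``/``.nii.gz`` — 2D or 3D, any kind except bit (bit volumes are
  written as u8); spacing via the NIfTI header zooms (mm).

Slice stacks use printf-style filename patterns (``slice%04d.tif``); the
source is strictly forward-only so streaming filters can rely on the
single-pass contract.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass

import numpy as np

from .core import Image, kind_of_dtype
from .errors import FormatError, FifoProtocolError

__all__ = [
    "read_image",
    "write_image",
    "StackPattern",
    "open_slice_source",
    "open_slice_sink",
    "SliceSource",
    "SliceSink",
]

_PNG_KINDS = {"bit", "u8", "u16"}
_TIFF_KINDS = {"u8", "u16", "u32", "f32"}


def _ext(path: str) -> str:
    p = str(path).lower()
    if p.endswith(".nii.gz"):
        return ".nii.gz"
    return os.path.splitext(p)[1]


def read_image(path) -> Image:
    """Read a gray-scale image; the format is chosen by extension."""
    ext = _ext(path)
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    if ext == ".png":
        return _read_png(path)
    if ext in (".tif", ".tiff"):
        return _read_tiff(path)
    if ext in (".nii", ".nii.gz"):
        return _read_nifti(path)
    raise FormatError(f"unsupported image extension {ext!r} for {path}")


def write_image(path, image: Image) -> None:
    """Write an image; the format is chosen by extension."""
    ext = _ext(path)
    if ext == ".png":
        _write_png(path, image)
    elif ext in (".tif", ".tiff"):
        _write_tiff(path, image)
    elif ext in (".nii", ".nii.gz"):
        _write_nifti(path, image)
    else:
        raise FormatError(f"unsupported image extension {ext!r} for {path}")


# ---------------------------------------------------------------------------
# PNG

def _read_png(path) -> Image:
    from PIL import Image as PILImage
    try:
        with PILImage.open(path) as im:
            im.load()
            mode = im.mode
            if mode == "1":
                data = np.asarray(im, dtype=bool)
            elif mode == "L":
                data = np.asarray(im, dtype=np.uint8)
            elif mode in ("I;16", "I;16B", "I"):
                data = np.asarray(im.convert("I"), dtype=np.int32)
                if data.min() < 0 or data.max() > 0xFFFF:
                    raise FormatError(
                        f"{path}: PNG sample range exceeds u16")
                data = data.astype(np.uint16)
            else:
                raise FormatError(
                    f"{path}: only gray-scale PNG supported, got mode {mode!r}")
    except FormatError:
        raise
    except Exception as e:
        raise FormatError(f"{path}: not a readable PNG ({e})") from e
    return Image(data)


def _write_png(path, image: Image) -> None:
    from PIL import Image as PILImage
    if image.rank != 2:
        raise FormatError("PNG holds 2D images; write slices or use NIfTI")
    kind = image.pixel_kind
    if kind.tag not in _PNG_KINDS:
        raise FormatError(
            f"pixel kind {kind.tag} not supported by PNG "
            f"(supported: {sorted(_PNG_KINDS)}); convert first")
    data = image.data
    if kind.is_bit:
        im = PILImage.fromarray(data.astype(np.uint8) * 255, mode="L").convert("1")
    elif kind.tag == "u8":
        im = PILImage.fromarray(data, mode="L")
    else:
        im = PILImage.fromarray(data.astype("<u2"))  # mode I;16
    im.save(path, format="PNG")


# ---------------------------------------------------------------------------
# TIFF

def _read_tiff(path) -> Image:
    import tifffile
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            data = page.asarray()
            spacing = _spacing_from_tiff(page)
    except Exception as e:
        raise FormatError(f"{path}: not a readable TIFF ({e})") from e
    if data.ndim != 2:
        raise FormatError(f"{path}: only single-plane gray TIFF supported")
    kind = kind_of_dtype(data.dtype)
    if kind.tag not in _TIFF_KINDS:
        raise FormatError(f"{path}: TIFF pixel kind {kind.tag} unsupported")
    return Image(data, spacing=spacing)


def _spacing_from_tiff(page) -> tuple[float, float]:
    tags = page.tags
    try:
        unit = tags["ResolutionUnit"].value
        xres = tags["XResolution"].value
        yres = tags["YResolution"].value
    except KeyError:
        return (1.0, 1.0)
    per_mm = {2: 25.4, 3: 10.0}  # inch, centimeter -> mm
    unit_val = getattr(unit, "value", unit)
    if unit_val not in per_mm:
        return (1.0, 1.0)

    def to_mm(res):
        num, den = (res if isinstance(res, tuple) else (res, 1))
        if not num:
            return 1.0
        return per_mm[unit_val] * den / num
    return (to_mm(xres), to_mm(yres))


def _write_tiff(path, image: Image) -> None:
    import tifffile
    if image.rank != 2:
        raise FormatError("TIFF writer holds 2D slices; use NIfTI for volumes")
    kind = image.pixel_kind
    if kind.tag not in _TIFF_KINDS:
        raise FormatError(
            f"pixel kind {kind.tag} not supported by TIFF "
            f"(supported: {sorted(_TIFF_KINDS)}); convert first")
    sx, sy = image.spacing
    tifffile.imwrite(path, image.data,
                     resolution=(10.0 / sx, 10.0 / sy),
                     resolutionunit="CENTIMETER")


# ---------------------------------------------------------------------------
# NIfTI

def _read_nifti(path) -> Image:
    import nibabel as nib
    try:
        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj)
        zooms = img.header.get_zooms()
    except Exception as e:
        raise FormatError(f"{path}: not a readable NIfTI ({e})") from e
    arr = np.squeeze(arr)
    if arr.ndim not in (2, 3):
        raise FormatError(f"{path}: NIfTI rank {arr.ndim} unsupported")
    spacing = tuple(float(z) for z in zooms[:arr.ndim])
    # NIfTI stores x fastest; transpose to numpy [z, y, x]
    return Image(np.ascontiguousarray(arr.T), spacing=spacing)


def _write_nifti(path, image: Image) -> None:
    import nibabel as nib
    data = image.data
    if image.pixel_kind.is_bit:
        data = data.astype(np.uint8)  # NIfTI has no 1-bit type
    affine = np.diag(list(image.spacing) + [1.0] * (4 - image.rank))
    nifti = nib.Nifti1Image(np.asfortranarray(data.T), affine)
    nifti.header.set_zooms(image.spacing)
    nib.save(nifti, str(path))


# ---------------------------------------------------------------------------
# slice stacks

@dataclass(frozen=True)
class StackPattern:
    """printf-style filename pattern plus index range for a slice stack."""

    template: str
    start: int = 0
    count: int = 0

    def path(self, i: int) -> str:
        return self.template % (self.start + i)

    def __post_init__(self):
        if not re.search(r"%0?\d*d", self.template):
            raise FormatError(
                f"pattern {self.template!r} needs one printf integer field")


class SliceSource:
    """Forward-only iterator over the slices of a stack pattern.

    Iterating twice (or calling ``iter`` twice) raises: streaming filters
    must never re-request an earlier slice.
    """

    def __init__(self, pattern: StackPattern):
        self.pattern = pattern
        missing = [(i, pattern.path(i)) for i in range(pattern.count)
                   if not os.path.exists(pattern.path(i))]
        if missing:
            i, p = missing[0]
            raise FormatError(f"missing slice {i}: {p}")
        self._index = 0
        self._iterated = False
        self.count = pattern.count

    def __iter__(self):
        if self._iterated:
            raise FifoProtocolError(
                "slice source is single-pass; it was already consumed")
        self._iterated = True
        return self

    def __next__(self) -> Image:
        if self._index >= self.pattern.count:
            raise StopIteration
        i = self._index
        path = self.pattern.path(i)
        try:
            img = read_image(path)
        except FormatError as e:
            raise FormatError(f"slice {i}: {e}") from e
        if img.rank != 2:
            raise FormatError(f"slice {i} ({path}): not a 2D image")
        self._index += 1
        return img


class SliceSink:
    """Writes slice ``i`` to the expanded pattern path ``i``."""

    def __init__(self, pattern: StackPattern):
        self.pattern = pattern
        self.count = 0
        directory = os.path.dirname(pattern.template) or "."
        if not os.path.isdir(directory):
            raise FormatError(f"output directory does not exist: {directory}")

    def __call__(self, image: Image) -> None:
        write_image(self.pattern.path(self.count), image)
        self.count += 1


def open_slice_source(pattern: StackPattern) -> SliceSource:
    """Open a forward-only slice sequence; all files must exist."""
    return SliceSource(pattern)


def open_slice_sink(pattern: StackPattern) -> SliceSink:
    """Open a slice consumer writing to the expanded pattern paths."""
    return SliceSink(pattern)
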