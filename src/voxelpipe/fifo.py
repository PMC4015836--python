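"""Out-of-core streaming: FIFO filters over slice stacks.

A stack of 2D slices is processed as one 3D volume without ever holding
more than a bounded number of slices in memory.  Each streaming filter
follows a three-stage protocol: slices are pushed until the buffer holds
enough z-neighborhood to emit, then every push emits exactly one output
slice (dropping the oldest buffered slice once the buffer is full), and
``finalize`` flushes the remaining tail slices using the same clipped
window border policy as the in-core filters.  Consequently a streamed
chain produces the same voxels as running the corresponding in-core 3D
chain on the assembled volume, while per-filter memory is
``span * w * h`` voxels regardless of stack length.

The declared spans are ``2w+1`` for the binomial Gaussian (which
prefilters each slice in-plane on ingestion) and the median, ``4w+1`` for
the mean-of-least-variance filter (an output voxel depends on candidate
window centers up to ``w`` slices away, each reaching another ``w``), and
1 for the ``byslice`` adapter that applies an arbitrary 2D chain to every
slice independently.
"""

from __future__ import annotations

from collections import deque
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import ndimage

from .core import Image
from .errors import FifoProtocolError, ParameterError
from .pipeline import (
    FilterDescriptor,
    ParamDecl,
    PipelineContext,
    Registry,
    parse_chain,
    parse_descriptor,
    run_chain,
)
from . import filters as _filters

__all__ = [
    "FifoFilter",
    "GaussFifo",
    "MedianFifo",
    "MlvFifo",
    "BySliceFifo",
    "FIFO_FILTERS",
    "make_fifo",
    "make_fifo_chain",
    "run_stack",
    "chain_peak_retained",
]


class FifoFilter:
    """Base streaming filter: bounded slice buffer, push/finalize protocol.

    ``span`` is the maximum number of slices simultaneously retained and
    ``z_half`` the emission lag: output slice ``j`` is emitted once input
    slice ``j + z_half`` has been pushed.  Both depend only on the filter
    parameters, never on the stack length.
    """

    def __init__(self, span: int, z_half: int):
        self.span = int(span)
        self.z_half = int(z_half)
        self._buffer: deque[Image] = deque()
        self._first_index = 0  # global index of _buffer[0]
        self.pushed = 0
        self.emitted = 0
        self.peak_retained = 0
        self.downstream: Callable[[Image], None] = lambda img: None
        self._next: "FifoFilter | None" = None
        self._finalized = False
        self._extents: tuple[int, ...] | None = None

    # -- subclass hooks -----------------------------------------------------
    def _prepare(self, slice_img: Image) -> Image:
        """Transform a slice on ingestion (e.g. in-plane prefiltering)."""
        return slice_img

    def _compute(self, j: int) -> Image:
        """Compute output slice ``j`` from the buffered slices."""
        raise NotImplementedError

    # -- protocol -----------------------------------------------------------
    def push(self, slice_img: Image) -> None:
        if self._finalized:
            raise FifoProtocolError("push after finalize")
        if slice_img.rank != 2:
            raise FifoProtocolError(
                f"streaming filters take 2D slices, got rank {slice_img.rank}")
        if self._extents is None:
            self._extents = slice_img.extents
        elif slice_img.extents != self._extents:
            raise FifoProtocolError(
                f"slice extents {slice_img.extents} differ from first slice "
                f"{self._extents}")
        if len(self._buffer) == self.span:
            self._buffer.popleft()
            self._first_index += 1
        self._buffer.append(self._prepare(slice_img))
        self.peak_retained = max(self.peak_retained, len(self._buffer))
        self.pushed += 1
        j = self.pushed - 1 - self.z_half
        if j >= 0:
            self._emit(self._compute(j))

    def finalize(self) -> None:
        if self._finalized:
            raise FifoProtocolError("double finalize")
        if self.pushed == 0:
            raise FifoProtocolError("finalize before any push")
        for j in range(self.emitted, self.pushed):
            self._emit(self._compute(j))
        self._finalized = True
        if self._next is not None:
            self._next.finalize()

    def _emit(self, out: Image) -> None:
        self.emitted += 1
        self.downstream(out)

    # -- helpers ------------------------------------------------------------
    def _window(self, j: int, reach: int) -> tuple[np.ndarray, int]:
        """Stack the buffered slices covering ``[j-reach, j+reach]`` (clipped).

        Returns the stacked array and the local index of slice ``j``.
        """
        lo = max(j - reach, self._first_index)
        hi = min(j + reach, self._first_index + len(self._buffer) - 1)
        arrs = [self._buffer[k - self._first_index].data for k in range(lo, hi + 1)]
        return np.stack(arrs), j - lo

    def _volume_meta(self) -> tuple[tuple[float, ...], dict]:
        ref = self._buffer[0]
        return ref.spacing, ref.attributes


class MedianFifo(FifoFilter):
    """Streaming 3D median: buffers ``2w+1`` raw slices."""

    def __init__(self, w: int):
        if w < 0:
            raise ParameterError(f"median width must be >= 0, got {w}")
        self.w = w
        super().__init__(span=2 * w + 1, z_half=w)

    def _compute(self, j: int) -> Image:
        vol, local = self._window(j, self.w)
        ref = self._buffer[0]
        img = Image(vol, spacing=ref.spacing + (1.0,),
                    attributes=ref.attributes, copy=False)
        out = _filters.neighborhood_filter(img, "median", self.w)
        return Image(out.data[local], spacing=ref.spacing,
                     attributes=ref.attributes)


class MlvFifo(FifoFilter):
    """Streaming mean-of-least-variance: buffers ``4w+1`` raw slices."""

    def __init__(self, w: int):
        if w < 1:
            raise ParameterError(f"mlv width must be >= 1, got {w}")
        self.w = w
        super().__init__(span=4 * w + 1, z_half=2 * w)

    def _compute(self, j: int) -> Image:
        vol, local = self._window(j, 2 * self.w)
        ref = self._buffer[0]
        img = Image(vol, spacing=ref.spacing + (1.0,),
                    attributes=ref.attributes, copy=False)
        out = _filters.mlv(img, self.w)
        return Image(out.data[local], spacing=ref.spacing,
                     attributes=ref.attributes)


class GaussFifo(FifoFilter):
    """Streaming separable binomial smoother.

    Each slice is filtered in-plane on ingestion, so the buffer holds
    slices that are already filtered in two dimensions; emission runs the
    z pass (truncated and renormalized at stack ends) over the buffer.
    """

    def __init__(self, w: int):
        if w < 0:
            raise ParameterError(f"gauss width must be >= 0, got {w}")
        self.w = w
        self.kernel = _filters.binomial_kernel(w)
        super().__init__(span=2 * w + 1, z_half=w)

    def _prepare(self, slice_img: Image) -> Image:
        data = slice_img.data.astype(np.float64)
        for axis in (1, 0):  # x then y, matching the in-core axis order
            data = _filters._gauss_axis(data, self.kernel, axis)
        return slice_img.with_data(data)

    def _compute(self, j: int) -> Image:
        vol, local = self._window(j, self.w)
        num = ndimage.correlate1d(vol, self.kernel, axis=0,
                                  mode="constant", cval=0.0)
        den = ndimage.correlate1d(np.ones(vol.shape), self.kernel, axis=0,
                                  mode="constant", cval=0.0)
        out = (num / den)[local].astype(np.float32)
        ref = self._buffer[0]
        return Image(out, spacing=ref.spacing, attributes=ref.attributes)


class BySliceFifo(FifoFilter):
    """Adapter running an arbitrary 2D filter chain on every slice (span 1)."""

    def __init__(self, chain_text: str, registry: Registry | None = None):
        super().__init__(span=1, z_half=0)
        registry = registry or _filters.FILTERS_2D
        self._specs = [chain_text] if chain_text.strip() else []
        self._registry = registry
        if self._specs:  # validate up front
            ctx = PipelineContext(rank=2)
            for desc in parse_chain(chain_text):
                registry.create(desc, ctx)

    def _compute(self, j: int) -> Image:
        slice_img = self._buffer[j - self._first_index]
        if not self._specs:
            return slice_img.copy()
        return run_chain(slice_img, self._specs, self._registry)


FIFO_FILTERS = Registry("fifof")


@FIFO_FILTERS.register("gauss",
                       params=[ParamDecl("w", "int", default=1, min=0,
                                         help="kernel half-width")],
                       help="streaming separable binomial smoothing (span 2w+1)")
def _gauss_fifo(context, w):
    return GaussFifo(w)


@FIFO_FILTERS.register("median",
                       params=[ParamDecl("w", "int", default=1, min=0,
                                         help="window half-width")],
                       help="streaming 3D median (span 2w+1)")
def _median_fifo(context, w):
    return MedianFifo(w)


@FIFO_FILTERS.register("mlv",
                       params=[ParamDecl("w", "int", default=1, min=1,
                                         help="window half-width")],
                       help="streaming mean-of-least-variance (span 4w+1)")
def _mlv_fifo(context, w):
    return MlvFifo(w)


@FIFO_FILTERS.register("byslice",
                       params=[ParamDecl("filter", "chain", default="",
                                         help="2D filter chain applied per slice")],
                       help="apply a 2D filter chain to each slice (span 1)")
def _byslice_fifo(context, filter):
    return BySliceFifo(filter)


def make_fifo(spec: "str | FilterDescriptor",
              registry: Registry | None = None) -> FifoFilter:
    """Create one streaming filter from a descriptor."""
    registry = registry or FIFO_FILTERS
    return registry.create(spec)


def make_fifo_chain(text: str, registry: Registry | None = None) -> list[FifoFilter]:
    """Create a list of streaming filters from a ``+``-joined chain."""
    return [make_fifo(d, registry) for d in parse_chain(text)]


def run_stack(chain: Sequence[FifoFilter], source: Iterable[Image],
              sink: Callable[[Image], None]) -> int:
    """Push every source slice through the chain, finalize, count deliveries.

    The source is consumed exactly once, in order; the sink receives
    exactly as many slices as the source yielded.  Returns that count.
    """
    delivered = 0

    def counting_sink(img: Image) -> None:
        nonlocal delivered
        delivered += 1
        sink(img)

    chain = list(chain)
    if not chain:
        any_slice = False
        for img in source:
            any_slice = True
            counting_sink(img)
        if not any_slice:
            raise FifoProtocolError("empty slice source")
        return delivered

    for a, b in zip(chain, chain[1:]):
        a.downstream = b.push
        a._next = b
    chain[-1].downstream = counting_sink
    chain[-1]._next = None

    it = iter(source)
    count = 0
    while True:
        try:
            img = next(it)
        except StopIteration:
            break
        except Exception as e:
            raise FifoProtocolError(
                f"source failed at slice {count}: {e}") from e
        chain[0].push(img)
        count += 1
    if count == 0:
        raise FifoProtocolError("empty slice source")
    chain[0].finalize()
    return delivered


def chain_peak_retained(chain: Sequence[FifoFilter]) -> int:
    """Instrumented peak of simultaneously retained slices across a chain."""
    return sum(f.peak_retained for f in chain)
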