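"""Fuzzy c-means with gain-field correction, region growing, brain extraction.

The segmentation workhorse is an adaptive fuzzy c-means (FCM) clustering
of voxel intensities that simultaneously estimates a smooth multiplicative
gain field (the MR B0 inhomogeneity).  The model minimizes

    J = sum_p sum_k u_k(p)^m * (I(p) - g(p) * v_k)^2

over memberships ``u`` (fuzziness exponent ``m``), class centroids ``v``
and the positive gain field ``g`` by alternating optimization:

* memberships follow the standard inverse-distance^(2/(m-1)) rule,
* centroids are the membership-weighted least-squares solution,
* the gain field is a membership-weighted ratio estimate (observed over
  predicted intensity), regularized by binomial smoothing and
  renormalized to mean 1 over the foreground.

Initialization is deterministic (equally spaced quantiles of the
foreground intensities), so runs are exactly reproducible.  Foreground is
``intensity > 0``; background voxels get hard nearest-centroid
memberships and are excluded from centroid and gain estimation.

On top of FCM the module provides seeded region growing with two stopping
rules (intensity threshold, or "downhill": growth only into voxels not
brighter than the voxel grown from) and the packaged T1 brain-extraction
pipeline: FCM -> white-matter class -> binarize -> erode -> label ->
largest component -> region growing on the gain-corrected image ->
morphological close/open -> masking.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .core import Image
from .errors import DegenerateInputError, ParameterError, StageError
from . import filters as _filters
from .filters import NeighborhoodShape

__all__ = [
    "FcmResult",
    "fuzzy_cmeans",
    "select_class",
    "region_grow",
    "BrainExtractResult",
    "brain_extract",
    "dice",
]


@dataclass
class FcmResult:
    """Result of a fuzzy c-means run.

    ``centroids`` are strictly ascending class means in corrected-intensity
    units; ``memberships`` are K images in [0, 1] summing to 1 per voxel;
    ``gain`` is the positive multiplicative field with mean 1 over the
    foreground; ``corrected`` is ``input / gain``.
    """

    centroids: np.ndarray
    memberships: list[Image]
    gain: Image
    corrected: Image
    iterations: int
    converged: bool
    objective: list[float] = field(default_factory=list)


def _smooth_gain(raw: np.ndarray, fg: np.ndarray, w: int) -> np.ndarray:
    """Foreground-weighted binomial smoothing of the raw gain estimate."""
    kernel = _filters.binomial_kernel(w)
    num = raw * fg
    den = fg.astype(np.float64)
    for axis in range(raw.ndim - 1, -1, -1):
        num = _filters._gauss_axis(num, kernel, axis)
        den = _filters._gauss_axis(den, kernel, axis)
    out = np.ones_like(raw)
    ok = den > 1e-8
    out[ok] = num[ok] / den[ok]
    return out


def fuzzy_cmeans(image: Image, K: int = 3, m: float = 2.0, gain: bool = True,
                 gain_smooth_w: int = 128, tol: float = 1e-4, max_iter: int = 50,
                 seed_quantiles: bool = True) -> FcmResult:
    """Adaptive fuzzy c-means clustering of voxel intensities.

    Parameters
    ----------
    K:
        Number of classes (>= 2).
    m:
        Fuzziness exponent (> 1); 2 is the classic choice.
    gain:
        Estimate the multiplicative gain field; with ``gain=False`` the
        field is identically 1 and the algorithm is plain FCM.
    gain_smooth_w:
        Half-width of the binomial kernel regularizing the gain field.
    tol:
        Convergence threshold on the maximum relative centroid change.
    seed_quantiles:
        Deterministic initialization at the (k + 1/2)/K quantiles of the
        foreground intensities (the only initialization provided; the flag
        exists so callers can assert the contract).
    """
    if K < 2:
        raise ParameterError(f"need at least 2 classes, got {K}")
    if m <= 1:
        raise ParameterError(f"fuzziness must be > 1, got {m}")
    I = image.data.astype(np.float64)
    fg = I > 0
    vals = I[fg]
    if np.unique(vals).size < K:
        raise DegenerateInputError(
            f"foreground has fewer than {K} distinct intensities")
    if not seed_quantiles:
        raise ParameterError("only deterministic quantile seeding is provided")

    q = (np.arange(K) + 0.5) / K
    v = np.quantile(vals, q)
    # guarantee strictly ascending start even on spiky histograms
    for k in range(1, K):
        if v[k] <= v[k - 1]:
            v[k] = v[k - 1] + max(1e-6, 1e-6 * abs(v[k - 1]))

    g = np.ones_like(I)
    expo = 1.0 / (m - 1.0)
    eps = 1e-12
    converged = False
    objective: list[float] = []
    u = np.empty((K,) + I.shape)

    it = 0
    for it in range(1, max_iter + 1):
        # membership update from current (g, v)
        d2 = np.stack([(I - g * vk) ** 2 for vk in v])
        d2 = np.maximum(d2, eps)
        inv = d2 ** (-expo)
        u = inv / inv.sum(axis=0)

        um = u ** m
        objective.append(float((um * d2)[:, fg].sum()))

        # centroid update: least squares of J in v_k over the foreground
        v_new = np.empty(K)
        for k in range(K):
            w_k = um[k][fg]
            num = float((w_k * g[fg] * I[fg]).sum())
            den = float((w_k * g[fg] ** 2).sum())
            v_new[k] = num / max(den, eps)
        order = np.argsort(v_new, kind="stable")
        v_new = v_new[order]
        u = u[order]
        um = um[order]

        if gain:
            pred = (um * v_new.reshape((K,) + (1,) * I.ndim)).sum(axis=0) \
                / np.maximum(um.sum(axis=0), eps)
            raw = np.ones_like(I)
            ok = fg & (pred > eps)
            raw[ok] = I[ok] / pred[ok]
            g = _smooth_gain(raw, fg, gain_smooth_w)
            g = np.maximum(g, 1e-3)
            g /= g[fg].mean()

        change = np.max(np.abs(v_new - v) / np.maximum(np.abs(v), eps))
        v = v_new
        if change < tol:
            converged = True
            break

    # final membership pass against the converged parameters
    d2 = np.stack([(I - g * vk) ** 2 for vk in v])
    d2 = np.maximum(d2, eps)
    inv = d2 ** (-expo)
    u = inv / inv.sum(axis=0)
    # background: hard nearest-centroid assignment on corrected intensity
    corrected_arr = I / g
    bg = ~fg
    if bg.any():
        nearest = np.argmin(
            np.abs(corrected_arr[bg][None, :] - v[:, None]), axis=0)
        for k in range(K):
            u[k][bg] = nearest == k

    memberships = [image.with_data(u[k].astype(np.float32)) for k in range(K)]
    gain_img = image.with_data(g.astype(np.float32))
    corrected = image.with_data(corrected_arr.astype(np.float32))
    return FcmResult(centroids=v, memberships=memberships, gain=gain_img,
                     corrected=corrected, iterations=it, converged=converged,
                     objective=objective)


def select_class(result: FcmResult, which) -> Image:
    """Pick one membership image by index, ``"brightest"`` or ``"darkest"``.

    Centroids are ascending, so index 0 is the darkest class and index
    K-1 the brightest.
    """
    K = len(result.memberships)
    if which == "brightest":
        idx = K - 1
    elif which == "darkest":
        idx = 0
    else:
        idx = int(which)
        if not 0 <= idx < K:
            raise ParameterError(f"class index {idx} out of range 0..{K - 1}")
    return result.memberships[idx].copy()


def region_grow(image: Image, seeds: Image, shape,
                thresh: float | None = None) -> Image:
    """Seeded region growing under shape connectivity.

    With ``thresh`` given, a candidate voxel is accepted iff its intensity
    is >= thresh (threshold stopping rule).  Without it, growth proceeds
    "downhill": a neighbor is accepted iff it is not brighter than the
    accepted voxel it is reached from.  The result always contains the
    seeds; the growth queue is FIFO in (z, y, x) scan order, so the
    outcome is deterministic.
    """
    if image.shape != seeds.shape:
        raise ParameterError(
            f"region_grow: extent mismatch {image.extents} vs {seeds.extents}")
    if not seeds.pixel_kind.is_bit:
        raise ParameterError("seeds must be a bit image")
    shape = _filters._as_shape(shape, image.rank)
    seed_arr = seeds.data
    if not seed_arr.any():
        return seeds.with_data(np.zeros(seed_arr.shape, dtype=bool))

    if thresh is not None:
        return _grow_threshold(image, seeds, shape, float(thresh))
    return _grow_downhill(image, seeds, shape)


def _grow_threshold(image: Image, seeds: Image, shape: NeighborhoodShape,
                    thresh: float) -> Image:
    allowed = image.data >= thresh
    labels = _filters.label(image.with_data(allowed), shape)
    structure = _filters._connectivity_structure(shape)
    from scipy import ndimage
    reach = ndimage.binary_dilation(seeds.data, structure=structure)
    touched = np.unique(labels.data[reach & allowed])
    touched = touched[touched > 0]
    grown = np.isin(labels.data, touched)
    return seeds.with_data(grown | seeds.data)


def _grow_downhill(image: Image, seeds: Image, shape: NeighborhoodShape) -> Image:
    data = image.data
    accepted = seeds.data.copy()
    offsets = shape.neighbor_offsets
    queue = deque(map(tuple, np.argwhere(seeds.data)))  # scan order
    dims = data.shape
    while queue:
        p = queue.popleft()
        vp = data[p]
        for off in offsets:
            q = tuple(pi + oi for pi, oi in zip(p, off))
            if any(qi < 0 or qi >= n for qi, n in zip(q, dims)):
                continue
            if accepted[q]:
                continue
            if data[q] <= vp:
                accepted[q] = True
                queue.append(q)
    return seeds.with_data(accepted)


class BrainExtractResult(NamedTuple):
    image: Image
    mask: Image
    trace: tuple[str, ...]


_BRAIN_STAGES = ("fuzzy_cmeans", "select_class", "binarize", "erode", "label",
                 "select_biggest", "region_grow", "close", "open", "mask_apply")


def brain_extract(image: Image, K: int = 3, wm_class="brightest",
                  pthresh: float = 0.5, erode_shape="6n", grow_shape="6n",
                  grow_thresh="auto", close_shape="6n", open_shape="6n",
                  gain_smooth_w: int = 128) -> BrainExtractResult:
    """T1 brain extraction: white-matter-seeded region growing after FCM.

    The stages run in fixed order: gain-corrected ``K``-class FCM, white
    matter class selection, binarization at ``pthresh``, erosion, component
    labeling, largest-component selection, region growing on the corrected
    image, morphological closing then opening, and masking of the
    corrected image.  ``grow_thresh="auto"`` places the growth threshold
    midway between the two brightest centroids; ``grow_thresh=None``
    selects the downhill stopping rule; a number is used as-is.

    Returns the masked corrected image, the brain mask, and the ordered
    stage trace.
    """
    if image.rank != 3:
        raise ParameterError("brain extraction expects a 3D image")
    trace: list[str] = []

    def stage(name, fn):
        trace.append(name)
        try:
            return fn()
        except Exception as e:
            raise StageError(name, e) from e

    fcm = stage("fuzzy_cmeans",
                lambda: fuzzy_cmeans(image, K=K, gain=True,
                                     gain_smooth_w=gain_smooth_w))
    prob = stage("select_class", lambda: select_class(fcm, wm_class))
    wm = stage("binarize",
               lambda: _filters.binarize(prob, pthresh, float("inf")))
    wm = stage("erode", lambda: _filters.morph(wm, "erode", erode_shape))
    labels = stage("label", lambda: _filters.label(wm, grow_shape))
    seeds = stage("select_biggest", lambda: _filters.select_biggest(labels))
    if grow_thresh == "auto":
        thresh = float(fcm.centroids[-2:].mean())
    else:
        thresh = grow_thresh
    grown = stage("region_grow",
                  lambda: region_grow(fcm.corrected, seeds, grow_shape, thresh))
    grown = stage("close", lambda: _filters.morph(grown, "close", close_shape))
    mask = stage("open", lambda: _filters.morph(grown, "open", open_shape))
    out = stage("mask_apply", lambda: _filters.mask_apply(fcm.corrected, mask))
    return BrainExtractResult(out, mask, tuple(trace))


# ---------------------------------------------------------------------------
# descriptor-level plug-ins

def _register_segmentation(reg) -> None:
    from .pipeline import ParamDecl

    @reg.register("fuzzycm",
                  params=[ParamDecl("k", "int", default=3, min=2,
                                    help="number of classes"),
                          ParamDecl("gain", "int", default=1,
                                    help="estimate the gain field (0/1)"),
                          ParamDecl("smooth", "int", default=128, min=0,
                                    help="gain smoothing half-width")],
                  help="fuzzy c-means; stores class0..K-1, gain and "
                       "corrected in the pool, passes on the corrected image")
    def _fuzzycm(context, k, gain, smooth):
        pool = context.pool

        def apply(img):
            res = fuzzy_cmeans(img, K=k, gain=bool(gain), gain_smooth_w=smooth)
            for i, mem in enumerate(res.memberships):
                pool.store(f"class{i}", mem)
            pool.store("gain", res.gain)
            pool.store("corrected", res.corrected)
            return res.corrected
        return apply

    @reg.register("regiongrow",
                  params=[ParamDecl("seed", "str", required=True,
                                    help="pool key of the seed mask"),
                          ParamDecl("thresh", "float", default=None,
                                    help="acceptance threshold (omit for "
                                         "the downhill rule)"),
                          ParamDecl("shape", "shape", default="",
                                    help="connectivity shape (default "
                                         "4n in 2D, 6n in 3D)")],
                  help="seeded region growing on the current image")
    def _regiongrow(context, seed, thresh, shape):
        pool = context.pool

        def apply(img):
            shp = shape or ("4n" if img.rank == 2 else "6n")
            seeds = _filters.binarize_mask(pool.get(seed))
            return region_grow(img, seeds, shp, thresh)
        return apply


_register_segmentation(_filters.FILTERS_2D)
_register_segmentation(_filters.FILTERS_3D)


def dice(a: Image, b: Image) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two bit masks."""
    x = a.data.astype(bool)
    y = b.data.astype(bool)
    denom = int(x.sum()) + int(y.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((x & y).sum()) / denom
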