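"""Brute-force reference implementations used to validate the filters.

Everything here is written as directly as possible (explicit loops over
window offsets, fixed-point iteration, all-pairs distance search) and is
deliberately independent of the package's vectorized code paths.
"""

from __future__ import annotations

import itertools

import numpy as np


def _clip_window(shape, center, reach):
    """Slices of the clipped hypercube window around ``center``."""
    return tuple(slice(max(c - reach, 0), min(c + reach + 1, n))
                 for c, n in zip(center, shape))


def morph_oracle(data: np.ndarray, offsets, op: str) -> np.ndarray:
    """Erode/dilate as explicit min/max loops over in-bounds offsets."""
    if op == "open":
        return morph_oracle(morph_oracle(data, offsets, "erode"), offsets, "dilate")
    if op == "close":
        return morph_oracle(morph_oracle(data, offsets, "dilate"), offsets, "erode")
    out = np.empty_like(data)
    pick = min if op == "erode" else max
    for idx in np.ndindex(data.shape):
        vals = []
        for off in offsets:
            q = tuple(i + o for i, o in zip(idx, off))
            if all(0 <= qi < n for qi, n in zip(q, data.shape)):
                vals.append(data[q])
        out[idx] = pick(vals)
    return out


def window_oracle(data: np.ndarray, w: int, mode: str) -> np.ndarray:
    """Median (lower) or mean over the clipped window, voxel by voxel."""
    if mode == "median":
        out = np.empty_like(data)
    else:
        out = np.empty(data.shape, dtype=np.float64)
    for idx in np.ndindex(data.shape):
        vals = np.sort(data[_clip_window(data.shape, idx, w)], axis=None)
        if mode == "median":
            out[idx] = vals[(len(vals) - 1) // 2]
        else:
            out[idx] = vals.astype(np.float64).mean()
    return out


def gauss_dense_oracle(data: np.ndarray, w: int) -> np.ndarray:
    """Dense convolution with the clipped, renormalized outer-product kernel.

    Separability means the per-voxel normalization factorizes per axis, so
    the truncated outer-product kernel is renormalized axis by axis.
    """
    from math import comb
    k1 = np.array([comb(2 * w, k) for k in range(2 * w + 1)], dtype=float) / 4.0 ** w
    out = np.zeros(data.shape, dtype=np.float64)
    for idx in np.ndindex(data.shape):
        acc = 0.0
        norms = []
        for axis, (c, n) in enumerate(zip(idx, data.shape)):
            taps = [k1[t + w] for t in range(-w, w + 1) if 0 <= c + t < n]
            norms.append(sum(taps))
        for off in itertools.product(range(-w, w + 1), repeat=data.ndim):
            q = tuple(c + o for c, o in zip(idx, off))
            if all(0 <= qi < n for qi, n in zip(q, data.shape)):
                weight = 1.0
                for o in off:
                    weight *= k1[o + w]
                acc += weight * data[q]
        out[idx] = acc / np.prod(norms)
    return out


def mlv_oracle(data: np.ndarray, w: int) -> np.ndarray:
    """Mean of the least-variance window among windows containing the voxel.

    Candidate centers are the in-volume voxels within Chebyshev distance w;
    variance is the population variance over the clipped window; ties go to
    the smallest center in scan order.
    """
    data = data.astype(np.float64)
    out = np.empty(data.shape)
    for idx in np.ndindex(data.shape):
        best = None
        for off in itertools.product(range(-w, w + 1), repeat=data.ndim):
            u = tuple(i + o for i, o in zip(idx, off))
            if not all(0 <= ui < n for ui, n in zip(u, data.shape)):
                continue
            vals = data[_clip_window(data.shape, u, w)].ravel()
            mean = vals.sum() / vals.size
            var = (vals * vals).sum() / vals.size - mean * mean
            key = (var, np.ravel_multi_index(u, data.shape))
            if best is None or key < best[0]:
                best = (key, mean)
        out[idx] = best[1]
    return out


def label_oracle(mask: np.ndarray, offsets) -> np.ndarray:
    """Connected components by explicit BFS flood fill, scan-order labels."""
    labels = np.zeros(mask.shape, dtype=np.int32)
    current = 0
    for start in np.ndindex(mask.shape):
        if not mask[start] or labels[start]:
            continue
        current += 1
        frontier = [start]
        labels[start] = current
        while frontier:
            p = frontier.pop()
            for off in offsets:
                q = tuple(pi + oi for pi, oi in zip(p, off))
                if not all(0 <= qi < n for qi, n in zip(q, mask.shape)):
                    continue
                if mask[q] and not labels[q]:
                    labels[q] = current
                    frontier.append(q)
    return labels


def region_grow_oracle(data: np.ndarray, seeds: np.ndarray, offsets,
                       thresh=None) -> np.ndarray:
    """Fixed-point flood fill for both stopping rules.

    Threshold rule: iterate acceptance of neighbors with value >= thresh
    until nothing changes.  Downhill rule: accept neighbors with value <=
    the accepted voxel they are reached from, again to the fixed point
    (the FIFO order of the implementation cannot change the fixed point
    because acceptance only ever adds voxels).
    """
    accepted = seeds.copy()
    changed = True
    while changed:
        changed = False
        for p in np.ndindex(data.shape):
            if not accepted[p]:
                continue
            for off in offsets:
                q = tuple(pi + oi for pi, oi in zip(p, off))
                if not all(0 <= qi < n for qi, n in zip(q, data.shape)):
                    continue
                if accepted[q]:
                    continue
                ok = data[q] >= thresh if thresh is not None else data[q] <= data[p]
                if ok:
                    accepted[q] = True
                    changed = True
    return accepted


def distance_oracle(mask: np.ndarray, spacing=None) -> np.ndarray:
    """All-pairs nearest-true-voxel Euclidean distance."""
    if spacing is None:
        spacing = (1.0,) * mask.ndim
    true_pts = np.argwhere(mask).astype(np.float64) * np.asarray(spacing)
    out = np.empty(mask.shape)
    for idx in np.ndindex(mask.shape):
        p = np.asarray(idx, dtype=np.float64) * np.asarray(spacing)
        out[idx] = np.sqrt(((true_pts - p) ** 2).sum(axis=1)).min()
    return out
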