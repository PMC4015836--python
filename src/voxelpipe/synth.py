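"""Deterministic synthetic volumes with ground truth.

The phantoms are nested concentric spheres (synthetic stand-ins for the
head and tooth volumes the processing chains are meant for): each
compartment has a constant mean intensity, the whole volume is multiplied
by a smooth cosine-product bias field of known relative amplitude, and
per-voxel Gaussian noise is added.  Every generator is a pure function of
its parameters and seed, so fixtures are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Image, PIXEL_KINDS
from .errors import ParameterError

__all__ = [
    "Phantom",
    "nested_shell_phantom",
    "head_phantom",
    "three_class_phantom",
    "tooth_phantom",
    "random_stack",
    "enamel_thickness_truth",
]


@dataclass
class Phantom:
    """A synthetic volume plus ground-truth compartment masks.

    ``truth_masks`` maps compartment name to a bit image; the masks are
    disjoint by construction.  ``params`` records the generating
    parameters (means, radii, noise sigma, bias amplitude, seed).
    """

    image: Image
    truth_masks: dict[str, Image]
    params: dict


def _bias_field(shape: tuple[int, ...], amplitude: float) -> np.ndarray:
    """Smooth multiplicative field ``1 + amplitude * mean_axis cos(pi x/(X-1))``.

    Each axis contributes one half period of a cosine; the mean over axes
    keeps the field's extrema exactly ``1 +/- amplitude`` (at the two
    corners where all cosines align) while the gradient stays first-order
    everywhere, so centered objects see a genuinely varying bias.
    """
    acc = np.zeros(shape)
    for axis, n in enumerate(shape):
        coord = np.cos(np.pi * np.arange(n) / max(n - 1, 1))
        view = [1] * len(shape)
        view[axis] = n
        acc = acc + coord.reshape(view)
    return 1.0 + amplitude * acc / len(shape)


def nested_shell_phantom(size: int, radii, means, noise_sigma: float = 0.0,
                         bias_amp: float = 0.0, seed: int = 0,
                         spacing: float = 1.0, names=None) -> Phantom:
    """Concentric-sphere phantom with per-compartment ground truth.

    ``radii`` must be strictly descending; compartment ``k`` is the shell
    between ``radii[k]`` (inclusive) and ``radii[k+1]`` (exclusive), the
    last compartment is the solid core, and everything outside ``radii[0]``
    is zero background.  Intensity = compartment mean x bias field +
    N(0, noise_sigma).
    """
    radii = [float(r) for r in radii]
    means = [float(v) for v in means]
    if len(radii) != len(means):
        raise ParameterError(
            f"{len(radii)} radii vs {len(means)} means")
    if any(b >= a for a, b in zip(radii, radii[1:])):
        raise ParameterError(f"radii must be strictly descending: {radii}")
    if names is None:
        names = [f"compartment{k}" for k in range(len(radii))]

    shape = (size,) * 3
    center = (size - 1) / 2.0
    zz, yy, xx = np.meshgrid(*(np.arange(size),) * 3, indexing="ij")
    r = np.sqrt((zz - center) ** 2 + (yy - center) ** 2 + (xx - center) ** 2)

    clean = np.zeros(shape)
    masks: dict[str, Image] = {}
    spacing3 = (spacing,) * 3
    for k, (outer, mean) in enumerate(zip(radii, means)):
        inner = radii[k + 1] if k + 1 < len(radii) else -1.0
        mask = (r <= outer) & (r > inner)
        clean[mask] = mean
        masks[names[k]] = Image(mask, spacing=spacing3)

    bias = _bias_field(shape, bias_amp)
    rng = np.random.default_rng(seed)
    # noise is applied to the object only: the zero background is the
    # foreground convention every consumer of these phantoms relies on
    obj = r <= radii[0]
    noisy = clean * bias + rng.normal(0.0, noise_sigma, shape) * obj
    image = Image(noisy.astype(np.float32), spacing=spacing3)
    return Phantom(image=image, truth_masks=masks,
                   params={"size": size, "radii": radii, "means": means,
                           "noise_sigma": noise_sigma, "bias_amp": bias_amp,
                           "seed": seed, "spacing": spacing})


def head_phantom(size: int = 64, noise_sigma: float = 5.0,
                 bias_amp: float = 0.2, seed: int = 0) -> Phantom:
    """Head-like phantom: bright brain core inside dark skull and mid scalp.

    Compartment means (scalp 120, skull 40, brain 200) give three
    well-separated foreground classes with the brain as the brightest, as
    white matter is in a T1 image.
    """
    radii = (0.45 * size, 0.38 * size, 0.30 * size)
    return nested_shell_phantom(size, radii, (120.0, 40.0, 200.0),
                                noise_sigma=noise_sigma, bias_amp=bias_amp,
                                seed=seed, names=["scalp", "skull", "brain"])


def three_class_phantom(size: int = 64, noise_sigma: float = 5.0,
                        bias_amp: float = 0.0, seed: int = 0) -> Phantom:
    """Three nested foreground compartments with means 50/125/200."""
    radii = (0.45 * size, 0.35 * size, 0.22 * size)
    return nested_shell_phantom(size, radii, (50.0, 125.0, 200.0),
                                noise_sigma=noise_sigma, bias_amp=bias_amp,
                                seed=seed, names=["outer", "middle", "core"])


def tooth_phantom(size: int = 64, noise_sigma: float = 5.0, seed: int = 0,
                  spacing: float = 0.028) -> Phantom:
    """Tooth-like phantom: bright enamel shell around a dentine core.

    The default spacing matches a high-resolution micro-CT voxel size of
    0.028 mm.  Radii scale with the volume so the enamel shell keeps a
    fixed relative thickness.
    """
    outer = 0.32 * size
    inner = 0.22 * size
    return nested_shell_phantom(size, (outer, inner), (200.0, 120.0),
                                noise_sigma=noise_sigma, seed=seed,
                                spacing=spacing, names=["enamel", "dentine"])


def random_stack(w: int, h: int, n: int, pixel_kind="u16",
                 seed: int = 0) -> list[Image]:
    """``n`` uniform-random 2D slices of the given pixel kind."""
    if w <= 0 or h <= 0 or n <= 0:
        raise ParameterError(f"stack dimensions must be positive: {w}x{h}x{n}")
    kind = PIXEL_KINDS[pixel_kind] if isinstance(pixel_kind, str) else pixel_kind
    rng = np.random.default_rng(seed)
    slices = []
    for _ in range(n):
        if kind.is_bit:
            data = rng.integers(0, 2, (h, w)).astype(bool)
        elif kind.is_float:
            data = rng.random((h, w)).astype(kind.dtype)
        else:
            data = rng.integers(kind.min, int(kind.max) + 1, (h, w),
                                dtype=np.int64 if kind.max < 2 ** 63 else np.uint64)
            data = data.astype(kind.dtype)
        slices.append(Image(data))
    return slices


def enamel_thickness_truth(phantom: Phantom) -> tuple[float, float]:
    """Analytic enamel shell thickness of a tooth phantom, (voxels, mm)."""
    masks = phantom.truth_masks
    if "enamel" not in masks or "dentine" not in masks:
        raise ParameterError(
            f"phantom lacks enamel/dentine compartments: {sorted(masks)}")
    radii = phantom.params["radii"]
    names = list(masks)
    outer = radii[names.index("enamel")]
    inner = radii[names.index("dentine")]
    voxels = outer - inner
    return voxels, voxels * phantom.params["spacing"]
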