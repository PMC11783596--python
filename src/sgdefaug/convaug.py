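"""Conventional on-the-fly augmentation baseline.

Random 3D patches, Rician/Gaussian noise, gamma contrast and intensity
shifts, and a global coarse-grid elastic deformation that — unlike the
structure-guided approach — ignores organ locations entirely.  Magnitude
defaults are mild, generic values (documented in the methods note as not
calibrated to any clinical dataset); every transform at its neutral
parameter is the identity, and all randomness flows from the caller's
seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    ImageGeometry,
    ScalarVolume,
    StructureSet,
    _require_same_grid,
)
from .dvf import DisplacementField, warp
from .core import labelmap_to_structures, structures_to_labelmap

__all__ = [
    "ConvAugConfig",
    "random_patch",
    "add_gaussian_noise",
    "add_rician_noise",
    "adjust_contrast_and_shift",
    "elastic_deform",
    "conv_augment",
]


@dataclass
class ConvAugConfig:
    patch_size: tuple[int, int, int] = (240, 240, 80)
    patches_per_image: int = 3
    gaussian_sigma_frac: float = 0.05  # fraction of the intensity range
    rician_sigma_frac: float = 0.05
    intensity_shift_range: tuple[float, float] = (-0.1, 0.1)
    gamma_range: tuple[float, float] = (0.7, 1.5)
    elastic_amplitude_mm: float = 10.0
    elastic_grid_spacing_mm: float = 50.0
    p_noise: float = 0.5
    p_contrast: float = 0.5
    p_elastic: float = 0.5

    def __post_init__(self) -> None:
        if self.patches_per_image < 1:
            raise ValueError("patches_per_image must be >= 1")
        if self.gaussian_sigma_frac < 0 or self.rician_sigma_frac < 0:
            raise ValueError("noise sigmas must be non-negative")
        if self.intensity_shift_range[0] > self.intensity_shift_range[1]:
            raise ValueError("intensity_shift_range must be ordered")
        if not (0 < self.gamma_range[0] <= self.gamma_range[1]):
            raise ValueError("gamma_range must be positive and ordered")
        if self.elastic_amplitude_mm < 0:
            raise ValueError("elastic amplitude must be non-negative")
        if self.elastic_grid_spacing_mm <= 0:
            raise ValueError("elastic grid spacing must be positive")


def random_patch(
    img: ScalarVolume,
    ss: StructureSet,
    cfg: ConvAugConfig,
    rng: np.random.Generator,
) -> list[tuple[ScalarVolume, StructureSet, tuple[int, int, int]]]:
    """Extract ``patches_per_image`` patches at uniform random valid corners.

    Image and label patches are cut at identical corners; patch origins are
    shifted so world coordinates are preserved.
    """
    _require_same_grid(img.geometry, ss.geometry, "image vs structures")
    size = np.array(img.geometry.size)
    patch = np.array(cfg.patch_size, dtype=int)
    if np.any(patch > size):
        raise ValueError(f"patch size {tuple(patch)} exceeds image size {tuple(size)}")
    out = []
    for _ in range(cfg.patches_per_image):
        corner = np.array([rng.integers(0, size[a] - patch[a] + 1) for a in range(3)])
        box = tuple(slice(int(corner[a]), int(corner[a] + patch[a])) for a in range(3))
        geom = img.geometry
        new_geom = ImageGeometry(
            size=tuple(int(p) for p in patch),
            spacing=geom.spacing,
            origin=tuple(geom.index_to_world(corner.astype(float))),
            direction=geom.direction,
        )
        out.append(
            (
                ScalarVolume(new_geom, img.values[box].copy()),
                StructureSet(new_geom, {n: m[box].copy() for n, m in ss.items()}),
                tuple(int(c) for c in corner),
            )
        )
    return out


def add_gaussian_noise(img: ScalarVolume, sigma: float, rng: np.random.Generator) -> ScalarVolume:
    """Additive i.i.d. N(0, sigma^2) noise; sigma=0 is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return img.copy()
    noisy = np.asarray(img.values, dtype=np.float64) + rng.normal(0.0, sigma, img.geometry.size)
    return ScalarVolume(img.geometry, noisy)


def add_rician_noise(img: ScalarVolume, sigma: float, rng: np.random.Generator) -> ScalarVolume:
    """Rician noise: sqrt((x + n1)^2 + n2^2) with n1, n2 ~ N(0, sigma^2).

    Output is non-negative; sigma=0 is the identity on non-negative images.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return ScalarVolume(img.geometry, np.abs(np.asarray(img.values, dtype=np.float64)))
    x = np.asarray(img.values, dtype=np.float64)
    n1 = rng.normal(0.0, sigma, img.geometry.size)
    n2 = rng.normal(0.0, sigma, img.geometry.size)
    return ScalarVolume(img.geometry, np.sqrt((x + n1) ** 2 + n2**2))


def adjust_contrast_and_shift(img: ScalarVolume, gamma: float, shift: float) -> ScalarVolume:
    """Gamma transform on the [0,1]-rescaled image (mapped back to the
    original range), then an additive shift.  Monotone for any gamma > 0."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    values = np.asarray(img.values, dtype=np.float64)
    vmin, vmax = values.min(), values.max()
    if vmax > vmin:
        unit = (values - vmin) / (vmax - vmin)
        values = vmin + (vmax - vmin) * unit**gamma
    return ScalarVolume(img.geometry, values + shift)


def _coarse_elastic_field(
    geom: ImageGeometry,
    amplitude_mm: float,
    grid_spacing_mm: float,
    rng: np.random.Generator,
) -> DisplacementField:
    """Coarse-grid N(0, amplitude^2) offsets linearly upsampled to a dense
    field (so the dense max norm never exceeds the max coarse offset)."""
    extent = np.array(geom.size) * np.asarray(geom.spacing)
    n_coarse = np.maximum(np.ceil(extent / grid_spacing_mm).astype(int) + 1, 2)
    coarse = rng.normal(0.0, amplitude_mm, size=(*n_coarse, 3))
    dense = np.empty(geom.size + (3,))
    # positions of dense voxels in coarse-grid units
    coords_1d = [
        np.arange(geom.size[a]) * (n_coarse[a] - 1) / max(geom.size[a] - 1, 1)
        for a in range(3)
    ]
    mesh = np.meshgrid(*coords_1d, indexing="ij")
    from scipy import ndimage

    for c in range(3):
        dense[..., c] = ndimage.map_coordinates(
            coarse[..., c], mesh, order=1, mode="nearest"
        )
    return DisplacementField(geom, dense)


def elastic_deform(
    img: ScalarVolume,
    ss: StructureSet,
    cfg: ConvAugConfig,
    rng: np.random.Generator,
) -> tuple[ScalarVolume, StructureSet]:
    """Global random elastic warp of image and structures (no anatomical
    constraints); amplitude 0 is the identity."""
    _require_same_grid(img.geometry, ss.geometry, "image vs structures")
    if cfg.elastic_amplitude_mm == 0:
        return img.copy(), ss.copy()
    fld = _coarse_elastic_field(
        img.geometry, cfg.elastic_amplitude_mm, cfg.elastic_grid_spacing_mm, rng
    )
    out_img = warp(img, fld)
    lv = warp(structures_to_labelmap(ss), fld)
    return out_img, labelmap_to_structures(lv, list(ss.names))


def conv_augment(
    img: ScalarVolume,
    ss: StructureSet,
    cfg: ConvAugConfig,
    rng: np.random.Generator,
) -> list[tuple[ScalarVolume, StructureSet]]:
    """Full baseline: patches, then per-patch noise, contrast/shift and
    elastic warp, each gated by its probability.  Fixed application order
    keeps a given seed fully reproducible."""
    rng_range = float(img.values.max() - img.values.min())
    out = []
    for patch_img, patch_ss, _ in random_patch(img, ss, cfg, rng):
        if rng.uniform() < cfg.p_noise:
            if rng.uniform() < 0.5:
                patch_img = add_gaussian_noise(
                    patch_img, cfg.gaussian_sigma_frac * rng_range, rng
                )
            else:
                patch_img = add_rician_noise(
                    patch_img, cfg.rician_sigma_frac * rng_range, rng
                )
        if rng.uniform() < cfg.p_contrast:
            gamma = rng.uniform(*cfg.gamma_range)
            shift = rng.uniform(*cfg.intensity_shift_range) * rng_range
            patch_img = adjust_contrast_and_shift(patch_img, gamma, shift)
        if rng.uniform() < cfg.p_elastic:
            patch_img, patch_ss = elastic_deform(patch_img, patch_ss, cfg, rng)
        out.append((patch_img, patch_ss))
    return out
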