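"""Image preparation chain: overlap resolution, foreground cropping,
Perona-Malik diffusion denoising, grid resizing, intensity normalization.

The chain is deterministic and order-fixed:

    resolve_overlaps -> crop_foreground -> anisotropic_diffusion
        -> resample_to_size -> normalize_intensity

Bias-field correction is deliberately not part of the chain; run an
external corrector (e.g. N4) on the input volume beforehand if needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import ball

from .core import (
    ImageGeometry,
    LabelVolume,
    ScalarVolume,
    StructureSet,
    _require_same_grid,
)

__all__ = [
    "PreprocessConfig",
    "resolve_overlaps",
    "detect_body_foreground",
    "crop_foreground",
    "anisotropic_diffusion",
    "resample_to_size",
    "normalize_intensity",
    "run_pipeline",
]

#: Explicit 3D scheme stability bound for the diffusion time step.
MAX_DIFFUSION_TIME_STEP = 0.0625


@dataclass
class PreprocessConfig:
    crop_margin_voxels: int = 5
    diffusion_iterations: int = 5
    diffusion_conductance: float = 3.0
    diffusion_time_step: float = 0.0625
    target_size: Optional[tuple[int, int, int]] = None
    normalize: bool = True
    closing_radius_voxels: int = 3
    percentile_clip: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.crop_margin_voxels < 0:
            raise ValueError("crop margin must be non-negative")
        if self.diffusion_iterations < 0:
            raise ValueError("diffusion iterations must be non-negative")
        if self.diffusion_conductance <= 0:
            raise ValueError("conductance must be positive")
        if not (0 < self.diffusion_time_step <= MAX_DIFFUSION_TIME_STEP):
            raise ValueError(
                f"time step must be in (0, {MAX_DIFFUSION_TIME_STEP}] for stability"
            )
        if self.target_size is not None and any(s <= 0 for s in self.target_size):
            raise ValueError("target_size must be positive")


def resolve_overlaps(ss: StructureSet) -> StructureSet:
    """Assign each overlap voxel to the closest structure (Euclidean mm).

    Distances are measured to each structure's *non-overlapping remainder*;
    ties break by structure order.  Idempotent; a structure entirely
    contained in overlaps has no remainder and is an error.
    """
    names = ss.names
    count = np.zeros(ss.geometry.size, dtype=np.uint16)
    for _, m in ss.items():
        count += m
    overlap = count > 1
    if not overlap.any():
        return ss.copy()

    remainders = {n: ss[n] & ~overlap for n in names}
    for n in names:
        if ss[n][overlap].any() and not remainders[n].any():
            raise ValueError(
                f"structure {n!r} is entirely contained in overlaps; "
                "cannot measure a distance to its remainder"
            )

    ov_idx = np.nonzero(overlap)
    best = np.full(ov_idx[0].size, np.inf)
    winner = np.full(ov_idx[0].size, -1)
    for k, n in enumerate(names):
        participates = ss[n][overlap]
        if not participates.any():
            continue
        dist = ndimage.distance_transform_edt(
            ~remainders[n], sampling=ss.geometry.spacing
        )
        d = np.where(participates, dist[ov_idx], np.inf)
        better = d < best  # strict: earlier structures win ties
        best[better] = d[better]
        winner[better] = k

    out = {}
    for k, n in enumerate(names):
        m = remainders[n].copy()
        chosen = winner == k
        m[ov_idx[0][chosen], ov_idx[1][chosen], ov_idx[2][chosen]] = True
        out[n] = m
    return StructureSet(ss.geometry, out)


def detect_body_foreground(img: ScalarVolume, closing_radius_voxels: int = 3) -> np.ndarray:
    """Otsu threshold, largest 6-connected component, morphological closing."""
    values = np.asarray(img.values, dtype=float)
    if values.max() == values.min():
        # constant image: all foreground if non-zero, empty if zero (air)
        return np.full(img.geometry.size, bool(values.flat[0] != 0))
    thresh = threshold_otsu(values)
    fg = values > thresh
    labeled, n = ndimage.label(fg, structure=ndimage.generate_binary_structure(3, 1))
    if n == 0:
        return fg
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=range(1, n + 1))
    fg = labeled == (1 + int(np.argmax(sizes)))
    if closing_radius_voxels > 0:
        fg = ndimage.binary_closing(fg, structure=ball(closing_radius_voxels))
    return fg


def crop_foreground(
    img: ScalarVolume, ss: StructureSet, cfg: PreprocessConfig | None = None
) -> tuple[ScalarVolume, StructureSet]:
    """Crop image and structures to the bounding box of body-foreground and
    structure voxels (plus margin, clipped to the FOV).

    The origin is shifted so world coordinates of retained voxels are
    unchanged; no labeled voxel is ever discarded.
    """
    cfg = cfg or PreprocessConfig()
    _require_same_grid(img.geometry, ss.geometry, "image vs structures")
    keep = detect_body_foreground(img, cfg.closing_radius_voxels)
    for _, m in ss.items():
        keep |= m
    if not keep.any():
        raise ValueError("empty foreground and empty structures: nothing to crop to")

    idx = np.nonzero(keep)
    size = np.array(img.geometry.size)
    lo = np.maximum(
        np.array([idx[a].min() for a in range(3)]) - cfg.crop_margin_voxels, 0
    )
    hi = np.minimum(
        np.array([idx[a].max() for a in range(3)]) + cfg.crop_margin_voxels, size - 1
    )
    box = tuple(slice(int(lo[a]), int(hi[a]) + 1) for a in range(3))

    geom = img.geometry
    new_origin = geom.index_to_world(lo.astype(float))
    new_geom = ImageGeometry(
        size=tuple(int(hi[a] - lo[a]) + 1 for a in range(3)),
        spacing=geom.spacing,
        origin=tuple(new_origin),
        direction=geom.direction,
    )
    out_img = ScalarVolume(new_geom, img.values[box].copy())
    out_ss = StructureSet(new_geom, {n: m[box].copy() for n, m in ss.items()})
    return out_img, out_ss


def anisotropic_diffusion(img: ScalarVolume, cfg: PreprocessConfig | None = None) -> ScalarVolume:
    """Perona-Malik gradient-modulated diffusion (explicit scheme).

    Conductance ``g = exp(-(|grad| / K)^2)`` on forward differences per
    axis; ``cfg.diffusion_iterations`` explicit steps of size
    ``cfg.diffusion_time_step``.  The output range never expands beyond the
    input min/max (discrete extremum principle).
    """
    cfg = cfg or PreprocessConfig()
    u = np.asarray(img.values, dtype=np.float64).copy()
    k = cfg.diffusion_conductance
    dt = cfg.diffusion_time_step
    for _ in range(cfg.diffusion_iterations):
        total = np.zeros_like(u)
        for axis in range(3):
            fwd = np.diff(u, axis=axis, append=np.take(u, [-1], axis=axis))
            g = np.exp(-((fwd / k) ** 2))
            flux = g * fwd
            bwd_flux = np.roll(flux, 1, axis=axis)
            # zero-flux boundary: no flow across the first face
            sl = [slice(None)] * 3
            sl[axis] = slice(0, 1)
            bwd_flux[tuple(sl)] = 0.0
            total += flux - bwd_flux
        u += dt * total
    return ScalarVolume(img.geometry, u.astype(img.values.dtype, copy=False))


def resample_to_size(v, target_size: tuple[int, int, int]):
    """Resample to a new grid size over the same physical extent.

    Spacing rescales as ``old_size / new_size``; scalar volumes use linear
    interpolation, label volumes nearest-neighbour.
    """
    target_size = tuple(int(s) for s in target_size)
    if any(s <= 0 for s in target_size):
        raise ValueError("target_size must be positive")
    geom = v.geometry
    if target_size == geom.size:
        return v.copy()
    old = np.array(geom.size, dtype=float)
    new = np.array(target_size, dtype=float)
    new_spacing = np.asarray(geom.spacing) * old / new
    # voxel-edge-aligned physical extent: centre i' maps to ((i'+.5)*s'/s)-.5
    coords_1d = [
        (np.arange(target_size[a]) + 0.5) * (new_spacing[a] / geom.spacing[a]) - 0.5
        for a in range(3)
    ]
    mesh = np.meshgrid(*coords_1d, indexing="ij")
    new_origin = geom.index_to_world(
        np.array([coords_1d[0][0], coords_1d[1][0], coords_1d[2][0]])
    )
    new_geom = ImageGeometry(
        size=target_size,
        spacing=tuple(new_spacing),
        origin=tuple(new_origin),
        direction=geom.direction,
    )
    if isinstance(v, LabelVolume):
        data = ndimage.map_coordinates(v.labels, mesh, order=0, mode="nearest")
        return LabelVolume(new_geom, data)
    data = ndimage.map_coordinates(
        np.asarray(v.values, dtype=np.float64), mesh, order=1, mode="nearest"
    )
    return ScalarVolume(new_geom, data.astype(v.values.dtype, copy=False))


def normalize_intensity(
    img: ScalarVolume, percentile_clip: Optional[tuple[float, float]] = None
) -> ScalarVolume:
    """Affine rescale to [-1, 1]; a constant image maps to all zeros.

    With ``percentile_clip=(p_lo, p_hi)`` values are clipped to those
    percentiles before rescaling (off by default).
    """
    values = np.asarray(img.values, dtype=np.float64)
    if percentile_clip is not None:
        lo, hi = np.percentile(values, percentile_clip)
        values = np.clip(values, lo, hi)
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        return ScalarVolume(img.geometry, np.zeros_like(values))
    out = 2.0 * (values - vmin) / (vmax - vmin) - 1.0
    return ScalarVolume(img.geometry, out)


def run_pipeline(
    img: ScalarVolume, ss: StructureSet, cfg: PreprocessConfig | None = None
) -> tuple[ScalarVolume, StructureSet]:
    """Run the full preparation chain with one config."""
    cfg = cfg or PreprocessConfig()
    ss = resolve_overlaps(ss)
    img, ss = crop_foreground(img, ss, cfg)
    if cfg.diffusion_iterations > 0:
        img = anisotropic_diffusion(img, cfg)
    if cfg.target_size is not None:
        img = resample_to_size(img, cfg.target_size)
        from .core import labelmap_to_structures, structures_to_labelmap

        lv = resample_to_size(structures_to_labelmap(ss), cfg.target_size)
        ss = labelmap_to_structures(lv, list(ss.names))
    if cfg.normalize:
        img = normalize_intensity(img, cfg.percentile_clip)
    return img, ss
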