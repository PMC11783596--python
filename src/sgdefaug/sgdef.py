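"""Structure-guided deformable augmentation (sgDefAug).

One augmentation visits every organ of a structure set in random order.
The visited organ draws a random rigid displacement and a random per-axis
scaling about its centroid, both bounded in mm (defaults 40 mm, matching
bounds chosen to keep abdominal deformations anatomically plausible).  The
organ's affine motion is turned into a dense displacement field, smoothed
with a 5 mm Gaussian so contours stay regular, composed with the running
transform, and the next organ is drawn from the *already deformed* anatomy.
After the last organ, the original image and label map are resampled once
through the composed field, so each output voxel is interpolated a single
time.

Because each per-structure motion is affine, the pull-back (resampling)
field of a step is built analytically in the destination frame: its support
is the forward-mapped organ mask plus a smoothing collar, and the Gaussian
leaves affine values untouched deep inside that support, so the organ lands
exactly where the drawn transform says.  A volume-ratio plausibility guard
rejects and redraws transforms that would implausibly inflate or crush any
organ (an automated stand-in for visual inspection of augmented images).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage

from .core import (
    ImageGeometry,
    LabelVolume,
    ScalarVolume,
    StructureSet,
    labelmap_to_structures,
    structures_to_labelmap,
    _require_same_grid,
)
from .dvf import DisplacementField, compose_pullback, warp

__all__ = [
    "SgDefParams",
    "StructureTransform",
    "AugmentationRecord",
    "sample_structure_transform",
    "build_structure_dvf",
    "build_structure_pullback",
    "sgdef_augment",
    "expand_dataset",
    "iter_expand",
    "PlausibilityError",
]


class PlausibilityError(RuntimeError):
    """Raised when no plausible transform is found within the retry budget."""


@dataclass
class SgDefParams:
    """Tunable bounds of the augmentation.

    ``displacement_limit_mm`` and ``scale_limit_mm`` bound the uniform draws
    for organ translation and per-axis extent change (both default 40 mm);
    ``smoothing_sigma_mm`` is the Gaussian applied to each per-structure
    field (default 5 mm); ``expansion_factor`` is the dataset multiplier
    (default 10, e.g. 43 source images -> 430 total).
    """

    displacement_limit_mm: float = 40.0
    scale_limit_mm: float = 40.0
    smoothing_sigma_mm: float = 5.0
    expansion_factor: int = 10
    seed: int = 0
    isotropic_scaling: bool = False
    plausibility_volume_ratio_bounds: tuple[float, float] = (0.3, 3.0)
    max_structure_retries: int = 40
    #: "identity": a structure with no plausible draw keeps its shape (recorded);
    #: "error": raise PlausibilityError instead.
    on_retry_exhaustion: str = "identity"

    def __post_init__(self) -> None:
        if self.displacement_limit_mm < 0 or self.scale_limit_mm < 0:
            raise ValueError("limits must be non-negative")
        if self.smoothing_sigma_mm < 0:
            raise ValueError("smoothing sigma must be non-negative")
        if self.expansion_factor < 1:
            raise ValueError("expansion_factor must be >= 1")
        lo, hi = self.plausibility_volume_ratio_bounds
        if not (0 < lo < 1 < hi):
            raise ValueError("volume ratio bounds must satisfy 0 < lo < 1 < hi")
        if self.on_retry_exhaustion not in ("identity", "error"):
            raise ValueError("on_retry_exhaustion must be 'identity' or 'error'")


@dataclass
class StructureTransform:
    """One organ's drawn motion: translation (mm), per-axis scale factors,
    and the scaling centre (the organ centroid, world mm)."""

    structure: str
    translation: tuple[float, float, float]
    scale: tuple[float, float, float]
    centroid: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.translation = tuple(float(v) for v in self.translation)
        self.scale = tuple(float(v) for v in self.scale)
        self.centroid = tuple(float(v) for v in self.centroid)
        if len(self.translation) != 3 or len(self.scale) != 3 or len(self.centroid) != 3:
            raise ValueError("translation, scale and centroid must have 3 components")
        if any(s < 0.1 for s in self.scale):
            raise ValueError("scale factors below 0.1 are not allowed")

    @property
    def det(self) -> float:
        return float(np.prod(self.scale))


@dataclass
class AugmentationRecord:
    """Provenance of one augmentation: processing order and drawn transforms."""

    source_id: str
    steps: list[StructureTransform] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)
    fallback_identity: list[str] = field(default_factory=list)
    seed: int | None = None
    params: SgDefParams | None = None
    rejected_draws: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.params is not None:
            d["params"] = asdict(self.params)
        return d


def mask_extent_mm(mask: np.ndarray, geom: ImageGeometry) -> np.ndarray:
    """Axis-aligned extent of a mask in mm (index-aligned axes)."""
    idx = np.nonzero(mask)
    spacing = np.asarray(geom.spacing)
    return np.array(
        [(idx[a].max() - idx[a].min() + 1) * spacing[a] for a in range(3)]
    )


def mask_centroid_mm(mask: np.ndarray, geom: ImageGeometry) -> np.ndarray:
    """Centre of mass of a mask in world mm."""
    idx = np.nonzero(mask)
    centre_idx = np.array([idx[a].mean() for a in range(3)])
    return geom.index_to_world(centre_idx)


def sample_structure_transform(
    mask: np.ndarray,
    geom: ImageGeometry,
    params: SgDefParams,
    rng: np.random.Generator,
    structure: str = "",
) -> StructureTransform:
    """Draw a bounded random translation and scaling for one organ.

    Translation components are i.i.d. uniform on
    ``[-displacement_limit_mm, +displacement_limit_mm]``.  The per-axis
    extent change ``delta_a`` is uniform on
    ``[-min(scale_limit_mm, E_a/2), +scale_limit_mm]`` where ``E_a`` is the
    organ extent along axis ``a``, so the organ can at most halve and the
    mm bound stays meaningful across organ sizes; the scale factor is
    ``(E_a + delta_a) / E_a`` clamped at 0.1.  With ``isotropic_scaling``
    a single delta is drawn and converted via the smallest extent.
    """
    if not mask.any():
        raise ValueError("cannot sample a transform for an empty mask")
    limit = params.displacement_limit_mm
    translation = rng.uniform(-limit, limit, size=3) if limit > 0 else np.zeros(3)
    extents = mask_extent_mm(mask, geom)
    if params.isotropic_scaling:
        e_min = float(extents.min())
        delta = rng.uniform(-min(params.scale_limit_mm, e_min / 2), params.scale_limit_mm)
        s = max((e_min + delta) / e_min, 0.1)
        scale = np.array([s, s, s])
    else:
        scale = np.empty(3)
        for a in range(3):
            lo = -min(params.scale_limit_mm, extents[a] / 2)
            delta = rng.uniform(lo, params.scale_limit_mm)
            scale[a] = max((extents[a] + delta) / extents[a], 0.1)
    centroid = mask_centroid_mm(mask, geom)
    return StructureTransform(
        structure=structure,
        translation=tuple(translation),
        scale=tuple(scale),
        centroid=tuple(centroid),
    )


# ---------------------------------------------------------------------------
# field construction


def _smooth_field_in_box(
    field_arr: np.ndarray, box: tuple[slice, ...], sigma_vox: np.ndarray
) -> None:
    """Gaussian-smooth the 3 components in-place over a padded sub-box.

    ``box`` must contain the field's support; the smoothing window extends
    3 sigma beyond it, where the result decays to (numerically) zero.
    """
    size = field_arr.shape[:3]
    pad = np.ceil(3 * sigma_vox).astype(int) + 1
    lo = [max(0, box[a].start - pad[a]) for a in range(3)]
    hi = [min(size[a], box[a].stop + pad[a]) for a in range(3)]
    big = tuple(slice(lo[a], hi[a]) for a in range(3))
    for c in range(3):
        field_arr[big + (c,)] = ndimage.gaussian_filter(
            field_arr[big + (c,)], sigma=sigma_vox, mode="constant", cval=0.0,
            truncate=3.0,
        )


def _collar_voxels(sigma_mm: float, geom: ImageGeometry) -> np.ndarray:
    return np.ceil(3.5 * sigma_mm / np.asarray(geom.spacing)).astype(int)


def _index_offsets_arr(vectors: np.ndarray, geom: ImageGeometry) -> np.ndarray:
    """World-mm displacements (..., 3) -> continuous index-space offsets."""
    if geom._axis_aligned:
        return vectors / np.asarray(geom.spacing)
    return (vectors @ geom.direction_matrix) / np.asarray(geom.spacing)


def _dilate_box(mask: np.ndarray, radius: int) -> np.ndarray:
    """Chebyshev-ball dilation via a separable maximum filter."""
    if radius <= 0:
        return mask
    return ndimage.maximum_filter(
        mask.astype(np.uint8), size=2 * radius + 1, mode="constant", cval=0
    ).astype(bool)


def _bbox_of(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    idx = np.nonzero(mask)
    return (
        np.array([idx[a].min() for a in range(3)]),
        np.array([idx[a].max() for a in range(3)]),
    )


def build_structure_dvf(
    mask: np.ndarray,
    t: StructureTransform,
    sigma_mm: float,
    geom: ImageGeometry,
    smooth: bool = True,
) -> DisplacementField:
    """Forward displacement field of one organ's affine motion.

    ``u(x) = S (x - c) - (x - c) + translation`` on the organ (extended over
    a smoothing collar so the Gaussian cannot erode the motion at the organ
    boundary), zero beyond, then smoothed per component with ``sigma_mm``.
    ``smooth=False`` returns the pre-convolution field on the same support
    (the convolution with a normalized kernel never increases its max norm).
    """
    if not mask.any():
        raise ValueError("empty mask")
    if sigma_mm < 0:
        raise ValueError("sigma must be non-negative")
    scale = np.asarray(t.scale)
    centre = np.asarray(t.centroid)
    trans = np.asarray(t.translation)

    field_arr = np.zeros(geom.size + (3,))
    if np.allclose(scale, 1.0) and not trans.any():
        return DisplacementField(geom, field_arr)

    collar = _collar_voxels(sigma_mm, geom)
    support = _dilate_box(mask, int(collar.max()))
    idx = np.nonzero(support)
    world = geom.index_to_world(np.stack(idx, axis=-1))
    u = (world - centre) * (scale - 1.0) + trans
    field_arr[idx[0], idx[1], idx[2]] = u

    if smooth and sigma_mm > 0:
        lo, hi = _bbox_of(support)
        box = tuple(slice(int(lo[a]), int(hi[a]) + 1) for a in range(3))
        _smooth_field_in_box(field_arr, box, sigma_mm / np.asarray(geom.spacing))
    return DisplacementField(geom, field_arr)


def build_structure_pullback(
    mask: np.ndarray,
    t: StructureTransform,
    sigma_mm: float,
    geom: ImageGeometry,
) -> DisplacementField:
    """Pull-back (resampling) field realizing one organ's affine motion.

    Built directly in the destination frame: support is the forward-mapped
    organ mask plus a smoothing collar, carrying the exact affine pull-back
    ``d(y) = S^-1 (y - c - t) + c - y``; smoothing then leaves the values on
    the organ untouched (a Gaussian preserves affine functions) while
    tapering the field to zero outside the collar.  This realizes arbitrary
    in-FOV shifts exactly, which a numerically inverted source-side field
    cannot (its support never reaches a far destination).
    """
    if not mask.any():
        raise ValueError("empty mask")
    if sigma_mm < 0:
        raise ValueError("sigma must be non-negative")
    scale = np.asarray(t.scale)
    centre = np.asarray(t.centroid)
    trans = np.asarray(t.translation)

    field_arr = np.zeros(geom.size + (3,))
    if np.allclose(scale, 1.0) and not trans.any():
        return DisplacementField(geom, field_arr)

    inv_scale = 1.0 / scale
    size = np.array(geom.size)
    collar = _collar_voxels(sigma_mm, geom)
    sigma_vox = sigma_mm / np.asarray(geom.spacing)
    smooth_pad = np.ceil(3 * sigma_vox).astype(int) + 1

    def affine_pullback(box: tuple[slice, ...]) -> np.ndarray:
        bshape = tuple(s.stop - s.start for s in box)
        bidx = np.indices(bshape, dtype=np.float64)
        bidx += np.array([s.start for s in box]).reshape(3, 1, 1, 1)
        world = geom.index_to_world(np.moveaxis(bidx, 0, -1))
        return (world - centre - trans) * inv_scale + centre - world

    # destination lobe: forward-map the source bbox, then keep voxels whose
    # preimage lies in the source mask
    lo_src, hi_src = _bbox_of(mask)
    corners_idx = np.array(
        [
            [a, b, c]
            for a in (lo_src[0], hi_src[0])
            for b in (lo_src[1], hi_src[1])
            for c in (lo_src[2], hi_src[2])
        ],
        dtype=float,
    )
    fwd_corners = centre + (geom.index_to_world(corners_idx) - centre) * scale + trans
    fwd_idx = geom.world_to_index(fwd_corners)
    lo_d = np.maximum(np.floor(fwd_idx.min(axis=0)).astype(int) - 1, 0)
    hi_d = np.minimum(np.ceil(fwd_idx.max(axis=0)).astype(int) + 1, size - 1)

    support = np.zeros(geom.size, dtype=bool)
    if np.all(lo_d <= hi_d):  # destination overlaps the FOV
        box_d = tuple(slice(int(lo_d[a]), int(hi_d[a]) + 1) for a in range(3))
        d_aff = affine_pullback(box_d)
        bidx = np.indices(tuple(s.stop - s.start for s in box_d), dtype=np.float64)
        bidx += lo_d.reshape(3, 1, 1, 1)
        pre_idx = np.moveaxis(bidx, 0, -1) + _index_offsets_arr(d_aff, geom)
        pi = np.round(pre_idx[..., 0]).astype(int)
        pj = np.round(pre_idx[..., 1]).astype(int)
        pk = np.round(pre_idx[..., 2]).astype(int)
        inside = (
            (pi >= 0) & (pi < size[0])
            & (pj >= 0) & (pj < size[1])
            & (pk >= 0) & (pk < size[2])
        )
        dst = np.zeros(inside.shape, dtype=bool)
        dst[inside] = mask[pi[inside], pj[inside], pk[inside]]
        support[box_d] = dst
    # source region: there the affine pull-back samples the tissue behind
    # the organ, evacuating its original position (no ghost left behind)
    support |= mask
    support = _dilate_box(support, int(collar.max()))

    # smoothing is linear and support components are disjoint, so each
    # component is evaluated and smoothed over its own padded bbox and
    # summed — exact, and far cheaper than one box spanning the distant
    # source/destination lobes of a large translation
    labeled, ncomp = ndimage.label(support, structure=np.ones((3, 3, 3), dtype=bool))
    for c, comp_slice in enumerate(ndimage.find_objects(labeled), start=1):
        clo = [max(0, comp_slice[a].start - smooth_pad[a]) for a in range(3)]
        chi = [min(geom.size[a], comp_slice[a].stop + smooth_pad[a]) for a in range(3)]
        sub = tuple(slice(clo[a], chi[a]) for a in range(3))
        comp_field = np.where(
            (labeled[sub] == c)[..., None], affine_pullback(sub), 0.0
        )
        if sigma_mm > 0:
            for ch in range(3):
                comp_field[..., ch] = ndimage.gaussian_filter(
                    comp_field[..., ch], sigma=sigma_vox, mode="constant",
                    cval=0.0, truncate=3.0,
                )
        field_arr[sub] += comp_field
    return DisplacementField(geom, field_arr)


# ---------------------------------------------------------------------------
# sequential augmentation


def _touches_fov_boundary(mask: np.ndarray) -> bool:
    return bool(
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    )


def _forward_maps_outside(
    mask: np.ndarray, t: StructureTransform, geom: ImageGeometry
) -> bool:
    """True when the forward-mapped organ bbox pokes beyond the FOV."""
    lo, hi = _bbox_of(mask)
    corners = np.array(
        [
            [a, b, c]
            for a in (lo[0], hi[0])
            for b in (lo[1], hi[1])
            for c in (lo[2], hi[2])
        ],
        dtype=float,
    )
    world = geom.index_to_world(corners)
    fwd = np.asarray(t.centroid) + (world - np.asarray(t.centroid)) * np.asarray(
        t.scale
    ) + np.asarray(t.translation)
    idx = geom.world_to_index(fwd)
    size = np.array(geom.size)
    return bool(np.any(idx < 0) or np.any(idx > size - 1))


def sgdef_augment(
    img: ScalarVolume,
    ss: StructureSet,
    params: SgDefParams,
    rng: np.random.Generator,
    source_id: str = "image",
) -> tuple[ScalarVolume, StructureSet, AugmentationRecord]:
    """Apply one full structure-guided random deformation.

    Organs are visited in a uniformly random order; each visit draws a
    bounded transform from the *current* (already deformed) organ, composes
    its smoothed pull-back field into the running transform, and re-derives
    the current anatomy by warping the original label map through the
    running field (never chaining nearest-neighbour warps).  Transforms
    whose cumulative effect pushes any organ's volume ratio outside the
    plausibility bounds are rolled back and redrawn.  The output image and
    label map are each produced by a single final resampling; zero limits
    reproduce the input bit-exactly.
    """
    _require_same_grid(img.geometry, ss.geometry, "image vs structures")
    geom = img.geometry
    lv = structures_to_labelmap(ss)
    names = ss.names
    in_counts = np.bincount(lv.labels.ravel(), minlength=len(names) + 1)

    record = AugmentationRecord(source_id=source_id, params=params)
    nonempty = [n for n in names if in_counts[names.index(n) + 1] > 0]
    record.skipped = [n for n in names if n not in nonempty]

    order = [nonempty[i] for i in rng.permutation(len(nonempty))]
    lo, hi = params.plausibility_volume_ratio_bounds

    running: DisplacementField | None = None
    current_labels = lv.labels

    # a step is rejected only for violations it introduces or worsens;
    # violations inherited from an accepted earlier step (e.g. an organ
    # legitimately clipped at the FOV edge) never block later structures,
    # otherwise the sequence can deadlock on a state no draw can repair
    drift_tol = 0.02

    for name in order:
        label = names.index(name) + 1
        accepted = False
        prev_counts = np.bincount(current_labels.ravel(), minlength=len(names) + 1)
        for _ in range(params.max_structure_retries):
            mask = current_labels == label
            if not mask.any():
                # pushed out of the FOV by an earlier (guard-approved) step
                record.skipped.append(name)
                accepted = True
                break
            t = sample_structure_transform(mask, geom, params, rng, structure=name)
            # cheap pre-guard: predicted volume ratio from det(S), 20% margin
            predicted = t.det * mask.sum() / in_counts[label]
            if predicted < lo * 0.8 or predicted > hi * 1.2:
                record.rejected_draws += 1
                continue
            step = build_structure_pullback(mask, t, params.smoothing_sigma_mm, geom)
            candidate = (
                step if running is None else compose_pullback(running, step)
            )
            new_labels = (
                lv.labels if candidate.is_zero() else warp(lv, candidate).labels
            )
            counts = np.bincount(new_labels.ravel(), minlength=len(names) + 1)
            ok = True
            for j, other in enumerate(names, start=1):
                if in_counts[j] == 0:
                    continue
                ratio = counts[j] / in_counts[j]
                prev_ratio = prev_counts[j] / in_counts[j]
                if counts[j] == 0:
                    # empty is acceptable only when the organ left the FOV
                    # (or already was empty entering this step)
                    if prev_counts[j] == 0:
                        continue
                    if not (other == name and _forward_maps_outside(mask, t, geom)):
                        ok = False
                        break
                elif ratio > hi and ratio > prev_ratio + drift_tol:
                    ok = False
                    break
                elif ratio < lo and ratio < prev_ratio - drift_tol and not (
                    _touches_fov_boundary(new_labels == j)
                    or (other == name and _forward_maps_outside(mask, t, geom))
                ):
                    ok = False
                    break
            if not ok:
                record.rejected_draws += 1
                continue
            running = candidate
            current_labels = new_labels
            record.steps.append(t)
            accepted = True
            break
        if not accepted:
            if params.on_retry_exhaustion == "error":
                raise PlausibilityError(
                    f"no plausible transform for {name!r} within "
                    f"{params.max_structure_retries} draws"
                )
            # identity step: the structure is processed but keeps its shape
            # (rare; happens when earlier accepted steps leave neighbours
            # near the plausibility floor so that any further motion of this
            # structure would crush them)
            mask = current_labels == label
            record.steps.append(
                StructureTransform(
                    name, (0.0, 0.0, 0.0), (1.0, 1.0, 1.0),
                    tuple(mask_centroid_mm(mask, geom)),
                )
            )
            record.fallback_identity.append(name)

    if running is None or running.is_zero():
        out_img = img.copy()
        out_lv = lv.copy()
    else:
        out_img = warp(img, running)
        out_lv = warp(lv, running)
    out_ss = labelmap_to_structures(out_lv, names)
    return out_img, out_ss, record


# ---------------------------------------------------------------------------
# dataset expansion


def _item_rng(seed: int, item: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(item, replicate)))


def iter_expand(
    dataset: Sequence[tuple[ScalarVolume, StructureSet]],
    params: SgDefParams,
) -> Iterator[tuple[int, int, ScalarVolume, StructureSet, AugmentationRecord | None]]:
    """Lazily yield the expanded dataset.

    Yields ``(item_index, replicate_index, image, structures, record)``;
    replicate 0 is the untouched original (record ``None``), replicates
    1..expansion_factor-1 are sgDefAug variants with per-item deterministic
    RNG streams derived from ``(params.seed, item, replicate)``.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    for i, (img, ss) in enumerate(dataset):
        yield i, 0, img, ss, None
        for r in range(1, params.expansion_factor):
            rng = _item_rng(params.seed, i, r)
            out_img, out_ss, record = sgdef_augment(
                img, ss, params, rng, source_id=f"item{i:03d}"
            )
            record.seed = params.seed
            yield i, r, out_img, out_ss, record


def expand_dataset(
    dataset: Sequence[tuple[ScalarVolume, StructureSet]],
    params: SgDefParams,
) -> tuple[list[tuple[ScalarVolume, StructureSet]], list[AugmentationRecord | None]]:
    """Materialize the expansion: N inputs -> N * expansion_factor outputs."""
    out, records = [], []
    for _, _, img, ss, rec in iter_expand(dataset, params):
        out.append((img, ss))
        records.append(rec)
    return out, records
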