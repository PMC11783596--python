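"""Synthetic abdominal phantom: a body-shaped 3D image with the 8 labeled
organs at risk, MR-like intensity structure, and a synthetic dose grid.

The phantom is stylized, not anatomically faithful: its job is to carry the
statistical structure the pipeline assumes — disjoint labeled organs inside
a body, organ-dependent contrast, a smooth multiplicative bias field, and
Rician noise — so that every algorithm in the package is testable without
patient data.  Solid organs are jittered ellipsoids; duodenum and small
bowel are curved tubes; the spinal canal is a straight tube spanning the
field of view.  The world frame is LPS mm with the grid centred on the
origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import (
    CANONICAL_OARS,
    ImageGeometry,
    ScalarVolume,
    StructureSet,
)

__all__ = [
    "PhantomSpec",
    "DoseSpec",
    "generate_phantom",
    "generate_dose",
    "generate_cohort",
]


def _default_organ_shapes() -> dict:
    """Organ shape parameters in mm, local frame (x=left, y=posterior, z=sup)."""
    return {
        "duodenum": {
            "kind": "arc_tube",
            "center": (-2.0, 2.0, 6.0),
            "loop_radius": 16.0,
            "z_amplitude": 20.0,
            "tube_radius": 6.0,
        },
        "liver": {"kind": "ellipsoid", "center": (-42.0, -10.0, 28.0), "semi_axes": (34.0, 26.0, 26.0)},
        "left_kidney": {"kind": "ellipsoid", "center": (45.0, 35.0, -12.0), "semi_axes": (11.0, 11.0, 17.0)},
        "right_kidney": {"kind": "ellipsoid", "center": (-45.0, 35.0, -12.0), "semi_axes": (11.0, 11.0, 17.0)},
        "spleen": {"kind": "ellipsoid", "center": (60.0, 18.0, 18.0), "semi_axes": (13.0, 10.0, 13.0)},
        "stomach": {"kind": "ellipsoid", "center": (30.0, -20.0, 25.0), "semi_axes": (22.0, 14.0, 16.0)},
        "spinal_canal": {"kind": "z_tube", "center_xy": (0.0, 55.0), "tube_radius": 6.0},
        "small_bowel": {
            "kind": "sine_tube",
            "y_center": -8.0,
            "y_amplitude": 10.0,
            "x_amplitude": 28.0,
            "z_range": (-62.0, -18.0),
            "period_mm": 44.0,
            "tube_radius": 8.0,
        },
    }


def _default_intensities() -> dict[str, float]:
    # loose emulation of motion-averaged balanced-contrast MR appearance
    return {
        "duodenum": 70.0,
        "liver": 140.0,
        "left_kidney": 170.0,
        "right_kidney": 170.0,
        "spleen": 150.0,
        "stomach": 60.0,
        "spinal_canal": 190.0,
        "small_bowel": 80.0,
    }


@dataclass
class PhantomSpec:
    """Parameters of one synthetic phantom."""

    size: tuple[int, int, int] = (96, 96, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.5)
    body_semi_axes_mm: tuple[float, float] = (86.0, 76.0)
    organ_shapes: dict = field(default_factory=_default_organ_shapes)
    intensities: dict = field(default_factory=_default_intensities)
    background_intensity: float = 10.0
    body_intensity: float = 100.0
    center_jitter_mm: float = 3.0
    axis_jitter_frac: float = 0.05
    bias_field_amplitude: float = 0.2
    bias_sigma_mm: float = 40.0
    rician_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        missing = set(CANONICAL_OARS) - set(self.organ_shapes)
        if missing:
            raise ValueError(f"organ_shapes missing canonical organs: {sorted(missing)}")

    def geometry(self) -> ImageGeometry:
        size = np.asarray(self.size)
        spacing = np.asarray(self.spacing)
        origin = -(size - 1) * spacing / 2.0  # grid centred on the world origin
        return ImageGeometry(
            size=tuple(int(s) for s in size),
            spacing=tuple(float(s) for s in spacing),
            origin=tuple(float(o) for o in origin),
        )


@dataclass
class DoseSpec:
    """Synthetic dose grid: prescription inside a spherical target, Gaussian
    penumbra falloff outside (defaults: 40 Gy in 5 fractions)."""

    target_center: tuple[float, float, float] = (0.0, 0.0, 5.0)
    target_radius_mm: float = 15.0
    prescription_gy: float = 40.0
    fractions: int = 5
    penumbra_sigma_mm: float = 8.0

    def __post_init__(self) -> None:
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be positive")
        if self.penumbra_sigma_mm <= 0:
            raise ValueError("penumbra sigma must be positive")


def _world_grid(geom: ImageGeometry) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    idx = [np.arange(geom.size[a]) * geom.spacing[a] + geom.origin[a] for a in range(3)]
    return np.meshgrid(*idx, indexing="ij")


def _ellipsoid_mask(geom, center, semi_axes) -> np.ndarray:
    wx, wy, wz = _world_grid(geom)
    c, s = np.asarray(center), np.asarray(semi_axes)
    return (
        ((wx - c[0]) / s[0]) ** 2
        + ((wy - c[1]) / s[1]) ** 2
        + ((wz - c[2]) / s[2]) ** 2
    ) <= 1.0


def _tube_mask(geom: ImageGeometry, path_mm: np.ndarray, radius_mm: float) -> np.ndarray:
    """Voxels within ``radius_mm`` of a polyline (via a distance transform)."""
    seeds = np.zeros(geom.size, dtype=bool)
    idx = np.round(geom.world_to_index(path_mm)).astype(int)
    inside = np.all((idx >= 0) & (idx < np.array(geom.size)), axis=1)
    idx = idx[inside]
    if idx.size == 0:
        return seeds
    seeds[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    dist = ndimage.distance_transform_edt(~seeds, sampling=geom.spacing)
    return dist <= radius_mm


def _organ_mask(geom: ImageGeometry, shape: dict, rng: np.random.Generator,
                jitter_mm: float, axis_jitter: float) -> np.ndarray:
    kind = shape["kind"]
    jit = rng.uniform(-jitter_mm, jitter_mm, size=3)
    if kind == "ellipsoid":
        semi = np.asarray(shape["semi_axes"]) * (
            1.0 + rng.uniform(-axis_jitter, axis_jitter, size=3)
        )
        return _ellipsoid_mask(geom, np.asarray(shape["center"]) + jit, semi)
    if kind == "z_tube":
        cx, cy = np.asarray(shape["center_xy"]) + jit[:2]
        z = np.linspace(geom.origin[2], geom.origin[2] + (geom.size[2] - 1) * geom.spacing[2], 160)
        path = np.column_stack([np.full_like(z, cx), np.full_like(z, cy), z])
        return _tube_mask(geom, path, shape["tube_radius"])
    if kind == "arc_tube":
        c = np.asarray(shape["center"]) + jit
        theta = np.linspace(-1.4, 1.4, 120)
        path = np.column_stack(
            [
                c[0] + shape["loop_radius"] * np.cos(theta),
                np.full_like(theta, c[1]),
                c[2] + shape["z_amplitude"] * np.sin(theta),
            ]
        )
        return _tube_mask(geom, path, shape["tube_radius"])
    if kind == "sine_tube":
        z0, z1 = shape["z_range"]
        z = np.linspace(z0, z1, 150) + jit[2]
        phase = 2 * np.pi * (z - z[0]) / shape["period_mm"]
        path = np.column_stack(
            [
                jit[0] + shape["x_amplitude"] * np.sin(phase),
                shape["y_center"] + jit[1] + shape["y_amplitude"] * np.cos(phase),
                z,
            ]
        )
        return _tube_mask(geom, path, shape["tube_radius"])
    raise ValueError(f"unknown organ shape kind {kind!r}")


def _body_mask(geom: ImageGeometry, semi_axes_xy) -> np.ndarray:
    wx, wy, _ = _world_grid(geom)
    a, b = semi_axes_xy
    return (wx / a) ** 2 + (wy / b) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[ScalarVolume, StructureSet]:
    """Generate one phantom image and its 8-organ structure set.

    Deterministic given ``spec`` (including ``spec.seed``); structures are
    pairwise disjoint by construction and confined to the body.
    """
    geom = spec.geometry()
    rng = np.random.default_rng(spec.seed)
    body = _body_mask(geom, spec.body_semi_axes_mm)

    masks: dict[str, np.ndarray] = {}
    occupied = np.zeros(geom.size, dtype=bool)
    for name in CANONICAL_OARS:
        m = _organ_mask(
            geom, spec.organ_shapes[name], rng, spec.center_jitter_mm, spec.axis_jitter_frac
        )
        m &= body
        m &= ~occupied
        if not m.any():
            raise ValueError(
                f"organ {name!r} fell outside the body; adjust the phantom parameters"
            )
        occupied |= m
        masks[name] = m

    clean = np.full(geom.size, spec.background_intensity)
    clean[body] = spec.body_intensity
    for name in CANONICAL_OARS:
        clean[masks[name]] = spec.intensities[name]

    image = clean.astype(np.float64)
    if spec.bias_field_amplitude > 0:
        noise = rng.standard_normal(geom.size)
        sigma_vox = spec.bias_sigma_mm / np.asarray(geom.spacing)
        smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox)
        peak = np.abs(smooth).max()
        if peak > 0:
            image = image * (1.0 + spec.bias_field_amplitude * smooth / peak)
    if spec.rician_sigma > 0:
        n1 = rng.normal(0.0, spec.rician_sigma, geom.size)
        n2 = rng.normal(0.0, spec.rician_sigma, geom.size)
        image = np.sqrt((image + n1) ** 2 + n2**2)

    return (
        ScalarVolume(geom, image.astype(np.float32)),
        StructureSet(geom, masks),
    )


def generate_dose(geom: ImageGeometry, spec: DoseSpec) -> ScalarVolume:
    """Synthetic dose grid: flat prescription in the target sphere, Gaussian
    penumbra outside; maximal at the target centre, non-negative."""
    centre_idx = geom.world_to_index(np.asarray(spec.target_center))
    if np.any(centre_idx < 0) or np.any(centre_idx > np.array(geom.size) - 1):
        raise ValueError("dose target centre lies outside the field of view")
    wx, wy, wz = _world_grid(geom)
    c = np.asarray(spec.target_center)
    r = np.sqrt((wx - c[0]) ** 2 + (wy - c[1]) ** 2 + (wz - c[2]) ** 2)
    outside = np.clip(r - spec.target_radius_mm, 0.0, None)
    dose = spec.prescription_gy * np.exp(-(outside**2) / (2 * spec.penumbra_sigma_mm**2))
    return ScalarVolume(geom, dose.astype(np.float32))


def generate_cohort(
    n: int, spec: PhantomSpec | None = None, seed: int = 0
) -> list[tuple[ScalarVolume, StructureSet]]:
    """Generate ``n`` phantoms with independent per-item seeds derived from
    ``seed``; deterministic given ``(n, spec, seed)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if spec is None:
        spec = PhantomSpec()
    cohort = []
    for i in range(n):
        item_seed = int(np.random.SeedSequence(seed, spawn_key=(i,)).generate_state(1)[0])
        cohort.append(generate_phantom(replace(spec, seed=item_seed)))
    return cohort
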