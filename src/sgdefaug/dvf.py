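"""Dense displacement fields: warping, composition, inversion.

Convention: fields are *pull-back* maps unless a function says otherwise.
A pull-back field ``d`` resamples an image as ``out(x) = src(x + d(x))``
for world point ``x`` (vectors in mm, world frame).  Pull-back fields
compose as ``d(x) = d1(x + d2(x)) + d2(x)`` where ``d1`` is the field
applied first.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import _interp
from .core import ImageGeometry, LabelVolume, ScalarVolume, _require_same_grid


@dataclass
class DisplacementField:
    """Per-voxel 3-vector (mm, world frame) on a geometry."""

    geometry: ImageGeometry
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.ascontiguousarray(self.vectors, dtype=np.float64)
        if self.vectors.shape != self.geometry.size + (3,):
            raise ValueError(
                f"vector array shape {self.vectors.shape} != {self.geometry.size + (3,)}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field contains non-finite values")
        self._zero: bool | None = None

    @classmethod
    def zeros(cls, geometry: ImageGeometry) -> "DisplacementField":
        fld = cls(geometry, np.zeros(geometry.size + (3,)))
        fld._zero = True
        return fld

    def is_zero(self) -> bool:
        # cached: callers never mutate vectors after construction
        if self._zero is None:
            self._zero = not self.vectors.any()
        return self._zero

    def max_norm_mm(self) -> float:
        if self.vectors.size == 0:
            return 0.0
        return float(np.sqrt((self.vectors**2).sum(axis=-1)).max())


@lru_cache(maxsize=8)
def _index_grid(size: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ii, jj, kk = np.indices(size, dtype=np.float64)
    return (
        np.ascontiguousarray(ii.ravel()),
        np.ascontiguousarray(jj.ravel()),
        np.ascontiguousarray(kk.ravel()),
    )


def _index_offsets(vectors_flat: np.ndarray, geom: ImageGeometry) -> np.ndarray:
    """World-mm displacement vectors -> continuous index-space offsets."""
    # index offset = diag(1/spacing) @ D^T @ d  (rowwise: d @ D / spacing)
    return (vectors_flat @ geom.direction_matrix) / np.asarray(geom.spacing)


def _axis_aligned(geom: ImageGeometry) -> bool:
    return geom.direction == (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)


def _inv_spacing(geom: ImageGeometry) -> tuple[float, float, float]:
    return (1.0 / geom.spacing[0], 1.0 / geom.spacing[1], 1.0 / geom.spacing[2])


def warp(v, d: DisplacementField):
    """Resample a volume through a pull-back field.

    Scalar volumes use trilinear interpolation with the input minimum as the
    out-of-FOV fill; label volumes use nearest-neighbour with background
    fill.  A zero field short-circuits to a bit-exact copy.
    """
    _require_same_grid(v.geometry, d.geometry, "volume vs displacement field")
    if d.is_zero():
        return v.copy()
    geom = v.geometry
    if _axis_aligned(geom):
        inv0, inv1, inv2 = _inv_spacing(geom)
        if isinstance(v, LabelVolume):
            src = np.ascontiguousarray(v.labels)
            out = np.empty_like(src)
            _interp.warp_label_field(src, d.vectors, inv0, inv1, inv2, out)
            return LabelVolume(geom, out)
        src = np.ascontiguousarray(v.values, dtype=np.float64)
        out = np.empty_like(src)
        _interp.warp_scalar_field(src, d.vectors, inv0, inv1, inv2, float(src.min()), out)
        return ScalarVolume(geom, out.astype(v.values.dtype, copy=False))
    bi, bj, bk = _index_grid(geom.size)
    off = _index_offsets(d.vectors.reshape(-1, 3), geom)
    ci = bi + off[:, 0]
    cj = bj + off[:, 1]
    ck = bk + off[:, 2]
    if isinstance(v, LabelVolume):
        src = np.ascontiguousarray(v.labels)
        out = np.empty(src.size, dtype=src.dtype)
        _interp.nearest(src, ci, cj, ck, src.dtype.type(0), out)
        return LabelVolume(geom, out.reshape(geom.size))
    src = np.ascontiguousarray(v.values, dtype=np.float64)
    out = np.empty(src.size, dtype=np.float64)
    _interp.trilinear(src, ci, cj, ck, float(src.min()), out)
    return ScalarVolume(geom, out.reshape(geom.size).astype(v.values.dtype, copy=False))


def compose_pullback(first: DisplacementField, second: DisplacementField) -> DisplacementField:
    """Compose two pull-back fields: warping with the result equals warping
    with ``first`` then ``second``."""
    _require_same_grid(first.geometry, second.geometry, "field composition")
    if second.is_zero():
        return DisplacementField(first.geometry, first.vectors.copy())
    if first.is_zero():
        return DisplacementField(first.geometry, second.vectors.copy())
    geom = first.geometry
    if _axis_aligned(geom):
        inv0, inv1, inv2 = _inv_spacing(geom)
        out = np.empty_like(first.vectors)
        _interp.compose_fields(first.vectors, second.vectors, inv0, inv1, inv2, out)
        return DisplacementField(geom, out)
    out = first.vectors.copy()
    support = np.flatnonzero(second.vectors.reshape(-1, 3).any(axis=1))
    bi, bj, bk = _index_grid(geom.size)
    d2 = second.vectors.reshape(-1, 3)[support]
    off = _index_offsets(d2, geom)
    ci = np.ascontiguousarray(bi[support] + off[:, 0])
    cj = np.ascontiguousarray(bj[support] + off[:, 1])
    ck = np.ascontiguousarray(bk[support] + off[:, 2])
    d1i = np.empty((support.size, 3))
    _interp.sample_vec3(first.vectors, ci, cj, ck, d1i)
    out.reshape(-1, 3)[support] = d1i + d2
    return DisplacementField(geom, out)


@dataclass
class InversionResult:
    field: DisplacementField
    converged: bool
    residual_mm: float
    iterations: int


def _field_gradient_bound(u: np.ndarray, geom: ImageGeometry) -> float:
    """Max |d u_c / d x_a| over components/axes, in mm per mm."""
    bound = 0.0
    for c in range(3):
        grads = np.gradient(u[..., c], *geom.spacing)
        for g in grads:
            m = float(np.abs(g).max())
            bound = max(bound, m)
    return bound


def invert_field(
    fwd: DisplacementField, iterations: int = 30, tol_mm: float = 0.1
) -> InversionResult:
    """Numerically invert a forward field by damped fixed-point iteration.

    Solves ``u(x + d(x)) + d(x) = 0`` for the pull-back field ``d`` given
    the forward field ``u``, iterating ``d <- d + a (-u(x+d) - d)`` with a
    damping factor ``a`` derived from the field's gradient bound.  The
    residual is measured in mm where ``x + d`` stays inside the grid; a
    residual above ``tol_mm`` after ``iterations`` steps is flagged as
    non-convergence (the caller decides whether to reject the transform).
    """
    geom = fwd.geometry
    u = fwd.vectors
    if not u.any():
        return InversionResult(DisplacementField.zeros(geom), True, 0.0, 0)

    spacing = np.asarray(geom.spacing)
    nz = np.any(u != 0, axis=-1)
    idx = np.nonzero(nz)
    pad = np.ceil(np.abs(u).max() / spacing).astype(int) + 1
    lo = [max(0, int(idx[a].min()) - pad[a]) for a in range(3)]
    hi = [min(geom.size[a], int(idx[a].max()) + pad[a] + 1) for a in range(3)]
    box = tuple(slice(lo[a], hi[a]) for a in range(3))
    bshape = tuple(hi[a] - lo[a] for a in range(3))

    grad_bound = _field_gradient_bound(u[box], geom)
    alpha = min(1.0, 1.6 / (1.0 + grad_bound))

    bi, bj, bk = np.indices(bshape, dtype=np.float64)
    bi = (bi + lo[0]).ravel()
    bj = (bj + lo[1]).ravel()
    bk = (bk + lo[2]).ravel()
    d = -u[box].reshape(-1, 3).copy()
    ui = np.empty_like(d)
    residual = np.inf
    prev_residual = np.inf
    it = 0
    for it in range(1, iterations + 1):
        off = _index_offsets(d, geom)
        ci = np.ascontiguousarray(bi + off[:, 0])
        cj = np.ascontiguousarray(bj + off[:, 1])
        ck = np.ascontiguousarray(bk + off[:, 2])
        _interp.sample_vec3(u, ci, cj, ck, ui)
        inside = (
            (ci >= 0) & (ci <= geom.size[0] - 1)
            & (cj >= 0) & (cj <= geom.size[1] - 1)
            & (ck >= 0) & (ck <= geom.size[2] - 1)
        )
        res_vec = ui + d
        norms = np.sqrt((res_vec**2).sum(axis=1))
        residual = float(norms[inside].max()) if inside.any() else 0.0
        if residual <= tol_mm:
            break
        if residual > 0.95 * prev_residual:  # stalled: damp harder
            alpha = max(0.5 * alpha, 0.05)
        prev_residual = residual
        d = d + alpha * (-ui - d)

    out = np.zeros(geom.size + (3,))
    out[box] = d.reshape(bshape + (3,))
    return InversionResult(
        DisplacementField(geom, out), residual <= tol_mm, residual, it
    )
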