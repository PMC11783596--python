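"""NIfTI readers/writers and the JSON structure-name sidecar.

NIfTI stores a RAS+ affine; everything in this package lives in the DICOM
LPS frame, so affines are sign-flipped on the first two world axes on read
and flipped back on write.  Label maps travel with a JSON sidecar
``{"labels": {"1": "duodenum", ...}}`` naming each integer label.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import nibabel as nib
import numpy as np

from .core import (
    ImageGeometry,
    LabelVolume,
    ScalarVolume,
    StructureSet,
    labelmap_to_structures,
    structures_to_labelmap,
)

_RAS_TO_LPS = np.diag([-1.0, -1.0, 1.0, 1.0])

Volume = Union[ScalarVolume, LabelVolume]


def _geometry_from_lps_affine(affine: np.ndarray, shape: tuple[int, ...]) -> ImageGeometry:
    mat = affine[:3, :3]
    spacing = np.linalg.norm(mat, axis=0)
    if np.any(spacing <= 0) or not np.all(np.isfinite(spacing)):
        raise ValueError("degenerate affine: zero or non-finite column norm")
    direction = mat / spacing
    return ImageGeometry(
        size=tuple(int(s) for s in shape),
        spacing=tuple(float(s) for s in spacing),
        origin=tuple(float(o) for o in affine[:3, 3]),
        direction=tuple(direction.ravel()),
    )


def _lps_affine(geom: ImageGeometry) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = geom.direction_matrix * np.asarray(geom.spacing)
    affine[:3, 3] = geom.origin
    return affine


def read_volume(path, role: str = "image") -> Volume:
    """Read a NIfTI volume as ``image``/``dose`` (scalar) or ``labels``.

    Raises on a missing file, a degenerate affine, or non-integral voxel
    values under the ``labels`` role.
    """
    if role not in ("image", "labels", "dose"):
        raise ValueError(f"unknown role {role!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    affine = _RAS_TO_LPS @ np.asarray(img.affine, dtype=float)
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    geom = _geometry_from_lps_affine(affine, data.shape)
    if role == "labels":
        if not np.allclose(data, np.round(data)):
            raise ValueError(f"{path} holds non-integral values under role='labels'")
        return LabelVolume(geom, np.round(data).astype(np.int64))
    return ScalarVolume(geom, data.astype(np.float32))


def write_volume(vol: Volume, path) -> Path:
    """Write a volume as NIfTI-1 (scalars float32, labels uint8)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(vol, LabelVolume):
        data = vol.labels.astype(np.uint8)
    else:
        data = np.asarray(vol.values, dtype=np.float32)
    affine_ras = _RAS_TO_LPS @ _lps_affine(vol.geometry)
    nib.save(nib.Nifti1Image(data, affine_ras), str(path))
    return path


def write_structure_names(names: Sequence[str], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sidecar = {"labels": {str(i + 1): name for i, name in enumerate(names)}}
    path.write_text(json.dumps(sidecar, indent=2) + "\n")
    return path


def read_structure_names(path) -> list[str]:
    payload = json.loads(Path(path).read_text())
    mapping = payload["labels"]
    keys = sorted(mapping, key=int)
    if [int(k) for k in keys] != list(range(1, len(keys) + 1)):
        raise ValueError(f"sidecar labels must be consecutive from 1, got {keys}")
    return [mapping[k] for k in keys]


def read_structures(labels_path, sidecar_path=None) -> StructureSet:
    """Read a label map plus its name sidecar into a StructureSet.

    When ``sidecar_path`` is omitted, ``<labels stem>.json`` next to the
    label file is used.
    """
    labels_path = Path(labels_path)
    if sidecar_path is None:
        stem = labels_path.name
        for suffix in (".nii.gz", ".nii"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
                break
        sidecar_path = labels_path.with_name(stem + ".json")
    lv = read_volume(labels_path, role="labels")
    names = read_structure_names(sidecar_path)
    return labelmap_to_structures(lv, names)


def write_structures(ss: StructureSet, labels_path, sidecar_path=None) -> Path:
    labels_path = Path(labels_path)
    if sidecar_path is None:
        stem = labels_path.name
        for suffix in (".nii.gz", ".nii"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
                break
        sidecar_path = labels_path.with_name(stem + ".json")
    write_volume(structures_to_labelmap(ss), labels_path)
    write_structure_names(list(ss.names), sidecar_path)
    return labels_path
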