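"""Dosimetric contour evaluation: cumulative DVH curves, D2%/D50%
extraction, and the three-way difference stratification.

``Dx%`` is the largest dose received by at least x% of a structure's
volume, computed without interpolation by sorting voxel doses descending
and taking the ``ceil(x/100 * n)``-th value.  D2% probes the near-maximum
dose, D50% the median dose.  Differences between predicted- and
ground-truth-contour values are stratified into three categories:

    delta < 1%   -> "✔"   (clinically negligible)
    1% <= delta < 5% -> "•"   (review)
    delta >= 5%  -> "✘"   (clinically relevant)

with half-open bins so the boundary values 1.0 and 5.0 map upward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import ScalarVolume, StructureSet, _require_same_grid

__all__ = [
    "DvhCurve",
    "DoseMetrics",
    "compute_dvh",
    "dose_at_volume",
    "dose_difference_category",
    "evaluate_dosimetry",
    "CATEGORY_GLYPHS",
]

CATEGORY_GLYPHS = {"pass": "✔", "review": "•", "fail": "✘"}


@dataclass
class DvhCurve:
    """Cumulative dose-volume histogram: fraction of organ volume receiving
    at least each dose level.  Non-increasing; starts at 1.0."""

    organ: str
    dose_edges_gy: np.ndarray
    volume_fraction: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "organ": self.organ,
                "dose_gy": self.dose_edges_gy,
                "volume_fraction": self.volume_fraction,
            }
        )


@dataclass
class DoseMetrics:
    organ: str
    d2_pred_gy: float
    d2_gt_gy: float
    d50_pred_gy: float
    d50_gt_gy: float
    delta_d2_pct: float
    delta_d50_pct: float
    category_d2: str
    category_d50: str
    note: str = ""


def _masked_doses(dose: ScalarVolume, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose.geometry.size:
        raise ValueError("mask shape does not match the dose grid")
    if not mask.any():
        raise ValueError("empty mask: DVH undefined")
    return np.asarray(dose.values, dtype=np.float64)[mask]


def compute_dvh(
    dose: ScalarVolume, mask: np.ndarray, organ: str = "", n_bins: int = 200
) -> DvhCurve:
    """Cumulative DVH of the mask's voxel doses on an even dose grid from 0
    to the maximum in-mask dose."""
    doses = _masked_doses(dose, mask)
    top = float(doses.max())
    edges = np.linspace(0.0, top if top > 0 else 1.0, n_bins + 1)
    frac = (doses[None, :] >= edges[:, None]).mean(axis=1)
    frac[0] = 1.0  # dose is non-negative, every voxel receives >= 0
    return DvhCurve(organ, edges, frac)


def dose_at_volume(dose: ScalarVolume, mask: np.ndarray, x_pct: float) -> float:
    """Dx%: the largest dose d such that at least x% of the organ's voxels
    receive >= d (descending sort, no interpolation)."""
    if not (0 < x_pct < 100):
        raise ValueError("x_pct must lie strictly between 0 and 100")
    doses = np.sort(_masked_doses(dose, mask))[::-1]
    k = int(np.ceil(x_pct / 100.0 * doses.size))
    return float(doses[k - 1])


def dose_difference_category(
    d_pred: float, d_gt: float, prescription_gy: float
) -> tuple[float, str]:
    """Relative D-metric difference (%) and its category glyph.

    The denominator is the ground-truth value, switched to the prescription
    when the ground-truth value is below 1% of the prescription (to avoid
    division blow-up on organs receiving essentially no dose).
    """
    if prescription_gy <= 0:
        raise ValueError("prescription must be positive")
    denom = d_gt if d_gt >= 0.01 * prescription_gy else prescription_gy
    delta = 100.0 * abs(d_pred - d_gt) / denom
    if delta < 1.0:
        return delta, CATEGORY_GLYPHS["pass"]
    if delta < 5.0:
        return delta, CATEGORY_GLYPHS["review"]
    return delta, CATEGORY_GLYPHS["fail"]


def evaluate_dosimetry(
    dose: ScalarVolume,
    pred: StructureSet,
    gt: StructureSet,
    prescription_gy: float,
) -> tuple[pd.DataFrame, float]:
    """Per-organ D2%/D50% comparison on a fixed dose grid.

    Both contour sets are evaluated against the *same* dose distribution.
    Returns the metric table and the summary fraction of organs whose D2%
    and D50% differences are both below 1%.  Organs empty in the ground
    truth are flagged and excluded from the summary.
    """
    _require_same_grid(dose.geometry, gt.geometry, "dose vs structures")
    _require_same_grid(pred.geometry, gt.geometry, "pred vs gt structures")
    if pred.names != gt.names:
        raise ValueError(f"organ rosters differ: {pred.names} vs {gt.names}")
    if prescription_gy <= 0:
        raise ValueError("prescription must be positive")

    rows: list[DoseMetrics] = []
    n_pass = 0
    n_eval = 0
    for name in gt.names:
        g, p = gt[name], pred[name]
        if not g.any() or not p.any():
            rows.append(
                DoseMetrics(name, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                            "", "", note="empty mask; excluded from summary")
            )
            continue
        d2_gt = dose_at_volume(dose, g, 2.0)
        d2_pred = dose_at_volume(dose, p, 2.0)
        d50_gt = dose_at_volume(dose, g, 50.0)
        d50_pred = dose_at_volume(dose, p, 50.0)
        delta2, cat2 = dose_difference_category(d2_pred, d2_gt, prescription_gy)
        delta50, cat50 = dose_difference_category(d50_pred, d50_gt, prescription_gy)
        rows.append(
            DoseMetrics(name, d2_pred, d2_gt, d50_pred, d50_gt, delta2, delta50, cat2, cat50)
        )
        n_eval += 1
        if delta2 < 1.0 and delta50 < 1.0:
            n_pass += 1

    ascii_map = {"✔": "pass", "•": "review", "✘": "fail", "": ""}
    df = pd.DataFrame(
        {
            "organ": [r.organ for r in rows],
            "d2_pred_gy": [r.d2_pred_gy for r in rows],
            "d2_gt_gy": [r.d2_gt_gy for r in rows],
            "d50_pred_gy": [r.d50_pred_gy for r in rows],
            "d50_gt_gy": [r.d50_gt_gy for r in rows],
            "delta_d2_pct": [r.delta_d2_pct for r in rows],
            "delta_d50_pct": [r.delta_d50_pct for r in rows],
            "category_d2": [r.category_d2 for r in rows],
            "category_d50": [r.category_d50 for r in rows],
            "category_d2_ascii": [ascii_map[r.category_d2] for r in rows],
            "category_d50_ascii": [ascii_map[r.category_d50] for r in rows],
            "note": [r.note for r in rows],
        }
    )
    summary = n_pass / n_eval if n_eval else float("nan")
    return df, summary
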