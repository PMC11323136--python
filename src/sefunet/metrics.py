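"""Per-organ Dice similarity coefficient and 95th-percentile Hausdorff
distance on 3-D cases, with per-case and cohort aggregation.

HD95 is computed in millimetres on the 3-D stacked prediction per organ:
boundary voxels are those with at least one 6-connected background
neighbour, distances are pooled symmetrically (both directions into one
set) and the 95th percentile of that pooled set is reported.  When one
mask is empty the volume diagonal in mm is returned as a sentinel; when
both are empty the structure is absent and correctly so, giving 0.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .config import ORGAN_ABBREV

_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def dice_coefficient(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """2|A n B| / (|A| + |B|); both empty -> 1.0, exactly one empty -> 0.0."""
    pred_mask = np.asarray(pred_mask, bool)
    true_mask = np.asarray(true_mask, bool)
    if pred_mask.shape != true_mask.shape:
        raise ValueError(
            f"shape mismatch {pred_mask.shape} vs {true_mask.shape}")
    a, b = int(pred_mask.sum()), int(true_mask.sum())
    if a == 0 and b == 0:
        return 1.0
    inter = int(np.logical_and(pred_mask, true_mask).sum())
    return 2.0 * inter / (a + b)


def _boundary_points(mask: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Physical coordinates (mm) of voxels on the 6-connected boundary."""
    eroded = ndimage.binary_erosion(mask, structure=_STRUCT6, border_value=0)
    border = mask & ~eroded
    idx = np.argwhere(border)
    return idx * spacing


def hd95_distance(pred_mask: np.ndarray, true_mask: np.ndarray,
                  spacing=(1.0, 1.0, 1.0)) -> float:
    """95th percentile of pooled symmetric surface distances, in mm."""
    pred_mask = np.asarray(pred_mask, bool)
    true_mask = np.asarray(true_mask, bool)
    if pred_mask.shape != true_mask.shape:
        raise ValueError(
            f"shape mismatch {pred_mask.shape} vs {true_mask.shape}")
    spacing = np.asarray(spacing, float)
    if spacing.shape != (3,) or (spacing <= 0).any():
        raise ValueError("spacing must be 3 positive values")
    a, b = pred_mask.any(), true_mask.any()
    if not a and not b:
        return 0.0
    if a != b:
        return float(np.linalg.norm(np.asarray(pred_mask.shape) * spacing))
    pa = _boundary_points(pred_mask, spacing)
    pb = _boundary_points(true_mask, spacing)
    d_ab = cKDTree(pb).query(pa, k=1)[0]
    d_ba = cKDTree(pa).query(pb, k=1)[0]
    pooled = np.concatenate([d_ab, d_ba])
    return float(np.percentile(pooled, 95))


@dataclass
class CaseMetrics:
    """Per-organ DSC (fraction) and HD95 (mm) for one 3-D case."""
    case_id: str
    dsc: dict[int, float] = field(default_factory=dict)
    hd95: dict[int, float] = field(default_factory=dict)

    @property
    def mean_dsc(self) -> float:
        return float(np.mean(list(self.dsc.values())))

    @property
    def mean_hd95(self) -> float:
        return float(np.mean(list(self.hd95.values())))


def evaluate_case(pred_labels: np.ndarray, true_labels: np.ndarray,
                  spacing=(1.0, 1.0, 1.0), num_classes: int = 9,
                  case_id: str = "case") -> CaseMetrics:
    """Binarize each foreground class and apply DSC / HD95."""
    pred_labels = np.asarray(pred_labels)
    true_labels = np.asarray(true_labels)
    if pred_labels.shape != true_labels.shape:
        raise ValueError("prediction and reference shapes differ")
    for name, arr in (("prediction", pred_labels), ("reference", true_labels)):
        if arr.min() < 0 or arr.max() >= num_classes:
            raise ValueError(f"{name} labels outside [0, {num_classes})")
    out = CaseMetrics(case_id=case_id)
    for cls in range(1, num_classes):
        p = pred_labels == cls
        t = true_labels == cls
        out.dsc[cls] = dice_coefficient(p, t)
        out.hd95[cls] = hd95_distance(p, t, spacing)
    return out


def aggregate_cases(cases: list[CaseMetrics]) -> dict:
    """Cohort summary: per-organ mean DSC (%), overall DSC (%), HD95 (mm)."""
    if not cases:
        raise ValueError("no cases to aggregate")
    classes = sorted(cases[0].dsc)
    for c in cases[1:]:
        if sorted(c.dsc) != classes:
            raise ValueError("inconsistent class alphabets across cases")
    per_organ = {cls: 100.0 * float(np.mean([c.dsc[cls] for c in cases]))
                 for cls in classes}
    return {
        "n_cases": len(cases),
        "mean_dsc_percent": float(np.mean([c.mean_dsc for c in cases])) * 100.0,
        "mean_hd95_mm": float(np.mean([c.mean_hd95 for c in cases])),
        "per_organ_dsc_percent": per_organ,
    }


def write_results_table(cases: list[CaseMetrics], path: str | Path) -> None:
    """One row per case plus a cohort row: DSC %, HD95 mm, then the organs."""
    summary = aggregate_cases(cases)
    classes = sorted(cases[0].dsc)
    header = ["case", "DSC", "HD95"] + [ORGAN_ABBREV[c - 1] for c in classes]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(header)
        for c in cases:
            writer.writerow(
                [c.case_id, f"{100 * c.mean_dsc:.2f}", f"{c.mean_hd95:.2f}"]
                + [f"{100 * c.dsc[cls]:.2f}" for cls in classes])
        writer.writerow(
            ["cohort", f"{summary['mean_dsc_percent']:.2f}",
             f"{summary['mean_hd95_mm']:.2f}"]
            + [f"{summary['per_organ_dsc_percent'][cls]:.2f}" for cls in classes])
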