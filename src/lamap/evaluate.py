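"""Detection-rate evaluation: point-in-region true-positive rate.

A predicted landmark counts as a true positive when the voxel containing its
position belongs to the labeled ground-truth region for that label — a set
membership criterion, not a distance threshold. TPR = TP / (TP + FN) per
label; the overall figure is the arithmetic mean of the per-label TPRs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .phantom import GroundTruth
from .volume import LANDMARK_LABELS, LandmarkResult


class CasePairingError(ValueError):
    """Prediction and truth case identifiers do not match."""


@dataclass(frozen=True)
class EvaluationReport:
    """Per-label TP/FN counts and TPRs plus the per-case hit table."""

    per_label_tp: Mapping[str, int]
    per_label_fn: Mapping[str, int]
    per_label_tpr: Mapping[str, float]
    per_case_hits: Mapping[str, Mapping[str, bool]]
    mean_tpr: float
    per_label_distance_hits: Mapping[str, int] | None = None  # diagnostic only

    def to_dict(self) -> dict:
        out = {
            "per_label": {
                k: {
                    "TP": self.per_label_tp[k],
                    "FN": self.per_label_fn[k],
                    "TPR": self.per_label_tpr[k],
                }
                for k in LANDMARK_LABELS
            },
            "mean_tpr": self.mean_tpr,
            "per_case": {c: dict(h) for c, h in self.per_case_hits.items()},
        }
        if self.per_label_distance_hits is not None:
            out["distance_hits"] = dict(self.per_label_distance_hits)
        return out


def _position_in_mask(
    position_mm: Sequence[float], truth: GroundTruth, label: str
) -> bool:
    mask = truth.target_masks[label]
    idx = (np.asarray(position_mm) - np.asarray(truth.origin)) / np.asarray(
        truth.spacing
    )
    i, j, k = (int(round(v)) for v in idx)
    nz, ny, nx = mask.shape
    if not (0 <= i < nx and 0 <= j < ny and 0 <= k < nz):
        return False
    return bool(mask[k, j, i])


def evaluate(
    predictions: Mapping[str, Sequence[LandmarkResult]],
    truths: Mapping[str, GroundTruth],
    tolerance_mm: float | None = None,
) -> EvaluationReport:
    """Score predicted landmark sets against ground truth, case by case.

    ``tolerance_mm``, when given, additionally counts centroid-distance hits
    as a diagnostic; it never changes the TPR.
    """
    unmatched = set(predictions) ^ set(truths)
    if unmatched:
        raise CasePairingError(f"case ids without a counterpart: {sorted(unmatched)}")
    tp = {k: 0 for k in LANDMARK_LABELS}
    fn = {k: 0 for k in LANDMARK_LABELS}
    dist_hits = {k: 0 for k in LANDMARK_LABELS} if tolerance_mm is not None else None
    per_case: dict[str, dict[str, bool]] = {}
    for case_id in sorted(predictions):
        results = {r.label: r for r in predictions[case_id]}
        truth = truths[case_id]
        hits: dict[str, bool] = {}
        for label in LANDMARK_LABELS:
            if label not in truth.target_masks:
                continue
            result = results.get(label)
            hit = result is not None and _position_in_mask(
                result.position_mm, truth, label
            )
            hits[label] = hit
            if hit:
                tp[label] += 1
            else:
                fn[label] += 1
            if dist_hits is not None and result is not None:
                center = np.asarray(truth.target_centers_mm[label])
                if np.linalg.norm(np.asarray(result.position_mm) - center) <= tolerance_mm:
                    dist_hits[label] += 1
        per_case[case_id] = hits
    tpr = {
        k: (tp[k] / (tp[k] + fn[k])) if (tp[k] + fn[k]) > 0 else float("nan")
        for k in LANDMARK_LABELS
    }
    valid = [v for v in tpr.values() if not np.isnan(v)]
    return EvaluationReport(
        per_label_tp=tp,
        per_label_fn=fn,
        per_label_tpr=tpr,
        per_case_hits=per_case,
        mean_tpr=float(np.mean(valid)) if valid else float("nan"),
        per_label_distance_hits=dist_hits,
    )
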