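"""Estimation of the geometric prior table from annotated geometry samples.

Each annotated case supplies the in-plane centroids of the two reference
vessels plus labeled 3D landmark positions. Per case the reference
separation delta, the directed AA->DA angle theta, each landmark's in-plane
distances to both references, and its side of the AA-DA axis are measured;
across cases the prior means and (n-1)-denominator deviations are estimated,
with the reference deviations stored normalized by their means.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .geometry import angle_deg, side_sign
from .priors import DEFAULT_ALPHA, DEFAULT_SIGMA_R, PriorTable
from .volume import LANDMARK_LABELS

logger = logging.getLogger(__name__)

SIGMA_FLOOR_MM = 0.5  # degenerate-sample deviation floor


class InsufficientSamplesError(ValueError):
    """Fewer than two samples for an estimated quantity."""


@dataclass(frozen=True)
class GeometrySample:
    """Measured geometry of one annotated case."""

    case_id: str
    aa_xy: tuple[float, float]
    da_xy: tuple[float, float]
    delta_mm: float
    theta_deg: float
    landmark_distances: Mapping[str, tuple[float, float]]  # label -> (d_AA, d_DA)
    landmark_sides: Mapping[str, int]


def measure_geometry(
    annotations: Iterable[Mapping], case_ids: Sequence[str] | None = None
) -> list[GeometrySample]:
    """Derive per-case geometric measurements from annotation records.

    Each record needs ``reference: {AA: [x, y], DA: [x, y]}`` and
    ``landmarks: {label: [x, y, z], ...}`` (mm). Cases missing a reference
    are skipped with a warning; distances are in-plane (x, y) Euclidean.
    """
    samples: list[GeometrySample] = []
    for idx, record in enumerate(annotations):
        case_id = case_ids[idx] if case_ids is not None else record.get("case_id", str(idx))
        ref = record.get("reference", {})
        if "AA" not in ref or "DA" not in ref:
            logger.warning("case %s: missing reference centroid(s); skipped", case_id)
            continue
        aa = np.asarray(ref["AA"], dtype=float)[:2]
        da = np.asarray(ref["DA"], dtype=float)[:2]
        diff = da - aa
        delta = float(np.linalg.norm(diff))
        if delta == 0.0:
            logger.warning("case %s: coincident references; skipped", case_id)
            continue
        landmarks = record.get("landmarks", {})
        distances: dict[str, tuple[float, float]] = {}
        sides: dict[str, int] = {}
        for label, pos in landmarks.items():
            if label not in LANDMARK_LABELS:
                logger.warning("case %s: unknown label %r ignored", case_id, label)
                continue
            xy = np.asarray(pos, dtype=float)[:2]
            distances[label] = (
                float(np.linalg.norm(xy - aa)),
                float(np.linalg.norm(xy - da)),
            )
            sides[label] = side_sign(aa, da, xy)
        samples.append(
            GeometrySample(
                case_id=str(case_id),
                aa_xy=(float(aa[0]), float(aa[1])),
                da_xy=(float(da[0]), float(da[1])),
                delta_mm=delta,
                theta_deg=angle_deg(diff),
                landmark_distances=distances,
                landmark_sides=sides,
            )
        )
    return samples


def _mean_sd(values: Sequence[float], name: str, floor: float) -> tuple[float, float]:
    if len(values) < 2:
        raise InsufficientSamplesError(
            f"need >= 2 samples to estimate {name}, got {len(values)}"
        )
    arr = np.asarray(values, dtype=float)
    mu = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if sd < floor:
        logger.warning("%s: degenerate deviation %.4g replaced by floor %.2g", name, sd, floor)
        sd = floor
    return mu, sd


def estimate_params(
    samples: Sequence[GeometrySample],
    sigma_floor_mm: float = SIGMA_FLOOR_MM,
    sigma_r: float = DEFAULT_SIGMA_R,
    alpha: float = DEFAULT_ALPHA,
) -> PriorTable:
    """Estimate a complete :class:`PriorTable` from measured geometry samples."""
    delta_bar, delta_sd = _mean_sd([s.delta_mm for s in samples], "delta", sigma_floor_mm)
    theta_bar, theta_sd = _mean_sd(
        [s.theta_deg for s in samples], "theta", sigma_floor_mm
    )
    target_distances: dict[str, dict[str, tuple[float, float]]] = {}
    side_signs: dict[str, int] = {}
    for label in LANDMARK_LABELS:
        d_a = [s.landmark_distances[label][0] for s in samples if label in s.landmark_distances]
        d_d = [s.landmark_distances[label][1] for s in samples if label in s.landmark_distances]
        target_distances[label] = {
            "AA": _mean_sd(d_a, f"{label}/AA distance", sigma_floor_mm),
            "DA": _mean_sd(d_d, f"{label}/DA distance", sigma_floor_mm),
        }
        votes = [s.landmark_sides[label] for s in samples if label in s.landmark_sides]
        side_signs[label] = 1 if sum(votes) >= 0 else -1
    return PriorTable(
        delta_bar=delta_bar,
        theta_bar=theta_bar,
        sigma_delta=delta_sd / delta_bar,
        sigma_theta=theta_sd / theta_bar,
        target_distances=target_distances,
        side_signs=side_signs,
        sigma_r=sigma_r,
        alpha=alpha,
        pairwise=None,  # re-derived from the estimated means
    )


def load_annotations(directory: str | Path) -> tuple[list[dict], list[str]]:
    """Read all ``*.json`` annotation files from a directory, sorted by name."""
    directory = Path(directory)
    records, ids = [], []
    for path in sorted(directory.glob("*.json")):
        records.append(json.loads(path.read_text()))
        ids.append(path.stem)
    return records, ids


def learn_priors(annotation_dir: str | Path, **kwargs) -> PriorTable:
    """measure_geometry + estimate_params over a directory of annotation files."""
    records, ids = load_annotations(annotation_dir)
    samples = measure_geometry(records, case_ids=ids)
    return estimate_params(samples, **kwargs)
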