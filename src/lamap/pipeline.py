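"""End-to-end detection: intensity adaptation -> references -> targets.

The two-stage MAP decomposition first commits to the reference pair (the
posterior over the aorta axes is assumed sharply peaked), then maximizes the
target posterior conditioned on those fixed references.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .intensity import IntensityModel, candidate_mask, estimate_intensity_model
from .priors import PriorTable, default_priors
from .reference import ReferenceAxes, detect_references
from .targets import (
    Assignment,
    CandidateObject3D,
    candidate_objects,
    localize_targets,
)
from .volume import CTVolume, LandmarkResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionOutput:
    """Results plus every intermediate product, for inspection and logging."""

    results: list[LandmarkResult]
    assignment: Assignment
    axes: ReferenceAxes
    intensity_model: IntensityModel
    candidates: list[CandidateObject3D]


def detect_landmarks(
    volume: CTVolume,
    prior: PriorTable | None = None,
    alpha: float | None = None,
) -> DetectionOutput:
    """Run the full pipeline on one volume and return all stages' outputs."""
    prior = prior or default_priors()
    model = estimate_intensity_model(volume)
    logger.info(
        "intensity model: muB=%.1f sigmaB=%.1f muF=%.1f sigmaF=%.1f I1=%.1f I2=%.1f",
        model.mu_b, model.sigma_b, model.mu_f, model.sigma_f, model.i1, model.i2,
    )
    mask = candidate_mask(volume, model)
    axes = detect_references(volume, mask, prior)
    logger.info(
        "references: delta=%.2f mm theta=%.2f deg over %d slices",
        axes.delta_mm, axes.theta_deg, len(axes.detections),
    )
    candidates = candidate_objects(volume, mask, axes, prior, alpha=alpha)
    logger.info("candidate objects: %d", len(candidates))
    results, assignment = localize_targets(candidates, prior, model)
    logger.info(
        "assignment score: total=%.3f (intensity %.3f + geometry %.3f)",
        assignment.total, assignment.intensity_term, assignment.geometry_term,
    )
    return DetectionOutput(
        results=results,
        assignment=assignment,
        axes=axes,
        intensity_model=model,
        candidates=candidates,
    )


def detect_references_only(
    volume: CTVolume, prior: PriorTable | None = None
) -> tuple[ReferenceAxes, IntensityModel]:
    """Run only the intensity and reference stages."""
    prior = prior or default_priors()
    model = estimate_intensity_model(volume)
    mask = candidate_mask(volume, model)
    return detect_references(volume, mask, prior), model
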