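"""Geometric prior tables for reference and target localization.

The prior couples two kinds of knowledge measured from annotated cardiac CTA
geometry:

* the reference pair (ascending / descending aorta): mean centroid separation
  ``delta_bar`` and mean AA->DA angle ``theta_bar`` against the +x axis, with
  deviations normalized by the means;
* per-landmark mean/deviation distances to each reference, one column per
  target (LSPV, LIPV, RSPV, RIPV, LAA), plus the side of the AA-DA axis the
  target lies on;
* pairwise inter-landmark distances used by the complete-graph assignment
  prior. These are not part of the measured table: the defaults are derived
  once by trilaterating each landmark at its mean distances and measuring the
  resulting pairwise separations.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .geometry import solve_position
from .volume import LANDMARK_LABELS

# Measured reference-geometry parameters (8 annotated training cases).
DEFAULT_DELTA_BAR = 81.6  # mm
DEFAULT_THETA_BAR = 66.9  # degrees
DEFAULT_SIGMA_DELTA = 0.132  # normalized by delta_bar
DEFAULT_SIGMA_THETA = 0.011  # normalized by theta_bar

# Per-landmark (mu, sigma) distances in mm to each reference, same 8 cases.
DEFAULT_TARGET_DISTANCES: dict[str, dict[str, tuple[float, float]]] = {
    "LSPV": {"AA": (65.71, 2.95), "DA": (46.54, 7.31)},
    "LIPV": {"AA": (80.09, 6.04), "DA": (26.22, 4.38)},
    "RSPV": {"AA": (44.16, 3.55), "DA": (82.15, 9.62)},
    "RIPV": {"AA": (63.74, 8.71), "DA": (63.31, 8.66)},
    "LAA": {"AA": (49.23, 3.02), "DA": (65.37, 10.77)},
}

DEFAULT_SIGMA_R = 0.1  # isotropy-ratio deviation (not printed; configurable)
DEFAULT_ALPHA = -8.0  # similarity threshold, log units
DEFAULT_PAIRWISE_SIGMA = 8.0  # mm, for the derived inter-landmark prior


class PriorConfigError(ValueError):
    """Prior table is incomplete or violates its invariants."""


def _pair_key(a: str, b: str) -> tuple[str, str]:
    ia, ib = LANDMARK_LABELS.index(a), LANDMARK_LABELS.index(b)
    return (a, b) if ia < ib else (b, a)


@dataclass(frozen=True)
class PriorTable:
    """All geometric prior parameters consumed by the detection pipeline."""

    delta_bar: float = DEFAULT_DELTA_BAR
    theta_bar: float = DEFAULT_THETA_BAR
    sigma_delta: float = DEFAULT_SIGMA_DELTA
    sigma_theta: float = DEFAULT_SIGMA_THETA
    target_distances: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_TARGET_DISTANCES.items()
        }
    )
    side_signs: Mapping[str, int] = field(
        default_factory=lambda: {k: 1 for k in LANDMARK_LABELS}
    )
    sigma_r: float = DEFAULT_SIGMA_R
    alpha: float = DEFAULT_ALPHA
    pairwise: Mapping[tuple[str, str], tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.delta_bar <= 0 or self.theta_bar <= 0:
            raise PriorConfigError("reference means must be positive")
        for name in ("sigma_delta", "sigma_theta", "sigma_r"):
            if getattr(self, name) <= 0:
                raise PriorConfigError(f"{name} must be positive")
        for label in LANDMARK_LABELS:
            if label not in self.target_distances:
                raise PriorConfigError(f"missing distance parameters for {label}")
            for ref in ("AA", "DA"):
                mu, sigma = self.target_distances[label][ref]
                if mu <= 0 or sigma <= 0:
                    raise PriorConfigError(
                        f"{label}/{ref}: mu and sigma must be positive, got {mu}, {sigma}"
                    )
            mu_a, _ = self.target_distances[label]["AA"]
            mu_d, _ = self.target_distances[label]["DA"]
            if not (abs(mu_a - mu_d) < self.delta_bar < mu_a + mu_d):
                raise PriorConfigError(
                    f"{label}: mean distances ({mu_a}, {mu_d}) infeasible against "
                    f"delta_bar={self.delta_bar} (triangle inequality)"
                )
            if self.side_signs.get(label) not in (1, -1):
                raise PriorConfigError(f"{label}: side sign must be +1 or -1")
        if self.pairwise is None:
            object.__setattr__(self, "pairwise", derive_pairwise(self))
        else:
            pw = {_pair_key(*k): tuple(v) for k, v in self.pairwise.items()}
            for a, b in itertools.combinations(LANDMARK_LABELS, 2):
                if (a, b) not in pw:
                    raise PriorConfigError(f"missing pairwise parameters for ({a}, {b})")
                mu, sigma = pw[(a, b)]
                if mu <= 0 or sigma <= 0:
                    raise PriorConfigError(f"pairwise ({a},{b}): non-positive mu/sigma")
            object.__setattr__(self, "pairwise", pw)

    def distance_params(self, label: str, ref: str) -> tuple[float, float]:
        """(mu, sigma) distance in mm from ``label`` to reference ``ref``."""
        return tuple(self.target_distances[label][ref])  # type: ignore[return-value]

    def pairwise_params(self, a: str, b: str) -> tuple[float, float]:
        """(mu, sigma) inter-landmark distance in mm for the unordered pair."""
        assert self.pairwise is not None
        return self.pairwise[_pair_key(a, b)]

    def mean_position(self, label: str) -> np.ndarray:
        """Trilaterated mean landmark position in the canonical reference frame.

        Canonical frame: AA at the origin, DA at (delta_bar, 0), landmark on
        its configured side.
        """
        mu_a, _ = self.distance_params(label, "AA")
        mu_d, _ = self.distance_params(label, "DA")
        return solve_position(
            (0.0, 0.0), (self.delta_bar, 0.0), mu_a, mu_d, self.side_signs[label]
        )


def derive_pairwise(
    prior: PriorTable, sigma: float = DEFAULT_PAIRWISE_SIGMA
) -> dict[tuple[str, str], tuple[float, float]]:
    """Derive inter-landmark distance priors from the per-reference table.

    Each landmark is placed at its trilaterated mean position in the canonical
    frame; the pairwise separations become the means, with a common deviation.
    """
    positions = {k: prior.mean_position(k) for k in LANDMARK_LABELS}
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for a, b in itertools.combinations(LANDMARK_LABELS, 2):
        mu = float(np.linalg.norm(positions[a] - positions[b]))
        out[(a, b)] = (mu, sigma)
    return out


def default_priors() -> PriorTable:
    """The measured defaults with the derived pairwise table."""
    return PriorTable()


def _to_plain(prior: PriorTable) -> dict:
    assert prior.pairwise is not None
    return {
        "reference": {
            "delta_bar_mm": prior.delta_bar,
            "theta_bar_deg": prior.theta_bar,
            "sigma_delta": prior.sigma_delta,
            "sigma_theta": prior.sigma_theta,
        },
        "targets": {
            label: {
                "AA": list(prior.target_distances[label]["AA"]),
                "DA": list(prior.target_distances[label]["DA"]),
                "side": prior.side_signs[label],
            }
            for label in LANDMARK_LABELS
        },
        "sigma_r": prior.sigma_r,
        "alpha": prior.alpha,
        "pairwise_mm": {
            f"{a}-{b}": list(v) for (a, b), v in sorted(prior.pairwise.items())
        },
    }


def save_priors(prior: PriorTable, path: str | Path) -> None:
    """Write a prior table as YAML (or JSON when the suffix is .json)."""
    path = Path(path)
    plain = _to_plain(prior)
    if path.suffix == ".json":
        path.write_text(json.dumps(plain, indent=2))
    else:
        path.write_text(yaml.safe_dump(plain, sort_keys=False))


def load_priors(path: str | Path) -> PriorTable:
    """Read a prior table written by :func:`save_priors`."""
    path = Path(path)
    text = path.read_text()
    plain = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    try:
        ref = plain["reference"]
        targets = plain["targets"]
        pairwise = {
            tuple(key.split("-")): tuple(val)
            for key, val in plain.get("pairwise_mm", {}).items()
        } or None
        return PriorTable(
            delta_bar=ref["delta_bar_mm"],
            theta_bar=ref["theta_bar_deg"],
            sigma_delta=ref["sigma_delta"],
            sigma_theta=ref["sigma_theta"],
            target_distances={
                label: {"AA": tuple(t["AA"]), "DA": tuple(t["DA"])}
                for label, t in targets.items()
            },
            side_signs={label: int(t["side"]) for label, t in targets.items()},
            sigma_r=plain.get("sigma_r", DEFAULT_SIGMA_R),
            alpha=plain.get("alpha", DEFAULT_ALPHA),
            pairwise=pairwise,
        )
    except KeyError as exc:
        raise PriorConfigError(f"{path}: missing prior field {exc}") from exc
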