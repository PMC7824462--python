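"""Planar geometry helpers shared by the prior tables and the phantom generator."""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np


class NoIntersectionError(ValueError):
    """The two distance circles do not intersect (infeasible trilateration)."""


def angle_deg(vec_xy: Sequence[float]) -> float:
    """Angle of a 2D vector against the +x axis, in degrees folded to [0, 360)."""
    ang = math.degrees(math.atan2(vec_xy[1], vec_xy[0]))
    return ang % 360.0


def side_sign(ref_a: Sequence[float], ref_d: Sequence[float], point: Sequence[float]) -> int:
    """Sign of the perpendicular component of ``point`` relative to the ref_a->ref_d axis.

    +1 on the left of the directed axis (positive cross product), -1 on the
    right, 0 exactly on the axis.
    """
    a = np.asarray(ref_a, dtype=float)
    d = np.asarray(ref_d, dtype=float)
    p = np.asarray(point, dtype=float)
    r = d - a
    cross = r[0] * (p[1] - a[1]) - r[1] * (p[0] - a[0])
    return int(np.sign(cross))


def solve_position(
    ref_a: Sequence[float],
    ref_d: Sequence[float],
    d_a: float,
    d_d: float,
    side: int = 1,
) -> np.ndarray:
    """Trilaterate a 2D point from its distances to two reference points.

    Returns the circle-circle intersection lying on the half-plane selected by
    ``side`` (sign of the perpendicular component relative to ref_a->ref_d);
    tangent configurations return the single touching point.
    """
    a = np.asarray(ref_a, dtype=float)
    d = np.asarray(ref_d, dtype=float)
    delta = float(np.linalg.norm(d - a))
    if delta == 0.0:
        raise NoIntersectionError("reference points coincide")
    if d_a < 0 or d_d < 0:
        raise NoIntersectionError("distances must be non-negative")
    if abs(d_a - d_d) > delta or delta > d_a + d_d:
        raise NoIntersectionError(
            f"circles with radii {d_a}, {d_d} at separation {delta} do not intersect"
        )
    r_hat = (d - a) / delta
    n_hat = np.array([-r_hat[1], r_hat[0]])  # +90 deg rotation: side=+1 half-plane
    along = (d_a**2 - d_d**2 + delta**2) / (2.0 * delta)
    h_sq = d_a**2 - along**2
    h = math.sqrt(max(h_sq, 0.0))
    return a + along * r_hat + (1 if side >= 0 else -1) * h * n_hat
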