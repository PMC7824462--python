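"""Synthetic cardiac-CT phantoms with known reference and target geometry.

The phantom reduces a contrast-enhanced cardiac CTA to the features the
detection model actually uses: a soft-tissue background, two bright vertical
cylinders standing in for the ascending and descending aorta at a
configurable separation ``delta`` and angle ``theta``, five bright spherical
blobs placed by trilateration at configurable distances from the two
cylinder axes (one blob per landmark label), and optional decoy blobs whose
distances deliberately violate every label's learned distance band. Ground
truth (per-label voxel masks, reference axes, realized geometry) is recorded
for evaluation and prior learning.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .geometry import NoIntersectionError, angle_deg, solve_position
from .priors import DEFAULT_TARGET_DISTANCES, PriorTable, default_priors
from .volume import CTVolume, LANDMARK_LABELS


class PhantomSpecError(ValueError):
    """The requested phantom geometry is infeasible or does not fit the volume."""


def _default_targets() -> dict[str, "TargetSpec"]:
    return {
        label: TargetSpec(d_aa=v["AA"][0], d_da=v["DA"][0])
        for label, v in DEFAULT_TARGET_DISTANCES.items()
    }


@dataclass(frozen=True)
class TargetSpec:
    """One target blob: distances to the two reference axes plus its shape."""

    d_aa: float  # mm
    d_da: float  # mm
    radius: float = 6.0  # mm
    z_center_mm: float | None = None  # None -> volume mid-plane


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic volume; generation is (spec, seed)-deterministic."""

    shape_zyx: tuple[int, int, int] = (160, 160, 160)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    delta_mm: float = 81.6
    theta_deg: float = 66.9
    aa_center_mm: tuple[float, float] = (50.0, 25.0)
    aa_radius_mm: float = 14.0
    da_radius_mm: float = 10.0
    cylinder_z_mm: tuple[float, float] | None = None  # None -> full z extent
    targets: Mapping[str, TargetSpec] = field(default_factory=_default_targets)
    side: int = 1  # all landmarks on the left-atrial side of the AA->DA axis
    mu_f: float = 400.0  # contrast HU
    sigma_f: float = 50.0
    mu_b: float = 80.0  # soft-tissue HU
    sigma_b: float = 20.0
    noise_sigma: float = 0.0  # extra white acquisition noise on top of class spread
    noise_correlation_mm: float = 0.0  # optional smoothing of the class noise field
    n_decoys: int = 3
    decoy_radius_mm: float = 6.0


def noiseless(spec: PhantomSpec | None = None) -> PhantomSpec:
    """A copy of ``spec`` with all intensity spread removed (class-constant HU)."""
    spec = spec or PhantomSpec()
    return dataclasses.replace(spec, sigma_f=0.0, sigma_b=0.0, noise_sigma=0.0)


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows about the phantom it built."""

    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    aa_center_mm: tuple[float, float]
    da_center_mm: tuple[float, float]
    delta_mm: float
    theta_deg: float
    aa_radius_mm: float
    da_radius_mm: float
    target_centers_mm: Mapping[str, tuple[float, float, float]]
    target_masks: Mapping[str, np.ndarray]
    realized_distances: Mapping[str, tuple[float, float]]  # voxel-mask (d_AA, d_DA)
    decoy_centers_mm: tuple[tuple[float, float, float], ...]

    def to_annotation(self) -> dict:
        """Annotation record consumable by the prior-learning module."""
        return {
            "reference": {
                "AA": list(self.aa_center_mm),
                "DA": list(self.da_center_mm),
            },
            "landmarks": {
                label: list(pos) for label, pos in self.target_centers_mm.items()
            },
        }


def _reference_centers(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    aa = np.asarray(spec.aa_center_mm, dtype=float)
    theta = np.radians(spec.theta_deg)
    da = aa + spec.delta_mm * np.array([np.cos(theta), np.sin(theta)])
    return aa, da


def _check_inside(
    center_xy: np.ndarray, radius: float, extent_xy: tuple[float, float], what: str
) -> None:
    for axis in range(2):
        if center_xy[axis] - radius < 0 or center_xy[axis] + radius > extent_xy[axis]:
            raise PhantomSpecError(
                f"{what} at {tuple(np.round(center_xy, 1))} mm with radius {radius} mm "
                f"does not fit the in-plane extent {extent_xy} mm"
            )


def _solve_targets(spec: PhantomSpec) -> dict[str, np.ndarray]:
    aa, da = _reference_centers(spec)
    nz, ny, nx = spec.shape_zyx
    extent = (nx * spec.spacing[0], ny * spec.spacing[1])
    mid_z = 0.5 * (nz - 1) * spec.spacing[2]
    positions: dict[str, np.ndarray] = {}
    for label, tgt in spec.targets.items():
        try:
            pos = solve_position(aa, da, tgt.d_aa, tgt.d_da, spec.side)
        except NoIntersectionError as exc:
            raise PhantomSpecError(f"target {label}: {exc}") from exc
        _check_inside(pos, tgt.radius, extent, f"target {label}")
        positions[label] = pos
    _check_inside(aa, spec.aa_radius_mm, extent, "AA cylinder")
    _check_inside(da, spec.da_radius_mm, extent, "DA cylinder")
    # targets are distinct anatomical structures: reject overlapping blobs and
    # blobs that collide with a reference cylinder
    labels = list(spec.targets)
    for i, li in enumerate(labels):
        ti = spec.targets[li]
        zi = ti.z_center_mm if ti.z_center_mm is not None else mid_z
        for lj in labels[i + 1 :]:
            tj = spec.targets[lj]
            zj = tj.z_center_mm if tj.z_center_mm is not None else mid_z
            gap = np.linalg.norm(
                [*(positions[li] - positions[lj]), zi - zj]
            )
            if gap < ti.radius + tj.radius + 2.0:
                raise PhantomSpecError(
                    f"targets {li} and {lj} overlap (separation {gap:.1f} mm)"
                )
        for center, radius, name in ((aa, spec.aa_radius_mm, "AA"), (da, spec.da_radius_mm, "DA")):
            if np.linalg.norm(positions[li] - center) < ti.radius + radius + 2.0:
                raise PhantomSpecError(f"target {li} collides with the {name} cylinder")
    return positions


def draw_spec(
    prior: PriorTable,
    rng: np.random.Generator,
    base: PhantomSpec | None = None,
    draw_reference: bool = True,
    draw_targets: bool = True,
    max_tries: int = 200,
) -> PhantomSpec:
    """Sample a feasible :class:`PhantomSpec` from the prior's Gaussians.

    The reference separation/angle are drawn from N(delta_bar, sigma_delta *
    delta_bar) and N(theta_bar, sigma_theta * theta_bar); per-label distances
    from their learned (mu, sigma). Draws violating circle-intersection
    feasibility or the volume extent are rejected and redrawn.
    """
    base = base or PhantomSpec()
    for _ in range(max_tries):
        delta = base.delta_mm
        theta = base.theta_deg
        if draw_reference:
            delta = float(rng.normal(prior.delta_bar, prior.sigma_delta * prior.delta_bar))
            theta = float(rng.normal(prior.theta_bar, prior.sigma_theta * prior.theta_bar))
            if delta <= 0:
                continue
        targets = dict(base.targets)
        if draw_targets:
            targets = {}
            for label in LANDMARK_LABELS:
                mu_a, sig_a = prior.distance_params(label, "AA")
                mu_d, sig_d = prior.distance_params(label, "DA")
                tgt_base = base.targets[label]
                for _ in range(max_tries):
                    d_a = float(rng.normal(mu_a, sig_a))
                    d_d = float(rng.normal(mu_d, sig_d))
                    if d_a > 0 and d_d > 0 and abs(d_a - d_d) < delta < d_a + d_d:
                        break
                else:
                    break  # label failed; reject the whole draw
                targets[label] = dataclasses.replace(tgt_base, d_aa=d_a, d_da=d_d)
            if len(targets) < len(LANDMARK_LABELS):
                continue
        cand = dataclasses.replace(base, delta_mm=delta, theta_deg=theta, targets=targets)
        try:
            _solve_targets(cand)
        except PhantomSpecError:
            continue
        return cand
    raise PhantomSpecError(f"no feasible spec found in {max_tries} draws")


def _sphere_mask(
    x: np.ndarray, y: np.ndarray, z: np.ndarray, center: np.ndarray, radius: float
) -> np.ndarray:
    return (
        (x[np.newaxis, np.newaxis, :] - center[0]) ** 2
        + (y[np.newaxis, :, np.newaxis] - center[1]) ** 2
        + (z[:, np.newaxis, np.newaxis] - center[2]) ** 2
    ) <= radius**2


def generate_phantom(
    spec: PhantomSpec, seed: int
) -> tuple[CTVolume, GroundTruth]:
    """Render the phantom volume and its ground truth; reproducible from (spec, seed)."""
    positions = _solve_targets(spec)  # feasibility-checked before any voxel is written
    aa, da = _reference_centers(spec)
    nz, ny, nx = spec.shape_zyx
    sx, sy, sz = spec.spacing
    rng = np.random.default_rng(seed)

    x = np.arange(nx) * sx
    y = np.arange(ny) * sy
    z = np.arange(nz) * sz
    z_lo, z_hi = spec.cylinder_z_mm if spec.cylinder_z_mm else (z[0], z[-1])
    mid_z = 0.5 * (z[0] + z[-1])

    foreground = np.zeros((nz, ny, nx), dtype=bool)
    in_z = (z >= z_lo) & (z <= z_hi)
    for center, radius in ((aa, spec.aa_radius_mm), (da, spec.da_radius_mm)):
        disc = (
            (x[np.newaxis, :] - center[0]) ** 2 + (y[:, np.newaxis] - center[1]) ** 2
        ) <= radius**2
        foreground |= in_z[:, np.newaxis, np.newaxis] & disc[np.newaxis]

    target_masks: dict[str, np.ndarray] = {}
    target_centers: dict[str, tuple[float, float, float]] = {}
    for label, tgt in spec.targets.items():
        zc = tgt.z_center_mm if tgt.z_center_mm is not None else mid_z
        center3 = np.array([positions[label][0], positions[label][1], zc])
        mask = _sphere_mask(x, y, z, center3, tgt.radius)
        if not mask.any():
            raise PhantomSpecError(f"target {label} rasterized to zero voxels")
        target_masks[label] = mask
        target_centers[label] = tuple(float(c) for c in center3)
        foreground |= mask

    decoy_centers = _place_decoys(spec, rng, aa, da, positions, (x[-1], y[-1]))
    for center in decoy_centers:
        foreground |= _sphere_mask(x, y, z, np.asarray(center), spec.decoy_radius_mm)

    values = np.where(foreground, float(spec.mu_f), float(spec.mu_b))
    if spec.sigma_b > 0 or spec.sigma_f > 0:
        # one correlated noise field, scaled per class: emulates the spatially
        # smooth texture of reconstructed CT rather than voxel-white noise
        field = rng.standard_normal(values.shape)
        if spec.noise_correlation_mm > 0:
            from scipy import ndimage

            sigmas = [spec.noise_correlation_mm / s for s in (sz, sy, sx)]
            field = ndimage.gaussian_filter(field, sigma=sigmas)
            field /= max(field.std(), 1e-12)
        values += np.where(foreground, spec.sigma_f, spec.sigma_b) * field
    if spec.noise_sigma > 0:
        values += rng.normal(0.0, spec.noise_sigma, size=values.shape)

    volume = CTVolume(values, spacing=spec.spacing)
    realized = {}
    for label, mask in target_masks.items():
        kk, jj, ii = np.nonzero(mask)
        cen = np.array([ii.mean() * sx, jj.mean() * sy])
        realized[label] = (
            float(np.linalg.norm(cen - aa)),
            float(np.linalg.norm(cen - da)),
        )
    truth = GroundTruth(
        spacing=spec.spacing,
        origin=(0.0, 0.0, 0.0),
        aa_center_mm=(float(aa[0]), float(aa[1])),
        da_center_mm=(float(da[0]), float(da[1])),
        delta_mm=float(np.linalg.norm(da - aa)),
        theta_deg=angle_deg(da - aa),
        aa_radius_mm=spec.aa_radius_mm,
        da_radius_mm=spec.da_radius_mm,
        target_centers_mm=target_centers,
        target_masks=target_masks,
        realized_distances=realized,
        decoy_centers_mm=tuple(decoy_centers),
    )
    return volume, truth


def _place_decoys(
    spec: PhantomSpec,
    rng: np.random.Generator,
    aa: np.ndarray,
    da: np.ndarray,
    targets: Mapping[str, np.ndarray],
    extent_xy: tuple[float, float],
    max_tries: int = 2000,
) -> list[tuple[float, float, float]]:
    """Rejection-sample contrast-like blobs that are geometrically wrong.

    A decoy's (d_AA, d_DA) must fall outside every label's 2-sigma distance
    band, so the decoys stress the assignment prior rather than the
    similarity threshold.
    """
    if spec.n_decoys == 0:
        return []
    prior = default_priors()
    delta = float(np.linalg.norm(da - aa))
    nz = spec.shape_zyx[0]
    mid_z = 0.5 * (nz - 1) * spec.spacing[2]
    margin = spec.decoy_radius_mm
    out: list[tuple[float, float, float]] = []
    for _ in range(max_tries):
        if len(out) >= spec.n_decoys:
            break
        d_a = float(rng.uniform(20.0, delta + 40.0))
        d_d = float(rng.uniform(20.0, delta + 40.0))
        if not (abs(d_a - d_d) < delta < d_a + d_d):
            continue
        in_band = False
        for label in LANDMARK_LABELS:
            mu_a, sig_a = prior.distance_params(label, "AA")
            mu_d, sig_d = prior.distance_params(label, "DA")
            if abs(d_a - mu_a) < 2 * sig_a and abs(d_d - mu_d) < 2 * sig_d:
                in_band = True
                break
        if in_band:
            continue
        try:
            pos = solve_position(aa, da, d_a, d_d, spec.side)
        except NoIntersectionError:
            continue
        if not (
            margin <= pos[0] <= extent_xy[0] - margin
            and margin <= pos[1] <= extent_xy[1] - margin
        ):
            continue
        if np.linalg.norm(pos - aa) < spec.aa_radius_mm + margin + 2:
            continue
        if np.linalg.norm(pos - da) < spec.da_radius_mm + margin + 2:
            continue
        if any(
            np.linalg.norm(pos - tpos) < 2 * margin + 3 for tpos in targets.values()
        ):
            continue
        if any(np.linalg.norm(pos - np.asarray(d[:2])) < 2 * margin + 3 for d in out):
            continue
        out.append((float(pos[0]), float(pos[1]), float(mid_z)))
    if len(out) < spec.n_decoys:
        raise PhantomSpecError(
            f"could only place {len(out)} of {spec.n_decoys} decoys"
        )
    return out


def generate_annotation_cases(
    prior: PriorTable,
    n_cases: int,
    rng: np.random.Generator,
    aa_center: tuple[float, float] = (60.0, 40.0),
    max_tries: int = 200,
) -> list[dict]:
    """Draw synthetic annotated geometries from the prior's Gaussians.

    Each case draws the reference separation/angle and every label's distance
    pair (rejection-sampled to circle-intersection feasibility), places the
    landmarks by trilateration, and emits the annotation-record schema that
    :func:`lamap.learning.measure_geometry` consumes. Used to exercise prior
    learning without rendering volumes.
    """
    cases: list[dict] = []
    aa = np.asarray(aa_center, dtype=float)
    for i in range(n_cases):
        for _ in range(max_tries):
            delta = float(rng.normal(prior.delta_bar, prior.sigma_delta * prior.delta_bar))
            if delta > 0:
                break
        theta = float(rng.normal(prior.theta_bar, prior.sigma_theta * prior.theta_bar))
        rad = np.radians(theta)
        da = aa + delta * np.array([np.cos(rad), np.sin(rad)])
        landmarks: dict[str, list[float]] = {}
        for label in LANDMARK_LABELS:
            mu_a, sig_a = prior.distance_params(label, "AA")
            mu_d, sig_d = prior.distance_params(label, "DA")
            for _ in range(max_tries):
                d_a = float(rng.normal(mu_a, sig_a))
                d_d = float(rng.normal(mu_d, sig_d))
                if d_a > 0 and d_d > 0 and abs(d_a - d_d) < delta < d_a + d_d:
                    break
            else:
                raise PhantomSpecError(
                    f"case {i}: no feasible distances for {label} in {max_tries} draws"
                )
            pos = solve_position(aa, da, d_a, d_d, prior.side_signs[label])
            landmarks[label] = [float(pos[0]), float(pos[1]), 0.0]
        cases.append(
            {
                "case_id": f"case{i:04d}",
                "reference": {"AA": [float(aa[0]), float(aa[1])],
                              "DA": [float(da[0]), float(da[1])]},
                "landmarks": landmarks,
            }
        )
    return cases


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write ground truth as JSON (masks summarized as voxel counts, not stored)."""
    payload = {
        "reference": {
            "AA": list(truth.aa_center_mm),
            "DA": list(truth.da_center_mm),
            "delta_mm": truth.delta_mm,
            "theta_deg": truth.theta_deg,
            "aa_radius_mm": truth.aa_radius_mm,
            "da_radius_mm": truth.da_radius_mm,
        },
        "landmarks": {k: list(v) for k, v in truth.target_centers_mm.items()},
        "realized_distances": {
            k: list(v) for k, v in truth.realized_distances.items()
        },
        "decoys": [list(d) for d in truth.decoy_centers_mm],
        "mask_voxels": {k: int(m.sum()) for k, m in truth.target_masks.items()},
        "spacing": list(truth.spacing),
        "origin": list(truth.origin),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def truth_label_volume(truth: GroundTruth) -> CTVolume:
    """Per-label masks rendered as one integer label volume (1..5 in label order)."""
    first = next(iter(truth.target_masks.values()))
    labels = np.zeros(first.shape, dtype=np.int16)
    for idx, label in enumerate(LANDMARK_LABELS, start=1):
        labels[truth.target_masks[label]] = idx
    return CTVolume(labels, spacing=truth.spacing, origin=truth.origin)
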