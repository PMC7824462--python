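"""Detection of the ascending and descending aorta (the reference objects).

In an axial CT slice the two aortae appear as large, near-circular
cross-sections of the candidate mask. Per slice, connected components are
scored by how isotropic they are (ratio of covariance eigenvalues, ~1 for a
circle) and every ordered pair of components is additionally scored by a
geometric prior on the centroid separation delta and the angle theta of the
AA->DA vector against the +x axis. The argmax ordered pair is taken as
(AA, DA); the ordering itself disambiguates the two vessels because the
angle prior is directional. The per-slice centroids are then fitted with a
robust 3D line per vessel, giving reference axes that span the volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .geometry import angle_deg
from .priors import PriorTable
from .volume import CTVolume

MIN_REGION_AREA_MM2 = 50.0  # aortic cross-sections are far larger; kills speckle
MIN_REGION_PIXELS = 3
_STRUCTURE_2D = np.ones((3, 3), dtype=bool)  # 8-connectivity

OUTLIER_SD = 2.5
MAX_OUTLIER_ROUNDS = 5


class CoincidentCentroidsError(ValueError):
    """Angle between coincident centroids is undefined."""


class AxisFitError(ValueError):
    """Too few accepted slices to fit a reference axis."""


@dataclass(frozen=True)
class CandidateRegion2D:
    """A connected component of the candidate mask on one axial slice."""

    slice_index: int
    pixel_count: int
    centroid_mm: tuple[float, float]  # in-slice (x, y)
    covariance_mm2: np.ndarray  # 2x2, population covariance of pixel coords
    eigenvalues: tuple[float, float]  # lambda1 <= lambda2

    @property
    def isotropy_ratio(self) -> float:
        lam1, lam2 = self.eigenvalues
        if lam2 <= 0.0:
            return 0.0
        return lam1 / lam2


@dataclass(frozen=True)
class SliceDetection:
    """The winning (AA, DA) pair on one slice with its joint log-score."""

    slice_index: int
    aa: CandidateRegion2D
    da: CandidateRegion2D
    score: float


@dataclass(frozen=True)
class ReferenceAxis:
    """A 3D line in mm: point + unit direction with positive z-component."""

    point_mm: np.ndarray
    direction: np.ndarray

    def at_z(self, z_mm: float) -> np.ndarray:
        """Point on the axis at physical height ``z_mm``."""
        t = (z_mm - self.point_mm[2]) / self.direction[2]
        return self.point_mm + t * self.direction


@dataclass(frozen=True)
class ReferenceAxes:
    """Fitted AA and DA axes plus per-slice detections and a mid-volume summary."""

    aa: ReferenceAxis
    da: ReferenceAxis
    detections: tuple[SliceDetection, ...]
    delta_mm: float  # AA-DA separation at the mid-volume slice
    theta_deg: float  # AA->DA angle at the mid-volume slice
    z_range_mm: tuple[float, float]


def extract_regions_2d(
    mask_slice: np.ndarray,
    spacing_xy: Sequence[float],
    slice_index: int = 0,
    min_area_mm2: float = MIN_REGION_AREA_MM2,
) -> list[CandidateRegion2D]:
    """Label a binary axial slice and compute per-component shape statistics.

    ``mask_slice`` is indexed ``[j, i]`` (y, x); centroids and covariances are
    returned in mm. Components smaller than ``min_area_mm2`` or with fewer
    than 3 pixels are dropped.
    """
    sx, sy = float(spacing_xy[0]), float(spacing_xy[1])
    labels, n = ndimage.label(mask_slice, structure=_STRUCTURE_2D)
    if n == 0:
        return []
    pixel_area = sx * sy
    regions: list[CandidateRegion2D] = []
    objects = ndimage.find_objects(labels)
    for lab, slc in enumerate(objects, start=1):
        if slc is None:
            continue
        jj, ii = np.nonzero(labels[slc] == lab)
        count = jj.size
        if count < MIN_REGION_PIXELS or count * pixel_area < min_area_mm2:
            continue
        x = (ii + slc[1].start) * sx
        y = (jj + slc[0].start) * sy
        coords = np.stack([x, y])
        centroid = coords.mean(axis=1)
        cov = np.cov(coords, ddof=0)
        eigvals = np.linalg.eigvalsh(cov)
        eigvals = np.clip(eigvals, 0.0, None)
        regions.append(
            CandidateRegion2D(
                slice_index=slice_index,
                pixel_count=int(count),
                centroid_mm=(float(centroid[0]), float(centroid[1])),
                covariance_mm2=cov,
                eigenvalues=(float(eigvals[0]), float(eigvals[1])),
            )
        )
    return regions


def isotropy_ratio(region: CandidateRegion2D) -> float:
    """lambda1/lambda2 of the region's coordinate covariance (1 = circular)."""
    return region.isotropy_ratio


def pair_shape_loglik(r_a: float, r_d: float, sigma_r: float) -> float:
    """Joint log-likelihood of two isotropy ratios against the circular ideal."""
    return -((1.0 - r_a) ** 2 + (1.0 - r_d) ** 2) / sigma_r**2


def pair_geometry_logprior(
    centroid_a: Sequence[float], centroid_d: Sequence[float], prior: PriorTable
) -> float:
    """Log-prior of an ordered (AA, DA) centroid pair from (delta, theta).

    theta is the angle of the directed AA->DA vector against the +x axis in
    degrees folded to [0, 360), so the reversed ordering is a distinct (and
    heavily penalized) hypothesis.
    """
    a = np.asarray(centroid_a, dtype=float)
    d = np.asarray(centroid_d, dtype=float)
    diff = d - a
    delta = float(np.linalg.norm(diff))
    if delta == 0.0:
        raise CoincidentCentroidsError("coincident centroids: angle undefined")
    theta = angle_deg(diff)
    return -(
        (1.0 - delta / prior.delta_bar) ** 2 / prior.sigma_delta**2
        + (1.0 - theta / prior.theta_bar) ** 2 / prior.sigma_theta**2
    )


def detect_references_slice(
    regions: Sequence[CandidateRegion2D], prior: PriorTable
) -> SliceDetection | None:
    """Pick the ordered region pair maximizing shape likelihood + geometry prior.

    Returns ``None`` (no-detection) when fewer than two regions are available.
    Ties break on the lexicographically smallest index pair for determinism.
    """
    if len(regions) < 2:
        return None
    best: tuple[float, int, int] | None = None
    for i, reg_a in enumerate(regions):
        for j, reg_d in enumerate(regions):
            if i == j:
                continue
            score = pair_shape_loglik(
                reg_a.isotropy_ratio, reg_d.isotropy_ratio, prior.sigma_r
            ) + pair_geometry_logprior(reg_a.centroid_mm, reg_d.centroid_mm, prior)
            key = (score, -i, -j)
            if best is None or key > (best[0], -best[1], -best[2]):
                best = (score, i, j)
    assert best is not None
    score, i, j = best
    return SliceDetection(
        slice_index=regions[i].slice_index, aa=regions[i], da=regions[j], score=score
    )


def _fit_line_robust(points: np.ndarray) -> ReferenceAxis:
    """Least-squares 3D line x(z), y(z) with iterative in-plane outlier rejection."""
    pts = points.copy()
    keep = np.ones(len(pts), dtype=bool)
    for _ in range(MAX_OUTLIER_ROUNDS):
        z = pts[keep, 2]
        coeffs_x = np.polyfit(z, pts[keep, 0], 1)
        coeffs_y = np.polyfit(z, pts[keep, 1], 1)
        res = np.hypot(
            pts[:, 0] - np.polyval(coeffs_x, pts[:, 2]),
            pts[:, 1] - np.polyval(coeffs_y, pts[:, 2]),
        )
        sd = res[keep].std()
        if sd <= 1e-9:
            break
        new_keep = res <= OUTLIER_SD * sd
        new_keep &= keep  # rejection only shrinks the accepted set
        if new_keep.sum() < 3 or np.array_equal(new_keep, keep):
            break
        keep = new_keep
    if keep.sum() < 3:
        raise AxisFitError("fewer than 3 accepted slices after outlier rejection")
    z0 = float(pts[keep, 2].mean())
    point = np.array([np.polyval(coeffs_x, z0), np.polyval(coeffs_y, z0), z0])
    direction = np.array([coeffs_x[0], coeffs_y[0], 1.0])
    direction /= np.linalg.norm(direction)
    return ReferenceAxis(point_mm=point, direction=direction)


def fit_reference_axes(
    detections: Iterable[SliceDetection], volume: CTVolume
) -> ReferenceAxes:
    """Fit robust 3D lines to the per-slice AA and DA centroids."""
    dets = sorted(detections, key=lambda d: d.slice_index)
    if len(dets) < 3:
        raise AxisFitError(f"need detections on >= 3 slices, got {len(dets)}")
    z = np.array([volume.slice_z_mm(d.slice_index) for d in dets])
    aa_pts = np.column_stack(
        [[d.aa.centroid_mm[0] for d in dets], [d.aa.centroid_mm[1] for d in dets], z]
    )
    da_pts = np.column_stack(
        [[d.da.centroid_mm[0] for d in dets], [d.da.centroid_mm[1] for d in dets], z]
    )
    aa_axis = _fit_line_robust(aa_pts)
    da_axis = _fit_line_robust(da_pts)

    mid_z = volume.slice_z_mm((volume.n_slices - 1) // 2)
    aa_mid = aa_axis.at_z(mid_z)
    da_mid = da_axis.at_z(mid_z)
    diff = da_mid[:2] - aa_mid[:2]
    return ReferenceAxes(
        aa=aa_axis,
        da=da_axis,
        detections=tuple(dets),
        delta_mm=float(np.linalg.norm(diff)),
        theta_deg=angle_deg(diff),
        z_range_mm=(float(z.min()), float(z.max())),
    )


def detect_references(
    volume: CTVolume, mask: np.ndarray, prior: PriorTable
) -> ReferenceAxes:
    """Run per-slice reference detection over the whole mask and fit the axes."""
    sx, sy = volume.spacing[0], volume.spacing[1]
    detections = []
    for k in range(volume.n_slices):
        regions = extract_regions_2d(mask[k], (sx, sy), slice_index=k)
        det = detect_references_slice(regions, prior)
        if det is not None:
            detections.append(det)
    return fit_reference_axes(detections, volume)
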