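"""Relative-distance similarity maps and MAP assignment of the five targets.

The pulmonary veins and the LAA have no crisp boundary, so they are not
detected as shapes. Instead every pixel gets a per-label similarity built
from ratios of distances: with the two reference centroids at a slice, the
triple (d_AA, d_DA, d_AADA) is first rescaled by the patient's reference
size — distances are multiplied by delta_bar/d_AADA, mapping the scene onto
the mean reference separation — and the rescaled distances are scored
against the learned per-label Gaussians:

    f_k(x, y) = -|d_AA * delta_bar/d_AADA - mu_kAA|^2 / sigma_kAA^2
                -|d_DA * delta_bar/d_AADA - mu_kDA|^2 / sigma_kDA^2.

Each term depends only on the dimensionless ratios d_AA/d_AADA and
d_DA/d_AADA, so the map is invariant to rigid rotation, translation and
uniform scaling of the scene — the prior "follows" the patient's reference
geometry. The two-circle ambiguity is resolved by
masking the half-plane on the wrong side of the AA->DA axis.

Suprathreshold voxels inside the intensity candidate mask form 3D connected
candidate objects; the five labels are then assigned to candidates by
maximizing an intensity likelihood (candidates should look like contrast)
plus a complete-graph prior on all pairwise inter-landmark distances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .intensity import IntensityModel
from .priors import PriorTable
from .reference import ReferenceAxes
from .volume import CTVolume, LANDMARK_LABELS, LandmarkResult

MIN_CANDIDATE_VOXELS = 10
MAX_CANDIDATES = 20  # pre-pruning cap before assignment search
_STRUCTURE_3D = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


class InsufficientCandidatesError(ValueError):
    """Not enough candidate objects to assign all five labels."""


@dataclass(frozen=True)
class SimilarityMap:
    """Per-label relative-distance similarity on one axial slice (log units)."""

    label: str
    slice_index: int
    values: np.ndarray  # (ny, nx); wrong-side half-plane is -inf
    ref_a_mm: tuple[float, float]
    ref_d_mm: tuple[float, float]


@dataclass(frozen=True)
class CandidateObject3D:
    """A 26-connected set of suprathreshold voxels with summary statistics."""

    index: int
    voxel_count: int
    centroid_mm: tuple[float, float, float]
    mean_intensity: float
    peak_similarity: float
    supporting_labels: frozenset[str]


@dataclass(frozen=True)
class Assignment:
    """An injective label -> candidate mapping with its score decomposition."""

    mapping: Mapping[str, CandidateObject3D]
    intensity_term: float
    geometry_term: float

    @property
    def total(self) -> float:
        return self.intensity_term + self.geometry_term


def relative_distance_feature(
    point: Sequence[float], ref_a: Sequence[float], ref_d: Sequence[float]
) -> tuple[float, float, float]:
    """(d_AA, d_DA, d_AADA) in mm for one 2D point and the two references."""
    p = np.asarray(point, dtype=float)
    a = np.asarray(ref_a, dtype=float)
    d = np.asarray(ref_d, dtype=float)
    return (
        float(np.linalg.norm(p - a)),
        float(np.linalg.norm(p - d)),
        float(np.linalg.norm(a - d)),
    )


def similarity_values(
    x_mm: np.ndarray,
    y_mm: np.ndarray,
    ref_a: Sequence[float],
    ref_d: Sequence[float],
    prior: PriorTable,
    label: str,
) -> np.ndarray:
    """Vectorized f_k over arbitrary coordinate arrays (broadcastable x, y)."""
    ax, ay = float(ref_a[0]), float(ref_a[1])
    dx, dy = float(ref_d[0]), float(ref_d[1])
    d_ad = np.hypot(dx - ax, dy - ay)
    d_a = np.hypot(x_mm - ax, y_mm - ay)
    d_d = np.hypot(x_mm - dx, y_mm - dy)

    mu_a, sig_a = prior.distance_params(label, "AA")
    mu_d, sig_d = prior.distance_params(label, "DA")
    scale = prior.delta_bar / d_ad  # undo the patient's reference scale
    f = -((d_a * scale - mu_a) ** 2) / sig_a**2 - (
        (d_d * scale - mu_d) ** 2
    ) / sig_d**2

    # directional disambiguation: drop the mirror solution across the AA-DA axis
    mx, my = 0.5 * (ax + dx), 0.5 * (ay + dy)
    cross = (dx - ax) * (y_mm - my) - (dy - ay) * (x_mm - mx)
    side = prior.side_signs[label]
    return np.where(np.sign(cross) == side, f, -np.inf)


def similarity_map(
    volume: CTVolume,
    slice_index: int,
    axes: ReferenceAxes,
    prior: PriorTable,
    label: str,
) -> SimilarityMap:
    """Compute the per-label similarity map on one axial slice.

    Reference centroids are read off the fitted axes at the slice height,
    not from the raw per-slice detections, so slices where the per-slice
    pair search failed still get a map.
    """
    z_mm = volume.slice_z_mm(slice_index)
    ref_a = axes.aa.at_z(z_mm)[:2]
    ref_d = axes.da.at_z(z_mm)[:2]
    nz, ny, nx = volume.shape_zyx
    x = volume.origin[0] + np.arange(nx) * volume.spacing[0]
    y = volume.origin[1] + np.arange(ny) * volume.spacing[1]
    values = similarity_values(
        x[np.newaxis, :], y[:, np.newaxis], ref_a, ref_d, prior, label
    )
    return SimilarityMap(
        label=label,
        slice_index=slice_index,
        values=values,
        ref_a_mm=(float(ref_a[0]), float(ref_a[1])),
        ref_d_mm=(float(ref_d[0]), float(ref_d[1])),
    )


def candidate_objects(
    volume: CTVolume,
    mask: np.ndarray,
    axes: ReferenceAxes,
    prior: PriorTable,
    alpha: float | None = None,
    min_voxels: int = MIN_CANDIDATE_VOXELS,
    despeckle: bool = True,
) -> list[CandidateObject3D]:
    """Threshold the pooled similarity maps and extract 3D candidate objects.

    A voxel is selected iff max_k f_k >= alpha and it lies in the intensity
    candidate mask; 26-connected components of the selection become
    candidates, each recording which labels' maps supported it.

    ``despeckle`` applies one binary opening (6-connected cross) to the
    selected voxel set before component analysis. The candidate-mask band
    keeps the upper tail of the background class by construction, and that
    suprathreshold speckle sits above the 26-connectivity percolation
    threshold — without the opening it would chain into arbitrarily large
    components that swallow genuine targets. Solid target-sized objects pass
    through an opening essentially unchanged.
    """
    if alpha is None:
        alpha = prior.alpha
    nz, ny, nx = volume.shape_zyx
    z_lo, z_hi = axes.z_range_mm
    max_sim = np.full((nz, ny, nx), -np.inf, dtype=np.float32)
    supra = {k: np.zeros((nz, ny, nx), dtype=bool) for k in LANDMARK_LABELS}
    for k in range(nz):
        z_mm = volume.slice_z_mm(k)
        if not (z_lo <= z_mm <= z_hi):
            continue
        for label in LANDMARK_LABELS:
            smap = similarity_map(volume, k, axes, prior, label)
            supra[label][k] = smap.values >= alpha
            np.maximum(max_sim[k], smap.values.astype(np.float32), out=max_sim[k])

    selected = (max_sim >= alpha) & mask
    if despeckle:
        cross = ndimage.generate_binary_structure(3, 1)
        selected = ndimage.binary_opening(selected, structure=cross)
    labels_arr, n = ndimage.label(selected, structure=_STRUCTURE_3D)
    out: list[CandidateObject3D] = []
    if n == 0:
        return out
    intensities = np.asarray(volume.intensities, dtype=np.float64)
    for lab, slc in enumerate(ndimage.find_objects(labels_arr), start=1):
        if slc is None:
            continue
        kk, jj, ii = np.nonzero(labels_arr[slc] == lab)
        if kk.size < min_voxels:
            continue
        kk = kk + slc[0].start
        jj = jj + slc[1].start
        ii = ii + slc[2].start
        centroid_idx = np.array([ii.mean(), jj.mean(), kk.mean()])
        centroid = volume.index_to_physical(centroid_idx)
        member = (kk, jj, ii)
        supporting = frozenset(
            k for k in LANDMARK_LABELS if supra[k][member].any()
        )
        out.append(
            CandidateObject3D(
                index=len(out),
                voxel_count=int(kk.size),
                centroid_mm=tuple(float(c) for c in centroid),
                mean_intensity=float(intensities[member].mean()),
                peak_similarity=float(max_sim[member].max()),
                supporting_labels=supporting,
            )
        )
    return out


def intensity_loglik(candidate: CandidateObject3D, model: IntensityModel) -> float:
    """Contrast likelihood: penalize mean intensity away from the foreground."""
    return -((model.mu_f - candidate.mean_intensity) ** 2) / model.sigma_f**2


def assignment_logprior(
    assignment: Mapping[str, CandidateObject3D], prior: PriorTable
) -> float:
    """Complete-graph prior over all 10 pairwise inter-landmark distances."""
    total = 0.0
    for a, b in itertools.combinations(LANDMARK_LABELS, 2):
        mu, sigma = prior.pairwise_params(a, b)
        pa = np.asarray(assignment[a].centroid_mm)
        pb = np.asarray(assignment[b].centroid_mm)
        dist = float(np.linalg.norm(pa - pb))
        total += -((mu - dist) ** 2) / sigma**2
    return total


def _pair_term(
    ca: CandidateObject3D, cb: CandidateObject3D, mu: float, sigma: float
) -> float:
    dist = float(
        np.linalg.norm(np.asarray(ca.centroid_mm) - np.asarray(cb.centroid_mm))
    )
    return -((mu - dist) ** 2) / sigma**2


def score_assignment(
    assignment: Mapping[str, CandidateObject3D],
    prior: PriorTable,
    model: IntensityModel,
) -> Assignment:
    """Score a complete 5-label assignment with its printed decomposition."""
    intensity = sum(intensity_loglik(assignment[k], model) for k in LANDMARK_LABELS)
    geometry = assignment_logprior(assignment, prior)
    return Assignment(
        mapping=dict(assignment), intensity_term=intensity, geometry_term=geometry
    )


def localize_targets(
    candidates: Sequence[CandidateObject3D],
    prior: PriorTable,
    model: IntensityModel,
    max_candidates: int = MAX_CANDIDATES,
) -> tuple[list[LandmarkResult], Assignment]:
    """MAP-assign the five labels to distinct candidates.

    Each label may only take candidates whose similarity map supported it;
    candidates are pre-pruned to the ``max_candidates`` highest peak
    similarities, then a branch-and-bound search (exact: geometry terms are
    never positive, so the partial-sum plus best remaining intensity terms is
    a valid upper bound) finds the argmax over injective assignments. Exact
    score ties break on the lexicographically smallest candidate-index tuple.
    """
    if len(candidates) < 5:
        missing = [
            k
            for k in LANDMARK_LABELS
            if not any(k in c.supporting_labels for c in candidates)
        ]
        raise InsufficientCandidatesError(
            f"need >= 5 candidates, got {len(candidates)}; "
            f"labels without support: {missing or 'n/a'}"
        )
    pool = sorted(candidates, key=lambda c: (-c.peak_similarity, c.index))[
        :max_candidates
    ]
    options = {
        k: [c for c in pool if k in c.supporting_labels] for k in LANDMARK_LABELS
    }
    empty = [k for k, v in options.items() if not v]
    if empty:
        raise InsufficientCandidatesError(
            f"labels without any supporting candidate: {empty}"
        )

    ll = {c.index: intensity_loglik(c, model) for c in pool}
    pair_cache: dict[tuple[int, int, str, str], float] = {}

    def pair_term(label_a: str, ca: CandidateObject3D, label_b: str, cb: CandidateObject3D) -> float:
        key = (ca.index, cb.index, label_a, label_b)
        if key not in pair_cache:
            mu, sigma = prior.pairwise_params(label_a, label_b)
            pair_cache[key] = _pair_term(ca, cb, mu, sigma)
        return pair_cache[key]

    # search labels with the fewest options first; report in canonical order
    order = sorted(LANDMARK_LABELS, key=lambda k: len(options[k]))
    best_score = -np.inf
    best_tuple: tuple[int, ...] | None = None
    best_map: dict[str, CandidateObject3D] | None = None

    def canonical_tuple(mapping: Mapping[str, CandidateObject3D]) -> tuple[int, ...]:
        return tuple(mapping[k].index for k in LANDMARK_LABELS)

    def recurse(depth: int, partial: dict[str, CandidateObject3D], score: float) -> None:
        nonlocal best_score, best_tuple, best_map
        if depth == len(order):
            tup = canonical_tuple(partial)
            if score > best_score or (score == best_score and (best_tuple is None or tup < best_tuple)):
                best_score = score
                best_tuple = tup
                best_map = dict(partial)
            return
        label = order[depth]
        used = {c.index for c in partial.values()}
        # upper bound: remaining labels at their best intensity term, geometry <= 0
        bound_rest = 0.0
        for later in order[depth:]:
            avail = [ll[c.index] for c in options[later] if c.index not in used]
            if not avail:
                return
            bound_rest += max(avail)
        if score + bound_rest < best_score:
            return
        for cand in options[label]:
            if cand.index in used:
                continue
            inc = ll[cand.index]
            for assigned_label, assigned_cand in partial.items():
                inc += pair_term(label, cand, assigned_label, assigned_cand)
            recurse(depth + 1, {**partial, label: cand}, score + inc)

    recurse(0, {}, 0.0)
    if best_map is None:
        raise InsufficientCandidatesError(
            "no injective assignment exists for the five labels"
        )
    assignment = score_assignment(best_map, prior, model)
    results = [
        LandmarkResult(
            label=k,
            position_mm=best_map[k].centroid_mm,
            score=assignment.total,
            voxel_count=best_map[k].voxel_count,
        )
        for k in LANDMARK_LABELS
    ]
    return results, assignment
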