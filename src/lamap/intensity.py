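"""Patient-specific intensity adaptation.

Contrast density varies from scan to scan, so the foreground (contrast-filled
blood pool) and background (soft tissue) intensity statistics are estimated
per volume: voxels at or below 0 HU (air, lung, fat) are discarded and the
remaining values are split into two clusters by 1-D k-means minimizing the
within-cluster sum of squares. The cluster statistics define the candidate
mask thresholds

    I1 = min(muB + sigmaB, muF - sigmaF),   I2 = muF + sigmaF,

and the foreground parameters later feed the target intensity likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import CTVolume

# Above this voxel count the clustering runs on a 1-HU-binned histogram
# (weighted k-means) instead of raw samples; identical to within bin width.
HISTOGRAM_VOXEL_THRESHOLD = 10_000_000
SIGMA_FLOOR_HU = 1.0  # degenerate-cluster deviation floor


class NoContrastError(ValueError):
    """No voxels above 0 HU: nothing to cluster."""


class DegenerateHistogramError(ValueError):
    """Fewer than two distinct positive intensity values."""


@dataclass(frozen=True)
class IntensityModel:
    """Foreground/background intensity statistics and derived mask thresholds."""

    mu_b: float
    sigma_b: float
    mu_f: float
    sigma_f: float

    def __post_init__(self) -> None:
        if not self.mu_b < self.mu_f:
            raise ValueError(f"need mu_b < mu_f, got {self.mu_b} >= {self.mu_f}")
        if self.sigma_b <= 0 or self.sigma_f <= 0:
            raise ValueError("deviations must be positive")
        if not self.i1 < self.i2:
            raise ValueError(f"thresholds must satisfy I1 < I2, got {self.i1}, {self.i2}")

    @property
    def i1(self) -> float:
        return min(self.mu_b + self.sigma_b, self.mu_f - self.sigma_f)

    @property
    def i2(self) -> float:
        return self.mu_f + self.sigma_f


def _kmeans_1d_two(values: np.ndarray, weights: np.ndarray) -> float:
    """Deterministic two-cluster 1-D Lloyd iteration on weighted samples.

    Centers start at the (weighted) 25th and 75th percentiles; returns the
    final boundary (midpoint of the converged centers). With sorted 1-D data
    the two clusters are always split by a single threshold.
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    cum = np.cumsum(w)
    total = cum[-1]

    def weighted_quantile(q: float) -> float:
        return float(v[np.searchsorted(cum, q * total, side="left")])

    c_lo, c_hi = weighted_quantile(0.25), weighted_quantile(0.75)
    if c_lo == c_hi:  # degenerate start; spread to the extremes
        c_lo, c_hi = float(v[0]), float(v[-1])
    for _ in range(300):
        boundary = 0.5 * (c_lo + c_hi)
        split = np.searchsorted(v, boundary, side="right")
        if split == 0 or split == len(v):  # keep both clusters non-empty
            split = max(1, min(len(v) - 1, split))
        w_lo = cum[split - 1]
        new_lo = float(np.dot(v[:split], w[:split]) / w_lo)
        new_hi = float(np.dot(v[split:], w[split:]) / (total - w_lo))
        if abs(new_lo - c_lo) < 1e-6 and abs(new_hi - c_hi) < 1e-6:
            c_lo, c_hi = new_lo, new_hi
            break
        c_lo, c_hi = new_lo, new_hi
    return 0.5 * (c_lo + c_hi)


def _weighted_stats(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    total = weights.sum()
    mean = float(np.dot(values, weights) / total)
    var = float(np.dot((values - mean) ** 2, weights) / total)
    return mean, np.sqrt(var)


def estimate_intensity_model(volume: CTVolume) -> IntensityModel:
    """Fit the two-cluster intensity model to a volume's positive-HU voxels."""
    data = np.asarray(volume.intensities, dtype=np.float64).ravel()
    positive = data[data > 0]
    if positive.size == 0:
        raise NoContrastError("all voxels are <= 0 HU; no contrast region found")
    if np.unique(positive).size < 2:
        raise DegenerateHistogramError(
            "need >= 2 distinct positive intensity values to separate tissue classes"
        )
    if positive.size > HISTOGRAM_VOXEL_THRESHOLD:
        lo = np.floor(positive.min())
        edges = np.arange(lo, np.ceil(positive.max()) + 1.0)  # 1-HU bins
        counts, _ = np.histogram(positive, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = counts > 0
        values, weights = centers[keep], counts[keep].astype(np.float64)
    else:
        values, weights = positive, np.ones_like(positive)

    boundary = _kmeans_1d_two(values, weights)
    lo_mask = values <= boundary
    mu_b, sigma_b = _weighted_stats(values[lo_mask], weights[lo_mask])
    mu_f, sigma_f = _weighted_stats(values[~lo_mask], weights[~lo_mask])
    sigma_b = max(sigma_b, SIGMA_FLOOR_HU)
    sigma_f = max(sigma_f, SIGMA_FLOOR_HU)
    return IntensityModel(mu_b=mu_b, sigma_b=sigma_b, mu_f=mu_f, sigma_f=sigma_f)


def candidate_mask(volume: CTVolume, model: IntensityModel) -> np.ndarray:
    """Binary mask of voxels inside [I1, I2], inclusive at both ends."""
    arr = volume.intensities
    return (arr >= model.i1) & (arr <= model.i2)
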