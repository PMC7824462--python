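"""Core data containers and file I/O for CT volumes and landmark results.

Conventions used throughout the package:

* Voxel indices are 0-based ``(i, j, k)`` along the ``(x, y, z)`` axes.
* The intensity grid is stored as a numpy array indexed ``[k, j, i]`` (z, y, x),
  so ``volume.intensities[k]`` is the axial slice at z-index ``k``.
* Physical coordinates are millimetres: ``position = origin + index * spacing``.
* All geometry downstream (distances, angles, priors) is computed in mm.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

LANDMARK_LABELS = ("LSPV", "LIPV", "RSPV", "RIPV", "LAA")


class VolumeFormatError(ValueError):
    """Unsupported or unreadable volume file."""


class VolumeMetadataError(ValueError):
    """Volume file lacks usable spacing/origin metadata."""


class LandmarkValidationError(ValueError):
    """Landmark result set violates the output contract."""


@dataclass(frozen=True)
class CTVolume:
    """A 3D CT scalar field in Hounsfield units with axis-aligned geometry.

    Parameters
    ----------
    intensities
        Array of shape ``(nz, ny, nx)``; axial slice = fixed first index.
    spacing
        Voxel spacing in mm per axis, ordered ``(sx, sy, sz)``.
    origin
        Physical position (mm) of voxel index ``(0, 0, 0)``, ordered ``(x, y, z)``.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3:
            raise ValueError(f"intensities must be 3D, got shape {arr.shape}")
        nz, ny, nx = arr.shape
        if nz < 1 or ny < 2 or nx < 2:
            raise ValueError(
                f"volume needs >=1 slice of >=2x2 pixels, got shape {arr.shape}"
            )
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values: {self.spacing}")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[0]

    def index_to_physical(self, index_xyz: Sequence[float]) -> np.ndarray:
        """Map a (possibly fractional) 0-based voxel index (i, j, k) to mm."""
        idx = np.asarray(index_xyz, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def physical_to_index(self, position_mm: Sequence[float]) -> np.ndarray:
        """Inverse of :meth:`index_to_physical` (fractional indices)."""
        pos = np.asarray(position_mm, dtype=float)
        return (pos - np.asarray(self.origin)) / np.asarray(self.spacing)

    def slice_z_mm(self, k: int) -> float:
        """Physical z coordinate (mm) of axial slice ``k``."""
        return self.origin[2] + k * self.spacing[2]

    def contains_physical(self, position_mm: Sequence[float]) -> bool:
        idx = self.physical_to_index(position_mm)
        nz, ny, nx = self.intensities.shape
        limits = (nx - 1, ny - 1, nz - 1)
        return all(-0.5 <= idx[a] <= limits[a] + 0.5 for a in range(3))


@dataclass(frozen=True)
class LandmarkResult:
    """A localized landmark: label, physical position and its MAP score."""

    label: str
    position_mm: tuple[float, float, float]
    score: float
    voxel_count: int

    def __post_init__(self) -> None:
        if self.label not in LANDMARK_LABELS:
            raise LandmarkValidationError(f"unknown landmark label {self.label!r}")
        object.__setattr__(
            self, "position_mm", tuple(float(v) for v in self.position_mm)
        )


def _sitk():
    import SimpleITK as sitk  # deferred: keeps numpy-only use light

    return sitk


_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise VolumeFormatError(
            f"unsupported volume format {path.name!r}; expected one of {_SUPPORTED_SUFFIXES}"
        )


def read_volume(path: str | Path) -> CTVolume:
    """Read a NIfTI or MetaImage volume into a :class:`CTVolume`.

    Intensities are returned exactly as stored (after the format's own
    slope/intercept, which SimpleITK applies); no rescaling is performed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_suffix(path)
    sitk = _sitk()
    try:
        image = sitk.ReadImage(str(path))
    except Exception as exc:  # SimpleITK raises RuntimeError on corrupt headers
        raise VolumeMetadataError(f"cannot read volume {path}: {exc}") from exc
    if image.GetDimension() != 3:
        raise VolumeMetadataError(
            f"{path}: expected a 3D volume, got {image.GetDimension()}D"
        )
    spacing = image.GetSpacing()  # (sx, sy, sz)
    if any(not math.isfinite(s) or s <= 0 for s in spacing):
        raise VolumeMetadataError(f"{path}: invalid voxel spacing {spacing}")
    arr = sitk.GetArrayFromImage(image)  # (z, y, x)
    return CTVolume(arr, spacing=spacing, origin=image.GetOrigin())


def write_volume(volume: CTVolume, path: str | Path) -> None:
    """Write a :class:`CTVolume` as NIfTI or MetaImage, chosen by suffix."""
    path = Path(path)
    _check_suffix(path)
    sitk = _sitk()
    image = sitk.GetImageFromArray(np.ascontiguousarray(volume.intensities))
    image.SetSpacing(volume.spacing)
    image.SetOrigin(volume.origin)
    sitk.WriteImage(image, str(path))


def write_landmarks(results: Sequence[LandmarkResult], path: str | Path) -> None:
    """Write a complete 5-landmark result set as structured JSON text.

    All five labels must be present exactly once with finite positions;
    :func:`read_landmarks` inverts the file exactly.
    """
    labels = [r.label for r in results]
    if sorted(labels) != sorted(LANDMARK_LABELS):
        missing = set(LANDMARK_LABELS) - set(labels)
        dupes = {l for l in labels if labels.count(l) > 1}
        raise LandmarkValidationError(
            f"need each label exactly once; missing={sorted(missing)} duplicated={sorted(dupes)}"
        )
    for r in results:
        if not all(math.isfinite(v) for v in r.position_mm) or not math.isfinite(r.score):
            raise LandmarkValidationError(f"non-finite values in result for {r.label}")
    payload = {
        "landmarks": [
            {
                "label": r.label,
                "position_mm": list(r.position_mm),
                "score": r.score,
                "voxel_count": r.voxel_count,
            }
            for r in results
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_landmarks(path: str | Path) -> list[LandmarkResult]:
    """Read a landmark JSON file written by :func:`write_landmarks`."""
    payload = json.loads(Path(path).read_text())
    return [
        LandmarkResult(
            label=rec["label"],
            position_mm=tuple(rec["position_mm"]),
            score=rec["score"],
            voxel_count=rec["voxel_count"],
        )
        for rec in payload["landmarks"]
    ]
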