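"""Grid-aligned volumetric containers.

Conventions used throughout the package:

* arrays are indexed ``[i, j, k]`` with one index per spatial axis;
* ``origin`` is the world-space (mm) position of the *corner* of voxel
  ``(0, 0, 0)``, so the center of voxel ``(i, j, k)`` sits at
  ``origin + (index + 0.5) * spacing``;
* all geometric predicates (sphere/cylinder masks, peak kernels) use
  voxel-center inclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["UptakeVolume", "VoiMask"]

VALID_UNITS = ("Bq/mL", "SUV", "SUL")


@dataclass
class UptakeVolume:
    """A 3D scalar uptake field on a regular grid.

    Parameters
    ----------
    data
        3D array of voxel values (activity concentration, SUV or SUL).
    spacing
        Voxel edge lengths in mm, one per axis.
    origin
        World coordinate (mm) of the corner of voxel (0, 0, 0).
    unit
        One of ``"Bq/mL"``, ``"SUV"``, ``"SUL"``.
    modality
        Optional acquisition tag, ``"db"`` (dedicated breast) or
        ``"wb"`` (whole body).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str = "Bq/mL"
    modality: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("uptake values must be finite")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def voxel_centers(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def index_of(self, point_mm) -> tuple[int, int, int]:
        """Grid index of the voxel containing a world-space point."""
        idx = tuple(
            int(np.floor((float(p) - o) / s))
            for p, o, s in zip(point_mm, self.origin, self.spacing)
        )
        if any(i < 0 or i >= n for i, n in zip(idx, self.shape)):
            raise ValueError(f"point {tuple(point_mm)} mm falls outside the image grid")
        return idx

    def with_data(self, data: np.ndarray, unit: str | None = None) -> "UptakeVolume":
        """Copy of this volume with new voxel values (same geometry)."""
        return replace(self, data=data, unit=self.unit if unit is None else unit)

    # -- I/O ----------------------------------------------------------------

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        # NIfTI stores the world position of the first voxel *center*.
        aff[:3, 3] = [o + 0.5 * s for o, s in zip(self.origin, self.spacing)]
        return aff

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        img.header.set_xyzt_units("mm")
        nib.save(img, str(path))
        return path

    @classmethod
    def load(
        cls, path: str | Path, unit: str = "Bq/mL", modality: str | None = None
    ) -> "UptakeVolume":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        center0 = img.affine[:3, 3]
        origin = tuple(float(c - 0.5 * s) for c, s in zip(center0, spacing))
        return cls(data=data, spacing=spacing, origin=origin, unit=unit, modality=modality)


@dataclass
class VoiMask:
    """A binary volume of interest aligned to an :class:`UptakeVolume` grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    role: str = "tumor"  # tumor | background-liver | background-contralateral
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_ml(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3 / 1000.0

    def congruent_with(self, image: UptakeVolume) -> bool:
        return (
            self.shape == image.shape
            and np.allclose(self.spacing, image.spacing)
            and np.allclose(self.origin, image.origin)
        )

    def require_congruent(self, image: UptakeVolume) -> None:
        if not self.congruent_with(image):
            raise ValueError(
                f"mask geometry {self.shape}/{self.spacing} does not match "
                f"image {image.shape}/{image.spacing}"
            )

    def values_in(self, image: UptakeVolume) -> np.ndarray:
        self.require_congruent(image)
        return np.asarray(image.data)[self.data]

    def save(self, path: str | Path) -> Path:
        vol = UptakeVolume(
            data=self.data.astype(np.uint8), spacing=self.spacing, origin=self.origin,
            unit="SUV",
        )
        return vol.save(path)
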