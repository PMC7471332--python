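"""3D scalar-field containers with voxel geometry.

Conventions: 0-based, half-open voxel indexing; the world coordinate of the
center of voxel ``i`` along an axis with voxel size ``v`` is ``(i + 0.5) * v``
(millimetres). Values are floats; NaN marks failed/filtered voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ImageVolume", "T1Map", "B1Map", "voxel_centers"]


def voxel_centers(n: int, voxel_size_mm: float) -> np.ndarray:
    """World coordinates (mm) of the n voxel centers along one axis."""
    return (np.arange(n) + 0.5) * voxel_size_mm


@dataclass
class ImageVolume:
    """A 3D scalar field with isotropic-or-not voxel size in mm."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    units: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be three positive mm values, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        return tuple(n * v for n, v in zip(self.data.shape, self.voxel_size))

    def affine(self) -> np.ndarray:
        """RAS affine placing voxel (0,0,0) center at half a voxel from origin."""
        aff = np.diag([*self.voxel_size, 1.0])
        aff[:3, 3] = [0.5 * v for v in self.voxel_size]
        return aff

    def copy(self) -> "ImageVolume":
        return replace(self, data=self.data.copy())


@dataclass
class T1Map(ImageVolume):
    """Longitudinal relaxation time per voxel, ms. NaN = failed or filtered."""

    units: str = "ms"


@dataclass
class B1Map(ImageVolume):
    """Transmit-field scale factor kappa; effective flip angle = kappa * nominal."""

    units: str = ""
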