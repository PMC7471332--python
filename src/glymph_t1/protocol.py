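"""Acquisition protocols for the two scans.

Two acquisitions are modeled:

* a 3D variable-flip-angle spoiled gradient echo (VFA-SPGR) stack used for
  T1 mapping — short TR, six flip angles, fine isotropic grid;
* a two-angle (alpha, 2*alpha) RARE pair used for double-angle B1+ mapping —
  long TR (fully relaxed), coarser in-plane grid, gapped 2D slices.

Defaults reproduce a 9.4 T mouse head-and-neck protocol: TR 16 ms / TE 3 ms,
flip angles 2-30 degrees at 0.18 mm isotropic over a 100^3 matrix, and a
70/140-degree RARE pair at 0.24 mm in-plane with 36 slices of 0.3 mm
thickness separated by 0.2 mm gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import voxel_centers

__all__ = ["RareGrid", "AcquisitionProtocol", "default_protocol"]

DEFAULT_FLIP_ANGLES_DEG = (2.0, 5.0, 10.0, 15.0, 20.0, 30.0)
DEFAULT_DAM_ANGLES_DEG = (70.0, 140.0)


@dataclass(frozen=True)
class RareGrid:
    """Geometry of the gapped multi-slice RARE acquisition.

    Slice centers sit at ``(k + 0.5) * (thickness + gap)`` mm along the slice
    axis (axis 2), so 36 slices at 0.3 + 0.2 mm cover an 18 mm slab at 0.5 mm
    center-to-center spacing.
    """

    shape: tuple[int, int, int]  # (nx, ny, n_slices)
    in_plane_mm: float
    slice_thickness_mm: float
    slice_gap_mm: float

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"bad RARE grid shape {self.shape}")
        if self.in_plane_mm <= 0 or self.slice_thickness_mm <= 0 or self.slice_gap_mm < 0:
            raise ValueError("RARE grid spacings must be positive (gap may be 0)")

    @property
    def slice_spacing_mm(self) -> float:
        return self.slice_thickness_mm + self.slice_gap_mm

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """Nominal voxel size used when wrapping RARE data as an ImageVolume."""
        return (self.in_plane_mm, self.in_plane_mm, self.slice_spacing_mm)

    def axis_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of sample centers along each axis."""
        cx = voxel_centers(self.shape[0], self.in_plane_mm)
        cy = voxel_centers(self.shape[1], self.in_plane_mm)
        cz = voxel_centers(self.shape[2], self.slice_spacing_mm)
        return cx, cy, cz


@dataclass(frozen=True)
class AcquisitionProtocol:
    tr_ms: float = 16.0
    te_ms: float = 3.0
    flip_angles_deg: tuple[float, ...] = DEFAULT_FLIP_ANGLES_DEG
    dam_angles_deg: tuple[float, float] = DEFAULT_DAM_ANGLES_DEG
    dam_tr_ms: float = 10_000.0
    spgr_shape: tuple[int, int, int] = (100, 100, 100)
    spgr_voxel_mm: tuple[float, float, float] = (0.18, 0.18, 0.18)
    rare_grid: RareGrid = field(
        default_factory=lambda: RareGrid((75, 75, 36), 0.24, 0.3, 0.2)
    )

    def __post_init__(self) -> None:
        if self.tr_ms <= 0:
            raise ValueError("TR must be positive")
        fa = np.asarray(self.flip_angles_deg, dtype=float)
        if fa.size < 2 or np.any(np.diff(fa) <= 0) or fa[0] <= 0 or fa[-1] > 90:
            raise ValueError(
                "flip angles must be >= 2 strictly increasing values in (0, 90] degrees"
            )
        a1, a2 = self.dam_angles_deg
        if not np.isclose(a2, 2 * a1):
            raise ValueError("second double-angle flip must be twice the first")

    @property
    def spgr_fov_mm(self) -> tuple[float, float, float]:
        return tuple(n * v for n, v in zip(self.spgr_shape, self.spgr_voxel_mm))


def default_protocol(grid_shape: tuple[int, int, int] = (100, 100, 100),
                     fov_mm: float = 18.0) -> AcquisitionProtocol:
    """Protocol with the default timing/angles on a possibly rescaled grid.

    The field of view is held fixed at ``fov_mm`` so that coarser grids image
    the same anatomy at lower resolution (useful for fast tests); the RARE
    grid is rescaled by the same factor relative to the SPGR voxel.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    voxel = tuple(fov_mm / n for n in grid_shape)
    scale = voxel[0] / 0.18
    in_plane = 0.24 * scale
    thickness = 0.3 * scale
    gap = 0.2 * scale
    n_inplane = max(2, int(round(fov_mm / in_plane)))
    n_slices = max(2, int(round(fov_mm / (thickness + gap))))
    return AcquisitionProtocol(
        spgr_shape=grid_shape,
        spgr_voxel_mm=voxel,
        rare_grid=RareGrid((n_inplane, n_inplane, n_slices), in_plane, thickness, gap),
    )
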