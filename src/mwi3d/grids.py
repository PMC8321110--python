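"""Voxel grids shared by every volume in a run.

A grid is an axis-aligned lattice of cubic voxels.  It may be 2-D (a TM
slice used by the fast test profile) or 3-D (the full imaging volume,
64x64x64 by default).  All phantom, field and reconstruction volumes in
one pipeline run live on the same grid (or on its 2x refinement for
forward simulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid"]


@dataclass(frozen=True)
class VoxelGrid:
    """Uniform cubic-voxel lattice.

    Parameters
    ----------
    shape
        Voxel extents per axis; length 2 or 3.  Default ``(64, 64, 64)``.
    spacing
        Voxel edge length in meters (same along every axis).
    origin
        Position of the center of voxel ``(0, ..., 0)`` in meters.  By
        default the grid is centered on the coordinate origin.
    """

    shape: tuple = (64, 64, 64)
    spacing: float = 3.3e-3
    origin: tuple = None  # type: ignore[assignment]

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) not in (2, 3) or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be 2 or 3 positive extents, got {shape}")
        if not self.spacing > 0:
            raise ValueError("voxel spacing must be > 0")
        object.__setattr__(self, "shape", shape)
        if self.origin is None:
            origin = tuple(-(s - 1) / 2.0 * self.spacing for s in shape)
            object.__setattr__(self, "origin", origin)
        else:
            origin = tuple(float(o) for o in self.origin)
            if len(origin) != len(shape):
                raise ValueError("origin dimensionality must match shape")
            object.__setattr__(self, "origin", origin)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def cell_volume(self) -> float:
        """Voxel measure: area (2-D) or volume (3-D) in m^ndim."""
        return self.spacing ** self.ndim

    @property
    def extent(self) -> tuple:
        """Physical edge lengths of the grid in meters."""
        return tuple(s * self.spacing for s in self.shape)

    def axes(self) -> list:
        """Per-axis voxel-center coordinates in meters."""
        return [
            self.origin[d] + self.spacing * np.arange(self.shape[d])
            for d in range(self.ndim)
        ]

    def coords(self) -> np.ndarray:
        """Voxel-center coordinates, shape ``(*shape, ndim)``."""
        mesh = np.meshgrid(*self.axes(), indexing="ij")
        return np.stack(mesh, axis=-1)

    def refine(self, factor: int = 2) -> "VoxelGrid":
        """Grid with ``factor``x more voxels per axis covering the same box.

        Used to simulate forward data on a finer lattice than the one the
        inversion runs on, so the inverse problem is not committed as an
        inverse crime.
        """
        if factor < 1:
            raise ValueError("refinement factor must be >= 1")
        shape = tuple(s * factor for s in self.shape)
        spacing = self.spacing / factor
        # keep the box center fixed
        origin = tuple(
            self.origin[d] - self.spacing / 2.0 + spacing / 2.0
            for d in range(self.ndim)
        )
        return VoxelGrid(shape=shape, spacing=spacing, origin=origin)

    def same_as(self, other: "VoxelGrid", tol: float = 1e-12) -> bool:
        return (
            self.shape == other.shape
            and abs(self.spacing - other.spacing) <= tol
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )
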