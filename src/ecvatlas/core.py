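"""Shared voxel-grid container used by every stage of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class VoxelVolume:
    """A scalar field sampled on a regular 3-D grid.

    Index order is ``(x, y, z)``: the world position (mm) of voxel
    ``(i, j, k)`` is ``origin + (i, j, k) * spacing``, where indices are
    0-based and refer to voxel *centers*.

    Parameters
    ----------
    values
        3-D array of voxel values (any numeric dtype; masks are uint8/bool).
    spacing
        Voxel spacing in mm along (x, y, z). Must be positive.
    origin
        World coordinates (mm) of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-D, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of a single voxel in mm^3."""
        return self.spacing[0] * self.spacing[1] * self.spacing[2]

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers along each axis."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)
        )  # type: ignore[return-value]

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """World positions (N, 3) of the given (N, 3) integer voxel indices."""
        indices = np.asarray(indices)
        return np.asarray(self.origin) + indices * np.asarray(self.spacing)

    def index_of(self, points: np.ndarray) -> np.ndarray:
        """Nearest voxel index (N, 3) for world points (N, 3)."""
        points = np.atleast_2d(points)
        idx = np.rint((points - np.asarray(self.origin)) / np.asarray(self.spacing))
        return idx.astype(int)

    def like(self, values: np.ndarray) -> "VoxelVolume":
        """A new volume on the same grid holding ``values``."""
        return VoxelVolume(values, self.spacing, self.origin)

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(self.values.copy(), self.spacing, self.origin)


def same_grid(a: VoxelVolume, b: VoxelVolume, atol: float = 1e-6) -> bool:
    """True if two volumes share shape, spacing and origin."""
    return (
        a.shape == b.shape
        and np.allclose(a.spacing, b.spacing, atol=atol)
        and np.allclose(a.origin, b.origin, atol=atol)
    )
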