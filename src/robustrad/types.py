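"""Core value types shared across the pipeline.

Axis convention: arrays are indexed ``(i, j, k)`` with axis 0 = superior-inferior
(SI), axis 1 = anterior-posterior (AP) and axis 2 = left-medial (LM).  Spacing is
given in mm per axis in the same order; world coordinates are
``origin + index * spacing``, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageVolume", "Mask", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Raised when two volumes that must share a voxel grid do not."""


@dataclass
class ImageVolume:
    """A volumetric grayscale image with voxel spacing metadata.

    Parameters
    ----------
    array
        Voxel intensities, shape ``(n_si, n_ap, n_lm)``.
    spacing
        Voxel size in mm per axis, same order as the array axes.
    origin
        World coordinate of voxel ``(0, 0, 0)`` in mm.
    """

    array: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array)
        if self.array.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.array.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.array.shape

    def same_grid(self, other: "ImageVolume | Mask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def require_same_grid(self, other: "ImageVolume | Mask") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grid mismatch: {self.shape}/{self.spacing} vs "
                f"{other.shape}/{other.spacing}"
            )


@dataclass
class Mask(ImageVolume):
    """A binary segmentation mask on the same grid as its image."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.array = np.asarray(self.array) > 0

    @property
    def n_voxels(self) -> int:
        return int(self.array.sum())

    @property
    def is_empty(self) -> bool:
        return not bool(self.array.any())

    def volume_mm3(self) -> float:
        return self.n_voxels * float(np.prod(self.spacing))

    def centroid_mm(self) -> np.ndarray:
        """Centroid of the foreground in world coordinates (mm)."""
        if self.is_empty:
            raise ValueError("centroid of an empty mask is undefined")
        idx = np.argwhere(self.array)
        return np.asarray(self.origin) + idx.mean(axis=0) * np.asarray(self.spacing)
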