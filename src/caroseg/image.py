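"""Core in-memory containers for volumetric images and binary lumen masks.

Arrays are indexed ``(slice, row, col)``; ``spacing`` (mm) and ``origin``
(mm) follow the same axis order, so a voxel index ``(i, j, k)`` maps to the
world point ``origin + index * spacing``.  All stages of the pipeline share
these two containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["VolumeImage", "LumenLabel"]


def _as_triple(x, name: str) -> tuple[float, float, float]:
    t = tuple(float(v) for v in np.asarray(x, dtype=float).ravel())
    if len(t) != 3:
        raise ValueError(f"{name} must have exactly 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass
class VolumeImage:
    """A 3D scalar image with physical voxel spacing and origin.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Scalar intensities (arbitrary units).  Must be finite.
    spacing : triple of float
        Voxel size in mm, ordered (slice, row, col).  Strictly positive.
    origin : triple of float
        World coordinate (mm) of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing = _as_triple(self.spacing, "spacing")
        self.origin = _as_triple(self.origin, "origin")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in mm^3."""
        return float(np.prod(self.spacing))

    def world_coords(self, index: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (..., 3) to world mm coordinates."""
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + index * np.asarray(self.spacing)

    def with_values(self, values: np.ndarray) -> "VolumeImage":
        return replace(self, values=values)


@dataclass
class LumenLabel:
    """A binary lumen mask aligned to a :class:`VolumeImage` grid."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={mask.ndim}")
        uniq = np.unique(mask)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("label mask must be binary (values in {0, 1})")
        self.mask = mask.astype(np.uint8)
        self.spacing = _as_triple(self.spacing, "spacing")
        self.origin = _as_triple(self.origin, "origin")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def labeled_fraction(self) -> float:
        """Foreground voxels as a fraction of the whole grid."""
        return float(self.mask.sum()) / self.mask.size

    @property
    def volume_mm3(self) -> float:
        return float(self.mask.sum()) * self.voxel_volume

    def check_aligned(self, vol: VolumeImage) -> None:
        if self.mask.shape != vol.values.shape:
            raise ValueError(
                f"label shape {self.mask.shape} does not match volume {vol.values.shape}"
            )
        if not np.allclose(self.spacing, vol.spacing):
            raise ValueError("label spacing does not match volume spacing")

    def with_mask(self, mask: np.ndarray) -> "LumenLabel":
        return replace(self, mask=mask)
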