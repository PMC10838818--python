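"""Volumes and masks on physically spaced 3D grids.

The package works in a fixed coordinate convention: arrays are indexed
``(x, y, z)`` with ``z`` the across-plane axis (slice direction), voxel
indices are 0-based, and the world position of voxel ``(i, j, k)`` is
``origin + index * spacing`` in millimetres.  All spatial parameters in the
toolkit (dilation radii, gap lengths, scales) are expressed in mm so that
anisotropic grids — clinical slice thickness is typically larger than the
in-plane pixel size — are handled uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import DimensionalityError, GeometryError, ParameterError

__all__ = ["Volume", "Mask", "resample", "restrict_to_mask"]

#: grids are considered identical when spacings agree within this (mm)
SPACING_ATOL = 1e-6


@dataclass
class Volume:
    """A 3D scalar grid with physical spacing and origin.

    Parameters
    ----------
    data:
        3D array, axis order ``(x, y, z)``.  Houses CT-like intensities,
        probabilities in [0, 1], or non-negative vesselness responses.
    spacing:
        Per-axis voxel size in mm, strictly positive.
    origin:
        World position of voxel ``(0, 0, 0)`` in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D volume, got {self.data.ndim} dimensions"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ParameterError("spacing and origin must have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ParameterError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of (fractional) voxel indices."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(
            self.spacing
        )

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world coordinates (mm)."""
        return (np.asarray(world, dtype=float) - np.asarray(self.origin)) / np.asarray(
            self.spacing
        )

    def same_grid(self, other: "Volume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=SPACING_ATOL)
            and np.allclose(self.origin, other.origin, atol=SPACING_ATOL)
        )

    def with_data(self, data: np.ndarray) -> "Volume":
        """Same grid, new values (keeps the concrete class)."""
        return replace(self, data=data)


@dataclass
class Mask(Volume):
    """A binary label volume sharing the :class:`Volume` grid model."""

    def __post_init__(self) -> None:
        super().__post_init__()
        uniq = np.unique(self.data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ParameterError(f"mask values must be in {{0, 1}}, got {uniq}")
        self.data = self.data.astype(np.uint8)

    @classmethod
    def from_bool(
        cls,
        data: np.ndarray,
        spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
        origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "Mask":
        return cls(np.asarray(data).astype(np.uint8), spacing, origin)

    def volume_mm3(self) -> float:
        """Physical volume of the foreground in mm^3."""
        return float(self.data.sum()) * float(np.prod(self.spacing))


def _check_same_grid(a: Volume, b: Volume, what: str = "volumes") -> None:
    if not a.same_grid(b):
        raise GeometryError(
            f"{what} must share one grid: shapes {a.shape} vs {b.shape}, "
            f"spacings {a.spacing} vs {b.spacing}"
        )


def resample(
    v: Volume, target_spacing: tuple[float, float, float] | float, order: int = 1
) -> Volume:
    """Resample a volume onto a grid with the given spacing.

    The output covers the same physical extent: its shape is
    ``ceil(extent / target_spacing)`` per axis so content is never truncated,
    and world coordinates of the content are preserved (origin is kept).
    Use ``order=0`` (nearest neighbour) for masks, ``order>=1`` for
    intensities and probability maps.
    """
    if np.isscalar(target_spacing):
        target_spacing = (float(target_spacing),) * 3
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ParameterError(f"target spacing must be positive, got {target_spacing}")
    if order not in (0, 1, 3):
        raise ParameterError(f"interpolation order must be 0, 1 or 3, got {order}")

    src_spacing = np.asarray(v.spacing)
    tgt_spacing = np.asarray(target_spacing)
    extent = np.asarray(v.shape) * src_spacing
    new_shape = np.ceil(extent / tgt_spacing - SPACING_ATOL).astype(int)
    new_shape = np.maximum(new_shape, 1)

    if np.allclose(tgt_spacing, src_spacing, atol=SPACING_ATOL):
        out = v.data.copy()
    else:
        # sample each output voxel centre at its source fractional index
        coords = np.meshgrid(
            *[np.arange(n) * t / s for n, t, s in zip(new_shape, tgt_spacing, src_spacing)],
            indexing="ij",
        )
        out = ndimage.map_coordinates(
            v.data.astype(np.float32 if order else v.data.dtype),
            np.stack(coords),
            order=order,
            mode="nearest",
        )
    cls = type(v)
    if isinstance(v, Mask):
        return cls(out.astype(np.uint8), target_spacing, v.origin)
    return cls(out, target_spacing, v.origin)


def restrict_to_mask(v: Volume, region: Mask) -> Volume:
    """Zero out values outside ``region``; values inside are untouched.

    Idempotent; used to score metrics only within the liver.
    """
    _check_same_grid(v, region, "volume and region mask")
    out = np.where(region.data > 0, v.data, 0)
    if isinstance(v, Mask):
        return type(v)(out.astype(np.uint8), v.spacing, v.origin)
    return v.with_data(out.astype(v.data.dtype))
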