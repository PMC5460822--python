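"""Core image containers: scalar volumes, ROI masks, quantized volumes.

Conventions used throughout the package (documented once, here):

* Arrays are indexed ``values[x, y, z]`` with ``x``/``y`` the in-plane axes
  and ``z`` the slice axis.
* Voxel indices are 0-based and refer to voxel centers; the center of voxel
  ``(i, j, k)`` sits at physical position ``((i + 0.5) sx, (j + 0.5) sy,
  (k + 0.5) sz)`` in mm, where ``(sx, sy, sz)`` is the spacing.
* Grey levels in a :class:`QuantizedVolume` run from 1 to ``n_levels`` on
  masked voxels; unmasked voxels carry the reserved marker 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageVolume", "ROIMask", "QuantizedVolume", "UNMASKED_LEVEL"]

#: Reserved grey-level marker for voxels outside the region of interest.
UNMASKED_LEVEL = 0


def _check_spacing(spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive lengths in mm, got {spacing}")
    return spacing


@dataclass(frozen=True, eq=False)
class ImageVolume:
    """A 3D scalar image with physical voxel spacing in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"image must be a 3D grid, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("image contains non-finite values")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical edge lengths of the grid, shape x spacing."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))


@dataclass(frozen=True, eq=False)
class ROIMask:
    """A binary region-of-interest grid congruent with an :class:`ImageVolume`."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"mask must be a 3D grid, got shape {values.shape}")
        object.__setattr__(self, "values", values.astype(bool))
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def check_congruent(self, image: ImageVolume) -> None:
        """Raise if the mask does not share the image's grid."""
        if self.shape != image.shape:
            raise ValueError(
                f"mask shape {self.shape} does not match image shape {image.shape}"
            )
        if not np.allclose(self.spacing, image.spacing):
            raise ValueError(
                f"mask spacing {self.spacing} does not match image spacing {image.spacing}"
            )


@dataclass(frozen=True, eq=False)
class QuantizedVolume:
    """Integer grey levels 1..N on masked voxels; 0 outside the mask.

    This is the common input to both texture matrices; ``label`` records
    which preprocessing configuration produced it (e.g. ``m256_st2mm_dr32``).
    """

    levels: np.ndarray
    n_levels: int
    mask: ROIMask
    label: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels)
        if not np.issubdtype(levels.dtype, np.integer):
            raise ValueError("quantized levels must be integers")
        if levels.shape != self.mask.shape:
            raise ValueError(
                f"levels shape {levels.shape} does not match mask shape {self.mask.shape}"
            )
        if self.n_levels < 2:
            raise ValueError(f"need at least 2 grey levels, got {self.n_levels}")
        inside = levels[self.mask.values]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise ValueError(
                f"masked levels must lie in [1, {self.n_levels}], "
                f"found range [{inside.min()}, {inside.max()}]"
            )
        if np.any(levels[~self.mask.values] != UNMASKED_LEVEL):
            raise ValueError("unmasked voxels must carry the reserved marker 0")
        object.__setattr__(self, "levels", levels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.levels.shape

    @property
    def n_masked(self) -> int:
        return self.mask.n_voxels
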