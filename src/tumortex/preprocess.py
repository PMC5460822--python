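"""Spatial-resolution and dynamic-range preprocessing of the tumor ROI.

The robustness protocol evaluates every subject under a grid of image
configurations: in-plane matrix sizes (native and a resampled standard
size), slice thicknesses (native and pairwise-merged), and grey-level
dynamic ranges (16/32/64 by default), 4 x 3 = 12 configurations per
subject in the default grid.

Resampling conventions
----------------------
In-plane resampling is bilinear at voxel centers with the physical extent
preserved: output voxel ``k`` along an in-plane axis of source length ``n``
and target length ``t`` samples the source at fractional index
``(k + 0.5) * n / t - 0.5``. Masks are interpolated the same way and
re-binarized at 0.5. Slice merging averages each disjoint pair of
consecutive slices (a trailing odd slice is dropped with a warning).

Quantization
------------
Uniform min-max binning *within the ROI*: the masked minimum maps to level
1 and the masked maximum to level N, with equal-width half-open bins (the
top bin closed). The intensity range is recomputed per configuration,
after resampling. Bins for N and 2N levels are nested by construction.
This is the common radiomics fixed-bin-number convention; other
normalizations exist and would change feature values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import ImageVolume, QuantizedVolume, ROIMask

__all__ = [
    "SpatialConfig",
    "GreyLevelConfig",
    "resample_inplane",
    "merge_slices",
    "quantize",
    "build_configuration_grid",
    "default_spatial_configs",
    "default_grey_configs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpatialConfig:
    """One spatial-resolution configuration: in-plane matrix x slice thickness."""

    matrix_size: int
    slice_thickness: float  # mm

    def __post_init__(self) -> None:
        if self.matrix_size < 2:
            raise ValueError(f"matrix_size must be >= 2, got {self.matrix_size}")
        if self.slice_thickness <= 0:
            raise ValueError(f"slice_thickness must be positive, got {self.slice_thickness}")

    @property
    def label(self) -> str:
        return f"m{self.matrix_size}_st{self.slice_thickness:g}mm"


@dataclass(frozen=True)
class GreyLevelConfig:
    """Dynamic range: the number N of discrete grey levels."""

    n_levels: int

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError(f"n_levels must be >= 2, got {self.n_levels}")

    @property
    def label(self) -> str:
        return f"dr{self.n_levels}"


def default_spatial_configs(matrix_sizes=(432, 256), slice_thicknesses=(1.0, 2.0)):
    """The 4 spatial configurations: each matrix size at each thickness."""
    return [
        SpatialConfig(m, st) for m in matrix_sizes for st in slice_thicknesses
    ]


def default_grey_configs(n_levels=(16, 32, 64)):
    return [GreyLevelConfig(n) for n in n_levels]


def resample_inplane(
    volume: ImageVolume, mask: ROIMask, target: int
) -> tuple[ImageVolume, ROIMask]:
    """Resample both in-plane axes to ``target`` samples, bilinearly.

    Physical extent is preserved (spacing grows by ``n/target``); the
    through-plane axis is untouched. Only downsampling (or identity) is
    allowed, mirroring a protocol that resamples a raw high-resolution
    matrix to a standard smaller one.
    """
    mask.check_congruent(volume)
    nx, ny, nz = volume.shape
    if target > nx or target > ny:
        raise ValueError(
            f"in-plane upsampling not supported: target {target} exceeds source {nx}x{ny}"
        )
    if target == nx and target == ny:
        return volume, mask

    # voxel-center sampling positions in source fractional indices
    ix = (np.arange(target) + 0.5) * nx / target - 0.5
    iy = (np.arange(target) + 0.5) * ny / target - 0.5
    iz = np.arange(nz, dtype=float)
    grid = np.meshgrid(ix, iy, iz, indexing="ij")

    values = ndimage.map_coordinates(volume.values, grid, order=1, mode="nearest")
    mask_f = ndimage.map_coordinates(mask.values.astype(np.float64), grid, order=1, mode="nearest")
    new_mask = mask_f >= 0.5

    sx, sy, sz = volume.spacing
    spacing = (sx * nx / target, sy * ny / target, sz)
    if not new_mask.any():
        raise ValueError(f"mask empty after in-plane resampling to {target}x{target}")
    return ImageVolume(values, spacing), ROIMask(new_mask, spacing)


def merge_slices(volume: ImageVolume, mask: ROIMask) -> tuple[ImageVolume, ROIMask]:
    """Halve the slice count by averaging disjoint pairs of consecutive slices.

    Slice spacing doubles; a trailing unpaired slice is dropped with a
    logged warning. The mask is averaged the same way and re-binarized at
    0.5 (i.e. a merged voxel stays in the ROI if both parents were in it,
    or exactly one was — ties round in).
    """
    mask.check_congruent(volume)
    nx, ny, nz = volume.shape
    if nz < 2:
        raise ValueError(f"need at least 2 slices to merge, got {nz}")
    if nz % 2:
        logger.warning("odd slice count %d: dropping the final unpaired slice", nz)
        nz -= 1
    vals = volume.values[:, :, :nz].reshape(nx, ny, nz // 2, 2).mean(axis=3)
    mvals = mask.values[:, :, :nz].astype(np.float64).reshape(nx, ny, nz // 2, 2).mean(axis=3)
    new_mask = mvals >= 0.5

    sx, sy, sz = volume.spacing
    spacing = (sx, sy, 2 * sz)
    if not new_mask.any():
        raise ValueError("mask empty after slice merging")
    return ImageVolume(vals, spacing), ROIMask(new_mask, spacing)


def quantize(volume: ImageVolume, mask: ROIMask, cfg: GreyLevelConfig) -> QuantizedVolume:
    """Discretize masked intensities into N equal-width grey-level bins.

    Binning runs from the masked minimum to the masked maximum; bin edges
    are half-open with the top bin closed, so the minimum maps to level 1
    and the maximum to level N. A constant ROI maps entirely to level 1.
    """
    mask.check_congruent(volume)
    n_masked = mask.n_voxels
    if n_masked == 0:
        raise ValueError("cannot quantize an empty mask")
    if n_masked < 2:
        raise ValueError(f"texture analysis needs >= 2 masked voxels, got {n_masked}")

    n = cfg.n_levels
    inside = volume.values[mask.values]
    vmin, vmax = inside.min(), inside.max()
    levels = np.zeros(volume.shape, dtype=np.int32)
    if vmax == vmin:
        levels[mask.values] = 1
    else:
        binned = np.floor((inside - vmin) / (vmax - vmin) * n).astype(np.int32) + 1
        np.clip(binned, 1, n, out=binned)
        levels[mask.values] = binned
    return QuantizedVolume(levels, n, mask)


def _apply_spatial(phantom_image: ImageVolume, phantom_mask: ROIMask, cfg: SpatialConfig):
    image, mask = resample_inplane(phantom_image, phantom_mask, cfg.matrix_size)
    sz = image.spacing[2]
    if np.isclose(cfg.slice_thickness, sz):
        return image, mask
    if np.isclose(cfg.slice_thickness, 2 * sz):
        return merge_slices(image, mask)
    raise ValueError(
        f"slice thickness {cfg.slice_thickness} mm is neither 1x nor 2x "
        f"the source thickness {sz} mm"
    )


def build_configuration_grid(
    phantom,
    spatial: list[SpatialConfig],
    grey: list[GreyLevelConfig],
) -> list[QuantizedVolume]:
    """Produce one labeled quantized dataset per (spatial, grey) pair.

    With the default 4 spatial x 3 grey-level configurations this yields
    the 12 datasets per subject of the robustness protocol. The
    quantization range is recomputed per configuration, after resampling.
    """
    if not spatial or not grey:
        raise ValueError("spatial and grey configuration lists must be nonempty")
    out: list[QuantizedVolume] = []
    for s_cfg in spatial:
        try:
            image, mask = _apply_spatial(phantom.image, phantom.mask, s_cfg)
        except ValueError as exc:
            raise ValueError(f"configuration {s_cfg.label} failed: {exc}") from exc
        for g_cfg in grey:
            label = f"{s_cfg.label}_{g_cfg.label}"
            try:
                q = quantize(image, mask, g_cfg)
            except ValueError as exc:
                raise ValueError(f"configuration {label} failed: {exc}") from exc
            out.append(QuantizedVolume(q.levels, q.n_levels, q.mask, label=label))
    return out
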