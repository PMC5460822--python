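"""Synthetic 3D tumor phantoms emulating contrast-enhanced T1-weighted MRI.

Real high-grade gliomas on CE-T1WI show a bright enhancing rim around a
darker (often necrotic) core, with spatially correlated intensity variation
inside the lesion. The phantoms here reproduce those gross features on an
ellipsoidal region of interest:

* mask: the ellipsoid inequality evaluated at voxel centers (center-in
  convention), so a brute-force voxel enumeration gives the same mask;
* mean structure: ``core_level`` inside, ``rim_level`` in the outer
  ``rim_fraction`` shell, ``background_level`` elsewhere;
* texture: seeded white noise smoothed with an isotropic Gaussian kernel of
  physical width ``texture_correlation_length``, rescaled to standard
  deviation ``texture_amplitude`` within the mask;
* noise: independent additive Gaussian noise of ``noise_sigma`` everywhere
  (or Rician magnitude noise with ``rician=True``), then clipping at zero
  to mimic magnitude MRI.

Identical spec + seed reproduces the volume bit-exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import ImageVolume, ROIMask

__all__ = ["PhantomSpec", "Phantom", "generate_phantom", "generate_cohort", "default_spec"]

_AXES = "xyz"


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic tumor volume.

    Lengths are in mm, intensities in arbitrary units. The default factory
    :func:`default_spec` provides study-scale and test-scale presets.
    """

    grid_shape: tuple[int, int, int]
    voxel_spacing: tuple[float, float, float]
    tumor_center: tuple[float, float, float]
    tumor_radii: tuple[float, float, float]
    rim_fraction: float
    core_level: float
    rim_level: float
    background_level: float
    texture_amplitude: float
    texture_correlation_length: float
    noise_sigma: float
    seed: int
    rician: bool = False

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < 1 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be three positive integers, got {self.grid_shape}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel_spacing must be positive, got {self.voxel_spacing}")
        if any(r <= 0 for r in self.tumor_radii):
            raise ValueError(f"tumor radii must be strictly positive, got {self.tumor_radii}")
        if not 0 <= self.rim_fraction < 1:
            raise ValueError(f"rim_fraction must lie in [0, 1), got {self.rim_fraction}")
        if not self.rim_level > self.core_level > self.background_level:
            raise ValueError(
                "enhancing-rim phenotype requires rim_level > core_level > background_level, "
                f"got {self.rim_level}, {self.core_level}, {self.background_level}"
            )
        if self.texture_amplitude < 0 or self.noise_sigma < 0:
            raise ValueError("texture_amplitude and noise_sigma must be non-negative")
        if self.texture_correlation_length <= 0:
            raise ValueError("texture_correlation_length must be positive")
        for ax in range(3):
            extent = self.grid_shape[ax] * self.voxel_spacing[ax]
            lo = self.tumor_center[ax] - self.tumor_radii[ax]
            hi = self.tumor_center[ax] + self.tumor_radii[ax]
            if lo < 0 or hi > extent:
                raise ValueError(
                    f"ellipsoid exceeds the grid along axis {_AXES[ax]}: "
                    f"[{lo:.2f}, {hi:.2f}] mm outside [0, {extent:.2f}] mm"
                )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("grid_shape", "voxel_spacing", "tumor_center", "tumor_radii"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("grid_shape", "voxel_spacing", "tumor_center", "tumor_radii"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True, eq=False)
class Phantom:
    """One synthetic subject: image plus tumor mask on the same grid."""

    image: ImageVolume
    mask: ROIMask

    def __post_init__(self) -> None:
        self.mask.check_congruent(self.image)
        if self.mask.n_voxels == 0:
            raise ValueError("phantom mask is empty")


def default_spec(scale: str = "test", seed: int = 0) -> PhantomSpec:
    """Preset phantom parameters.

    ``scale="full"`` matches the emulated acquisition: 432x432 in-plane
    matrix at 0.5x0.5x1 mm voxels. ``scale="test"`` is the scaled-down
    default used by the test suite and the analysis drivers: 64x64x16 at
    1x1x1 mm, a tumor of semi-axes 12x10x6 mm (about 3000 voxels).
    """
    if scale == "full":
        return PhantomSpec(
            grid_shape=(432, 432, 120),
            voxel_spacing=(0.5, 0.5, 1.0),
            tumor_center=(108.0, 108.0, 60.0),
            tumor_radii=(24.0, 20.0, 18.0),
            rim_fraction=0.25,
            core_level=100.0,
            rim_level=180.0,
            background_level=20.0,
            texture_amplitude=15.0,
            texture_correlation_length=2.5,
            noise_sigma=5.0,
            seed=seed,
        )
    if scale == "test":
        return PhantomSpec(
            grid_shape=(64, 64, 16),
            voxel_spacing=(1.0, 1.0, 1.0),
            tumor_center=(32.0, 32.0, 8.0),
            tumor_radii=(12.0, 10.0, 6.0),
            rim_fraction=0.25,
            core_level=100.0,
            rim_level=180.0,
            background_level=20.0,
            texture_amplitude=15.0,
            texture_correlation_length=2.5,
            noise_sigma=5.0,
            seed=seed,
        )
    raise ValueError(f"unknown scale {scale!r}, expected 'test' or 'full'")


def _normalized_radius(spec: PhantomSpec) -> np.ndarray:
    """Ellipsoid coordinate rho at every voxel center; rho <= 1 is inside."""
    coords = [
        ((np.arange(n) + 0.5) * s - c) / r
        for n, s, c, r in zip(spec.grid_shape, spec.voxel_spacing, spec.tumor_center, spec.tumor_radii)
    ]
    gx, gy, gz = np.meshgrid(*coords, indexing="ij")
    return np.sqrt(gx**2 + gy**2 + gz**2)


def _correlated_field(spec: PhantomSpec, rng: np.random.Generator, mask: np.ndarray) -> np.ndarray:
    """Smoothed white noise with unit variance inside the mask, scaled by amplitude."""
    if spec.texture_amplitude == 0:
        return np.zeros(spec.grid_shape)
    white = rng.standard_normal(spec.grid_shape)
    sigma_vox = [spec.texture_correlation_length / s for s in spec.voxel_spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="reflect")
    inside = smooth[mask]
    sd = inside.std()
    if sd == 0:  # pathological single-voxel mask; leave texture flat
        return np.zeros(spec.grid_shape)
    return (smooth - inside.mean()) / sd * spec.texture_amplitude


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build one tumor phantom from its spec, deterministically in the seed."""
    rng = np.random.default_rng(spec.seed)
    rho = _normalized_radius(spec)
    mask = rho <= 1.0
    if not mask.any():
        raise ValueError("phantom mask is empty; enlarge the radii or the grid")

    core = rho <= 1.0 - spec.rim_fraction
    rim = mask & ~core
    values = np.full(spec.grid_shape, spec.background_level, dtype=np.float64)
    values[core] = spec.core_level
    values[rim] = spec.rim_level

    texture = _correlated_field(spec, rng, mask)
    values[mask] += texture[mask]

    if spec.noise_sigma > 0:
        if spec.rician:
            # magnitude of complex signal + iid Gaussian noise on each channel
            re = values + rng.normal(0.0, spec.noise_sigma, spec.grid_shape)
            im = rng.normal(0.0, spec.noise_sigma, spec.grid_shape)
            values = np.hypot(re, im)
        else:
            values = values + rng.normal(0.0, spec.noise_sigma, spec.grid_shape)

    np.clip(values, 0.0, None, out=values)
    return Phantom(
        image=ImageVolume(values, spec.voxel_spacing),
        mask=ROIMask(mask, spec.voxel_spacing),
    )


def _jittered_spec(base: PhantomSpec, rng: np.random.Generator, seed: int) -> PhantomSpec:
    """Per-subject geometry/heterogeneity jitter around the base spec.

    Multiplicative jitters are kept narrow enough that the spec invariants
    (rim > core > background, ellipsoid inside the grid) hold for any draw
    starting from the presets in :func:`default_spec`.
    """
    radii = tuple(r * rng.uniform(0.85, 1.15) for r in base.tumor_radii)
    center = tuple(
        c + rng.uniform(-0.5, 0.5) * s
        for c, s in zip(base.tumor_center, base.voxel_spacing)
    )
    return dataclasses.replace(
        base,
        tumor_radii=radii,
        tumor_center=center,
        rim_fraction=float(np.clip(base.rim_fraction * rng.uniform(0.8, 1.2), 0.0, 0.95)),
        core_level=base.core_level * rng.uniform(0.95, 1.05),
        rim_level=base.rim_level * rng.uniform(0.95, 1.05),
        texture_amplitude=base.texture_amplitude * rng.uniform(0.8, 1.2),
        texture_correlation_length=base.texture_correlation_length * rng.uniform(0.8, 1.2),
        seed=seed,
    )


def generate_cohort(n_subjects: int, base_spec: PhantomSpec, seed: int) -> list[Phantom]:
    """Generate a cohort of phantoms with per-subject jittered parameters.

    Each subject draws its jitter and its voxel-level randomness from a
    dedicated substream of ``seed``, so the cohort is deterministic and
    individual subjects are independent of the cohort size.
    """
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    streams = np.random.SeedSequence(seed).spawn(n_subjects)
    phantoms = []
    for stream in streams:
        rng = np.random.default_rng(stream)
        subject_seed = int(rng.integers(0, 2**31 - 1))
        spec = _jittered_spec(base_spec, rng, subject_seed)
        phantoms.append(generate_phantom(spec))
    return phantoms
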