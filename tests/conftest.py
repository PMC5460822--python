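"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use naive enumeration (double loops, explicit
line walking) so they share no code path with the vectorized
implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from tumortex import default_spec, generate_phantom
from tumortex.volume import QuantizedVolume, ROIMask


def brute_force_cm(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """O(V^2) co-occurrence counts: every ordered masked pair at Chebyshev distance 1."""
    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    voxels = list(zip(*np.nonzero(mask)))
    for a in voxels:
        for b in voxels:
            if a == b:
                continue
            if max(abs(a[k] - b[k]) for k in range(3)) == 1:
                counts[levels[a] - 1, levels[b] - 1] += 1
    return counts


def brute_force_rlm(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Walk every line of every direction independently and count maximal runs."""
    shape = levels.shape
    directions = [
        d for d in itertools.product((-1, 0, 1), repeat=3) if d > (0, 0, 0)
    ]
    runs: list[tuple[int, int]] = []  # (level, length)
    for d in directions:
        for start in itertools.product(*(range(n) for n in shape)):
            prev = tuple(start[k] - d[k] for k in range(3))
            if all(0 <= prev[k] < shape[k] for k in range(3)):
                continue  # not the head of a line
            pos = start
            current_level, current_len = 0, 0
            while all(0 <= pos[k] < shape[k] for k in range(3)):
                lev = levels[pos] if mask[pos] else 0
                if lev == current_level:
                    current_len += 1
                else:
                    if current_level > 0:
                        runs.append((current_level, current_len))
                    current_level, current_len = lev, 1
                pos = tuple(pos[k] + d[k] for k in range(3))
            if current_level > 0:
                runs.append((current_level, current_len))
    if not runs:
        return np.zeros((n_levels, 1), dtype=np.int64)
    max_len = max(length for _, length in runs)
    counts = np.zeros((n_levels, max_len), dtype=np.int64)
    for lev, length in runs:
        counts[lev - 1, length - 1] += 1
    return counts


def brute_force_ellipsoid_count(spec) -> int:
    """Voxel-by-voxel ellipsoid-inequality check at voxel centers."""
    count = 0
    for idx in itertools.product(*(range(n) for n in spec.grid_shape)):
        rho2 = sum(
            (((idx[k] + 0.5) * spec.voxel_spacing[k] - spec.tumor_center[k])
             / spec.tumor_radii[k]) ** 2
            for k in range(3)
        )
        if rho2 <= 1.0:
            count += 1
    return count


def random_quantized(rng: np.random.Generator, max_side: int = 6, max_levels: int = 4) -> QuantizedVolume:
    """A random small quantized volume with a random (possibly sparse) mask."""
    shape = tuple(int(rng.integers(2, max_side + 1)) for _ in range(3))
    n_levels = int(rng.integers(2, max_levels + 1))
    mask = rng.random(shape) < rng.uniform(0.4, 1.0)
    if mask.sum() < 2:
        flat = rng.choice(np.prod(shape), size=2, replace=False)
        mask.ravel()[flat] = True
    levels = np.zeros(shape, dtype=np.int32)
    levels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    return QuantizedVolume(levels, n_levels, ROIMask(mask, (1.0, 1.0, 1.0)))


def make_quantized(level_array, n_levels: int, mask=None) -> QuantizedVolume:
    """Convenience constructor for hand-built examples."""
    levels = np.asarray(level_array, dtype=np.int32)
    if mask is None:
        mask = levels > 0
    return QuantizedVolume(levels, n_levels, ROIMask(np.asarray(mask, bool), (1.0, 1.0, 1.0)))


@pytest.fixture(scope="session")
def test_phantom():
    """One deterministic test-scale phantom (64x64x16 at 1 mm isotropic in-plane)."""
    return generate_phantom(default_spec(scale="test", seed=7))
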