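"""3D grey-level co-occurrence and run-length matrices and their features.

Co-occurrence matrix (CM)
-------------------------
``counts[i-1, j-1]`` is the number of ordered pairs of masked voxels at
unit Chebyshev distance (the 26-neighborhood) whose grey levels are
``(i, j)``. Both orders of every pair are counted, so the matrix is
symmetric. Features operate on the matrix normalized to unit sum — the
probability that a random adjacent masked pair shows levels ``(i, j)`` —
which is the convention under which the entropy below is a conventional
non-negative Shannon entropy. All logarithms are natural.

With ``p(i, j)`` the normalized matrix:

* Entropy       ``-sum p ln p``            (``0 ln 0 = 0``)
* Homogeneity   ``sum p / (1 + (i - j)^2)``
* Contrast      ``sum p (i - j)^2``
* Dissimilarity ``sum p |i - j|``
* Uniformity    ``sum p^2``

Run-length matrix (RLM)
-----------------------
``counts[i-1, j-1]`` is the number of maximal collinear runs of ``j``
consecutive masked voxels at grey level ``i``, accumulated (summed) over
all 13 direction vectors of the 26-neighborhood (one per antipodal pair).
Runs break at level changes, at mask boundaries and at the grid edge;
every masked voxel therefore belongs to exactly one run per direction,
giving the conservation law ``sum counts[i,j] * j = 13 * |mask|``.

With ``r(i, j)`` the raw counts and ``nr`` the total number of runs:

* SRE ``(1/nr) sum r / j^2``, LRE ``(1/nr) sum r j^2``
* LGRE ``(1/nr) sum r / i^2``, HGRE ``(1/nr) sum r i^2``
* SRLGE, SRHGE, LRLGE, LRHGE: the four mixed second moments
* GLNU ``(1/nr) sum_i (sum_j r)^2``, RLNU ``(1/nr) sum_j (sum_i r)^2``
* RPC ``nr / sum r j`` = runs per voxel-direction incidence, in (0, 1]
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import QuantizedVolume

__all__ = [
    "DIRECTIONS_13",
    "CooccurrenceMatrix",
    "RunLengthMatrix",
    "CM_FEATURE_NAMES",
    "RLM_FEATURE_NAMES",
    "FEATURE_NAMES",
    "build_cm",
    "cm_features",
    "build_rlm",
    "rlm_features",
    "extract_features",
]

#: The 13 direction vectors covering the 26-neighborhood up to sign:
#: every nonzero offset in {-1,0,1}^3 whose first nonzero component is +1.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(DIRECTIONS_13) == 13

CM_FEATURE_NAMES = ("Entropy", "Homogeneity", "Contrast", "Dissimilarity", "Uniformity")
RLM_FEATURE_NAMES = (
    "LRE", "SRE", "LGRE", "HGRE", "SRLGE", "SRHGE",
    "LRLGE", "LRHGE", "GLNU", "RLNU", "RPC",
)
FEATURE_NAMES = CM_FEATURE_NAMES + RLM_FEATURE_NAMES


@dataclass(frozen=True, eq=False)
class CooccurrenceMatrix:
    counts: np.ndarray       # (N, N) int64, symmetric
    probabilities: np.ndarray  # (N, N), sums to 1
    n_levels: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True, eq=False)
class RunLengthMatrix:
    counts: np.ndarray  # (N, M) int64
    n_levels: int

    @property
    def max_run_length(self) -> int:
        return self.counts.shape[1]

    @property
    def n_runs(self) -> int:
        return int(self.counts.sum())


def _shift_slices(shape, offset):
    """Index tuples (a, b) such that arr[a] and arr[b] are offset by `offset`."""
    sl_a, sl_b = [], []
    for n, d in zip(shape, offset):
        if d == 0:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
        elif d == 1:
            sl_a.append(slice(0, n - 1))
            sl_b.append(slice(1, n))
        else:
            sl_a.append(slice(1, n))
            sl_b.append(slice(0, n - 1))
    return tuple(sl_a), tuple(sl_b)


def build_cm(q: QuantizedVolume) -> CooccurrenceMatrix:
    """Accumulate the symmetric 26-neighbor co-occurrence matrix."""
    if q.n_masked < 2:
        raise ValueError(f"co-occurrence needs >= 2 masked voxels, got {q.n_masked}")
    n = q.n_levels
    lv = q.levels
    m = q.mask.values
    counts = np.zeros((n, n), dtype=np.int64)
    for d in DIRECTIONS_13:
        a, b = _shift_slices(lv.shape, d)
        sel = m[a] & m[b]
        if not sel.any():
            continue
        la = lv[a][sel] - 1
        lb = lv[b][sel] - 1
        counts += np.bincount(la * n + lb, minlength=n * n).reshape(n, n)
    counts = counts + counts.T  # count both orders of every pair
    total = counts.sum()
    if total == 0:
        raise ValueError(
            "no masked voxel pair is 26-adjacent; texture is undefined for scattered masks"
        )
    return CooccurrenceMatrix(counts, counts / total, n)


def cm_features(cm: CooccurrenceMatrix) -> dict[str, float]:
    """The 5 co-occurrence features, on the unit-sum normalized matrix."""
    p = np.asarray(cm.probabilities, dtype=np.float64)
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"co-occurrence probabilities must sum to 1, got {p.sum()!r}")
    n = cm.n_levels
    i = np.arange(1, n + 1)[:, None]
    j = np.arange(1, n + 1)[None, :]
    diff2 = (i - j) ** 2

    nz = p > 0
    entropy = float(-(p[nz] * np.log(p[nz])).sum())
    return {
        "Entropy": entropy,
        "Homogeneity": float((p / (1.0 + diff2)).sum()),
        "Contrast": float((p * diff2).sum()),
        "Dissimilarity": float((p * np.abs(i - j)).sum()),
        "Uniformity": float((p**2).sum()),
    }


def build_rlm(q: QuantizedVolume) -> RunLengthMatrix:
    """Accumulate maximal-run counts over the 13 directions, summed.

    Implementation: for each direction, every grid line is recovered by
    lexicographically sorting voxels on (line base point, step along the
    direction); runs are then boundaries in the sorted level sequence.
    Unmasked voxels carry level 0 and act as run breakers.
    """
    if q.n_masked < 1:
        raise ValueError("run-length matrix needs a nonempty mask")
    n = q.n_levels
    shape = q.shape
    lv_flat = q.levels.reshape(-1)
    idx = np.indices(shape).reshape(3, -1)
    max_len = max(shape)
    counts = np.zeros((n, max_len), dtype=np.int64)

    for d in DIRECTIONS_13:
        axis = next(k for k in range(3) if d[k] != 0)
        t = idx[axis] * d[axis]  # step parameter: +1 per move along d
        base = [idx[k] - d[k] * t for k in range(3)]  # constant along each line
        order = np.lexsort((t, base[2], base[1], base[0]))
        seq = lv_flat[order]
        b0, b1, b2 = (b[order] for b in base)
        new_line = np.empty(seq.size, dtype=bool)
        new_line[0] = True
        new_line[1:] = (np.diff(b0) != 0) | (np.diff(b1) != 0) | (np.diff(b2) != 0)
        run_start = new_line.copy()
        run_start[1:] |= seq[1:] != seq[:-1]
        starts = np.flatnonzero(run_start)
        lengths = np.diff(np.append(starts, seq.size))
        levels = seq[starts]
        keep = levels > 0
        if keep.any():
            flat = (levels[keep] - 1) * max_len + (lengths[keep] - 1)
            counts += np.bincount(flat, minlength=n * max_len).reshape(n, max_len)

    m_tight = int(np.max(np.nonzero(counts.any(axis=0))[0])) + 1
    return RunLengthMatrix(counts[:, :m_tight], n)


def rlm_features(rlm: RunLengthMatrix) -> dict[str, float]:
    """The 11 run-length features, on raw counts with the 1/nr prefactor."""
    r = np.asarray(rlm.counts, dtype=np.float64)
    nr = r.sum()
    if nr <= 0:
        raise ValueError("run-length features need at least one run")
    n, m = r.shape
    i2 = (np.arange(1, n + 1) ** 2)[:, None].astype(np.float64)
    j2 = (np.arange(1, m + 1) ** 2)[None, :].astype(np.float64)

    return {
        "LRE": float((r * j2).sum() / nr),
        "SRE": float((r / j2).sum() / nr),
        "LGRE": float((r / i2).sum() / nr),
        "HGRE": float((r * i2).sum() / nr),
        "SRLGE": float((r / (i2 * j2)).sum() / nr),
        "SRHGE": float((r * i2 / j2).sum() / nr),
        "LRLGE": float((r * j2 / i2).sum() / nr),
        "LRHGE": float((r * i2 * j2).sum() / nr),
        "GLNU": float((r.sum(axis=1) ** 2).sum() / nr),
        "RLNU": float((r.sum(axis=0) ** 2).sum() / nr),
        "RPC": float(nr / (r * np.sqrt(j2)).sum()),
    }


def extract_features(q: QuantizedVolume) -> dict[str, float]:
    """All 16 features of one quantized dataset, CM family then RLM family."""
    out = cm_features(build_cm(q))
    out.update(rlm_features(build_rlm(q)))
    assert tuple(out) == FEATURE_NAMES
    return out
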