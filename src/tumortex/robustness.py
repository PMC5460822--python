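"""Coefficient-of-variation robustness protocol over the configuration grid.

Experiment 1 fixes a spatial resolution and varies the dynamic range
(grey levels, e.g. 16/32/64): for each feature, subject and spatial
configuration the CV is taken over the grey-level values, then averaged
over subjects (mean and SD, in percent). The result is one table of
features x spatial configurations.

Experiment 2 fixes a dynamic range and varies the spatial resolution: the
CV is taken over the (matrix size x slice thickness) values, then averaged
over subjects, giving a table of features x dynamic ranges.

A feature is called *robust* in a cell when the across-subject mean CV is
strictly below the threshold (10% by default), and robust overall when
every cell of its row is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .texture import FEATURE_NAMES

__all__ = [
    "ZeroMeanError",
    "coefficient_of_variation",
    "RobustnessTable",
    "experiment1",
    "experiment2",
    "classify_robust",
    "normalized_feature_profiles",
    "GROUP_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Provenance columns expected in a tidy cohort feature table.
GROUP_COLUMNS = ("subject", "matrix_size", "slice_thickness_mm", "n_levels")


class ZeroMeanError(ValueError):
    """The CV is undefined when the series mean is (numerically) zero."""


def coefficient_of_variation(values, ddof: int = 1, mean_tol: float = 1e-12) -> float:
    """CV in percent: 100 x SD / |mean| of a series of at least two scalars.

    ``ddof=1`` gives the sample SD (default); ``ddof=0`` the population SD.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError(f"CV needs a series of >= 2 scalars, got {arr.size}")
    mean = arr.mean()
    if abs(mean) <= mean_tol:
        raise ZeroMeanError(f"CV undefined: series mean {mean!r} is numerically zero")
    return float(100.0 * arr.std(ddof=ddof) / abs(mean))


@dataclass(frozen=True)
class RobustnessTable:
    """Per-feature mean and SD of the CV across subjects, by grouping.

    ``mean_cv`` and ``sd_cv`` are DataFrames indexed by feature name with
    one column per grouping (spatial configuration for Experiment 1,
    dynamic range for Experiment 2), in percent. ``robust_flags`` is
    filled in by :func:`classify_robust`.
    """

    experiment: str
    mean_cv: pd.DataFrame
    sd_cv: pd.DataFrame
    n_subjects: int
    threshold: float | None = None
    robust_flags: pd.DataFrame | None = None

    @property
    def robust_overall(self) -> pd.Series | None:
        """Per-feature flag: robust in every grouping."""
        if self.robust_flags is None:
            return None
        return self.robust_flags.all(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Report table: 'mean (SD)' display cells plus machine-readable columns."""
        out = pd.DataFrame(index=self.mean_cv.index)
        for col in self.mean_cv.columns:
            out[col] = [
                f"{m:.2f} ({s:.2f})"
                for m, s in zip(self.mean_cv[col], self.sd_cv[col])
            ]
        for col in self.mean_cv.columns:
            out[f"{col}__mean_cv_pct"] = self.mean_cv[col].round(6)
            out[f"{col}__sd_cv_pct"] = self.sd_cv[col].round(6)
        if self.robust_flags is not None:
            for col in self.robust_flags.columns:
                out[f"{col}__robust"] = self.robust_flags[col]
            out["robust_overall"] = self.robust_overall
        out.index.name = "feature"
        return out


def _validate_table(features: pd.DataFrame) -> tuple[list, list]:
    """Check completeness of the subject x spatial x grey grid; return the axes."""
    missing_cols = [c for c in GROUP_COLUMNS if c not in features.columns]
    if missing_cols:
        raise ValueError(f"feature table lacks provenance columns {missing_cols}")
    missing_feats = [f for f in FEATURE_NAMES if f not in features.columns]
    if missing_feats:
        raise ValueError(f"feature table lacks feature columns {missing_feats}")

    # paper-order spatial configs: large matrix first, thin slices first
    spatial = sorted(
        set(zip(features["matrix_size"], features["slice_thickness_mm"])),
        key=lambda ms: (-ms[0], ms[1]),
    )
    greys = sorted(set(features["n_levels"]))
    subjects = sorted(set(features["subject"]))
    seen = set(zip(features["subject"], features["matrix_size"],
                   features["slice_thickness_mm"], features["n_levels"]))
    missing = [
        (subj, m, st, g)
        for subj in subjects
        for (m, st) in spatial
        for g in greys
        if (subj, m, st, g) not in seen
    ]
    if missing:
        raise ValueError(f"feature table is missing {len(missing)} cells: {missing[:5]} ...")
    return spatial, greys


def _spatial_label(matrix_size: int, slice_thickness: float) -> str:
    return f"{matrix_size}x{matrix_size}; {slice_thickness:g} mm"


def _aggregate(
    features: pd.DataFrame,
    within: list[str],
    group_labels: list[tuple],
    label_fn,
    experiment: str,
    ddof: int,
) -> RobustnessTable:
    """CV over the `within` axis per (feature, subject, group); mean/SD over subjects."""
    subjects = sorted(set(features["subject"]))
    mean_cv = pd.DataFrame(index=list(FEATURE_NAMES), dtype=float)
    sd_cv = pd.DataFrame(index=list(FEATURE_NAMES), dtype=float)
    group_cols = [c for c in GROUP_COLUMNS if c not in within and c != "subject"]
    for key in group_labels:
        label = label_fn(key)
        cvs = np.empty((len(FEATURE_NAMES), len(subjects)))
        for s_idx, subj in enumerate(subjects):
            sel = features["subject"] == subj
            for col, val in zip(group_cols, np.atleast_1d(key)):
                sel &= features[col] == val
            block = features.loc[sel]
            for f_idx, feat in enumerate(FEATURE_NAMES):
                cvs[f_idx, s_idx] = coefficient_of_variation(
                    block[feat].to_numpy(), ddof=ddof
                )
        mean_cv[label] = cvs.mean(axis=1)
        sd_cv[label] = cvs.std(axis=1, ddof=1) if len(subjects) > 1 else 0.0
    return RobustnessTable(experiment, mean_cv, sd_cv, n_subjects=len(subjects))


def experiment1(features: pd.DataFrame, ddof: int = 1) -> RobustnessTable:
    """Robustness under dynamic-range changes at fixed spatial resolution.

    Returns a features x spatial-configurations table of across-subject
    mean (SD) CVs, the CV being taken over the grey-level axis.
    """
    spatial, greys = _validate_table(features)
    if len(greys) < 2:
        raise ValueError(f"need >= 2 dynamic ranges to compute a CV, got {greys}")
    return _aggregate(
        features,
        within=["n_levels"],
        group_labels=spatial,
        label_fn=lambda ms: _spatial_label(*ms),
        experiment="experiment1",
        ddof=ddof,
    )


def experiment2(features: pd.DataFrame, ddof: int = 1) -> RobustnessTable:
    """Robustness under spatial-resolution changes at fixed dynamic range.

    Returns a features x dynamic-ranges table, the CV being taken over the
    four (matrix size x slice thickness) configurations.
    """
    spatial, greys = _validate_table(features)
    if len(spatial) < 2:
        raise ValueError(f"need >= 2 spatial configurations to compute a CV, got {spatial}")
    return _aggregate(
        features,
        within=["matrix_size", "slice_thickness_mm"],
        group_labels=greys,
        label_fn=lambda g: f"{g} levels",
        experiment="experiment2",
        ddof=ddof,
    )


def classify_robust(table: RobustnessTable, threshold: float = 10.0) -> RobustnessTable:
    """Flag each cell whose mean CV is strictly below the threshold (percent)."""
    flags = table.mean_cv < threshold
    return replace(table, threshold=threshold, robust_flags=flags)


def normalized_feature_profiles(features: pd.DataFrame) -> pd.DataFrame:
    """One subject's feature values, each divided by its maximum over configurations.

    Mirrors per-subject profile plots where each feature's trace is
    normalized to the maximum value it attains across the grid, so the
    maximum maps to 1. Features whose maximum is numerically zero are
    skipped with a log entry.
    """
    if features.empty:
        raise ValueError("empty feature table")
    if features["subject"].nunique() != 1:
        raise ValueError("normalized profiles are per-subject; pass one subject's rows")
    keep = [c for c in GROUP_COLUMNS if c in features.columns]
    out = features[keep].copy()
    for feat in FEATURE_NAMES:
        fmax = features[feat].max()
        if abs(fmax) <= 1e-12:
            logger.warning("feature %s has max ~ 0; skipped in normalized profile", feat)
            continue
        out[feat] = features[feat] / fmax
    return out
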