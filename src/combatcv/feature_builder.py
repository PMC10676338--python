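"""Connectivity feature construction and the structural feature schema.

Functional-connectivity features are built from region-of-interest (ROI)
time series in three steps: Pearson correlation between every pair of ROI
series, Fisher z-transform of the coefficients (``arctanh``, which makes
their sampling distribution approximately normal), and vectorization of the
strictly-upper triangle of the correlation matrix in row-major order, giving
``n*(n-1)/2`` named features for ``n`` ROIs.  ROIs whose series are null
(identically zero or constant) in more than a configurable fraction of
subjects are pruned beforehand, because a constant series has no defined
correlation.

The structural side is a fixed 221-name schema: volume, mean thickness and
thickness standard deviation for 62 cortical structures (31 per hemisphere),
26 subcortical/callosal volumes, and 9 global quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyFeatureError,
    SchemaError,
    UndefinedCorrelationError,
)

__all__ = [
    "RoiTimeseriesSet",
    "FeatureMatrix",
    "pearson_correlation_matrix",
    "fisher_z",
    "vectorize_connectivity",
    "devectorize_connectivity",
    "prune_null_rois",
    "structural_schema",
    "connectivity_feature_names",
    "build_connectivity_features",
]


@dataclass
class RoiTimeseriesSet:
    """Per-subject multichannel ROI signal: ``n_timepoints x n_rois``."""

    subject_id: str
    data: pd.DataFrame  # columns = ROI names, rows = timepoints

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise SchemaError(f"duplicate ROI names: {dupes}")

    @property
    def roi_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_timepoints(self) -> int:
        return len(self.data)


@dataclass
class FeatureMatrix:
    """Subjects x named features, tagged as ``structural`` or ``connectivity``.

    ``data`` is indexed by subject ID; every downstream stage (selection,
    harmonization, cross-validation) transforms this object.
    """

    data: pd.DataFrame
    kind: str = "structural"

    def __post_init__(self) -> None:
        if self.kind not in ("structural", "connectivity"):
            raise SchemaError(f"unknown feature kind {self.kind!r}")
        if self.data.index.duplicated().any():
            raise SchemaError("duplicate subject IDs in feature matrix")
        if self.data.columns.duplicated().any():
            raise SchemaError("duplicate feature names in feature matrix")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise SchemaError("feature matrix contains non-finite values")
        if self.kind == "connectivity":
            p = self.data.shape[1]
            # p must equal n*(n-1)/2 for an integer n
            n = (1 + np.sqrt(1 + 8 * p)) / 2
            if abs(n - round(n)) > 1e-9:
                raise SchemaError(
                    f"{p} columns is not n(n-1)/2 for any integer n"
                )

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, subject_ids: Sequence[str]) -> "FeatureMatrix":
        missing = [s for s in subject_ids if s not in self.data.index]
        if missing:
            raise SchemaError(f"unknown subject IDs: {missing[:5]}")
        return FeatureMatrix(self.data.loc[list(subject_ids)], kind=self.kind)


def pearson_correlation_matrix(ts: RoiTimeseriesSet) -> pd.DataFrame:
    """Pearson correlation between every pair of ROI time series.

    Returns a symmetric matrix with unit diagonal, entries clipped to
    ``[-1, 1]`` against round-off.  A zero-variance series makes the
    correlation undefined and raises, naming the ROI.
    """
    X = ts.data.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise SchemaError(
            f"subject {ts.subject_id}: need >=3 timepoints, got {X.shape[0]}"
        )
    sd = X.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [ts.roi_names[i] for i in dead]
        raise UndefinedCorrelationError(
            f"subject {ts.subject_id}: zero-variance series for ROI(s) {names}"
        )
    corr = np.corrcoef(X, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=ts.roi_names, columns=ts.roi_names)


def fisher_z(r):
    """Fisher z-transform ``arctanh(r) = 0.5*ln((1+r)/(1-r))``.

    Odd and strictly increasing on (-1, 1); raises outside the open
    interval, where the transform diverges.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1.0):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(arr)
    return out if arr.ndim else float(out)


def connectivity_feature_names(roi_names: Sequence[str]) -> list[str]:
    """Feature names for the strictly-upper triangle in row-major order."""
    return [
        f"{roi_names[i]}__{roi_names[j]}"
        for i in range(len(roi_names))
        for j in range(i + 1, len(roi_names))
    ]


def vectorize_connectivity(
    corr_matrix, roi_names: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Fisher-z values of the strictly-upper triangle, row-major (i < j).

    The ordering is fixed so that feature names are stable across
    harmonization strategies, which the importance comparison relies on.
    """
    if isinstance(corr_matrix, pd.DataFrame):
        if roi_names is None:
            roi_names = list(corr_matrix.columns)
        corr = corr_matrix.to_numpy(dtype=float)
    else:
        corr = np.asarray(corr_matrix, dtype=float)
    n = corr.shape[0]
    if corr.ndim != 2 or corr.shape[1] != n:
        raise SchemaError(f"correlation matrix must be square, got {corr.shape}")
    if np.max(np.abs(corr - corr.T)) > 1e-8:
        raise SchemaError("correlation matrix is asymmetric beyond 1e-8")
    if np.max(np.abs(np.diag(corr) - 1.0)) > 1e-8:
        raise SchemaError("correlation matrix diagonal departs from 1")
    if roi_names is None:
        roi_names = [f"ROI{i + 1:03d}" for i in range(n)]
    iu = np.triu_indices(n, k=1)
    vec = fisher_z(corr[iu])
    return vec, connectivity_feature_names(roi_names)


def devectorize_connectivity(
    vector: Sequence[float], roi_names: Sequence[str]
) -> np.ndarray:
    """Inverse of :func:`vectorize_connectivity` (back to a correlation matrix)."""
    n = len(roi_names)
    vec = np.asarray(vector, dtype=float)
    if vec.size != n * (n - 1) // 2:
        raise SchemaError(
            f"vector length {vec.size} does not match {n} ROIs"
        )
    corr = np.eye(n)
    iu = np.triu_indices(n, k=1)
    corr[iu] = np.tanh(vec)
    corr[(iu[1], iu[0])] = corr[iu]
    return corr


def _is_null_series(col: np.ndarray) -> bool:
    # identically zero or constant: either way Pearson r is undefined
    return bool(np.all(col == col[0]))


def prune_null_rois(
    subjects: Iterable[RoiTimeseriesSet], max_null_fraction: float = 0.05
) -> list[str]:
    """Names of ROIs to keep, dropping those null in too many subjects.

    An ROI is dropped when its series is identically zero or constant in
    more than ``max_null_fraction`` of subjects.  Order of the surviving
    names follows the input ordering.  Idempotent by construction.
    """
    subjects = list(subjects)
    if not subjects:
        raise SchemaError("no subjects provided")
    names = subjects[0].roi_names
    for s in subjects[1:]:
        if s.roi_names != names:
            raise SchemaError(
                f"subject {s.subject_id}: ROI names differ from the first subject"
            )
    null_counts = np.zeros(len(names), dtype=int)
    for s in subjects:
        X = s.data.to_numpy(dtype=float)
        for i in range(len(names)):
            if _is_null_series(X[:, i]):
                null_counts[i] += 1
    frac = null_counts / len(subjects)
    kept = [name for name, f in zip(names, frac) if f <= max_null_fraction]
    if not kept:
        raise EmptyFeatureError("all ROIs were dropped by null-series pruning")
    return kept


def build_connectivity_features(
    subjects: Iterable[RoiTimeseriesSet], max_null_fraction: float = 0.05
) -> FeatureMatrix:
    """Full pipeline: prune null ROIs, correlate, Fisher-z, vectorize."""
    subjects = list(subjects)
    kept = prune_null_rois(subjects, max_null_fraction=max_null_fraction)
    rows = {}
    names = None
    for s in subjects:
        pruned = RoiTimeseriesSet(s.subject_id, s.data[kept])
        corr = pearson_correlation_matrix(pruned)
        vec, names = vectorize_connectivity(corr)
        rows[s.subject_id] = vec
    data = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    return FeatureMatrix(data, kind="connectivity")


# 31 cortical structures per hemisphere (Desikan-Killiany-Tourville style)
_CORTICAL_STRUCTURES = [
    "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus", "entorhinal",
    "fusiform", "inferiorparietal", "inferiortemporal", "isthmuscingulate",
    "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal",
    "transversetemporal", "insula",
]

_SUBCORTICAL_BILATERAL = [
    "Thalamus-Proper", "Caudate", "Putamen", "Pallidum", "Hippocampus",
    "Amygdala", "Accumbens-area", "VentralDC", "Cerebellum-Cortex",
    "Cerebellum-White-Matter",
]

_SUBCORTICAL_MIDLINE = [
    "Brain-Stem", "CC_Posterior", "CC_Mid_Posterior", "CC_Central",
    "CC_Mid_Anterior", "CC_Anterior",
]

_GLOBAL_QUANTITIES = [
    "lh_MeanThickness", "rh_MeanThickness",
    "lh_CortexVol", "rh_CortexVol",
    "lh_CerebralWhiteMatterVol", "rh_CerebralWhiteMatterVol",
    "CSF", "TotalGrayVol", "BrainSegVolNotVent",
]


def structural_schema() -> list[str]:
    """Canonical ordered list of the 221 structural feature names.

    62 cortical structures (31 per hemisphere) x {volume, mean thickness,
    thickness SD} = 186 cortical features, then 26 subcortical/callosal
    volumes, then 9 global quantities.  The order is fixed.
    """
    names: list[str] = []
    for hemi in ("lh", "rh"):
        for structure in _CORTICAL_STRUCTURES:
            for measure in ("volume", "thickness_mean", "thickness_std"):
                names.append(f"{hemi}_{structure}_{measure}")
    for structure in _SUBCORTICAL_BILATERAL:
        for side in ("Left", "Right"):
            names.append(f"{side}-{structure}_volume")
    for structure in _SUBCORTICAL_MIDLINE:
        names.append(f"{structure}_volume")
    names.extend(_GLOBAL_QUANTITIES)
    return names


def cortical_block_length() -> int:
    """Number of cortical features in the structural schema (62 x 3)."""
    return 2 * len(_CORTICAL_STRUCTURES) * 3
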