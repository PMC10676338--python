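"""Phenotype- and quality-based subject selection.

Two selection variants are provided.  The minimal variant (``minSC``) keeps
males aged 6-40 whose structural and functional preprocessing both
succeeded.  The fMRI-quality variant (``fQC``) keeps males scanned
eyes-open with a recorded full-scale IQ (FIQ > 0), preprocessing success,
and head motion (mean framewise displacement) not flagged as an outlier by
a median + k*MAD rule (k = 3 by default).

High mean-FD means heavy motion, so the MAD rule flags values *above*
median + k*MAD; low motion cannot indicate poor quality.  The MAD here is
unscaled (no 1.4826 normal-consistency factor); a ``scale_factor`` argument
exposes the scaled variant.

A further age-window/site-size selection (ages 9-20, sites with >= 30
remaining subjects) is intended to run *after* harmonization, so the
harmonizer can estimate the age trend on the wider age range; the pipeline
driver enforces that ordering.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = [
    "mad_outlier_mask",
    "select_minsc",
    "select_fqc",
    "apply_age_and_site_selection",
    "selection_report",
]

_MINSC_COLUMNS = ["subject_id", "site", "diagnosis", "age", "sex",
                  "struct_ok", "func_ok"]
_FQC_COLUMNS = _MINSC_COLUMNS + ["eye_status", "fiq", "mean_fd"]


def _require_columns(phenotypes: pd.DataFrame, columns: Sequence[str]) -> None:
    missing = [c for c in columns if c not in phenotypes.columns]
    if missing:
        raise SchemaError(f"phenotype table is missing columns: {missing}")


def mad_outlier_mask(values, k: float = 3.0, scale_factor: float = 1.0) -> np.ndarray:
    """Boolean mask flagging values above ``median + k * MAD``.

    MAD = median(|x - median(x)|), unscaled by default.  With zero
    dispersion (all values identical) nothing is flagged and a
    degenerate-scale warning is emitted.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise SchemaError(f"need >=3 values for a MAD rule, got {arr.size}")
    if not np.isfinite(arr).all():
        raise SchemaError("non-finite values in MAD input")
    if k <= 0:
        raise SchemaError(f"k must be > 0, got {k}")
    med = np.median(arr)
    mad = np.median(np.abs(arr - med)) * scale_factor
    if mad == 0:
        warnings.warn(
            "MAD is zero (degenerate scale); no outliers flagged",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.zeros(arr.shape, dtype=bool)
    return arr > med + k * mad


def select_minsc(phenotypes: pd.DataFrame) -> list[str]:
    """Minimal selection: males aged 6-40, both preprocessing stages OK."""
    _require_columns(phenotypes, _MINSC_COLUMNS)
    keep = (
        (phenotypes["sex"] == "M")
        & (phenotypes["age"] >= 6)
        & (phenotypes["age"] <= 40)
        & phenotypes["struct_ok"].astype(bool)
        & phenotypes["func_ok"].astype(bool)
    )
    return phenotypes.loc[keep, "subject_id"].tolist()


def select_fqc(
    phenotypes: pd.DataFrame, k: float = 3.0, mad_scale_factor: float = 1.0
) -> list[str]:
    """fMRI-quality selection: males, eyes-open, FIQ > 0, preprocessing OK,
    and mean FD not a high outlier.

    The MAD threshold is computed over the candidates that survive the
    other filters (one pooled selection, not per site).
    """
    _require_columns(phenotypes, _FQC_COLUMNS)
    keep = (
        (phenotypes["sex"] == "M")
        & (phenotypes["eye_status"] == "open")
        & (phenotypes["fiq"] > 0)
        & phenotypes["struct_ok"].astype(bool)
        & phenotypes["func_ok"].astype(bool)
    )
    candidates = phenotypes.loc[keep]
    if len(candidates) < 3:
        # too few candidates to estimate a MAD; motion filter is skipped
        flagged = np.zeros(len(candidates), dtype=bool)
    else:
        flagged = mad_outlier_mask(
            candidates["mean_fd"].to_numpy(), k=k, scale_factor=mad_scale_factor
        )
    return candidates.loc[~flagged, "subject_id"].tolist()


def apply_age_and_site_selection(
    subject_ids: Sequence[str],
    phenotypes: pd.DataFrame,
    age_window: tuple[float, float] = (9.0, 20.0),
    min_site_n: int = 30,
) -> list[str]:
    """Keep subjects inside the age window, then drop undersized sites.

    Sites whose remaining count is below ``min_site_n`` are removed
    entirely.  Input order is preserved.  Intended to run after
    harmonization (see module docstring).
    """
    lo, hi = age_window
    if not lo < hi:
        raise SchemaError(f"age window is degenerate: ({lo}, {hi})")
    if min_site_n < 1:
        raise SchemaError(f"min_site_n must be >= 1, got {min_site_n}")
    _require_columns(phenotypes, ["subject_id", "site", "age"])
    pheno = phenotypes.set_index("subject_id")
    missing = [s for s in subject_ids if s not in pheno.index]
    if missing:
        raise SchemaError(f"unknown subject IDs: {missing[:5]}")
    in_window = [
        s for s in subject_ids if lo <= pheno.at[s, "age"] <= hi
    ]
    counts = pd.Series([pheno.at[s, "site"] for s in in_window]).value_counts()
    big_sites = set(counts[counts >= min_site_n].index)
    return [s for s in in_window if pheno.at[s, "site"] in big_sites]


def selection_report(
    phenotypes: pd.DataFrame, selections: dict[str, Sequence[str]]
) -> pd.DataFrame:
    """Per-site, per-class and total counts for each named selection stage.

    ``selections`` maps a stage name to the subject IDs it keeps; a row per
    (stage, site) plus a per-stage ``TOTAL`` row, with TD/ASD/total columns.
    An empty selection yields an all-zero total row.
    """
    _require_columns(phenotypes, ["subject_id", "site", "diagnosis"])
    pheno = phenotypes.set_index("subject_id")
    sites = sorted(phenotypes["site"].unique())
    rows = []
    for stage, ids in selections.items():
        sub = pheno.loc[list(ids)] if len(ids) else pheno.iloc[0:0]
        for site in sites:
            at_site = sub[sub["site"] == site]
            rows.append({
                "stage": stage,
                "site": site,
                "TD": int((at_site["diagnosis"] == "TD").sum()),
                "ASD": int((at_site["diagnosis"] == "ASD").sum()),
                "total": len(at_site),
            })
        rows.append({
            "stage": stage,
            "site": "TOTAL",
            "TD": int((sub["diagnosis"] == "TD").sum()),
            "ASD": int((sub["diagnosis"] == "ASD").sum()),
            "total": len(sub),
        })
    return pd.DataFrame(rows, columns=["stage", "site", "TD", "ASD", "total"])
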