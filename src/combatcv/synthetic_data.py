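"""Synthetic multi-site cohorts with known ground-truth effects.

Real multi-site case/control collections (ABIDE-like) carry three kinds of
structure that matter for harmonization studies: additive and multiplicative
per-site effects on every feature, a linear age trend, and a small diagnosis
effect confined to a subset of features.  This module generates phenotype
tables and feature matrices from exactly that generative model,

    y_ijv = alpha_v + beta_v * age_ij + theta_v * 1[diag_ij = ASD]
            + gamma_iv + delta_iv * eps_ijv,        eps_ijv ~ N(0, sigma_v^2)

for subject j at site i and feature v, and returns the sampled parameters as
a :class:`GroundTruth` so downstream recovery and importance tests can be
scored against the truth.

The site priors mirror what the empirical-Bayes harmonizer assumes: additive
effects ``gamma_iv ~ Normal(0, tau^2)`` and squared multiplicative effects
``delta_iv^2`` drawn from an inverse-gamma distribution with mean 1, making
parameter recovery a fair test rather than a model-mismatch exercise.

Phenotype fields (sex, eye status, FIQ, mean framewise displacement with a
configurable outlier fraction, preprocessing-success flags) are rich enough
to exercise every cohort-selection filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import GenerationError, ParameterError, SchemaError
from .feature_builder import FeatureMatrix, RoiTimeseriesSet

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_feature_matrix",
    "generate_roi_timeseries",
]

PHENOTYPE_COLUMNS = [
    "subject_id", "site", "diagnosis", "age", "sex", "eye_status",
    "fiq", "mean_fd", "struct_ok", "func_ok",
]


def _nearest_int(x: float) -> int:
    """Nearest integer, round-half-to-even (Python built-in round)."""
    return int(round(x))


@dataclass
class SyntheticConfig:
    """Generative parameters of a synthetic multi-site cohort.

    Defaults describe a 4-site study of 60 subjects per site with strong
    site effects (location SD three times the noise SD, so an unharmonized
    site classifier is near-perfect), a weak linear age trend, and a
    diagnosis effect of half a noise SD on 20% of features.  Per-site age
    windows are staggered so that sites differ in median age, as real
    multi-site collections do.
    """

    n_sites: int = 4
    subjects_per_site: int | Sequence[int] = 60
    asd_fraction: float = 0.5
    age_range_per_site: Sequence[tuple[float, float]] | None = None
    n_features: int = 50
    site_location_sd: float = 3.0     # tau, feature units
    site_scale_spread: float = 0.2    # SD of delta^2 around 1
    age_slope_sd: float = 0.05        # feature units per year
    diag_effect_size: float = 0.5     # theta, feature units
    diag_affected_fraction: float = 0.2
    noise_sd: float = 1.0             # sigma, feature units
    male_fraction: float = 0.85
    eyes_open_fraction: float = 0.80
    fiq_mean: float = 110.0
    fiq_sd: float = 15.0
    mean_fd_median: float = 0.10
    mean_fd_mad: float = 0.04
    fd_outlier_rate: float = 0.05
    struct_success_rate: float = 0.97
    func_success_rate: float = 0.90
    seed: int = 0

    def site_sizes(self) -> list[int]:
        if isinstance(self.subjects_per_site, int):
            return [self.subjects_per_site] * self.n_sites
        return [int(n) for n in self.subjects_per_site]

    def age_ranges(self) -> list[tuple[float, float]]:
        if self.age_range_per_site is None:
            # staggered 20-year windows -> sites differ in median age
            return [(6.0 + 2 * i, 26.0 + 2 * i) for i in range(self.n_sites)]
        return [tuple(r) for r in self.age_range_per_site]

    def validate(self) -> None:
        if self.n_sites < 2:
            raise ParameterError("n_sites must be >= 2")
        sizes = self.site_sizes()
        if len(sizes) != self.n_sites:
            raise ParameterError(
                "subjects_per_site list length must equal n_sites"
            )
        if any(n < 1 for n in sizes):
            raise ParameterError("subjects_per_site entries must be >= 1")
        for name in ("asd_fraction", "diag_affected_fraction", "male_fraction",
                     "eyes_open_fraction", "fd_outlier_rate",
                     "struct_success_rate", "func_success_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        for name in ("site_location_sd", "site_scale_spread", "age_slope_sd",
                     "noise_sd", "fiq_sd", "mean_fd_mad"):
            v = getattr(self, name)
            if v < 0:
                raise ParameterError(f"{name} must be non-negative, got {v}")
        if self.n_features < 1:
            raise ParameterError("n_features must be >= 1")
        ranges = self.age_ranges()
        if len(ranges) != self.n_sites:
            raise ParameterError(
                "age_range_per_site list length must equal n_sites"
            )
        for i, (lo, hi) in enumerate(ranges):
            if not lo < hi:
                raise ParameterError(
                    f"age_range_per_site[{i}] is degenerate: ({lo}, {hi})"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        if not isinstance(d["subjects_per_site"], int):
            d["subjects_per_site"] = list(d["subjects_per_site"])
        if d["age_range_per_site"] is not None:
            d["age_range_per_site"] = [list(r) for r in d["age_range_per_site"]]
        return d


@dataclass
class GroundTruth:
    """Sampled generative parameters behind a synthetic feature matrix."""

    feature_names: list[str]
    site_names: list[str]
    intercept: np.ndarray        # alpha_v, (p,)
    age_slope: np.ndarray        # beta_v, (p,)
    diag_effect: np.ndarray      # theta_v, (p,); 0 for unaffected features
    site_location: np.ndarray    # gamma_iv, (S, p)
    site_scale: np.ndarray       # delta_iv, (S, p), > 0
    noise_sd: np.ndarray         # sigma_v, (p,)

    @property
    def affected_features(self) -> list[str]:
        return [f for f, t in zip(self.feature_names, self.diag_effect) if t != 0]

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "site_names": self.site_names,
            "intercept": self.intercept.tolist(),
            "age_slope": self.age_slope.tolist(),
            "diag_effect": self.diag_effect.tolist(),
            "site_location": self.site_location.tolist(),
            "site_scale": self.site_scale.tolist(),
            "noise_sd": self.noise_sd.tolist(),
        }


def _shuffled_binary(rng, n: int, n_true: int, true_val, false_val):
    vals = np.array([true_val] * n_true + [false_val] * (n - n_true), dtype=object)
    rng.shuffle(vals)
    return vals


def generate_cohort(config: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """One phenotype record per subject, deterministic given (config, seed).

    Class, sex, eye-status and motion-outlier fractions are realized as
    nearest-integer counts per site; ages are uniform within each site's
    window.  Motion outliers receive mean-FD values far above the
    median + 3*MAD threshold used by quality-control selection.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sizes = config.site_sizes()
    ranges = config.age_ranges()
    rows = []
    counter = 1
    for i, (n, (lo, hi)) in enumerate(zip(sizes, ranges)):
        site = f"site{i + 1:02d}"
        diag = _shuffled_binary(rng, n, _nearest_int(config.asd_fraction * n),
                                "ASD", "TD")
        sex = _shuffled_binary(rng, n, _nearest_int(config.male_fraction * n),
                               "M", "F")
        eyes = _shuffled_binary(rng, n,
                                _nearest_int(config.eyes_open_fraction * n),
                                "open", "closed")
        outlier = _shuffled_binary(
            rng, n, _nearest_int(config.fd_outlier_rate * n), True, False
        )
        age = rng.uniform(lo, hi, size=n)
        fiq = rng.normal(config.fiq_mean, config.fiq_sd, size=n)
        # mean FD around the configured median with MAD-scaled spread
        fd = np.abs(rng.normal(config.mean_fd_median,
                               1.4826 * config.mean_fd_mad, size=n))
        inflated = config.mean_fd_median + config.mean_fd_mad * (
            10.0 + 5.0 * np.abs(rng.standard_normal(n))
        )
        fd = np.where(outlier.astype(bool), inflated, fd)
        struct_ok = rng.random(n) < config.struct_success_rate
        func_ok = rng.random(n) < config.func_success_rate
        for j in range(n):
            rows.append({
                "subject_id": f"sub-{counter:04d}",
                "site": site,
                "diagnosis": diag[j],
                "age": float(age[j]),
                "sex": sex[j],
                "eye_status": eyes[j],
                "fiq": float(fiq[j]),
                "mean_fd": float(fd[j]),
                "struct_ok": bool(struct_ok[j]),
                "func_ok": bool(func_ok[j]),
            })
            counter += 1
    return pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS)


def _sample_delta_sq(rng, shape, spread: float) -> np.ndarray:
    """delta^2 from an inverse gamma with mean 1 and SD ``spread``.

    Mean 1 requires b = a - 1; variance 1/(a-2) = spread^2 fixes a.
    ``spread`` -> 0 collapses to delta = 1 exactly.
    """
    if spread <= 0:
        return np.ones(shape)
    a = 2.0 + 1.0 / spread**2
    b = a - 1.0
    # inverse-gamma(a, b) = b / gamma(a, 1)
    return b / rng.gamma(a, 1.0, size=shape)


def generate_feature_matrix(
    phenotypes: pd.DataFrame,
    config: SyntheticConfig,
    seed: int | None = None,
    kind: str = "structural",
) -> tuple[FeatureMatrix, GroundTruth]:
    """Sample features from the additive/multiplicative site-effect model.

    Returns the feature matrix plus the :class:`GroundTruth` holding every
    sampled parameter, including which features carry the diagnosis effect.
    """
    config.validate()
    if phenotypes.empty:
        raise SchemaError("phenotype table is empty")
    bad = set(phenotypes["diagnosis"]) - {"ASD", "TD"}
    if bad:
        raise SchemaError(f"unknown diagnosis labels: {sorted(bad)}")
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 1_000_003
    )
    p = config.n_features
    feature_names = [f"feat{v + 1:04d}" for v in range(p)]
    site_names = sorted(phenotypes["site"].unique())
    S = len(site_names)

    intercept = rng.normal(0.0, 1.0, size=p)
    age_slope = rng.normal(0.0, config.age_slope_sd, size=p) \
        if config.age_slope_sd > 0 else np.zeros(p)
    n_affected = _nearest_int(config.diag_affected_fraction * p)
    affected = rng.choice(p, size=n_affected, replace=False)
    diag_effect = np.zeros(p)
    diag_effect[affected] = config.diag_effect_size * rng.choice(
        [-1.0, 1.0], size=n_affected
    )
    site_location = rng.normal(0.0, config.site_location_sd, size=(S, p)) \
        if config.site_location_sd > 0 else np.zeros((S, p))
    site_scale = np.sqrt(_sample_delta_sq(rng, (S, p), config.site_scale_spread))
    noise_sd = np.full(p, config.noise_sd)

    site_idx = pd.Categorical(
        phenotypes["site"], categories=site_names
    ).codes
    age = phenotypes["age"].to_numpy(dtype=float)
    is_asd = (phenotypes["diagnosis"] == "ASD").to_numpy()
    eps = rng.standard_normal((len(phenotypes), p)) * noise_sd
    Y = (
        intercept
        + np.outer(age, age_slope)
        + np.outer(is_asd.astype(float), diag_effect)
        + site_location[site_idx]
        + site_scale[site_idx] * eps
    )
    data = pd.DataFrame(
        Y, index=phenotypes["subject_id"].tolist(), columns=feature_names
    )
    truth = GroundTruth(
        feature_names=feature_names,
        site_names=site_names,
        intercept=intercept,
        age_slope=age_slope,
        diag_effect=diag_effect,
        site_location=site_location,
        site_scale=site_scale,
        noise_sd=noise_sd,
    )
    return FeatureMatrix(data, kind=kind), truth


def _repair_correlation(C: np.ndarray, min_eig: float = 1e-8) -> np.ndarray:
    """Nearest-by-clipping valid correlation matrix.

    Eigenvalues clipped at ``min_eig``, then the diagonal re-normalized to 1.
    """
    C = (C + C.T) / 2.0
    vals, vecs = np.linalg.eigh(C)
    vals = np.clip(vals, min_eig, None)
    C = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return C


def generate_roi_timeseries(
    phenotypes: pd.DataFrame,
    n_rois: int,
    n_timepoints: int,
    config: SyntheticConfig | None = None,
    seed: int = 0,
    *,
    group_perturbation: dict[tuple[int, int], float] | None = None,
    site_perturbations: dict[str, dict[tuple[int, int], float]] | None = None,
    null_rois: dict[str, Sequence[int]] | None = None,
    base_offdiag_scale: float = 0.5,
) -> list[RoiTimeseriesSet]:
    """Per-subject ROI series from a multivariate normal.

    Each subject's series is drawn with a correlation matrix equal to a
    shared base matrix plus group-specific (ASD) and site-specific additive
    perturbations on the given ROI pairs, projected back to the nearest
    valid correlation matrix by eigenvalue clipping.  ``null_rois`` maps
    subject IDs to ROI indices whose series are forced to zero, to exercise
    null-ROI pruning downstream.
    """
    if n_rois < 2:
        raise ParameterError("n_rois must be >= 2")
    if n_timepoints < 3:
        raise ParameterError("n_timepoints must be >= 3")
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((n_rois, 2 * n_rois))
    S = W @ W.T
    d = np.sqrt(np.diag(S))
    base = S / np.outer(d, d)
    # shrink toward identity for moderate, well-conditioned correlations
    base = base_offdiag_scale * base + (1 - base_offdiag_scale) * np.eye(n_rois)
    np.fill_diagonal(base, 1.0)

    roi_names = [f"ROI{i + 1:03d}" for i in range(n_rois)]
    group_perturbation = group_perturbation or {}
    site_perturbations = site_perturbations or {}
    null_rois = null_rois or {}

    out = []
    for _, row in phenotypes.iterrows():
        C = base.copy()
        perts: list[tuple[tuple[int, int], float]] = []
        if row["diagnosis"] == "ASD":
            perts.extend(group_perturbation.items())
        perts.extend(site_perturbations.get(row["site"], {}).items())
        for (i, j), delta in perts:
            C[i, j] += delta
            C[j, i] += delta
        off = C - np.diag(np.diag(C))
        if np.max(np.abs(off)) > 1.0 + 1e-6:
            raise GenerationError(
                f"subject {row['subject_id']}: perturbed correlations exceed "
                "magnitude 1; matrix cannot be repaired within tolerance"
            )
        if perts:
            C = _repair_correlation(C)
        L = np.linalg.cholesky(C + 1e-10 * np.eye(n_rois))
        Z = rng.standard_normal((n_timepoints, n_rois))
        X = Z @ L.T
        for idx in null_rois.get(row["subject_id"], ()):
            X[:, idx] = 0.0
        out.append(
            RoiTimeseriesSet(
                row["subject_id"],
                pd.DataFrame(X, columns=roi_names),
            )
        )
    return out
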