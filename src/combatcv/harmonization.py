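"""Reference-population ComBat harmonization and its deployment strategies.

ComBat models each feature as a covariate trend plus additive and
multiplicative site (batch) effects,

    y_ijv = alpha_v + x_ij' beta_v + gamma_iv + delta_iv eps_ijv,

and removes the site terms while preserving the covariate trend.  Per-site
effects are stabilized by parametric empirical Bayes (EB): additive effects
get Normal priors and squared multiplicative effects get Inverse-Gamma
priors, with hyperparameters moment-matched across features within each
site and posterior means iterated to a fixed point.

This implementation fits in *reference-population* mode: all model
parameters — covariate trend, pooled scale, site effects and their priors —
are estimated from a designated reference subset (typically the typically
developing controls), and the fitted transform is then applied to every
subject.  Fitting on controls only prevents disease effects from being
absorbed into the site effects.  Diagnosis is never a covariate; the
default covariate is age with a linear trend.

Four deployment strategies place the harmonization relative to a
cross-validation (CV) plan:

- ``none``       — raw data, fold-sliced.
- ``external``   — one fit on all reference subjects before CV; the test
  folds therefore influence the transform (data leakage by construction).
- ``external45`` — like ``external`` but fit on a fresh random 4/5 of the
  reference subjects per site at each CV repetition, matching the reference
  sample size of the internal strategy while retaining the leakage.
- ``internal``   — refit per fold on the training-fold reference subjects
  only; test subjects never influence any fitted parameter (leakage-free).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateFeatureError,
    FitError,
    ParameterError,
    SchemaError,
    UnknownSiteError,
)
from .feature_builder import FeatureMatrix

__all__ = [
    "CovariateSpec",
    "HarmonizationModel",
    "FoldData",
    "fit_reference_model",
    "apply_model",
    "strategy_none",
    "strategy_external",
    "strategy_external_45",
    "strategy_internal",
    "get_strategy",
    "STRATEGY_NAMES",
]

STRATEGY_NAMES = ("none", "external", "external45", "internal")

_EPS = 1e-12


@dataclass(frozen=True)
class CovariateSpec:
    """Which phenotype columns enter the covariate trend (all linear)."""

    covariates: tuple[str, ...] = ("age",)
    site_column: str = "site"

    def __post_init__(self) -> None:
        if "diagnosis" in self.covariates:
            raise ParameterError(
                "diagnosis must not be a covariate: it is unknown for test "
                "subjects and would absorb the effect under study"
            )


@dataclass
class HarmonizationModel:
    """Fitted reference-ComBat parameters.

    ``gamma_star``/``delta_star`` are the EB-shrunk per-site location and
    scale effects on the standardized scale; ``alpha``/``beta``/``sigma``
    are the pooled intercept, covariate slopes and residual scale estimated
    on the reference subjects.
    """

    feature_names: list[str]
    site_names: list[str]
    covariates: tuple[str, ...]
    alpha: np.ndarray          # (p,)
    beta: np.ndarray           # (c, p)
    sigma: np.ndarray          # (p,) pooled residual SD, > 0
    gamma_star: np.ndarray     # (S, p) EB additive site effect
    delta_star: np.ndarray     # (S, p) EB multiplicative site effect, > 0
    gamma_hat: np.ndarray      # (S, p) raw (pre-EB) estimates
    delta_hat: np.ndarray      # (S, p)
    hyperparameters: dict[str, dict[str, float]]
    n_reference: dict[str, int]
    eb_iterations: int
    empirical_bayes: bool = True

    def site_index(self, site: str) -> int:
        try:
            return self.site_names.index(site)
        except ValueError:
            raise UnknownSiteError(
                f"site {site!r} was not present in the reference set "
                f"(known sites: {self.site_names})"
            ) from None

    def to_json(self, path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "site_names": self.site_names,
            "covariates": list(self.covariates),
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "sigma": self.sigma.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_star": self.delta_star.tolist(),
            "gamma_hat": self.gamma_hat.tolist(),
            "delta_hat": self.delta_hat.tolist(),
            "hyperparameters": self.hyperparameters,
            "n_reference": self.n_reference,
            "eb_iterations": self.eb_iterations,
            "empirical_bayes": self.empirical_bayes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "HarmonizationModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            feature_names=d["feature_names"],
            site_names=d["site_names"],
            covariates=tuple(d["covariates"]),
            alpha=np.asarray(d["alpha"]),
            beta=np.asarray(d["beta"]),
            sigma=np.asarray(d["sigma"]),
            gamma_star=np.asarray(d["gamma_star"]),
            delta_star=np.asarray(d["delta_star"]),
            gamma_hat=np.asarray(d["gamma_hat"]),
            delta_hat=np.asarray(d["delta_hat"]),
            hyperparameters=d["hyperparameters"],
            n_reference={k: int(v) for k, v in d["n_reference"].items()},
            eb_iterations=int(d["eb_iterations"]),
            empirical_bayes=bool(d["empirical_bayes"]),
        )


def _covariate_matrix(
    phenotypes: pd.DataFrame, ids: Sequence[str], spec: CovariateSpec
) -> np.ndarray:
    pheno = phenotypes.set_index("subject_id")
    missing = [s for s in ids if s not in pheno.index]
    if missing:
        raise SchemaError(f"subjects missing from phenotype table: {missing[:5]}")
    for c in spec.covariates:
        if c not in pheno.columns:
            raise SchemaError(f"phenotype table lacks covariate column {c!r}")
    C = pheno.loc[list(ids), list(spec.covariates)].to_numpy(dtype=float)
    if not np.isfinite(C).all():
        raise SchemaError("non-finite covariate values")
    return C


def _sites_of(
    phenotypes: pd.DataFrame, ids: Sequence[str], spec: CovariateSpec
) -> pd.Series:
    pheno = phenotypes.set_index("subject_id")
    if spec.site_column not in pheno.columns:
        raise SchemaError(f"phenotype table lacks site column {spec.site_column!r}")
    return pheno.loc[list(ids), spec.site_column]


def fit_reference_model(
    features: FeatureMatrix,
    phenotypes: pd.DataFrame,
    spec: CovariateSpec | None = None,
    reference_ids: Sequence[str] | None = None,
    empirical_bayes: bool = True,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> HarmonizationModel:
    """Fit the location/scale site-effect model on the reference subjects.

    Steps, per feature v:

    1. least squares for ``y = alpha + x'beta + gamma_site`` with the
       weighted sum-to-zero constraint ``sum_i n_i gamma_i = 0``;
    2. pooled residual variance ``sigma^2`` (mean squared residual of the
       full fit);
    3. standardize the residual-plus-site signal,
       ``z = (y - alpha - x'beta) / sigma``;
    4. raw per-site estimates: ``gamma_hat_i = mean(z)``,
       ``delta_hat_i^2 = mean((z - gamma_hat_i)^2)`` within site;
    5. parametric EB: Normal prior on gamma, Inverse-Gamma prior on
       delta^2, hyperparameters moment-matched across features within each
       site; conditional posterior means iterated to a fixed point
       (max relative change below ``tol``, hard cap ``max_iter``).

    ``reference_ids`` defaults to the TD subjects.  Every reference site
    needs at least 2 subjects.  Sites whose raw estimates are (numerically)
    identical across features carry no between-feature spread to pool, and
    keep their raw estimates.
    """
    spec = spec or CovariateSpec()
    if reference_ids is None:
        if "diagnosis" not in phenotypes.columns:
            raise SchemaError("phenotype table lacks a diagnosis column")
        reference_ids = phenotypes.loc[
            phenotypes["diagnosis"] == "TD", "subject_id"
        ].tolist()
    reference_ids = [s for s in reference_ids]
    if not reference_ids:
        raise FitError("empty reference set")

    ref = features.subset(reference_ids)
    Y = ref.data.to_numpy(dtype=float)
    n, p = Y.shape
    sites = _sites_of(phenotypes, reference_ids, spec)
    site_names = sorted(sites.unique())
    S = len(site_names)
    counts = sites.value_counts()
    for site in site_names:
        if counts[site] < 2:
            raise FitError(
                f"reference site {site!r} has {counts[site]} subject(s); "
                "need at least 2 to estimate a scale"
            )
    n_i = np.array([counts[s] for s in site_names], dtype=float)
    site_idx = pd.Categorical(sites, categories=site_names).codes

    C = _covariate_matrix(phenotypes, reference_ids, spec)
    c = C.shape[1]
    # full-rank design: one indicator per site (no intercept) + covariates
    D = np.zeros((n, S))
    D[np.arange(n), site_idx] = 1.0
    X = np.hstack([D, C])
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    m = coef[:S]                    # per-site intercepts, (S, p)
    beta = coef[S:]                 # covariate slopes, (c, p)
    weights = n_i / n
    alpha = weights @ m             # grand intercept; sum_i n_i (m_i-alpha) = 0

    resid = Y - X @ coef
    sigma_sq = np.mean(resid**2, axis=0)
    degenerate = np.flatnonzero(sigma_sq <= _EPS)
    if degenerate.size:
        names = [ref.feature_names[i] for i in degenerate[:5]]
        raise DegenerateFeatureError(
            f"zero residual variance in feature(s) {names}"
        )
    sigma = np.sqrt(sigma_sq)

    trend = alpha + C @ beta
    Z = (Y - trend) / sigma

    gamma_hat = np.zeros((S, p))
    delta_hat_sq = np.zeros((S, p))
    for i in range(S):
        Zi = Z[site_idx == i]
        gamma_hat[i] = Zi.mean(axis=0)
        delta_hat_sq[i] = np.mean((Zi - gamma_hat[i]) ** 2, axis=0)

    hyper: dict[str, dict[str, float]] = {}
    iterations = 0
    if empirical_bayes and p >= 2:
        gamma_star = gamma_hat.copy()
        delta_star_sq = delta_hat_sq.copy()
        for i, site in enumerate(site_names):
            g_bar = float(gamma_hat[i].mean())
            tau_sq = float(gamma_hat[i].var(ddof=1))
            m_d = float(delta_hat_sq[i].mean())
            s_d = float(delta_hat_sq[i].var(ddof=1))
            hyper[site] = {
                "gamma_bar": g_bar, "tau_sq": tau_sq,
                "delta_sq_mean": m_d, "delta_sq_var": s_d,
            }
            if s_d > _EPS:
                lam = (2.0 * s_d + m_d**2) / s_d
                theta = (m_d * s_d + m_d**3) / s_d
                hyper[site]["lambda"] = lam
                hyper[site]["theta"] = theta
            ni = n_i[i]
            g, d_sq = gamma_hat[i].copy(), delta_hat_sq[i].copy()
            for it in range(max_iter):
                if tau_sq > _EPS:
                    g_new = (ni * tau_sq * gamma_hat[i] + d_sq * g_bar) / (
                        ni * tau_sq + d_sq
                    )
                else:
                    g_new = gamma_hat[i]
                if s_d > _EPS:
                    # sum_j (z_j - g)^2 = n*delta_hat^2 + n*(gamma_hat - g)^2
                    ssq = ni * (delta_hat_sq[i] + (gamma_hat[i] - g_new) ** 2)
                    d_new = (theta + 0.5 * ssq) / (ni / 2.0 + lam - 1.0)
                else:
                    d_new = delta_hat_sq[i]
                change = max(
                    float(np.max(np.abs(g_new - g) / (np.abs(g) + 1e-8))),
                    float(np.max(np.abs(d_new - d_sq) / (np.abs(d_sq) + 1e-8))),
                )
                g, d_sq = g_new, d_new
                if change < tol:
                    break
            else:
                raise FitError(
                    f"EB iteration did not converge for site {site!r} "
                    f"within {max_iter} iterations"
                )
            iterations = max(iterations, it + 1)
            gamma_star[i] = g
            delta_star_sq[i] = d_sq
    else:
        gamma_star = gamma_hat.copy()
        delta_star_sq = delta_hat_sq.copy()

    if np.any(delta_star_sq <= 0):
        raise FitError("non-positive posterior scale estimate")

    return HarmonizationModel(
        feature_names=ref.feature_names,
        site_names=site_names,
        covariates=spec.covariates,
        alpha=alpha,
        beta=beta,
        sigma=sigma,
        gamma_star=gamma_star,
        delta_star=np.sqrt(delta_star_sq),
        gamma_hat=gamma_hat,
        delta_hat=np.sqrt(delta_hat_sq),
        hyperparameters=hyper,
        n_reference={s: int(counts[s]) for s in site_names},
        eb_iterations=iterations,
        empirical_bayes=bool(empirical_bayes and p >= 2),
    )


def apply_model(
    model: HarmonizationModel,
    features: FeatureMatrix,
    phenotypes: pd.DataFrame,
    spec: CovariateSpec | None = None,
) -> FeatureMatrix:
    """Apply a fitted transform to any subjects, row-wise.

    ``y* = sigma * (z - gamma*_site) / delta*_site + alpha + x'beta`` with
    ``z = (y - alpha - x'beta) / sigma``.  Each output row depends only on
    that subject's own data and the model.  Unknown sites raise rather than
    passing data through unharmonized.
    """
    spec = spec or CovariateSpec(covariates=model.covariates)
    if list(features.feature_names) != list(model.feature_names):
        raise SchemaError("feature names differ from the fitted model")
    ids = features.subject_ids
    sites = _sites_of(phenotypes, ids, spec)
    idx = np.array([model.site_index(s) for s in sites])
    C = _covariate_matrix(phenotypes, ids, spec)
    Y = features.data.to_numpy(dtype=float)
    trend = model.alpha + C @ model.beta
    Z = (Y - trend) / model.sigma
    Ystar = model.sigma * (Z - model.gamma_star[idx]) / model.delta_star[idx] + trend
    return FeatureMatrix(
        pd.DataFrame(Ystar, index=ids, columns=model.feature_names),
        kind=features.kind,
    )


@dataclass
class FoldData:
    """Train/test feature slices for one fold of one CV repetition."""

    repetition: int
    fold: int
    train_ids: list[str]
    test_ids: list[str]
    train: pd.DataFrame
    test: pd.DataFrame


def _fold_slices(plan) -> Iterator[tuple[int, int, list[str], list[str]]]:
    for r in range(plan.n_repetitions):
        for f in range(plan.n_folds):
            yield r, f, plan.train_ids(r, f), plan.test_ids(r, f)


def strategy_none(
    features: FeatureMatrix,
    phenotypes: pd.DataFrame,
    plan,
    spec: CovariateSpec | None = None,
) -> Iterator[FoldData]:
    """Raw data, sliced along the CV plan (no site-effect correction)."""
    for r, f, train, test in _fold_slices(plan):
        yield FoldData(r, f, train, test,
                       features.data.loc[train], features.data.loc[test])


def strategy_external(
    features: FeatureMatrix,
    phenotypes: pd.DataFrame,
    plan,
    spec: CovariateSpec | None = None,
    empirical_bayes: bool = True,
) -> Iterator[FoldData]:
    """One reference fit on all TD before CV; every fold shares the matrix."""
    model = fit_reference_model(
        features, phenotypes, spec=spec, empirical_bayes=empirical_bayes
    )
    H = apply_model(model, features, phenotypes, spec=spec)
    for r, f, train, test in _fold_slices(plan):
        yield FoldData(r, f, train, test, H.data.loc[train], H.data.loc[test])


def draw_reference_subsample(
    phenotypes: pd.DataFrame,
    subject_ids: Sequence[str],
    rng: np.random.Generator,
    fraction: float = 0.8,
) -> list[str]:
    """Per-site random subsample of the TD subjects (round-half-even size)."""
    pheno = phenotypes.set_index("subject_id").loc[list(subject_ids)]
    td = pheno[pheno["diagnosis"] == "TD"]
    chosen: list[str] = []
    for site in sorted(td["site"].unique()):
        ids = td.index[td["site"] == site].to_numpy()
        n_take = int(round(fraction * len(ids)))
        if n_take < 2:
            raise FitError(
                f"site {site!r}: 4/5 reference subset has {n_take} subject(s)"
            )
        chosen.extend(sorted(rng.choice(ids, size=n_take, replace=False)))
    return chosen


def strategy_external_45(
    features: FeatureMatrix,
    phenotypes: pd.DataFrame,
    plan,
    spec: CovariateSpec | None = None,
    seed: int = 0,
    empirical_bayes: bool = True,
) -> Iterator[FoldData]:
    """External harmonization refit per repetition on 4/5 of TD per site.

    Matches the reference sample size of the internal strategy while still
    letting test subjects influence the transform.
    """
    children = np.random.SeedSequence(seed).spawn(plan.n_repetitions)
    cache: dict[int, pd.DataFrame] = {}
    for r, f, train, test in _fold_slices(plan):
        if r not in cache:
            rng = np.random.default_rng(children[r])
            ref = draw_reference_subsample(
                phenotypes, features.subject_ids, rng, fraction=0.8
            )
            model = fit_reference_model(
                features, phenotypes, spec=spec, reference_ids=ref,
                empirical_bayes=empirical_bayes,
            )
            cache[r] = apply_model(model, features, phenotypes, spec=spec).data
        H = cache[r]
        yield FoldData(r, f, train, test, H.loc[train], H.loc[test])


def strategy_internal(
    features: FeatureMatrix,
    phenotypes: pd.DataFrame,
    plan,
    spec: CovariateSpec | None = None,
    empirical_bayes: bool = True,
) -> Iterator[FoldData]:
    """Leakage-free harmonization: refit per fold on training-fold TD only.

    The transform applied to a test subject is a function of the training
    fold and that subject's own row; a test subject whose site has no TD in
    the training fold raises, signalling a broken CV plan.
    """
    pheno = phenotypes.set_index("subject_id")
    for r, f, train, test in _fold_slices(plan):
        ref = [s for s in train if pheno.at[s, "diagnosis"] == "TD"]
        model = fit_reference_model(
            features.subset(train), phenotypes, spec=spec,
            reference_ids=ref, empirical_bayes=empirical_bayes,
        )
        H_train = apply_model(model, features.subset(train), phenotypes, spec=spec)
        H_test = apply_model(model, features.subset(test), phenotypes, spec=spec)
        yield FoldData(r, f, train, test, H_train.data, H_test.data)


def get_strategy(name: str):
    """Look up a deployment strategy by name."""
    table = {
        "none": strategy_none,
        "external": strategy_external,
        "external45": strategy_external_45,
        "internal": strategy_internal,
    }
    if name not in table:
        raise ParameterError(
            f"unknown strategy {name!r}; expected one of {STRATEGY_NAMES}"
        )
    return table[name]
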