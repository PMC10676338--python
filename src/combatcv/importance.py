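"""Permutation feature importance and cross-strategy agreement.

The importance of a feature to a fitted classifier is the drop in test-set
AUC when that feature's column is shuffled within the test set — the
feature stays present but carries no information, so no retraining is
needed.  Importance is computed per fold and repetition of the CV scheme,
averaged over all folds, with a dispersion taken over the per-repetition
means.

The top 30% of features by mean importance are then compared across
harmonization strategies: correlation of importance values on a reference
strategy's top set, three-way intersection of top sets, and a per-feature
marking ("C" = common to all strategies' top sets, "NP" = not present in
at least one).  Fold-to-fold correlations within each strategy quantify the
internal stability of the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AggregationError,
    ParameterError,
    SchemaError,
)
from .evaluation import CVPlan, auc, fit_svm_rbf, robust_scale
from .feature_builder import FeatureMatrix
from .harmonization import CovariateSpec, get_strategy

__all__ = [
    "ImportanceTable",
    "permutation_importance",
    "run_importance",
    "aggregate_importance",
    "top_fraction",
    "compare_strategies",
]


@dataclass
class ImportanceTable:
    """Aggregated permutation importance for one strategy and feature set.

    ``raw`` keeps every fold-level importance vector (R x k x p) so that
    dispersion and fold-stability analyses can be recomputed from it.
    """

    feature_names: list[str]
    mean: np.ndarray       # (p,) mean over all k*R folds
    sd: np.ndarray         # (p,) SD over the R repetition means
    rank: np.ndarray       # (p,) 1 = most important; ties broken by name
    strategy: str
    feature_set: str
    raw: np.ndarray        # (R, k, p)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "mean_importance": self.mean,
                "sd_importance": self.sd,
                "rank": self.rank,
            }
        ).set_index("feature")


def permutation_importance(
    classifier,
    test_X,
    test_y,
    n_shuffles: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Per-feature AUC drop on the test fold for an already-fitted classifier.

    baseline AUC minus the mean AUC over ``n_shuffles`` within-test-set
    shuffles of each column, all other columns untouched.
    """
    X = np.asarray(test_X, dtype=float)
    y = np.asarray(test_y)
    rng = np.random.default_rng(seed)
    baseline = auc(classifier.decision_function(X), y)
    n, p = X.shape
    drops = np.zeros(p)
    work = X.copy()
    for v in range(p):
        scores = np.empty(n_shuffles)
        for s in range(n_shuffles):
            perm = rng.permutation(n)
            work[:, v] = X[perm, v]
            scores[s] = auc(classifier.decision_function(work), y)
        work[:, v] = X[:, v]
        drops[v] = baseline - scores.mean()
    return drops


def run_importance(
    features: FeatureMatrix,
    phenotypes: pd.DataFrame,
    strategy: str,
    plan: CVPlan,
    spec: CovariateSpec | None = None,
    n_shuffles: int = 5,
    seed: int = 0,
) -> ImportanceTable:
    """Permutation importance across a full CV scheme under one strategy."""
    pheno = phenotypes.set_index("subject_id")
    strat = get_strategy(strategy)
    kwargs = {"seed": seed} if strategy == "external45" else {}
    p = len(features.feature_names)
    raw = np.full((plan.n_repetitions, plan.n_folds, p), np.nan)
    shuffle_seeds = np.random.SeedSequence(seed + 7).generate_state(
        plan.n_repetitions * plan.n_folds
    )
    for fd in strat(features, phenotypes, plan, spec=spec, **kwargs):
        y_train = (pheno.loc[fd.train_ids, "diagnosis"] == "ASD").to_numpy()
        y_test = (pheno.loc[fd.test_ids, "diagnosis"] == "ASD").to_numpy()
        tr, te = robust_scale(fd.train, fd.test)
        clf = fit_svm_rbf(tr, y_train)
        child = int(shuffle_seeds[fd.repetition * plan.n_folds + fd.fold]) % (2**31)
        raw[fd.repetition, fd.fold] = permutation_importance(
            clf, te, y_test, n_shuffles=n_shuffles, seed=child
        )
    return aggregate_importance(raw, features.feature_names, strategy, features.kind)


def aggregate_importance(
    raw: np.ndarray,
    feature_names: Sequence[str],
    strategy: str = "",
    feature_set: str = "",
) -> ImportanceTable:
    """Aggregate fold-level importance arrays into an :class:`ImportanceTable`.

    Mean over all k*R folds; SD over the R per-repetition means (sample SD);
    descending-importance ranks with ties broken by feature-name order.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 3:
        raise AggregationError(
            f"expected (repetitions, folds, features) array, got shape {raw.shape}"
        )
    if raw.shape[2] != len(feature_names):
        raise AggregationError(
            f"{raw.shape[2]} importance columns vs {len(feature_names)} feature names"
        )
    if np.isnan(raw).any():
        raise AggregationError("missing fold results (NaN) in importance arrays")
    mean = raw.mean(axis=(0, 1))
    rep_means = raw.mean(axis=1)  # (R, p)
    sd = rep_means.std(axis=0, ddof=1) if raw.shape[0] > 1 else np.zeros_like(mean)
    order = sorted(range(len(feature_names)),
                   key=lambda i: (-mean[i], feature_names[i]))
    rank = np.empty(len(feature_names), dtype=int)
    rank[order] = np.arange(1, len(feature_names) + 1)
    return ImportanceTable(
        feature_names=list(feature_names),
        mean=mean, sd=sd, rank=rank,
        strategy=strategy, feature_set=feature_set, raw=raw,
    )


def top_fraction(table: ImportanceTable, fraction: float = 0.30) -> list[str]:
    """The most important ``round(fraction * p)`` features, best first.

    The count is the round-half-to-even nearest integer (e.g. 30% of 5253
    features is 1576 and 30% of 221 is 66).
    """
    if not 0 < fraction <= 1:
        raise ParameterError(f"fraction must be in (0, 1], got {fraction}")
    p = len(table.feature_names)
    if p == 0:
        raise ParameterError("empty importance table")
    count = int(round(fraction * p))
    by_rank = sorted(
        zip(table.rank.tolist(), table.feature_names)
    )
    return [name for _, name in by_rank[:count]]


def _fold_mean_correlations(table: ImportanceTable) -> np.ndarray:
    """k x k correlation matrix of per-fold mean importance vectors."""
    fold_means = table.raw.mean(axis=0)  # (k, p)
    return np.corrcoef(fold_means)


def compare_strategies(
    tables: Mapping[str, ImportanceTable],
    reference: str,
    fraction: float = 0.30,
    method: str = "pearson",
) -> dict:
    """Agreement of importance rankings across harmonization strategies.

    Restricted to the reference strategy's top-``fraction`` feature set:
    correlation of importance values between the reference and every other
    strategy, the across-strategy intersection of top sets (count and
    percentage), per-feature C/NP markings, and the within-strategy
    fold-to-fold correlation matrices.
    """
    if reference not in tables:
        raise ParameterError(f"reference strategy {reference!r} not in tables")
    if method not in ("pearson", "spearman"):
        raise ParameterError(f"unknown correlation method {method!r}")
    names = tables[reference].feature_names
    for s, t in tables.items():
        if t.feature_names != names:
            raise SchemaError(
                f"strategy {s!r} has a different feature set than the reference"
            )
    ref = tables[reference]
    ref_top = top_fraction(ref, fraction)
    ref_idx = [names.index(f) for f in ref_top]
    top_sets = {s: set(top_fraction(t, fraction)) for s, t in tables.items()}

    corr_fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    correlations = {}
    for s, t in tables.items():
        if s == reference:
            continue
        r = corr_fn(ref.mean[ref_idx], t.mean[ref_idx]).statistic
        correlations[s] = float(r)

    common = set(ref_top)
    for s in top_sets.values():
        common &= s
    marks = {
        f: "C" if all(f in top_sets[s] for s in tables) else "NP"
        for f in ref_top
    }
    fold_corr = {
        s: _fold_mean_correlations(t).tolist() for s, t in tables.items()
    }
    return {
        "reference": reference,
        "fraction": fraction,
        "method": method,
        "top_set_size": len(ref_top),
        "correlation_with_reference": correlations,
        "common_count": len(common),
        "common_percent": 100.0 * len(common) / len(ref_top) if ref_top else 0.0,
        "marks": marks,
        "fold_correlations": fold_corr,
    }
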