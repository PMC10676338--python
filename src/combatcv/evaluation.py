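"""Classification and site-distinguishability protocols.

Two evaluation tasks share the same machinery:

* **Case/control classification** — a soft-margin SVM with a Gaussian
  (RBF) kernel at default settings, inside a stratified k-fold CV plan
  (stratified jointly on class and site) repeated R times.  Features are
  robust-scaled (training-fold median and IQR) inside each fold, and
  performance is the AUC of the decision scores, aggregated as mean and SD
  over all k*R test folds.

* **Site distinguishability audit** — for every unordered pair of sites
  with enough control subjects, train the same classifier to tell the two
  sites apart using controls only, on the data each harmonization strategy
  would feed the classifier.  The first 20 principal components (fit on the
  training fold) reduce dimensionality.  Per-pair AUCs are summarized as
  the median and 25th/75th percentiles across pairs.  An unharmonized
  multi-site dataset yields near-perfect pair AUCs; a fully (externally)
  harmonized one sits near chance.

Seeding: a master seed spawns per-repetition (and per-pair) child seeds via
``numpy.random.SeedSequence``, so any single fold is re-runnable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import (
    EvaluationError,
    FitError,
    ParameterError,
    SchemaError,
    UndefinedMetricError,
)
from .feature_builder import FeatureMatrix
from .harmonization import (
    CovariateSpec,
    apply_model,
    draw_reference_subsample,
    fit_reference_model,
    get_strategy,
)

__all__ = [
    "CVPlan",
    "ClassificationResult",
    "SitePairResult",
    "make_cv_plan",
    "robust_scale",
    "fit_svm_rbf",
    "svm_rbf_fit_score",
    "auc",
    "run_asd_td",
    "pca_reduce",
    "site_distinguishability",
]


@dataclass
class CVPlan:
    """Fold assignments for every repetition of a stratified k-fold scheme.

    ``assignments[r, j]`` is the test-fold index of subject j in
    repetition r; within each repetition the folds partition the subjects.
    """

    subject_ids: list[str]
    n_folds: int
    n_repetitions: int
    assignments: np.ndarray  # (R, n) int
    seed: int

    def test_ids(self, repetition: int, fold: int) -> list[str]:
        mask = self.assignments[repetition] == fold
        return [s for s, m in zip(self.subject_ids, mask) if m]

    def train_ids(self, repetition: int, fold: int) -> list[str]:
        mask = self.assignments[repetition] != fold
        return [s for s, m in zip(self.subject_ids, mask) if m]


@dataclass
class ClassificationResult:
    """Per-fold AUCs plus their aggregate for one strategy/feature set."""

    strategy: str
    feature_set: str
    aucs: np.ndarray  # (R, k)

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())

    @property
    def sd_auc(self) -> float:
        return float(self.aucs.std(ddof=1)) if self.aucs.size > 1 else 0.0


@dataclass
class SitePairResult:
    """Per-pair site AUCs with the across-pair median and quartiles."""

    strategy: str
    feature_set: str
    pairs: list[tuple[str, str]]
    pair_aucs: dict[tuple[str, str], np.ndarray]  # fold-level values per pair

    @property
    def pair_means(self) -> dict[tuple[str, str], float]:
        return {p: float(v.mean()) for p, v in self.pair_aucs.items()}

    def summary(self) -> dict[str, float]:
        means = np.array([v.mean() for v in self.pair_aucs.values()])
        return {
            "median": float(np.median(means)),
            "q25": float(np.percentile(means, 25)),
            "q75": float(np.percentile(means, 75)),
        }


def _child_states(seed: int, n: int) -> list[int]:
    # 31-bit child seeds usable as sklearn random_state
    return [int(s) % (2**31) for s in np.random.SeedSequence(seed).generate_state(n)]


def make_cv_plan(
    class_labels: pd.Series,
    site_labels: pd.Series,
    k: int = 5,
    repetitions: int = 50,
    seed: int = 0,
) -> CVPlan:
    """Stratified k-fold plan, stratified jointly on (class, site).

    Both label series must be indexed by subject ID.  Cells with fewer than
    k members cannot be spread over every fold; a warning is emitted and
    stratification degrades gracefully for those cells.
    """
    if k < 2:
        raise ParameterError(f"k must be >= 2, got {k}")
    if repetitions < 1:
        raise ParameterError(f"repetitions must be >= 1, got {repetitions}")
    if not class_labels.index.equals(site_labels.index):
        raise SchemaError("class and site labels are indexed differently")
    ids = list(class_labels.index)
    joint = (class_labels.astype(str) + "||" + site_labels.astype(str)).to_numpy()
    cell_counts = pd.Series(joint).value_counts()
    small = cell_counts[cell_counts < k]
    if len(small):
        warnings.warn(
            f"(class, site) cells with fewer than k={k} members: "
            f"{small.to_dict()}; stratification will be approximate",
            RuntimeWarning,
            stacklevel=2,
        )
        # collapse undersized cells onto the class label so folds still
        # balance the classes; site balance degrades gracefully
        in_small = np.isin(joint, small.index.to_numpy())
        joint = joint.copy()
        joint[in_small] = class_labels.astype(str).to_numpy()[in_small]
        if pd.Series(joint).value_counts().max() < k:
            # fewer subjects per class than folds: plain shuffled folds
            joint = np.zeros(len(ids))
    assignments = np.empty((repetitions, len(ids)), dtype=np.int32)
    for r, state in enumerate(_child_states(seed, repetitions)):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=state)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sklearn small-class warnings
            for fold, (_, test_idx) in enumerate(
                skf.split(np.zeros(len(ids)), joint)
            ):
                assignments[r, test_idx] = fold
    return CVPlan(ids, k, repetitions, assignments, seed)


def robust_scale(
    train: pd.DataFrame, test: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median-center and IQR-scale using training statistics only.

    IQR is the 75th minus 25th percentile with linear interpolation.
    A degenerate (zero) IQR leaves the scale at 1, so constant features
    are centered but never produce non-finite values.
    """
    if train.empty:
        raise SchemaError("empty training set")
    X = train.to_numpy(dtype=float)
    med = np.median(X, axis=0)
    q75, q25 = np.percentile(X, [75, 25], axis=0)
    iqr = q75 - q25
    iqr[iqr == 0] = 1.0
    return (train - med) / iqr, (test - med) / iqr


def fit_svm_rbf(train_X, train_y) -> SVC:
    """Gaussian-kernel soft-margin classifier at default settings.

    C = 1 and kernel coefficient gamma = 1 / (p * Var(X_train)), the
    scikit-learn ``gamma='scale'`` convention.
    """
    y = np.asarray(train_y)
    if len(np.unique(y)) < 2:
        raise FitError("training fold contains a single class")
    clf = SVC(C=1.0, kernel="rbf", gamma="scale")
    clf.fit(np.asarray(train_X, dtype=float), y)
    return clf


def svm_rbf_fit_score(train_X, train_y, test_X) -> np.ndarray:
    """Fit the RBF SVM and return real-valued decision scores on the test set."""
    clf = fit_svm_rbf(train_X, train_y)
    return clf.decision_function(np.asarray(test_X, dtype=float))


def auc(scores, labels) -> float:
    """Rank-based AUC: P(correctly ordering a case-control pair), ties = 1/2."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError(
            "AUC undefined: only one class present in the labels"
        )
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def run_asd_td(
    features: FeatureMatrix,
    phenotypes: pd.DataFrame,
    strategy: str,
    plan: CVPlan,
    spec: CovariateSpec | None = None,
    seed: int = 0,
) -> ClassificationResult:
    """Case/control classification under one harmonization strategy.

    For every fold of every repetition: obtain the strategy's (train, test)
    matrices, robust-scale inside the fold, fit the RBF SVM, score the test
    fold, and record the AUC.
    """
    pheno = phenotypes.set_index("subject_id")
    strat = get_strategy(strategy)
    kwargs = {"seed": seed} if strategy == "external45" else {}
    aucs = np.full((plan.n_repetitions, plan.n_folds), np.nan)
    for fd in strat(features, phenotypes, plan, spec=spec, **kwargs):
        y_train = (pheno.loc[fd.train_ids, "diagnosis"] == "ASD").to_numpy()
        y_test = (pheno.loc[fd.test_ids, "diagnosis"] == "ASD").to_numpy()
        tr, te = robust_scale(fd.train, fd.test)
        scores = svm_rbf_fit_score(tr, y_train, te)
        aucs[fd.repetition, fd.fold] = auc(scores, y_test)
    return ClassificationResult(strategy, features.kind, aucs)


def pca_reduce(
    train, test, n_components: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Project onto the leading principal components of the training fold.

    Components are estimated from the centered training matrix only and the
    training center/loadings are applied to the test matrix.  If the
    training fold cannot support ``n_components`` the reduction falls back
    to what is available, with a warning.
    """
    Xtr = np.asarray(train, dtype=float)
    Xte = np.asarray(test, dtype=float)
    cap = min(Xtr.shape[0] - 1, Xtr.shape[1])
    if n_components > cap:
        warnings.warn(
            f"n_components={n_components} exceeds available rank {cap}; "
            "reducing",
            RuntimeWarning,
            stacklevel=2,
        )
        n_components = cap
    pca = PCA(n_components=n_components, svd_solver="full")
    return pca.fit_transform(Xtr), pca.transform(Xte)


def site_distinguishability(
    features: FeatureMatrix,
    phenotypes: pd.DataFrame,
    strategy: str,
    spec: CovariateSpec | None = None,
    k: int = 5,
    repetitions: int = 10,
    min_td: int = 20,
    n_components: int = 20,
    seed: int = 0,
    empirical_bayes: bool = True,
) -> SitePairResult:
    """Pairwise TD-only site classification under one strategy's data.

    External variants harmonize the whole matrix up front (the 4/5 variant
    redraws its reference subset each repetition); the internal strategy
    refits inside each training fold using the training TD of the two
    sites.  PCA is fit inside each training fold.  Only sites with at
    least ``min_td`` TD subjects participate.
    """
    if strategy not in ("none", "external", "external45", "internal"):
        raise ParameterError(f"unknown strategy {strategy!r}")
    pheno = phenotypes.set_index("subject_id")
    td_ids = [s for s in features.subject_ids if pheno.at[s, "diagnosis"] == "TD"]
    td_sites = pheno.loc[td_ids, "site"]
    counts = td_sites.value_counts()
    qualifying = sorted(counts[counts >= min_td].index)
    if len(qualifying) < 2:
        raise EvaluationError(
            f"fewer than 2 sites have >= {min_td} TD subjects"
        )
    pairs = list(combinations(qualifying, 2))

    # pre-harmonized matrices per repetition for the external variants
    rep_matrices: dict[int, pd.DataFrame] = {}
    if strategy == "none":
        for r in range(repetitions):
            rep_matrices[r] = features.data
    elif strategy == "external":
        model = fit_reference_model(
            features, phenotypes, spec=spec, reference_ids=td_ids,
            empirical_bayes=empirical_bayes,
        )
        H = apply_model(model, features, phenotypes, spec=spec).data
        for r in range(repetitions):
            rep_matrices[r] = H
    elif strategy == "external45":
        children = np.random.SeedSequence(seed).spawn(repetitions)
        for r in range(repetitions):
            rng = np.random.default_rng(children[r])
            ref = draw_reference_subsample(
                phenotypes, features.subject_ids, rng, fraction=0.8
            )
            model = fit_reference_model(
                features, phenotypes, spec=spec, reference_ids=ref,
                empirical_bayes=empirical_bayes,
            )
            rep_matrices[r] = apply_model(
                model, features, phenotypes, spec=spec
            ).data

    states = _child_states(seed + 1, repetitions * len(pairs))
    pair_aucs: dict[tuple[str, str], np.ndarray] = {}
    for p_idx, (a, b) in enumerate(pairs):
        ids = [s for s in td_ids if td_sites[s] in (a, b)]
        y = (td_sites.loc[ids] == b).to_numpy()
        vals = []
        for r in range(repetitions):
            state = states[p_idx * repetitions + r]
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=state)
            for train_idx, test_idx in skf.split(np.zeros(len(ids)), y):
                train = [ids[i] for i in train_idx]
                test = [ids[i] for i in test_idx]
                if strategy == "internal":
                    model = fit_reference_model(
                        features.subset(train), phenotypes, spec=spec,
                        reference_ids=train, empirical_bayes=empirical_bayes,
                    )
                    Xtr = apply_model(
                        model, features.subset(train), phenotypes, spec=spec
                    ).data
                    Xte = apply_model(
                        model, features.subset(test), phenotypes, spec=spec
                    ).data
                else:
                    M = rep_matrices[r]
                    Xtr, Xte = M.loc[train], M.loc[test]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    Ztr, Zte = pca_reduce(Xtr, Xte, n_components=n_components)
                scores = svm_rbf_fit_score(Ztr, y[train_idx], Zte)
                vals.append(auc(scores, y[test_idx]))
        pair_aucs[(a, b)] = np.asarray(vals)
    return SitePairResult(strategy, features.kind, pairs, pair_aucs)
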