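"""CV planning, scaling, the RBF classifier, AUC, and the site audit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from combatcv import (
    SyntheticConfig,
    auc,
    generate_cohort,
    generate_feature_matrix,
    make_cv_plan,
    pca_reduce,
    robust_scale,
    run_asd_td,
    site_distinguishability,
    svm_rbf_fit_score,
)
from combatcv.errors import (
    EvaluationError,
    FitError,
    ParameterError,
    UndefinedMetricError,
)
from combatcv.evaluation import fit_svm_rbf


def _labels(n, k_sites=2, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n)]
    cls = pd.Series(rng.choice(["ASD", "TD"], size=n), index=ids)
    site = pd.Series(rng.choice([f"site{j}" for j in range(k_sites)], size=n),
                     index=ids)
    return cls, site


class TestMakeCvPlan:
    def test_partition_and_fold_sizes(self):
        cls, site = _labels(100)
        plan = make_cv_plan(cls, site, k=5, repetitions=3, seed=0)
        for r in range(3):
            sizes = [len(plan.test_ids(r, f)) for f in range(5)]
            assert sizes == [20] * 5
            covered = sorted(s for f in range(5) for s in plan.test_ids(r, f))
            assert covered == sorted(plan.subject_ids)

    def test_class_ratio_stratified(self):
        cls, site = _labels(100, k_sites=1)
        plan = make_cv_plan(cls, site, k=5, repetitions=2, seed=1)
        global_n_asd = (cls == "ASD").sum()
        for r in range(2):
            for f in range(5):
                fold_asd = sum(cls[s] == "ASD" for s in plan.test_ids(r, f))
                assert abs(fold_asd - global_n_asd / 5) <= 1

    def test_deterministic(self):
        cls, site = _labels(60)
        a = make_cv_plan(cls, site, k=5, repetitions=2, seed=9)
        b = make_cv_plan(cls, site, k=5, repetitions=2, seed=9)
        np.testing.assert_array_equal(a.assignments, b.assignments)

    def test_k_too_small(self):
        cls, site = _labels(20)
        with pytest.raises(ParameterError):
            make_cv_plan(cls, site, k=1)

    def test_small_cell_warns(self):
        cls, site = _labels(12, k_sites=4, seed=3)
        with pytest.warns(RuntimeWarning, match="fewer than"):
            make_cv_plan(cls, site, k=5, repetitions=1, seed=0)


class TestRobustScale:
    def test_hand_computed_median_iqr(self):
        train = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0]})
        test = pd.DataFrame({"x": [5.0]})
        tr, te = robust_scale(train, test)
        # median 3, IQR 2 (linear-interpolation percentiles)
        assert te["x"].iloc[0] == pytest.approx(1.0)
        assert tr["x"].tolist() == pytest.approx([-1.0, -0.5, 0.0, 0.5, 1.0])

    def test_constant_column_centered_only(self):
        train = pd.DataFrame({"c": [7.0] * 5})
        tr, te = robust_scale(train, pd.DataFrame({"c": [9.0]}))
        assert (tr["c"] == 0).all()
        assert te["c"].iloc[0] == pytest.approx(2.0)

    def test_inverse_scaling_round_trip(self):
        rng = np.random.default_rng(0)
        train = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"))
        tr, _ = robust_scale(train, train)
        med = np.median(train, axis=0)
        iqr = np.percentile(train, 75, axis=0) - np.percentile(train, 25, axis=0)
        np.testing.assert_allclose(tr * iqr + med, train, atol=1e-12)


class TestSvmRbf:
    def test_separable_blobs_perfect_auc(self):
        rng = np.random.default_rng(1)
        train = np.vstack([rng.normal(0, 0.3, (20, 2)),
                           rng.normal(5, 0.3, (20, 2))])
        y = np.repeat([0, 1], 20)
        test = np.vstack([rng.normal(0, 0.3, (10, 2)),
                          rng.normal(5, 0.3, (10, 2))])
        scores = svm_rbf_fit_score(train, y, test)
        assert auc(scores, np.repeat([0, 1], 10)) == 1.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(2)
        aucs = []
        for _ in range(20):
            X = rng.standard_normal((60, 5))
            y = rng.permutation(np.repeat([0, 1], 30))
            Xt = rng.standard_normal((40, 5))
            yt = np.repeat([0, 1], 20)
            aucs.append(auc(svm_rbf_fit_score(X, y, Xt), yt))
        mean, sd = np.mean(aucs), np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(mean - 0.5) < max(3 * sd, 0.05)

    def test_kernel_coefficient_formula(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 4)) * 2.5
        y = np.repeat([0, 1], 15)
        clf = fit_svm_rbf(X, y)
        assert clf._gamma == pytest.approx(1.0 / (X.shape[1] * X.var()))

    def test_single_class_training_raises(self):
        with pytest.raises(FitError):
            fit_svm_rbf(np.zeros((5, 2)), np.zeros(5))


class TestAuc:
    def test_reference_cases(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert auc([0.5] * 6, [0, 0, 0, 1, 1, 1]) == 0.5
        # 4 case-control pairs: 3 ordered correctly, 1 wrong
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_one_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auc([0.2, 0.4], [1, 1])

    @given(st.permutations(list(range(8))))
    @settings(derandomize=True, deadline=None)
    def test_invariance_under_monotone_transform(self, ranks):
        scores = np.asarray(ranks, dtype=float)
        labels = np.array([0, 1] * 4)
        transformed = np.exp(scores / 3.0) + 7.0
        assert auc(scores, labels) == pytest.approx(auc(transformed, labels))


class TestPcaReduce:
    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(4)
        train = rng.standard_normal((5, 4))
        test = rng.standard_normal((2, 4))
        Ztr, Zte = pca_reduce(train, test, n_components=3)
        Xc = train - train.mean(axis=0)
        cov = Xc.T @ Xc / (len(train) - 1)
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1][:3]
        V = vecs[:, order]
        np.testing.assert_allclose(np.abs(Ztr), np.abs(Xc @ V), atol=1e-8)
        np.testing.assert_allclose(
            np.abs(Zte), np.abs((test - train.mean(axis=0)) @ V), atol=1e-8
        )

    def test_component_variances_non_increasing(self):
        rng = np.random.default_rng(5)
        train = rng.standard_normal((40, 6)) * np.array([5, 4, 3, 2, 1, 0.5])
        Ztr, _ = pca_reduce(train, train, n_components=6)
        v = Ztr.var(axis=0)
        assert (np.diff(v) <= 1e-10).all()

    def test_rank_deficit_warns_and_caps(self):
        rng = np.random.default_rng(6)
        train = rng.standard_normal((4, 10))
        with pytest.warns(RuntimeWarning, match="exceeds"):
            Ztr, _ = pca_reduce(train, train, n_components=8)
        assert Ztr.shape[1] == 3

    def test_exact_low_rank_reconstruction(self):
        rng = np.random.default_rng(7)
        basis = rng.standard_normal((3, 8))
        train = rng.standard_normal((30, 3)) @ basis
        Ztr, _ = pca_reduce(train, train, n_components=3)
        # 3 components capture a rank-3 matrix exactly
        total = ((train - train.mean(0)) ** 2).sum()
        assert Ztr.var(axis=0, ddof=1).sum() * (len(train) - 1) == pytest.approx(
            total, rel=1e-8
        )


class TestRunAsdTd:
    def _cohort(self, **kw):
        cfg = SyntheticConfig(
            n_sites=2, subjects_per_site=60, n_features=10,
            site_location_sd=0.5, **kw,
        )
        pheno = generate_cohort(cfg, seed=13)
        feats, truth = generate_feature_matrix(pheno, cfg, seed=13)
        idx = pheno.set_index("subject_id")
        plan = make_cv_plan(idx["diagnosis"], idx["site"], k=5, repetitions=2,
                            seed=13)
        return pheno, feats, plan

    def test_null_effect_near_chance(self):
        pheno, feats, plan = self._cohort(diag_effect_size=0.0)
        res = run_asd_td(feats, pheno, "external", plan)
        sd = res.aucs.std(ddof=1) / np.sqrt(res.aucs.size)
        assert abs(res.mean_auc - 0.5) < max(2 * res.aucs.std(ddof=1), 0.1)

    def test_strong_effect_high_auc(self):
        pheno, feats, plan = self._cohort(
            diag_effect_size=1.5, diag_affected_fraction=0.5
        )
        res = run_asd_td(feats, pheno, "external", plan)
        assert res.mean_auc > 0.8

    def test_site_confounding_changed_by_harmonization(self):
        # diagnosis imbalanced across sites: site effects leak class signal
        cfg = SyntheticConfig(n_sites=2, subjects_per_site=60, n_features=10,
                              diag_effect_size=0.0, site_location_sd=3.0)
        pheno = generate_cohort(cfg, seed=17)
        by_site = pheno["site"] == "site01"
        rng = np.random.default_rng(17)
        pheno.loc[by_site, "diagnosis"] = np.where(
            rng.random(by_site.sum()) < 0.8, "ASD", "TD")
        pheno.loc[~by_site, "diagnosis"] = np.where(
            rng.random((~by_site).sum()) < 0.2, "ASD", "TD")
        feats, _ = generate_feature_matrix(pheno, cfg, seed=17)
        idx = pheno.set_index("subject_id")
        plan = make_cv_plan(idx["diagnosis"], idx["site"], k=5, repetitions=2,
                            seed=17)
        raw = run_asd_td(feats, pheno, "none", plan)
        harm = run_asd_td(feats, pheno, "external", plan)
        # harmonization removes the TD-estimated site shift; what remains is
        # the residual (gamma_true - gamma_hat_TD) carried by ASD subjects,
        # so the AUC drops materially but not to chance
        assert harm.mean_auc < raw.mean_auc - 0.05


class TestSiteDistinguishability:
    def test_identical_sites_near_chance(self):
        # exchangeable sites: no site effects and matched age windows.
        # Tolerance allows the small-sample below-chance artifact of CV on
        # signal-free data (realized train/test class means anti-correlate).
        cfg = SyntheticConfig(n_sites=2, subjects_per_site=200, n_features=15,
                              site_location_sd=0.0, site_scale_spread=0.0,
                              diag_effect_size=0.0,
                              age_range_per_site=[(8, 24)] * 2)
        pheno = generate_cohort(cfg, seed=19)
        feats, _ = generate_feature_matrix(pheno, cfg, seed=19)
        for strategy in ("none", "external"):
            res = site_distinguishability(feats, pheno, strategy,
                                          repetitions=4, min_td=20, seed=19)
            assert abs(res.summary()["median"] - 0.5) < 0.15

    def test_no_qualifying_pair_raises(self):
        cfg = SyntheticConfig(n_sites=2, subjects_per_site=10)
        pheno = generate_cohort(cfg, seed=0)
        feats, _ = generate_feature_matrix(pheno, cfg, seed=0)
        with pytest.raises(EvaluationError):
            site_distinguishability(feats, pheno, "none", min_td=20)

    def test_pairs_are_unordered_and_unique(self, small_cohort):
        _, pheno, feats, _ = small_cohort
        res = site_distinguishability(feats, pheno, "none", repetitions=1,
                                      min_td=10, n_components=5, seed=0)
        assert len(res.pairs) == len(set(map(frozenset, res.pairs))) == 3
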