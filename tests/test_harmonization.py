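"""Reference-ComBat fitting, application, and the deployment strategies."""

import numpy as np
import pandas as pd
import pytest

from combatcv import (
    CovariateSpec,
    HarmonizationModel,
    SyntheticConfig,
    apply_model,
    fit_reference_model,
    generate_cohort,
    generate_feature_matrix,
    get_strategy,
    make_cv_plan,
    strategy_external,
    strategy_external_45,
    strategy_internal,
    strategy_none,
)
from combatcv.errors import (
    DegenerateFeatureError,
    FitError,
    ParameterError,
    UnknownSiteError,
)
from combatcv.feature_builder import FeatureMatrix
from conftest import toy_phenotypes


def _plan(pheno, ids=None, k=3, reps=2, seed=0):
    idx = pheno.set_index("subject_id")
    ids = ids if ids is not None else pheno["subject_id"].tolist()
    return make_cv_plan(idx.loc[ids, "diagnosis"], idx.loc[ids, "site"],
                        k=k, repetitions=reps, seed=seed)


class TestFitAndApply:
    def test_single_site_fit_is_identity(self, small_cohort):
        _, pheno, feats, _ = small_cohort
        one = pheno[pheno["site"] == "site01"]
        ids = one["subject_id"].tolist()
        sub = feats.subset(ids)
        model = fit_reference_model(sub, pheno, reference_ids=ids)
        np.testing.assert_allclose(model.gamma_star, 0.0, atol=1e-10)
        np.testing.assert_allclose(model.delta_star, 1.0, atol=1e-10)
        out = apply_model(model, sub, pheno)
        np.testing.assert_allclose(out.data.to_numpy(), sub.data.to_numpy(),
                                   atol=1e-10)

    def test_pure_location_shift_recovered(self):
        cfg = SyntheticConfig(
            n_sites=2, subjects_per_site=400, n_features=8,
            site_location_sd=0.0, site_scale_spread=0.0,
            diag_effect_size=0.0, age_slope_sd=0.0, noise_sd=1.0,
        )
        pheno = generate_cohort(cfg, seed=11)
        feats, _ = generate_feature_matrix(pheno, cfg, seed=11)
        delta = 1.7
        shifted = feats.data.copy()
        site2 = pheno.loc[pheno["site"] == "site02", "subject_id"]
        shifted.loc[site2] += delta
        model = fit_reference_model(
            FeatureMatrix(shifted, kind=feats.kind), pheno
        )
        gap = (model.gamma_star[1] - model.gamma_star[0]) * model.sigma
        np.testing.assert_allclose(gap, delta, atol=0.2)

    def test_eb_shrinkage_is_convex(self, small_cohort):
        # posterior means lie between the raw estimate and the prior mean
        _, pheno, feats, _ = small_cohort
        model = fit_reference_model(feats, pheno)
        for i, site in enumerate(model.site_names):
            g_bar = model.hyperparameters[site]["gamma_bar"]
            lo = np.minimum(model.gamma_hat[i], g_bar) - 1e-10
            hi = np.maximum(model.gamma_hat[i], g_bar) + 1e-10
            assert ((model.gamma_star[i] >= lo) & (model.gamma_star[i] <= hi)).all()

    def test_covariate_preserved_and_site_effect_removed(self):
        cfg = SyntheticConfig(n_sites=3, subjects_per_site=150, n_features=10,
                              age_slope_sd=0.1, diag_effect_size=0.0)
        pheno = generate_cohort(cfg, seed=21)
        feats, truth = generate_feature_matrix(pheno, cfg, seed=21)
        model = fit_reference_model(feats, pheno)
        H = apply_model(model, feats, pheno)
        age = pheno["age"].to_numpy()
        X = np.column_stack([np.ones_like(age), age])
        coef, *_ = np.linalg.lstsq(X, H.data.to_numpy(), rcond=None)
        # the recovered slope is essentially the model's TD-fitted slope, so
        # its sampling error vs truth is governed by the reference fit
        td_mask = (pheno["diagnosis"] == "TD").to_numpy()
        td_age = age[td_mask]
        se = model.sigma / np.sqrt(np.sum((td_age - td_age.mean()) ** 2))
        assert (np.abs(coef[1] - truth.age_slope) < 3 * se).all()
        td = pheno[pheno["diagnosis"] == "TD"].set_index("subject_id")

        def site_mean_var(F):
            g = F.data.loc[td.index].groupby(td["site"]).mean()
            return float(g.var(axis=0, ddof=0).mean())

        assert site_mean_var(H) < 0.1 * site_mean_var(feats)

    def test_apply_is_row_wise(self, small_cohort):
        # perturbing one non-reference subject leaves every other row intact
        _, pheno, feats, _ = small_cohort
        model = fit_reference_model(feats, pheno)
        out1 = apply_model(model, feats, pheno).data
        poked = feats.data.copy()
        asd_id = pheno.loc[pheno["diagnosis"] == "ASD", "subject_id"].iloc[0]
        poked.loc[asd_id] += 99.0
        out2 = apply_model(
            model, FeatureMatrix(poked, kind=feats.kind), pheno
        ).data
        others = [s for s in out1.index if s != asd_id]
        np.testing.assert_array_equal(out1.loc[others], out2.loc[others])

    def test_fit_invariant_to_subject_order(self, small_cohort):
        _, pheno, feats, _ = small_cohort
        model1 = fit_reference_model(feats, pheno)
        perm = feats.data.sample(frac=1.0, random_state=5)
        model2 = fit_reference_model(
            FeatureMatrix(perm, kind=feats.kind), pheno
        )
        np.testing.assert_allclose(model1.gamma_star, model2.gamma_star,
                                   atol=1e-10)
        np.testing.assert_allclose(model1.sigma, model2.sigma, atol=1e-10)

    def test_unknown_site_raises_not_passthrough(self, small_cohort):
        _, pheno, feats, _ = small_cohort
        ref = pheno[pheno["site"] != "site03"]
        model = fit_reference_model(
            feats.subset(ref["subject_id"].tolist()), pheno,
            reference_ids=ref.loc[ref["diagnosis"] == "TD", "subject_id"].tolist(),
        )
        with pytest.raises(UnknownSiteError):
            apply_model(model, feats, pheno)

    def test_small_reference_site_raises(self):
        pheno = toy_phenotypes(
            [{"site": "A"} for _ in range(6)] + [{"site": "B"}]
        )
        rng = np.random.default_rng(0)
        feats = FeatureMatrix(pd.DataFrame(
            rng.standard_normal((7, 4)), index=pheno["subject_id"],
            columns=list("wxyz"),
        ))
        with pytest.raises(FitError, match="B"):
            fit_reference_model(feats, pheno)

    def test_degenerate_feature_raises(self):
        pheno = toy_phenotypes([{"site": s} for s in "AAABBB"])
        data = pd.DataFrame(
            {"flat": np.ones(6), "ok": np.arange(6.0)},
            index=pheno["subject_id"],
        )
        with pytest.raises(DegenerateFeatureError, match="flat"):
            fit_reference_model(FeatureMatrix(data), pheno)

    def test_diagnosis_cannot_be_a_covariate(self):
        with pytest.raises(ParameterError):
            CovariateSpec(covariates=("age", "diagnosis"))

    def test_model_json_round_trip(self, small_cohort, tmp_path):
        _, pheno, feats, _ = small_cohort
        model = fit_reference_model(feats, pheno)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = HarmonizationModel.from_json(path)
        np.testing.assert_allclose(back.gamma_star, model.gamma_star)
        np.testing.assert_allclose(back.beta, model.beta)
        assert back.site_names == model.site_names

    def test_no_eb_matches_raw_estimates(self, small_cohort):
        _, pheno, feats, _ = small_cohort
        model = fit_reference_model(feats, pheno, empirical_bayes=False)
        np.testing.assert_array_equal(model.gamma_star, model.gamma_hat)
        np.testing.assert_array_equal(model.delta_star, model.delta_hat)

    def test_weighted_site_effects_sum_to_zero(self, small_cohort):
        _, pheno, feats, _ = small_cohort
        model = fit_reference_model(feats, pheno)
        n = np.array([model.n_reference[s] for s in model.site_names])
        np.testing.assert_allclose(n @ model.gamma_hat, 0.0, atol=1e-8)


class TestStrategies:
    def test_none_is_identity_per_fold(self, small_cohort):
        _, pheno, feats, _ = small_cohort
        plan = _plan(pheno)
        for fd in strategy_none(feats, pheno, plan):
            pd.testing.assert_frame_equal(fd.train, feats.data.loc[fd.train_ids])
            pd.testing.assert_frame_equal(fd.test, feats.data.loc[fd.test_ids])

    def test_external_identical_across_repetitions(self, small_cohort):
        _, pheno, feats, _ = small_cohort
        plan = _plan(pheno, reps=2)
        folds = list(strategy_external(feats, pheno, plan))
        full = {}
        for fd in folds:
            for ids, block in ((fd.train_ids, fd.train), (fd.test_ids, fd.test)):
                for s in ids:
                    row = block.loc[s].to_numpy()
                    if s in full:
                        np.testing.assert_array_equal(full[s], row)
                    full[s] = row

    def test_external_independent_of_fold_seed(self, small_cohort):
        _, pheno, feats, _ = small_cohort
        fd_a = next(iter(strategy_external(feats, pheno, _plan(pheno, seed=1))))
        fd_b = next(iter(strategy_external(feats, pheno, _plan(pheno, seed=2))))
        shared = sorted(set(fd_a.train_ids) & set(fd_b.train_ids))
        np.testing.assert_array_equal(
            fd_a.train.loc[shared].to_numpy(), fd_b.train.loc[shared].to_numpy()
        )

    def test_external45_draws_differ_across_repetitions(self, small_cohort):
        _, pheno, feats, _ = small_cohort
        plan = _plan(pheno, reps=2)
        sid = feats.subject_ids[0]
        by_rep = {}
        for fd in strategy_external_45(feats, pheno, plan, seed=3):
            block = fd.train if sid in fd.train.index else fd.test
            by_rep.setdefault(fd.repetition, block.loc[sid].to_numpy())
        assert not np.array_equal(by_rep[0], by_rep[1])

    def test_external45_subset_size(self, small_cohort):
        from combatcv.harmonization import draw_reference_subsample

        _, pheno, feats, _ = small_cohort
        rng = np.random.default_rng(0)
        ref = draw_reference_subsample(pheno, feats.subject_ids, rng)
        td = pheno[pheno["diagnosis"] == "TD"]
        expected = sum(
            round(0.8 * n) for n in td.groupby("site").size()
        )
        assert len(ref) == expected

    def test_internal_output_differs_across_folds(self, small_cohort):
        _, pheno, feats, _ = small_cohort
        plan = _plan(pheno, reps=1)
        folds = list(strategy_internal(feats, pheno, plan))
        s = folds[0].train_ids[0]
        other = next(f for f in folds[1:] if s in f.train_ids)
        assert not np.array_equal(
            folds[0].train.loc[s].to_numpy(), other.train.loc[s].to_numpy()
        )

    def test_internal_is_blind_to_test_fold(self, small_cohort):
        _, pheno, feats, _ = small_cohort
        plan = _plan(pheno, reps=1)
        fd0 = next(iter(strategy_internal(feats, pheno, plan)))
        victim = fd0.test_ids[0]
        poked = feats.data.copy()
        poked.loc[victim] += 123.0
        fd1 = next(iter(strategy_internal(
            FeatureMatrix(poked, kind=feats.kind), pheno, plan
        )))
        np.testing.assert_array_equal(fd0.train.to_numpy(), fd1.train.to_numpy())
        keep = [s for s in fd0.test_ids if s != victim]
        np.testing.assert_array_equal(
            fd0.test.loc[keep].to_numpy(), fd1.test.loc[keep].to_numpy()
        )

    def test_unknown_strategy_name(self):
        with pytest.raises(ParameterError):
            get_strategy("magic")
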