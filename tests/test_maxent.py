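import numpy as np
import pandas as pd
import pytest

from nicheshift.grid import RasterGrid, RasterStack
from nicheshift.maxent import (
    Feature,
    FeatureSet,
    MaxentModel,
    aicc_score,
    build_features,
    cross_validate,
    evaluate_auc,
    fit_maxent,
    predict_map,
    predict_map_ensemble,
    response_curve,
    select_rm,
    variable_importance,
)


def auc_oracle(pres, bg):
    """Exhaustive pair counting; ties count one half."""
    pres, bg = np.asarray(pres, float), np.asarray(bg, float)
    wins = (pres[:, None] > bg[None, :]).sum()
    ties = (pres[:, None] == bg[None, :]).sum()
    return (wins + 0.5 * ties) / (pres.size * bg.size)


def binary_feature_tables():
    """50/50 binary background, presences with mean 0.8 on the feature."""
    bg = pd.DataFrame({"x": np.r_[np.ones(50), np.zeros(50)]})
    pres = pd.DataFrame({"x": np.r_[np.ones(8), np.zeros(2)]})
    return pres, bg


def handmade_model(lam, bounds=(0.0, 1.0)):
    fs = FeatureSet([Feature("linear", ("x",))], {"x": bounds})
    return MaxentModel(
        feature_set=fs, lam=np.array([lam]), rm=1.0, n_presence=10,
        n_background=100, ln_z=0.0, entropy=0.0, penalties=np.array([0.0]),
        contributions={"x": 100.0}, gain=0.0, n_iter=0, converged=True,
    )


class TestBuildFeatures:
    def test_single_linear_feature_is_minmax_scaling(self):
        df = pd.DataFrame({"a": [2.0, 4.0, 6.0]})
        fs = build_features(df, classes=("linear",))
        np.testing.assert_allclose(fs.transform(df)[:, 0], [0.0, 0.5, 1.0])

    def test_constant_variable_dropped_with_warning(self):
        df = pd.DataFrame({"a": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            fs = build_features(df)
        assert fs.features == []

    def test_two_vars_linear_quadratic_product_count(self):
        df = pd.DataFrame({"a": [0.0, 1.0], "b": [1.0, 2.0]})
        fs = build_features(df, classes=("linear", "quadratic", "product"))
        assert len(fs.features) == 5  # 2 + 2 + 1

    def test_hinge_features_in_unit_interval(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.normal(size=200)})
        fs = build_features(df, classes=("hinge",), n_hinge_knots=10)
        F = fs.transform(df)
        assert F.shape == (200, 10)
        assert F.min() >= 0 and F.max() <= 1

    def test_clamp_truncates_to_training_bounds(self):
        train = pd.DataFrame({"a": [0.0, 1.0]})
        fs = build_features(train, classes=("linear",))
        out = fs.transform(pd.DataFrame({"a": [2.0]}), clamp=True)
        assert out[0, 0] == 1.0


class TestFitMaxent:
    def test_closed_form_single_binary_feature(self):
        pres, bg = binary_feature_tables()
        with pytest.warns(UserWarning, match="rm=0"):
            m = fit_maxent(pres, bg, rm=0.0, classes=("linear",),
                           add_samples_to_background=False)
        assert m.lam[0] == pytest.approx(np.log(4.0), abs=1e-4)

    def test_raw_sums_to_one_over_training_background(self):
        pres, bg = binary_feature_tables()
        with pytest.warns(UserWarning):
            m = fit_maxent(pres, bg, rm=0.0, classes=("linear",),
                           add_samples_to_background=False)
        assert np.exp(m.log_raw(bg)).sum() == pytest.approx(1.0, abs=1e-6)

    def test_total_shrinkage_gives_uniform_raw(self):
        pres, bg = binary_feature_tables()
        m = fit_maxent(pres, bg, rm=1e6, classes=("linear",),
                       add_samples_to_background=False)
        assert np.all(m.lam == 0.0)
        np.testing.assert_allclose(np.exp(m.log_raw(bg)), 1.0 / len(bg))

    def test_no_signal_gives_near_zero_coefficients(self):
        rng = np.random.default_rng(3)
        bg = pd.DataFrame({"a": rng.random(5000), "b": rng.random(5000)})
        m = fit_maxent(bg, bg, rm=1.0)  # presence distribution == background
        assert np.abs(m.lam).max() <= 0.05

    def test_penalized_objective_nonincreasing(self):
        rng = np.random.default_rng(7)
        bg = pd.DataFrame({"a": rng.normal(size=500), "b": rng.normal(size=500)})
        pres = pd.DataFrame({"a": rng.normal(1.0, 1.0, 80), "b": rng.normal(size=80)})
        m = fit_maxent(pres, bg, rm=1.0)
        diffs = np.diff(m.objective_trace)
        assert (diffs <= 1e-9).all()

    def test_stronger_regularization_shrinks_the_model(self):
        # the base-weighted L1 norm of the solution is non-increasing in rm
        # (a consequence of convexity); the model is also sparser overall at
        # the strong end of the grid than at the weak end
        rng = np.random.default_rng(11)
        bg = pd.DataFrame({c: rng.normal(size=800) for c in "abcd"})
        pres = pd.DataFrame(
            {"a": rng.normal(0.8, 1.0, 60), "b": rng.normal(-0.5, 1.0, 60),
             "c": rng.normal(size=60), "d": rng.normal(size=60)}
        )
        models = [fit_maxent(pres, bg, rm=rm) for rm in (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)]
        weighted_l1 = [
            float(np.abs(m.lam) @ (m.penalties / m.rm)) for m in models
        ]
        assert all(a >= b - 1e-8 for a, b in zip(weighted_l1, weighted_l1[1:]))
        assert models[-1].n_nonzero <= models[0].n_nonzero

    def test_input_validation(self):
        pres, bg = binary_feature_tables()
        with pytest.raises(ValueError, match="rm"):
            fit_maxent(pres, bg, rm=-1.0)
        with pytest.raises(ValueError, match="non-finite"):
            fit_maxent(pres.assign(x=[np.nan] * len(pres)), bg)


class TestEvaluateAuc:
    def test_perfect_separation(self):
        assert evaluate_auc([0.9, 0.8], [0.5, 0.3, 0.1]) == 1.0

    def test_partial_overlap(self):
        assert evaluate_auc([0.9, 0.4], [0.5, 0.3]) == pytest.approx(0.75)

    def test_all_ties(self):
        assert evaluate_auc([0.5, 0.5], [0.5, 0.5, 0.5]) == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            pres = np.round(rng.normal(size=rng.integers(1, 40)), 1)
            bg = np.round(rng.normal(size=rng.integers(1, 60)), 1)
            assert evaluate_auc(pres, bg) == pytest.approx(
                auc_oracle(pres, bg), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(17)
        eta_p, eta_b = rng.normal(size=30), rng.normal(size=100)
        raw_auc = evaluate_auc(np.exp(eta_p), np.exp(eta_b))
        cll_auc = evaluate_auc(1 - np.exp(-np.exp(eta_p)), 1 - np.exp(-np.exp(eta_b)))
        assert raw_auc == pytest.approx(cll_auc, abs=1e-12)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            evaluate_auc([], [0.5])


class TestCrossValidate:
    @pytest.fixture(scope="class")
    def signal_data(self):
        rng = np.random.default_rng(19)
        bg = pd.DataFrame({"a": rng.normal(size=1000), "b": rng.normal(size=1000)})
        pres = pd.DataFrame(
            {"a": rng.normal(1.5, 1.0, 100), "b": rng.normal(size=100)}
        )
        return pres, bg

    def test_folds_exhaustive_and_disjoint(self, signal_data):
        pres, bg = signal_data
        cv = cross_validate(pres, bg, k=5, rm=1.0, seed=1)
        assert sorted(np.bincount(cv.fold_of)) == [20] * 5

    def test_signal_gives_auc_above_half(self, signal_data):
        pres, bg = signal_data
        cv = cross_validate(pres, bg, k=5, rm=1.0, seed=1)
        assert all(a > 0.5 for a in cv.fold_aucs)
        assert cv.mean_auc > 0.7

    def test_same_seed_same_folds_and_aucs(self, signal_data):
        pres, bg = signal_data
        a = cross_validate(pres, bg, k=5, rm=1.0, seed=2)
        b = cross_validate(pres, bg, k=5, rm=1.0, seed=2)
        assert np.array_equal(a.fold_of, b.fold_of)
        assert a.fold_aucs == b.fold_aucs

    def test_too_few_presences_rejected(self, signal_data):
        _, bg = signal_data
        with pytest.raises(ValueError, match="fewer presences"):
            cross_validate(bg.head(3), bg, k=5, rm=1.0, seed=0)


class TestSelectRm:
    def test_aicc_hand_computation(self):
        assert aicc_score(-20.0, 2, 10) == pytest.approx(4 + 40 + 12 / 7)
        assert aicc_score(-20.0, 2, 10) == pytest.approx(45.714, abs=1e-3)

    def test_zero_parameters_reduce_to_minus_two_lnl(self):
        assert aicc_score(-33.5, 0, 10) == pytest.approx(67.0)

    def test_pole_is_nonfinite(self):
        assert not np.isfinite(aicc_score(-20.0, 9, 10))
        assert not np.isfinite(aicc_score(-20.0, 12, 10))

    def test_table_reproduces_formula_and_selects_minimum(self):
        rng = np.random.default_rng(23)
        bg = pd.DataFrame({"a": rng.normal(size=600), "b": rng.normal(size=600)})
        pres = pd.DataFrame({"a": rng.normal(1.0, 1.0, 50), "b": rng.normal(size=50)})
        best, table = select_rm(pres, bg, [0.5, 1.0, 2.0])
        for _, r in table.iterrows():
            assert r["AICc"] == pytest.approx(
                aicc_score(r["lnL"], int(r["k"]), 50), rel=1e-12
            )
        finite = table[np.isfinite(table["AICc"])]
        assert best == finite.loc[finite["AICc"].idxmin(), "rm"]
        assert table["delta_AICc"].min() == 0.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            select_rm(pd.DataFrame({"a": [1.0]}), pd.DataFrame({"a": [0.0, 1.0]}), [])


class TestImportanceAndResponse:
    @pytest.fixture(scope="class")
    def driven_fit(self):
        """Presences driven entirely by variable a; b is noise."""
        rng = np.random.default_rng(29)
        bg = pd.DataFrame({"a": rng.normal(size=1500), "b": rng.normal(size=1500)})
        keep = rng.random(1500) < np.exp(2.0 * bg["a"]) / np.exp(2.0 * bg["a"]).max()
        pres = bg[keep].head(150).reset_index(drop=True)
        model = fit_maxent(pres, bg, rm=1.0)
        return model, pres, bg

    def test_contributions_sum_to_100(self, driven_fit):
        model, _, _ = driven_fit
        assert sum(model.contributions.values()) == pytest.approx(100.0, abs=1e-6)

    def test_single_variable_model_contributes_everything(self):
        rng = np.random.default_rng(31)
        bg = pd.DataFrame({"a": rng.normal(size=400)})
        pres = pd.DataFrame({"a": rng.normal(1.0, 1.0, 60)})
        model = fit_maxent(pres, bg, rm=1.0)
        assert model.contributions["a"] == pytest.approx(100.0)

    def test_truth_variable_ranks_first(self, driven_fit):
        model, pres, bg = driven_fit
        imp = variable_importance(model, pres, bg)
        top = imp.sort_values("percent_contribution", ascending=False).iloc[0]
        assert top["variable"] == "a"
        only = imp.set_index("variable")["gain_only"]
        assert only["a"] > only["b"]

    def test_flat_response_for_null_model(self):
        model = handmade_model(0.0)
        bg = pd.DataFrame({"x": np.linspace(0, 1, 50)})
        _, y = response_curve(model, "x", bg)
        assert np.ptp(y) == 0.0

    def test_monotone_response_for_positive_linear_term(self):
        model = handmade_model(2.0)
        bg = pd.DataFrame({"x": np.linspace(0, 1, 50)})
        _, y = response_curve(model, "x", bg)
        assert np.all(np.diff(y) >= 0) and y[-1] > y[0]

    def test_curve_endpoints_match_pointwise_prediction(self, driven_fit):
        model, _, bg = driven_fit
        xs, y = response_curve(model, "a", bg, n_points=7)
        df = pd.DataFrame({"a": xs, "b": np.full(7, bg["b"].mean())})
        np.testing.assert_allclose(y, model.cloglog(df), atol=1e-12)

    def test_unknown_variable_rejected(self, driven_fit):
        model, _, bg = driven_fit
        with pytest.raises(ValueError, match="unknown"):
            response_curve(model, "zz", bg)


class TestPredictMap:
    def test_null_model_gives_uniform_raw(self, gradient_stack):
        m = handmade_model(0.0)
        out = predict_map(m, gradient_stack, scale="raw")
        np.testing.assert_allclose(out.values[out.mask], 1.0 / gradient_stack.n_valid)

    def test_positive_coefficient_monotone_in_variable(self, gradient_stack):
        m = handmade_model(3.0, bounds=(0.0, 1.0))
        out = predict_map(m, gradient_stack, scale="raw")
        row = out.values[0, :]
        assert np.all(np.diff(row) > 0)  # suitability rises with x

    def test_raw_scale_sums_to_one(self, gradient_stack):
        m = handmade_model(1.3)
        out = predict_map(m, gradient_stack, scale="raw")
        assert np.nansum(out.values) == pytest.approx(1.0, abs=1e-12)

    def test_cloglog_bounded(self, gradient_stack):
        m = handmade_model(2.0)
        out = predict_map(m, gradient_stack, scale="cloglog")
        vals = out.values[out.mask]
        assert vals.min() >= 0 and vals.max() <= 1

    def test_clamped_cells_beyond_training_max_saturate(self):
        grid = RasterGrid(1, 4, 1.0, x_min=0.0, y_max=1.0)
        stack = RasterStack(grid, {"x": np.array([[0.0, 0.5, 1.0, 2.0]])})
        m = handmade_model(2.0, bounds=(0.0, 1.0))  # training max = 1
        out = predict_map(m, stack, clamp=True, scale="cloglog")
        assert out.values[0, 3] == out.values[0, 2]

    def test_missing_layer_error_names_it(self, gradient_stack):
        m = handmade_model(1.0)
        bad = RasterStack(gradient_stack.grid, {"y": gradient_stack["x"]})
        with pytest.raises(KeyError, match="x"):
            predict_map(m, bad)

    def test_ensemble_mean_of_identical_models_is_identity(self, gradient_stack):
        m = handmade_model(1.0)
        single = predict_map(m, gradient_stack, scale="raw")
        ens = predict_map_ensemble([m, m, m], gradient_stack, scale="raw")
        np.testing.assert_allclose(ens.values, single.values, atol=1e-15)


def test_model_json_roundtrip():
    rng = np.random.default_rng(37)
    bg = pd.DataFrame({"a": rng.normal(size=300), "b": rng.normal(size=300)})
    pres = pd.DataFrame({"a": rng.normal(1.0, 1.0, 40), "b": rng.normal(size=40)})
    model = fit_maxent(pres, bg, rm=1.0)
    back = MaxentModel.from_json(model.to_json())
    np.testing.assert_array_equal(back.lam, model.lam)
    assert back.ln_z == model.ln_z and back.entropy == model.entropy
    np.testing.assert_allclose(back.log_raw(bg), model.log_raw(bg), atol=1e-15)
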