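import numpy as np
import pandas as pd
import pytest

from nicheshift import maxent, synthetic
from nicheshift.geo_io import OccurrenceSet, RasterStack
from nicheshift.maxent import (
    FeatureSpec,
    MaxEntModel,
    apply_soil_mask,
    evaluate,
    fit_maxent,
    make_features,
    sample_background,
    select_variables,
    split_occurrences,
)


class TestSelectVariables:
    def test_identical_layers_one_dropped(self, geometry):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(geometry.n_rows, geometry.n_cols))
        stack = RasterStack(geometry, {"a": a, "b": a.copy(),
                                       "c": rng.normal(size=a.shape)})
        sel = select_variables(stack, n_occurrences=100)
        assert len(sel.kept) == 2
        assert "c" in sel.kept
        victim, partner, r = sel.dropped[0]
        assert {victim, partner} == {"a", "b"}
        assert r == pytest.approx(1.0)

    def test_weakly_correlated_seven_all_kept_with_guard(self, small_stack):
        sel = select_variables(small_stack, n_occurrences=70)
        assert sel.kept == list(small_stack.layer_names)
        assert sel.guard_ok
        assert not select_variables(small_stack, n_occurrences=69).guard_ok

    def test_kept_set_verified_by_brute_force(self, geometry):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(geometry.n_rows, geometry.n_cols))
        layers = {
            "a": base,
            "b": base + 0.01 * rng.normal(size=base.shape),  # ~r > 0.95 with a
            "c": rng.normal(size=base.shape),
            "d": base * 0.5 + rng.normal(size=base.shape),
        }
        stack = RasterStack(geometry, layers)
        sel = select_variables(stack)
        data = {n: stack.layers[n].ravel() for n in sel.kept}
        for i, x in enumerate(sel.kept):
            for y in sel.kept[i + 1:]:
                r = np.corrcoef(data[x], data[y])[0, 1]
                assert abs(r) < 0.95

    def test_all_constant_layers_rejected(self, geometry):
        ones = np.ones((geometry.n_rows, geometry.n_cols))
        stack = RasterStack(geometry, {"a": ones, "b": 2 * ones})
        with pytest.raises(ValueError, match="constant"):
            select_variables(stack)


class TestMakeFeatures:
    def test_feature_count_for_seven_variables(self):
        cols = [f"v{i}" for i in range(7)]
        env = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 7)),
                           columns=cols)
        spec = FeatureSpec.from_data(env)
        f = make_features(env, spec)
        assert f.shape[1] == 7 + 7 + 21
        assert len(spec.feature_names()) == 35

    def test_scaling_endpoints_and_clamping(self):
        env = pd.DataFrame({"x": [0.0, 5.0, 10.0]})
        spec = FeatureSpec.from_data(env)
        f = make_features(env, spec)
        np.testing.assert_allclose(f[:, 0], [0.0, 0.5, 1.0])
        above = make_features(pd.DataFrame({"x": [42.0]}), spec, clamp=True)
        assert above[0, 0] == 1.0  # value above training max pinned to max
        assert (f >= 0).all() and (f <= 1).all()

    def test_hinge_and_threshold_not_representable(self):
        with pytest.raises(ValueError, match="unsupported"):
            FeatureSpec(variables=["x"], classes=("linear", "hinge"))

    def test_unknown_variable_rejected(self):
        env = pd.DataFrame({"x": [0.0, 1.0]})
        spec = FeatureSpec.from_data(env)
        with pytest.raises(KeyError, match="missing"):
            make_features(pd.DataFrame({"y": [1.0]}), spec)


class TestSampleBackground:
    def test_saturation_returns_all_cells(self, small_stack):
        table = sample_background(small_stack, n=10**6, seed=0)
        assert len(table) == 60 * 60

    def test_mask_constrains_samples(self, small_stack):
        mask = np.zeros((60, 60), dtype=int)
        mask[:, 30:] = 1
        table = sample_background(small_stack, n=500, seed=1, mask=mask)
        assert (table["col"] >= 30).all()

    def test_seeded_and_distinct(self, small_stack):
        t1 = sample_background(small_stack, n=500, seed=2)
        t2 = sample_background(small_stack, n=500, seed=2)
        pd.testing.assert_frame_equal(t1, t2)
        assert not t1[["row", "col"]].duplicated().any()


class TestSplit:
    @pytest.mark.parametrize("n, expected_train", [(100, 70), (10, 7), (9, 6)])
    def test_seventy_thirty_sizes(self, n, expected_train):
        occ = OccurrenceSet("a", np.random.default_rng(0).uniform(size=(n, 2)))
        train, test = split_occurrences(occ, 0.7, seed=0)
        assert len(train) == expected_train
        assert len(test) == n - expected_train

    def test_partition_is_disjoint_and_complete(self):
        occ = OccurrenceSet("a", np.arange(40, dtype=float).reshape(20, 2))
        train, test = split_occurrences(occ, 0.7, seed=1)
        merged = np.vstack([train.points, test.points])
        assert {tuple(p) for p in merged} == {tuple(p) for p in occ.points}
        assert len(merged) == len(occ)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            split_occurrences(OccurrenceSet("a", np.array([[0.0, 0.0]])), 0.7, 0)


def _toy_fit(seed=0, n_pres=150, beta=2.0):
    """One-layer landscape where presences concentrate at high layer values."""
    rng = np.random.default_rng(seed)
    bg = pd.DataFrame({"x": rng.normal(size=1500)})
    w = np.exp(beta * bg["x"])
    pres = bg.iloc[rng.choice(len(bg), n_pres, p=w / w.sum(), replace=True)]
    return pres.reset_index(drop=True), bg


class TestFitMaxent:
    def test_raw_distribution_sums_to_one_over_background(self):
        pres, bg = _toy_fit()
        model = fit_maxent(pres, bg)
        raw = model.predict(bg, transform="raw")
        assert raw.sum() == pytest.approx(1.0, rel=1e-9)

    def test_sign_recovery_on_one_layer_toy(self):
        pres, bg = _toy_fit()
        model = fit_maxent(pres, bg)
        assert model.coefficients[model.feature_names.index("x")] > 0

    def test_null_presences_shrink_to_near_uniform(self, small_background):
        rng = np.random.default_rng(11)
        pres = small_background.iloc[
            rng.choice(len(small_background), 1000, replace=False)]
        model = fit_maxent(pres, small_background)
        raw = model.predict(small_background, transform="raw")
        assert raw.max() / raw.min() < 2.0

    def test_regularization_path_monotone_in_l1_norm(self):
        pres, bg = _toy_fit(seed=3)
        norms = [np.abs(fit_maxent(pres, bg, reg_multiplier=r).coefficients).sum()
                 for r in (0.5, 1.0, 2.0, 4.0)]
        assert all(a >= b - 1e-8 for a, b in zip(norms, norms[1:]))

    def test_objective_non_decreasing_every_iteration(self):
        pres, bg = _toy_fit(seed=4)
        model = fit_maxent(pres, bg)
        assert np.all(np.diff(model.objective_path) >= -1e-12)

    def test_constant_feature_coefficient_forced_to_zero(self):
        rng = np.random.default_rng(5)
        bg = pd.DataFrame({"x": rng.normal(size=500), "c": np.ones(500)})
        pres = bg.iloc[:50]
        model = fit_maxent(pres, bg)
        for j, name in enumerate(model.feature_names):
            if "c" in name:
                assert model.coefficients[j] == 0.0

    def test_non_convergence_carries_diagnostics(self):
        pres, bg = _toy_fit(seed=6)
        with pytest.raises(maxent.ConvergenceError) as err:
            fit_maxent(pres, bg, max_iter=3, tol=1e-15)
        assert err.value.objective_path.size >= 1


class TestPredict:
    def test_cloglog_is_monotone_in_raw(self):
        pres, bg = _toy_fit(seed=7)
        model = fit_maxent(pres, bg)
        raw = model.predict(bg, transform="raw")
        clog = model.predict(bg, transform="cloglog")
        order = np.argsort(raw)
        assert np.all(np.diff(clog[order]) >= 0)
        assert (clog >= 0).all() and (clog <= 1).all()

    def test_projection_onto_training_stack_is_idempotent(self, small_stack,
                                                          small_background):
        rng = np.random.default_rng(8)
        pres = small_background.iloc[rng.choice(len(small_background), 80)]
        model = fit_maxent(pres, small_background)
        map1 = model.predict_stack(small_stack)
        map2 = model.predict_stack(small_stack)
        np.testing.assert_array_equal(map1, map2)
        table_pred = model.predict(small_background)
        at_cells = map1[small_background["row"], small_background["col"]]
        np.testing.assert_allclose(at_cells, table_pred, rtol=1e-12)

    def test_zero_era_shift_projection_identical(self, small_stack, small_background):
        rng = np.random.default_rng(9)
        pres = small_background.iloc[rng.choice(len(small_background), 80)]
        model = fit_maxent(pres, small_background)
        shifted = synthetic.apply_era_shift(small_stack, np.zeros(7))
        np.testing.assert_array_equal(model.predict_stack(small_stack),
                                      model.predict_stack(shifted))

    def test_model_save_load_round_trip(self, tmp_path):
        pres, bg = _toy_fit(seed=10)
        model = fit_maxent(pres, bg)
        model.save(tmp_path / "m.txt")
        back = MaxEntModel.load(tmp_path / "m.txt")
        np.testing.assert_array_equal(back.coefficients, model.coefficients)
        np.testing.assert_allclose(back.predict(bg), model.predict(bg), rtol=0,
                                   atol=0)


class TestEvaluate:
    def test_perfect_separation_gives_auc_and_tss_one(self):
        report = evaluate(None, None, None,
                          presence_scores=np.full(20, 0.9),
                          background_scores=np.full(50, 0.1))
        assert report.auc == 1.0
        assert report.tss == 1.0
        assert report.sensitivity + report.specificity - 1 == pytest.approx(report.tss)

    def test_exchangeable_scores_near_half_auc(self):
        rng = np.random.default_rng(12)
        scores = rng.uniform(size=2000)
        report = evaluate(None, None, None,
                          presence_scores=scores[:1000],
                          background_scores=scores[1000:])
        assert abs(report.auc - 0.5) < 0.04
        assert abs(report.tss) < 0.08

    def test_auc_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(13)
        pres = rng.uniform(size=20)
        bg = rng.uniform(size=50)
        report = evaluate(None, None, None, presence_scores=pres,
                          background_scores=bg)
        wins = sum((p > b) + 0.5 * (p == b) for p in pres for b in bg)
        assert report.auc == pytest.approx(wins / (20 * 50), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(14)
        pres, bg = rng.normal(1, 1, 30), rng.normal(0, 1, 60)
        a1 = evaluate(None, None, None, presence_scores=pres,
                      background_scores=bg).auc
        a2 = evaluate(None, None, None, presence_scores=np.tanh(pres),
                      background_scores=np.tanh(bg)).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_constant_scores_flagged_as_degenerate(self):
        report = evaluate(None, None, None,
                          presence_scores=np.full(5, 0.3),
                          background_scores=np.full(9, 0.3))
        assert report.auc == 0.5 and report.tss == 0.0 and report.degenerate

    def test_tss_invariant_holds_on_fitted_model(self, small_background):
        rng = np.random.default_rng(15)
        pres = small_background.iloc[rng.choice(len(small_background), 60)]
        model = fit_maxent(pres, small_background)
        report = evaluate(model, pres, small_background, n_train=60)
        assert report.tss == pytest.approx(
            report.sensitivity + report.specificity - 1, abs=1e-12)


class TestSoilMask:
    def test_identity_zero_and_monotone(self):
        rng = np.random.default_rng(16)
        suit = rng.uniform(size=(10, 10))
        np.testing.assert_array_equal(apply_soil_mask(suit, np.ones((10, 10))), suit)
        assert (apply_soil_mask(suit, np.zeros((10, 10))) == 0).all()
        mask = rng.integers(0, 2, size=(10, 10))
        masked = apply_soil_mask(suit, mask)
        assert (masked <= suit).all()

    def test_nan_cells_stay_nan_and_mismatch_rejected(self):
        suit = np.array([[np.nan, 0.5]])
        out = apply_soil_mask(suit, np.array([[0, 0]]))
        assert np.isnan(out[0, 0]) and out[0, 1] == 0.0
        with pytest.raises(ValueError, match="shape"):
            apply_soil_mask(suit, np.ones((2, 2)))
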