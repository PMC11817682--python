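import numpy as np
import pandas as pd
import pytest

from pocketsig.distance import DistanceWeights
from pocketsig.efficacy import (
    EfficacyRecord,
    EfficacyRegressor,
    EfficacyTable,
    GridSpec,
    Hyperparameters,
    evaluate,
    fit_slopes,
    grid_search,
    inner_loo_loss,
    median_efficacy,
    outer_loo_cross_validation,
    predict_efficacy,
)
from pocketsig.featurize import FeatureTable

from conftest import REFERENCE_W

HP_TRUE = Hyperparameters(weights=REFERENCE_W, h=12, delta=2.0, c=3)


def table_from(records):
    return EfficacyTable([EfficacyRecord(*r) for r in records])


class TestMedianEfficacy:
    def test_odd_count(self):
        t = table_from([("A", "Gprotein", v) for v in (90, 100, 110)]
                       + [("A", "barr2", 50)])
        assert median_efficacy(t).loc["A", "Gprotein"] == 100

    def test_even_count_averages_central_pair(self):
        t = table_from([("A", "Gprotein", 80), ("A", "Gprotein", 100), ("A", "barr2", 10)])
        assert median_efficacy(t).loc["A", "Gprotein"] == 90

    def test_reference_agonist_scale(self):
        # the reference agonist defines 100% on the relative-efficacy scale
        t = table_from([("DAMGO", "Gprotein", 100.0), ("DAMGO", "barr2", 100.0)])
        assert (median_efficacy(t).loc["DAMGO"] == 100.0).all()

    def test_missing_key_is_named(self):
        t = table_from([("A", "Gprotein", 90), ("A", "barr2", 10), ("B", "Gprotein", 50)])
        with pytest.raises(KeyError, match="B"):
            median_efficacy(t)

    def test_invalid_pathway_rejected(self):
        with pytest.raises(ValueError, match="pathway"):
            EfficacyRecord("A", "Gq", 50.0)


class TestSlopes:
    def test_identity_design(self):
        F = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["A", "B"], columns=[1, 2])
        E = pd.DataFrame({"Gprotein": [100.0, 20.0]}, index=["A", "B"])
        slopes = fit_slopes(F, E)
        assert list(slopes.loc["Gprotein"]) == pytest.approx([100.0, 20.0], abs=1e-12)

    def test_recovers_planted_slopes_exactly(self):
        rng = np.random.default_rng(0)
        F = rng.dirichlet(np.ones(3), size=6)
        beta = np.array([[100.0, 50.0, 0.0], [80.0, 10.0, 40.0]])
        E = pd.DataFrame(F @ beta.T, index=list("ABCDEF"), columns=["Gprotein", "barr2"])
        slopes = fit_slopes(pd.DataFrame(F, index=list("ABCDEF"), columns=[1, 2, 3]), E)
        assert np.abs(slopes.to_numpy() - beta).max() < 1e-8

    def test_unvisited_conformation_gets_zero_slope(self, caplog):
        # min-norm convention under rank deficiency, with a logged warning
        import logging

        F = pd.DataFrame(
            [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]], index=["A", "B"], columns=[1, 2, 3]
        )
        E = pd.DataFrame({"Gprotein": [100.0, 20.0]}, index=["A", "B"])
        with caplog.at_level(logging.WARNING, logger="pocketsig.efficacy"):
            slopes = fit_slopes(F, E)
        assert slopes.loc["Gprotein", 3] == pytest.approx(0.0, abs=1e-12)
        assert any("rank" in r.message for r in caplog.records)

    def test_too_few_ligands_rejected(self):
        with pytest.raises(ValueError, match="2"):
            EfficacyRegressor().fit(np.array([[1.0, 0.0]]), np.array([1.0]))


class TestPredict:
    def test_dot_product(self):
        assert predict_efficacy([0.5, 0.5], [100.0, 20.0]) == pytest.approx(60.0)

    def test_unit_fraction_projects_slope(self):
        assert predict_efficacy([0.0, 1.0, 0.0], [7.0, 13.0, 2.0]) == pytest.approx(13.0)

    def test_joint_permutation_invariance(self):
        f = np.array([0.2, 0.3, 0.5])
        b = np.array([10.0, 50.0, 90.0])
        perm = np.array([2, 0, 1])
        assert predict_efficacy(f, b) == pytest.approx(predict_efficacy(f[perm], b[perm]))

    def test_doubling_slopes_doubles_prediction(self):
        f = np.array([0.25, 0.75])
        b = np.array([40.0, 80.0])
        assert predict_efficacy(f, 2 * b) == pytest.approx(2 * predict_efficacy(f, b))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            predict_efficacy([0.5, 0.5], [1.0, 2.0, 3.0])


class TestInnerLoo:
    def test_noise_free_planted_scenario_has_zero_loss(self, separable_data):
        targets = median_efficacy(separable_data["efficacies"])
        per_pathway, total = inner_loo_loss(separable_data["table"], targets, HP_TRUE)
        assert total < 1e-6

    def test_zero_slope_null_model_identity(self, separable_data):
        # replacing targets by 0 (the zero-slope prediction) makes the loss
        # equal the mean squared target, i.e. 0 here; shifted targets give
        # loss equal to mean squared residual of the shift
        targets = median_efficacy(separable_data["efficacies"]) * 0.0 + 50.0
        per_pathway, _ = inner_loo_loss(separable_data["table"], targets, HP_TRUE)
        # constant targets are fit exactly by slopes (50, 50, 50)
        assert all(v < 1e-6 for v in per_pathway.values())

    def test_ligand_order_invariance(self, separable_data):
        targets = median_efficacy(separable_data["efficacies"])
        _, t1 = inner_loo_loss(separable_data["table"], targets, HP_TRUE)
        _, t2 = inner_loo_loss(separable_data["table"], targets.iloc[::-1], HP_TRUE)
        assert t1 == pytest.approx(t2, rel=1e-9)


class TestGridSpec:
    def test_default_grid_mirrors_selected_search_space(self):
        g = GridSpec()
        assert g.w_values == (0.1, 0.2, 0.25, 0.33)
        assert g.h_values == tuple(range(2, 41))
        assert g.delta_values == (1.0, 2.0, 3.0)
        triples = g.weight_triples()
        # every surviving triple is a valid convex combination
        for t in triples:
            assert min(t.as_array()) >= 0
            assert t.as_array().sum() == pytest.approx(1.0, abs=1e-12)

    def test_negative_weight_patterns_are_skipped(self):
        # w = 1 gives (1, 1, -1)-type triples, all invalid
        assert GridSpec(w_values=(1.0,), h_values=(5,)).weight_triples() == []
        with pytest.raises(ValueError, match="empty"):
            GridSpec(w_values=(1.0,), h_values=(5,)).points()

    def test_single_point_grid_returned_without_search(self, separable_data):
        targets = median_efficacy(separable_data["efficacies"])
        got = grid_search(separable_data["table"], targets, GridSpec.single(HP_TRUE))
        assert got == HP_TRUE

    def test_deterministic_point_order(self):
        g = GridSpec(w_values=(0.25,), h_values=(4, 3), delta_values=(2.0, 1.0), c_values=(2, 3))
        pts = g.points()
        assert [(p.h, p.delta, p.c) for p in pts[:5]] == [
            (3, 1.0, 2), (3, 2.0, 2), (4, 1.0, 2), (4, 1.0, 3), (4, 2.0, 2),
        ]


class TestOuterLoo:
    def test_noise_free_predictions_match_truth(self, separable_data):
        scen = separable_data["scenario"]
        res = outer_loo_cross_validation(
            separable_data["table"], separable_data["efficacies"], GridSpec.single(HP_TRUE)
        )
        truth = separable_data["fractions"].to_numpy() @ scen.true_slopes.to_numpy().T
        assert np.abs(res.predictions.to_numpy() - truth).max() < 1e-3

    def test_slope_stability_across_models(self, separable_data):
        res = outer_loo_cross_validation(
            separable_data["table"], separable_data["efficacies"], GridSpec.single(HP_TRUE)
        )
        scale = np.abs(res.slope_mean.to_numpy()).max()
        assert res.slope_sd.to_numpy().max() <= 0.05 * scale

    def test_duplicated_ligand_exchangeability(self, separable_data):
        # a ligand identical in frames and targets to another predicts identically
        table = separable_data["table"].for_ligands(["L1", "L2", "L3", "L4"])
        dup = separable_data["table"].for_ligands(["L4"])
        dup = FeatureTable(dup.values, dup.layout, ["L4copy"] * dup.n_frames)
        combined = FeatureTable.concat([table, dup])
        targets = median_efficacy(separable_data["efficacies"]).loc[["L1", "L2", "L3", "L4"]]
        targets.loc["L4copy"] = targets.loc["L4"]
        res = outer_loo_cross_validation(combined, targets, GridSpec.single(HP_TRUE))
        assert np.allclose(
            res.predictions.loc["L4"], res.predictions.loc["L4copy"], atol=1e-9
        )

    def test_too_few_ligands_rejected(self, separable_data):
        table = separable_data["table"].for_ligands(["L1", "L2", "L3"])
        targets = median_efficacy(separable_data["efficacies"]).loc[["L1", "L2", "L3"]]
        with pytest.raises(ValueError, match="at least 4"):
            outer_loo_cross_validation(table, targets, GridSpec.single(HP_TRUE))


class TestEvaluate:
    def test_perfect_predictions(self):
        obs = pd.DataFrame({"Gprotein": [10.0, 20.0, 30.0]}, index=list("ABC"))
        m = evaluate(obs.copy(), obs)
        assert m.loc["Gprotein", "MAE"] == 0
        assert m.loc["Gprotein", "RMSE"] == 0
        assert m.loc["Gprotein", "R2"] == 1

    def test_constant_prediction_at_mean_has_zero_r2(self):
        obs = pd.DataFrame({"Gprotein": [10.0, 20.0, 30.0]}, index=list("ABC"))
        pred = obs * 0 + 20.0
        assert evaluate(pred, obs).loc["Gprotein", "R2"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_errors(self):
        obs = pd.DataFrame({"Gprotein": [10.0, 20.0]}, index=list("AB"))
        pred = pd.DataFrame({"Gprotein": [13.0, 16.0]}, index=list("AB"))
        m = evaluate(pred, obs)
        assert m.loc["Gprotein", "MAE"] == pytest.approx(3.5)
        assert m.loc["Gprotein", "RMSE"] == pytest.approx(np.sqrt(12.5))

    def test_zero_variance_observed_warns_nan_r2(self):
        obs = pd.DataFrame({"Gprotein": [10.0, 10.0]}, index=list("AB"))
        pred = pd.DataFrame({"Gprotein": [9.0, 11.0]}, index=list("AB"))
        with pytest.warns(UserWarning, match="zero variance"):
            m = evaluate(pred, obs)
        assert np.isnan(m.loc["Gprotein", "R2"])


def test_grid_search_recovers_constructed_optimum():
    from pocketsig.synthetic import grid_identifiability_dataset

    features, targets, _, planted, _ = grid_identifiability_dataset(seed=11)
    # small grid around the planted point: wrong weight patterns and wrong c
    grid = GridSpec(w_values=(0.25,), h_values=(5,), delta_values=(1.0,), c_values=(2, 3, 4))
    best = grid_search(features, targets, grid)
    assert best == planted
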