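"""Balanced forest training, standardized-effort maps, importance, PD."""

import numpy as np
import numpy.testing as npt
import pandas as pd
import pytest

from nicheshift import (
    BalancedRandomForest,
    EffortStandard,
    gini_importance,
    partial_dependence,
    predict_map,
    train_ensemble,
)


@pytest.fixture(scope="module")
def imbalanced_table():
    """50 presences, 2000 absences, one informative predictor."""
    rng = np.random.default_rng(0)
    n_pres, n_abs = 50, 2000
    x_informative = np.concatenate([rng.normal(2, 1, n_pres), rng.normal(-2, 1, n_abs)])
    return pd.DataFrame(
        {
            "signal": x_informative,
            "noise": rng.normal(size=n_pres + n_abs),
            "species_detected": [1] * n_pres + [0] * n_abs,
        }
    )


class TestBalancedForest:
    def test_every_bootstrap_balanced(self, imbalanced_table):
        X = imbalanced_table[["signal", "noise"]].to_numpy()
        y = imbalanced_table["species_detected"].to_numpy()
        model = BalancedRandomForest(n_trees=25, random_state=1).fit(X, y)
        for n_pres, n_abs in model.bootstrap_class_counts():
            assert n_pres == n_abs == 50

    def test_separable_data_perfect_training_accuracy(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = BalancedRandomForest(n_trees=30, random_state=0).fit(X, y)
        score = model.predict_score(X)
        assert ((score >= 0.5).astype(int) == y).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            BalancedRandomForest(n_trees=5).fit(np.zeros((10, 2)), np.zeros(10))

    def test_scores_in_unit_interval(self, imbalanced_table):
        X = imbalanced_table[["signal", "noise"]].to_numpy()
        y = imbalanced_table["species_detected"].to_numpy()
        s = BalancedRandomForest(n_trees=15, random_state=2).fit(X, y).predict_score(X)
        assert ((s >= 0) & (s <= 1)).all()


class TestTrainEnsemble:
    def test_deterministic_given_master_seed(self, imbalanced_table):
        a = train_ensemble(imbalanced_table, n_replicates=2, trees_per_replicate=20, seed=5)
        b = train_ensemble(imbalanced_table, n_replicates=2, trees_per_replicate=20, seed=5)
        X = imbalanced_table[a.predictor_names].to_numpy()
        npt.assert_array_equal(
            np.mean([m.predict_score(X) for m in a.replicates], axis=0),
            np.mean([m.predict_score(X) for m in b.replicates], axis=0),
        )

    def test_replicate_manifests_record_seeds(self, imbalanced_table):
        ens = train_ensemble(imbalanced_table, n_replicates=3, trees_per_replicate=5, seed=1)
        assert len(ens.manifests) == 3
        assert len({m["seed"] for m in ens.manifests}) == 3

    def test_one_table_per_replicate_supported(self, imbalanced_table):
        tables = [imbalanced_table.sample(500, random_state=i) for i in range(3)]
        ens = train_ensemble(tables, n_replicates=3, trees_per_replicate=5, seed=1)
        assert ens.n_replicates == 3
        with pytest.raises(ValueError, match="one model table per replicate"):
            train_ensemble(tables, n_replicates=4, trees_per_replicate=5, seed=1)


class TestPredictMap:
    def test_single_driver_map_tracks_driver(self, hist_env, linear_niche, checklists):
        from scipy.stats import spearmanr

        from nicheshift import extract_predictors, spatiotemporal_subsample

        sub = spatiotemporal_subsample(checklists, seed=1)
        tbl, _ = extract_predictors(sub, hist_env, ["bio05"])
        ens = train_ensemble(tbl, n_replicates=3, trees_per_replicate=100, seed=0,
                             period_label="historic")
        m = predict_map(ens, hist_env)
        rho = spearmanr(m.values.ravel(), hist_env["bio05"].ravel()).statistic
        assert rho > 0.95

    def test_identical_replicates_mean_equals_single(self, imbalanced_table, hist_env):
        tbl = imbalanced_table.rename(columns={"signal": "bio05", "noise": "elevation"})
        ens = train_ensemble(tbl, n_replicates=1, trees_per_replicate=20, seed=3,
                             period_label="historic")
        tripled = type(ens)(
            replicates=ens.replicates * 3,
            predictor_names=ens.predictor_names,
            period_label="historic",
        )
        npt.assert_array_equal(
            predict_map(ens, hist_env).values, predict_map(tripled, hist_env).values
        )

    def test_provenance_labels(self, small_landscape, imbalanced_table):
        from nicheshift import with_bioclim

        hist, curr = (with_bioclim(s) for s in small_landscape)
        tbl = imbalanced_table.rename(columns={"signal": "bio05", "noise": "elevation"})
        hist_model = train_ensemble(tbl, n_replicates=1, trees_per_replicate=5, seed=0,
                                    period_label="historic")
        assert predict_map(hist_model, hist).provenance == "contemporary"
        assert predict_map(hist_model, curr).provenance == "forecast"
        hist_model.period_label = "current"
        assert predict_map(hist_model, hist).provenance == "backcast"

    def test_missing_layer_named_in_error(self, hist_env, imbalanced_table):
        tbl = imbalanced_table.rename(columns={"signal": "bio05", "noise": "no_such"})
        ens = train_ensemble(tbl, n_replicates=1, trees_per_replicate=5, seed=0)
        with pytest.raises(KeyError, match="no_such"):
            predict_map(ens, hist_env)

    def test_effort_standard_defaults(self):
        std = EffortStandard()
        assert std.day_of_year == 91  # April 1
        assert std.duration_hours == 1.0
        assert std.distance_km == 1.0
        assert std.n_observers == 1


class TestGiniImportance:
    def test_shares_sum_to_100(self, imbalanced_table):
        ens = train_ensemble(imbalanced_table, n_replicates=2, trees_per_replicate=20, seed=1)
        imp = gini_importance(ens)
        npt.assert_allclose(imp["importance_pct"].sum(), 100.0, atol=1e-6)

    def test_informative_predictor_ranks_first(self, imbalanced_table):
        ens = train_ensemble(imbalanced_table, n_replicates=2, trees_per_replicate=30, seed=1)
        imp = gini_importance(ens)
        assert imp.iloc[0]["predictor"] == "signal"

    def test_unused_predictor_zero(self):
        # constant column can never be chosen for a split
        rng = np.random.default_rng(0)
        tbl = pd.DataFrame(
            {
                "useful": np.concatenate([rng.normal(3, 1, 100), rng.normal(-3, 1, 100)]),
                "constant": np.zeros(200),
                "species_detected": [1] * 100 + [0] * 100,
            }
        )
        ens = train_ensemble(tbl, n_replicates=1, trees_per_replicate=20, seed=0,
                             predictor_names=["useful", "constant"])
        imp = gini_importance(ens).set_index("predictor")
        assert imp.loc["constant", "importance_pct"] == 0.0


class TestPartialDependence:
    def test_grid_spans_observed_range(self, imbalanced_table):
        ens = train_ensemble(imbalanced_table, n_replicates=1, trees_per_replicate=10, seed=0)
        pdc = partial_dependence(ens, "signal", imbalanced_table, n_values=25, seed=1)
        assert len(pdc.values) == 25
        npt.assert_allclose(pdc.values[0], imbalanced_table["signal"].min())
        npt.assert_allclose(pdc.values[-1], imbalanced_table["signal"].max())
        npt.assert_allclose(np.diff(pdc.values), pdc.values[1] - pdc.values[0])

    def test_marginal_effect_nonnegative_min_zero(self, imbalanced_table):
        ens = train_ensemble(imbalanced_table, n_replicates=2, trees_per_replicate=10, seed=0)
        pdc = partial_dependence(ens, "noise", imbalanced_table, seed=2)
        assert (pdc.marginal_effect >= 0).all()
        assert pdc.marginal_effect.min() == 0.0

    def test_uninfluential_predictor_flat_curve(self):
        # a constant classifier cannot respond to any predictor
        from nicheshift.sdm_ensemble import SDMEnsemble

        class ConstantModel:
            def predict_score(self, X):
                return np.full(len(X), 0.42)

        rng = np.random.default_rng(1)
        tbl = pd.DataFrame(
            {"useful": rng.normal(size=200), "inert": rng.normal(size=200)}
        )
        ens = SDMEnsemble(replicates=[ConstantModel()], predictor_names=["useful", "inert"])
        pdc = partial_dependence(ens, "inert", tbl, seed=0)
        npt.assert_allclose(pdc.marginal_effect, 0.0, atol=1e-12)
        npt.assert_allclose(pdc.mean_suitability, 0.42)

    def test_constant_predictor_rejected(self, imbalanced_table):
        tbl = imbalanced_table.copy()
        tbl["flat"] = 1.0
        ens = train_ensemble(tbl, n_replicates=1, trees_per_replicate=5, seed=0)
        with pytest.raises(ValueError, match="constant"):
            partial_dependence(ens, "flat", tbl, seed=0)

    def test_shared_reference_draw_is_seeded(self, imbalanced_table):
        ens = train_ensemble(imbalanced_table, n_replicates=1, trees_per_replicate=10, seed=0)
        a = partial_dependence(ens, "signal", imbalanced_table, seed=7)
        b = partial_dependence(ens, "signal", imbalanced_table, seed=7)
        npt.assert_array_equal(a.mean_suitability, b.mean_suitability)
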