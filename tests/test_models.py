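"""Forest tuning, both model families, ensembling, and Shapley importances."""

import warnings

import numpy as np
import pandas as pd
import pytest

from densimap.models import (ModelSpec, ensemble_predict, fit_model,
                             shap_importance, six_model_specs, tune_forest)
from densimap.smooth import (PenalizedAdditiveModel, SmoothFitError,
                             SplineTerm, SurfaceTerm)
from densimap.validation import compute_metrics


def spatial_table(n, seed, noise=0.05):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"lon": rng.uniform(-75, -45, n),
                       "lat": rng.uniform(-20, 5, n)})
    df["wd3"] = 2.0 * df["lon"] / 30.0 + rng.normal(0, noise, n)
    return df


class TestSmoothModel:
    def test_recovers_sine_curve(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 2 * np.pi, 500)
        y = np.sin(x) + rng.normal(0, 0.2, 500)
        m = PenalizedAdditiveModel([SplineTerm("x", k=9)]).fit(
            pd.DataFrame({"x": x}), y)
        grid = pd.DataFrame({"x": np.linspace(0.2, 2 * np.pi - 0.2, 200)})
        rmse = np.sqrt(np.mean((m.predict(grid) - np.sin(grid["x"])) ** 2))
        assert rmse < 0.1

    def test_constant_response_predicted_everywhere(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"x": rng.uniform(0, 1, 80)})
        m = PenalizedAdditiveModel([SplineTerm("x", k=9)]).fit(X, np.full(80, 0.7))
        assert np.allclose(m.predict(X), 0.7, atol=1e-6)

    def test_prediction_continuous_in_covariates(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"x": rng.uniform(0, 1, 200),
                          "z": rng.uniform(0, 1, 200)})
        y = np.sin(3 * X["x"]) + X["z"] + rng.normal(0, 0.1, 200)
        m = PenalizedAdditiveModel([SplineTerm("x"), SplineTerm("z")]).fit(X, y)
        probe = X.iloc[:20].copy()
        base = m.predict(probe)
        probe["x"] = probe["x"] + 1e-6
        assert np.abs(m.predict(probe) - base).max() < 1e-3

    def test_too_few_unique_values_signalled(self):
        X = pd.DataFrame({"x": np.repeat([1.0, 2.0, 3.0], 20)})
        with pytest.raises(SmoothFitError, match="x"):
            PenalizedAdditiveModel([SplineTerm("x")]).fit(X, np.ones(60))

    def test_surface_term_fits_radial_signal(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"u": rng.uniform(-1, 1, 400),
                          "v": rng.uniform(-1, 1, 400)})
        y = np.exp(-(X["u"] ** 2 + X["v"] ** 2)) + rng.normal(0, 0.05, 400)
        m = PenalizedAdditiveModel([SurfaceTerm(("u", "v"), k=30)]).fit(X, y)
        assert compute_metrics(y, m.predict(X)).r2 > 0.8


class TestForestTuning:
    def test_grid_size_and_signal_selection(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(60, 8)),
                         columns=[f"f{i}" for i in range(8)])
        y = X["f0"] + rng.normal(0, 0.1, 60)
        n_trees, m_try, grid = tune_forest(X, y, seed=0)
        assert len(grid) == 70  # 7 m_try values x 10 tree counts
        assert m_try >= 2
        assert grid.oob_mse.min() < y.var()

    def test_oversized_mtry_skipped_with_warning(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        y = X["a"] + rng.normal(0, 0.1, 60)
        with pytest.warns(UserWarning, match="skipping"):
            _, m_try, grid = tune_forest(X, y, m_try_values=[2, 3, 9],
                                         n_trees_values=[100, 200], seed=0)
        assert m_try <= 3
        assert set(grid.m_try) == {2, 3}

    def test_tiny_training_set_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 3)))
        with pytest.raises(ValueError):
            tune_forest(X, np.zeros(20))


class TestFitModel:
    def test_constant_response_both_methods(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"lon": rng.uniform(-70, -50, 100),
                           "lat": rng.uniform(-10, 5, 100)})
        df["wd3"] = 0.6
        rf = fit_model(ModelSpec("forest", "spatial",
                                 (("n_trees", 50), ("m_try", 2))), df)
        assert np.allclose(rf.predict(df), 0.6)
        gam = fit_model(ModelSpec("smooth_additive", "spatial"), df)
        assert np.allclose(gam.predict(df), 0.6, atol=1e-6)

    def test_linear_longitude_signal_recovered_out_of_sample(self, plot_table):
        rng = np.random.default_rng(5)
        df = plot_table.copy()
        df["wd3"] = 2.0 * df["lon"] + rng.normal(0, 0.1, len(df))
        train, test = df.iloc[:300], df.iloc[300:]
        for method in ("forest", "smooth_additive"):
            hp = (("n_trees", 300), ("m_try", 3)) if method == "forest" else ()
            m = fit_model(ModelSpec(method, "both", hp, seed=0), train)
            r2 = compute_metrics(test["wd3"], m.predict(test)).r2
            assert r2 > 0.8, method

    def test_training_feature_ranges_recorded(self, plot_table):
        m = fit_model(ModelSpec("forest", "spatial",
                                (("n_trees", 30), ("m_try", 2))), plot_table)
        lo, hi = m.training_feature_ranges["lon"]
        assert lo == plot_table["lon"].min() and hi == plot_table["lon"].max()

    def test_forest_beats_training_mean(self, plot_table):
        m = fit_model(ModelSpec("forest", "both",
                                (("n_trees", 200), ("m_try", 3))), plot_table)
        rmse = compute_metrics(plot_table["wd3"], m.predict(plot_table)).rmse
        assert rmse < plot_table["wd3"].std()

    def test_missing_feature_rejected(self):
        with pytest.raises(ValueError, match="lacks"):
            fit_model(ModelSpec("forest", "spatial"),
                      pd.DataFrame({"wd3": [0.5, 0.6]}))


class TestEnsemble:
    def test_hand_mean_and_sd(self):
        class Stub:
            def __init__(self, v):
                self.v = v
                self.spec = ModelSpec("forest", "spatial")

            def predict(self, X):
                return np.full(len(X), self.v)

        X = pd.DataFrame({"lon": [0.0, 1.0], "lat": [0.0, 1.0]})
        mean, sd = ensemble_predict([Stub(0.6), Stub(0.7)], X)
        assert np.allclose(mean, 0.65)
        assert np.allclose(sd, 0.1 / np.sqrt(2))

    def test_mean_bounded_by_members(self, plot_table):
        specs = six_model_specs(n_trees=50, m_try=3, seed=0)
        models = [fit_model(s, plot_table) for s in specs]
        preds = np.column_stack([m.predict(plot_table) for m in models])
        mean, _ = ensemble_predict(models, plot_table)
        assert (mean >= preds.min(axis=1) - 1e-12).all()
        assert (mean <= preds.max(axis=1) + 1e-12).all()

    def test_single_model_rejected(self, plot_table):
        m = fit_model(ModelSpec("forest", "spatial",
                                (("n_trees", 20), ("m_try", 2))), plot_table)
        with pytest.raises(ValueError):
            ensemble_predict([m], plot_table)


class TestShapImportance:
    def test_unused_feature_has_null_importance(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"lon": rng.uniform(-70, -50, 200),
                           "lat": rng.uniform(-10, 5, 200)})
        df["wd3"] = 0.5 + 0.3 * (df["lon"] > -60)  # latitude never used
        m = fit_model(ModelSpec("forest", "spatial",
                                (("n_trees", 100), ("m_try", 1)), seed=0), df)
        rep = shap_importance(m, df, n_permutations=50, seed=0)
        assert rep.per_feature_global["lat"] < 0.005

    def test_additive_model_matches_closed_form_contributions(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame({"x": rng.uniform(0, 1, 150),
                          "z": rng.uniform(0, 1, 150)})
        y = np.sin(4 * X["x"]) + 0.5 * X["z"] + rng.normal(0, 0.05, 150)
        gam = PenalizedAdditiveModel([SplineTerm("x"), SplineTerm("z")]).fit(X, y)

        # duck-typed model: an exactly additive predictor, for which the
        # Shapley contribution of feature j is f_j(x_j) - E[f_j] in closed form
        class AdditiveStub:
            class spec:
                features = ["x", "z"]

            @staticmethod
            def predict(df_):
                return gam.predict(df_)

        fm = AdditiveStub()
        terms = gam.term_contributions(X)
        rep = shap_importance(fm, X, n_permutations=600, seed=0,
                              background_size=150)
        rels = []
        for f in ("x", "z"):
            true = terms[f] - terms[f].mean()
            err = np.sqrt(np.mean((rep.per_observation[f] - true) ** 2))
            rels.append(err / np.sqrt(np.mean(true ** 2)))
        assert np.median(rels) < 0.05

    def test_contributions_reconstruct_predictions(self, plot_table):
        m = fit_model(ModelSpec("forest", "both",
                                (("n_trees", 100), ("m_try", 3)), seed=0),
                      plot_table)
        sub = plot_table.iloc[:100]
        rep = shap_importance(m, sub, n_permutations=20, seed=0)
        recon = rep.per_observation.sum(axis=1).to_numpy() + rep.per_observation_base
        pred = m.predict(sub)
        assert np.abs(recon - pred).max() < 0.05 * pred.std() + 1e-9

    def test_missing_feature_rejected(self, plot_table):
        m = fit_model(ModelSpec("forest", "spatial",
                                (("n_trees", 20), ("m_try", 2))), plot_table)
        with pytest.raises(ValueError):
            shap_importance(m, plot_table.drop(columns=["lat"]))
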