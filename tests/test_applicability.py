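"""Dissimilarity index, AOA threshold, extrapolation flags and subsample
sensitivity, against hand and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from densimap.applicability import (aoa_threshold, dissimilarity_index, loess,
                                    range_extrapolation, subsample_sensitivity)
from densimap.models import ModelSpec


class TestDissimilarityIndex:
    def test_zero_at_training_points(self):
        rng = np.random.default_rng(0)
        train = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        di = dissimilarity_index(train, train.iloc[:5])
        assert np.allclose(di, 0.0)

    def test_one_dimensional_hand_example(self):
        train = pd.DataFrame({"x": [0.0, 2.0]})
        query = pd.DataFrame({"x": [3.0]})
        # scaled train = {-1, 1}: mean pairwise distance 2; query scales to 2,
        # min distance 1 -> DI = 0.5
        di = dissimilarity_index(train, query)
        assert di[0] == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        train = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        query = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        di = dissimilarity_index(train, query)
        mu, sd = train.mean().to_numpy(), train.std(ddof=0).to_numpy()
        Ts = (train.to_numpy() - mu) / sd
        Qs = (query.to_numpy() - mu) / sd
        denom = pdist(Ts).mean()
        for i in range(len(query)):
            dmin = min(np.sqrt(((Qs[i] - t) ** 2).sum()) for t in Ts)
            assert di[i] == pytest.approx(dmin / denom, abs=1e-10)

    def test_fold_aware_uses_nearest_other_fold(self):
        train = pd.DataFrame({"x": [0.0, 0.1, 5.0, 5.1]})
        folds = np.array([0, 0, 1, 1])
        di = dissimilarity_index(train, fold_ids=folds)
        # point 0's nearest other-fold neighbour is x=5.0, not x=0.1
        mu, sd = train["x"].mean(), train["x"].std(ddof=0)
        scaled = (train["x"] - mu) / sd
        denom = pdist(scaled.to_numpy()[:, None]).mean()
        assert di[0] == pytest.approx(abs(scaled[0] - scaled[2]) / denom)

    def test_invariant_to_affine_feature_rescaling(self):
        rng = np.random.default_rng(2)
        train = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        query = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        base = dissimilarity_index(train, query)
        train2, query2 = train.copy(), query.copy()
        train2["b"] = train2["b"] * 37.0 + 5.0
        query2["b"] = query2["b"] * 37.0 + 5.0
        np.testing.assert_allclose(dissimilarity_index(train2, query2), base,
                                   atol=1e-10)

    def test_single_training_point_rejected(self):
        with pytest.raises(ValueError):
            dissimilarity_index(pd.DataFrame({"x": [1.0]}),
                                pd.DataFrame({"x": [2.0]}))


class TestAoaThreshold:
    def test_hand_quartile_example(self):
        assert aoa_threshold([0.2, 0.4, 0.6, 0.8]) == pytest.approx(1.1)

    def test_literal_reading_mode(self):
        assert aoa_threshold([0.2, 0.4, 0.6, 0.8],
                             rule="1.5iqr") == pytest.approx(0.45)

    def test_degenerate_equal_values(self):
        assert aoa_threshold([0.3] * 10) == pytest.approx(0.3)

    def test_monotone_in_the_maximum_and_scale_equivariant(self):
        # raising the largest DI leaves Q1 fixed and can only raise Q3, so the
        # whisker threshold never decreases; scaling all DI scales it linearly
        rng = np.random.default_rng(3)
        for _ in range(50):
            di = rng.uniform(0, 1, 20)
            base = aoa_threshold(di)
            bumped = di.copy()
            bumped[np.argmax(bumped)] += rng.uniform(0, 0.5)
            assert aoa_threshold(bumped) >= base - 1e-12
            assert aoa_threshold(di * 3.0) == pytest.approx(3.0 * base)

    def test_few_values_rejected(self):
        with pytest.raises(ValueError):
            aoa_threshold([0.1] * 3)

    def test_whisker_rule_bounds_outlier_mass(self, plot_table):
        feats = ["lon", "lat", "cec", "ph", "mat"]
        rng = np.random.default_rng(0)
        folds = rng.integers(0, 10, len(plot_table))
        di = dissimilarity_index(plot_table[feats], fold_ids=folds)
        thr = aoa_threshold(di)
        assert (di > thr).mean() <= 0.25


class TestRangeExtrapolation:
    def test_interior_queries_unflagged(self):
        train = pd.DataFrame({"cec": [5.0, 40.0], "ph": [4.0, 6.0]})
        q = pd.DataFrame({"cec": [20.0], "ph": [5.0]})
        assert not range_extrapolation(train, q).to_numpy().any()

    def test_exceeding_feature_flagged(self):
        train = pd.DataFrame({"cec": [5.0, 40.0], "ph": [4.0, 6.0]})
        q = pd.DataFrame({"cec": [50.0], "ph": [5.0]})
        flags = range_extrapolation(train, q)
        assert flags["cec"].iloc[0] and not flags["ph"].iloc[0]

    def test_matches_per_feature_brute_force(self):
        rng = np.random.default_rng(4)
        train = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        query = pd.DataFrame(rng.normal(scale=2.0, size=(100, 3)),
                             columns=list("abc"))
        flags = range_extrapolation(train, query)
        for c in "abc":
            lo, hi = train[c].min(), train[c].max()
            expect = (query[c] < lo) | (query[c] > hi)
            assert (flags[c] == expect).all()

    def test_missing_feature_rejected(self):
        with pytest.raises(ValueError):
            range_extrapolation(pd.DataFrame({"a": [1.0]}),
                                pd.DataFrame({"b": [1.0]}))


class TestSubsampleSensitivity:
    def test_mean_like_predictor_matches_resampling_oracle(self):
        # constant features force each tree to predict its bootstrap mean, so
        # the refitted forest reproduces the subsample mean almost exactly
        rng = np.random.default_rng(5)
        n = 200
        df = pd.DataFrame({"lon": np.zeros(n), "lat": np.zeros(n),
                           "wd3": rng.normal(0.6, 0.1, n)})
        spec = ModelSpec("forest", "spatial", (("n_trees", 100), ("m_try", 1)),
                         seed=0)
        res = subsample_sensitivity(df, spec, n=500, fraction=0.5, seed=0)
        means = [df["wd3"].sample(n // 2, random_state=s).mean()
                 for s in range(500)]
        oracle = np.std(means, ddof=1)
        assert np.allclose(res.per_plot_sd, res.per_plot_sd[0])
        assert res.per_plot_sd.mean() == pytest.approx(oracle, rel=0.10)

    def test_constant_response_yields_zero_sd_and_no_flags(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"lon": rng.uniform(-70, -50, 80),
                           "lat": rng.uniform(-10, 5, 80), "wd3": 0.6})
        spec = ModelSpec("forest", "spatial", (("n_trees", 20), ("m_try", 2)),
                         seed=0)
        res = subsample_sensitivity(df, spec, n=20, seed=0)
        assert np.allclose(res.per_plot_sd, 0.0)
        assert all(not v for v in res.flagged_feature_ranges.values())

    def test_noise_concentrated_at_high_longitude_is_flagged(self):
        hits = 0
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            n = 150
            df = pd.DataFrame({"lon": rng.uniform(-70, -50, n),
                               "lat": rng.uniform(-10, 5, n)})
            noisy = df["lon"] > -56
            y = 0.6 + 0.1 * np.sin(df["lon"] / 4)
            y = y + np.where(noisy, rng.normal(0, 0.2, n), rng.normal(0, 0.01, n))
            df["wd3"] = y
            spec = ModelSpec("forest", "spatial",
                             (("n_trees", 50), ("m_try", 2)), seed=seed)
            res = subsample_sensitivity(df, spec, n=200, seed=seed)
            flagged = res.flagged_feature_ranges["lon"]
            if any(hi > -56 for _, hi in flagged):
                hits += 1
        assert hits >= 2

    def test_too_few_subsamples_rejected(self, plot_table):
        spec = ModelSpec("forest", "spatial", (("n_trees", 10), ("m_try", 2)))
        with pytest.raises(ValueError):
            subsample_sensitivity(plot_table, spec, n=1)


class TestLoess:
    def test_recovers_smooth_trend(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 10, 300)
        y = np.sin(x) + rng.normal(0, 0.1, 300)
        grid = np.linspace(1, 9, 50)
        fit = loess(x, y, grid, span=0.3, degree=2)
        assert np.sqrt(np.mean((fit - np.sin(grid)) ** 2)) < 0.1
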