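"""The six-member model ensemble: 2 methods x 3 explanatory-variable sets.

Methods are a random forest (bagged regression trees, hyperparameters tuned
by out-of-bag mean square error over a 7 x 10 grid) and a penalized additive
model (univariate smooths of basis dimension 9 per environmental variable, a
single interacting isotropic surface of longitude and latitude with basis
dimension 50, and a CEC x pH interaction surface).  Feature sets are
``spatial`` (lon/lat only), ``environment`` (the screened covariates) and
``both`` (their union).  Global variable importance uses sampling-based
Shapley additive explanations: per-observation contributions estimated by
walking random feature permutations against background draws, summarised as
the mean absolute contribution per feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .env import ENV_FEATURES
from .smooth import PenalizedAdditiveModel, SplineTerm, SurfaceTerm

SPATIAL_FEATURES = ["lon", "lat"]

FEATURE_SETS = {
    "spatial": SPATIAL_FEATURES,
    "environment": ENV_FEATURES,
    "both": ENV_FEATURES + SPATIAL_FEATURES,
}


@dataclass(frozen=True)
class ModelSpec:
    method: str                      # "forest" | "smooth_additive"
    feature_set: str                 # "spatial" | "environment" | "both"
    hyperparams: tuple = ()          # forest: (("n_trees", .), ("m_try", .))
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("forest", "smooth_additive"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {self.feature_set!r}")

    @property
    def features(self) -> list[str]:
        return list(FEATURE_SETS[self.feature_set])

    @property
    def label(self) -> str:
        tag = {"forest": "RF", "smooth_additive": "GAM"}[self.method]
        return f"{tag} - {self.feature_set}"

    def hyper(self) -> dict:
        return dict(self.hyperparams)


def six_model_specs(n_trees: int = 800, m_try: int = 3, seed: int = 0,
                    k_env: int = 9, k_spatial: int = 50) -> list[ModelSpec]:
    """The standard ensemble: RF and smooth-additive for each feature set."""
    specs = []
    for fs in ("spatial", "environment", "both"):
        mtry = min(m_try, len(FEATURE_SETS[fs]))
        specs.append(ModelSpec("forest", fs,
                               (("n_trees", n_trees), ("m_try", mtry)), seed))
        specs.append(ModelSpec("smooth_additive", fs,
                               (("k_env", k_env), ("k_spatial", k_spatial)), seed))
    return specs


@dataclass
class FittedModel:
    spec: ModelSpec
    predictor: object
    training_feature_ranges: dict[str, tuple[float, float]]
    fit_diagnostics: dict = field(default_factory=dict)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Xs = X[self.spec.features]
        if self.spec.method == "forest":
            return self.predictor.predict(Xs.to_numpy(dtype=float))
        return self.predictor.predict(Xs)


def tune_forest(X: pd.DataFrame, y, m_try_values=range(2, 9),
                n_trees_values=range(100, 1001, 100),
                seed: int = 0) -> tuple[int, int, pd.DataFrame]:
    """Grid-search forest hyperparameters by out-of-bag mean square error.

    Ties resolve toward fewer trees, then smaller m_try. Combinations where
    m_try exceeds the feature count are skipped with a warning.
    """
    if len(X) < 50:
        raise ValueError("need at least 50 training rows to tune")
    y = np.asarray(y, dtype=float)
    Xa = X.to_numpy(dtype=float)
    nfeat = Xa.shape[1]
    records = []
    best = (np.inf, None, None)
    for n_trees in sorted(n_trees_values):
        for m_try in sorted(m_try_values):
            if m_try > nfeat:
                warnings.warn(f"skipping m_try={m_try} > {nfeat} features")
                continue
            rf = RandomForestRegressor(n_estimators=n_trees, max_features=m_try,
                                       oob_score=True, random_state=seed,
                                       bootstrap=True)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # rare never-OOB samples
                rf.fit(Xa, y)
            oob = rf.oob_prediction_
            mask = np.isfinite(oob)
            mse = float(np.mean((oob[mask] - y[mask]) ** 2))
            records.append({"n_trees": n_trees, "m_try": m_try, "oob_mse": mse})
            if mse < best[0]:
                best = (mse, n_trees, m_try)
    grid = pd.DataFrame(records)
    if best[1] is None:
        raise ValueError("no valid hyperparameter combination")
    return best[1], best[2], grid


def fit_model(spec: ModelSpec, train: pd.DataFrame, response: str = "wd3",
              ) -> FittedModel:
    """Fit one ensemble member on a complete-case training table."""
    feats = spec.features
    missing = [f for f in feats if f not in train.columns]
    if missing:
        raise ValueError(f"training table lacks features: {missing}")
    X = train[feats]
    y = train[response].to_numpy(dtype=float)
    ranges = {f: (float(X[f].min()), float(X[f].max())) for f in feats}

    if spec.method == "forest":
        hp = spec.hyper()
        rf = RandomForestRegressor(
            n_estimators=int(hp.get("n_trees", 500)),
            max_features=min(int(hp.get("m_try", 3)), len(feats)),
            random_state=spec.seed, bootstrap=True)
        rf.fit(X.to_numpy(dtype=float), y)
        return FittedModel(spec, rf, ranges, {"oob": None})

    hp = spec.hyper()
    k_env = int(hp.get("k_env", 9))
    k_spatial = int(hp.get("k_spatial", 50))
    terms: list = []
    env_in_set = [f for f in feats if f in ENV_FEATURES]
    paired = {"cec", "ph"}
    for f in env_in_set:
        if f in paired:
            continue
        terms.append(SplineTerm(f, k=k_env))
    if paired <= set(env_in_set):
        terms.append(SurfaceTerm(("cec", "ph"), k=k_env))
    if set(SPATIAL_FEATURES) <= set(feats):
        terms.append(SurfaceTerm(("lon", "lat"), k=k_spatial))
    gam = PenalizedAdditiveModel(terms).fit(X, y)
    return FittedModel(spec, gam, ranges, dict(gam.diagnostics))


def ensemble_predict(models: list[FittedModel], X: pd.DataFrame,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted ensemble mean and inter-model SD (n-1 denominator) per row."""
    if len(models) < 2:
        raise ValueError("an ensemble needs at least 2 models")
    preds = np.column_stack([m.predict(X) for m in models])
    return preds.mean(axis=1), preds.std(axis=1, ddof=1)


@dataclass
class ImportanceReport:
    per_feature_global: pd.Series       # mean |contribution| per feature
    per_observation: pd.DataFrame       # rows = observations, cols = features
    base_value: float                   # E[f] over background draws
    per_observation_base: np.ndarray | None = None  # exact per-row baseline


def shap_importance(model: FittedModel, data: pd.DataFrame,
                    n_permutations: int = 50, seed: int = 0,
                    background_size: int = 200) -> ImportanceReport:
    """Sampling-based Shapley additive explanations.

    For each Monte-Carlo iteration a random feature order and one background
    row per observation are drawn; features are switched from background to
    observed values along the order, and each feature's marginal effect on
    the prediction is recorded.  Contributions per iteration sum exactly to
    ``f(x) - f(background)``, so averaged contributions satisfy the additivity
    property up to Monte-Carlo error.  Global importance is the mean absolute
    contribution per feature across observations.
    """
    feats = model.spec.features
    missing = [f for f in feats if f not in data.columns]
    if missing:
        raise ValueError(f"data lacks model features: {missing}")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    Xobs = data[feats].to_numpy(dtype=float)
    n, d = Xobs.shape
    bg = Xobs if n <= background_size else \
        Xobs[rng.choice(n, background_size, replace=False)]

    def f(arr: np.ndarray) -> np.ndarray:
        return model.predict(pd.DataFrame(arr, columns=feats))

    contrib = np.zeros((n, d))
    base_rows = np.zeros(n)
    for _ in range(n_permutations):
        order = rng.permutation(d)
        Z = bg[rng.integers(0, len(bg), n)].copy()
        prev = f(Z)
        base_rows += prev
        for j in order:
            Z[:, j] = Xobs[:, j]
            cur = f(Z)
            contrib[:, j] += cur - prev
            prev = cur
    contrib /= n_permutations
    base_rows /= n_permutations
    per_obs = pd.DataFrame(contrib, columns=feats, index=data.index)
    return ImportanceReport(per_feature_global=per_obs.abs().mean(),
                            per_observation=per_obs,
                            base_value=float(base_rows.mean()),
                            per_observation_base=base_rows)
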