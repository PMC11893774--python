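"""Model validation: region assignment, the two cross-validation designs,
null baselines, residual spatial autocorrelation, and regional refits.

Non-spatial (k-fold) cross-validation probes interpolation skill; spatial
cross-validation withholds whole biogeographic clusters and probes
extrapolation, which is expected to bound performance from below.  Reported
headline statistics are the medians across folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import FittedModel, ModelSpec, ensemble_predict, fit_model

#: Display regions; Andes and Dry forests are threshold-defined.
DISPLAY_REGIONS = [
    "Lowland-NW", "Lowland-SW", "East-central Amazon", "Guiana Shield",
    "Brazilian Shield", "Atlantic forest", "Andes", "Dry forests",
]

#: Atlantic, Andean and dry-forest plots pool into one cross-validation cluster.
POOLED_CLUSTER = "Other"
CV_CLUSTERS = ["Lowland-NW", "Lowland-SW", "East-central Amazon",
               "Guiana Shield", "Brazilian Shield", POOLED_CLUSTER]

ELEVATION_THRESHOLD_M = 1200.0
DRY_PRECIP_THRESHOLD_MM = 1000.0


class UnassignedPlotError(ValueError):
    pass


def assign_regions(table: pd.DataFrame) -> pd.DataFrame:
    """Assign display regions and cross-validation clusters.

    Montane plots (elevation > 1200 m) are Andes wherever they sit; of the
    rest, plots with annual precipitation < 1000 mm are Dry forests; the
    remainder take the label of their landscape block (``region_id`` 1-8 in
    display-region order).  Blocks 7/8 cells failing their threshold fall
    back to Atlantic forest, which shares the pooled cluster.  The six
    cv_cluster labels keep the five lowland regions and pool the rest.
    """
    required = {"elevation", "annual_precip", "region_id"}
    if not required <= set(table.columns):
        raise UnassignedPlotError(f"need columns {sorted(required)}")
    display = []
    for _, row in table.iterrows():
        if row["elevation"] > ELEVATION_THRESHOLD_M:
            display.append("Andes")
        elif row["annual_precip"] < DRY_PRECIP_THRESHOLD_MM:
            display.append("Dry forests")
        else:
            rid = int(row["region_id"])
            if not 1 <= rid <= 8:
                raise UnassignedPlotError(f"region_id {rid} outside 1-8")
            label = DISPLAY_REGIONS[rid - 1]
            if label in ("Andes", "Dry forests"):
                label = "Atlantic forest"
            display.append(label)
    out = table.copy()
    out["display_region"] = display
    out["cv_cluster"] = [d if d in CV_CLUSTERS else POOLED_CLUSTER for d in display]
    return out


@dataclass
class CVMetrics:
    rmse: float
    r: float
    r2: float


def compute_metrics(observed, predicted) -> CVMetrics:
    """RMSE, Pearson correlation and coefficient of determination.

    r2 = 1 - RSS/TSS with TSS about the observed mean of the evaluation set;
    it is negative when predictions do worse than that mean.  r is NaN when
    either vector has zero variance; r2 is NaN when the observations do.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or len(obs) < 2:
        raise ValueError("observed and predicted must be equal-length vectors, n >= 2")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    tss = float(((obs - obs.mean()) ** 2).sum())
    obs_const, pred_const = np.ptp(obs) == 0, np.ptp(pred) == 0
    if obs_const or pred_const:
        r = float("nan")
    else:
        r = float(np.corrcoef(obs, pred)[0, 1])
    r2 = float("nan") if obs_const else \
        float(1.0 - ((obs - pred) ** 2).sum() / tss)
    return CVMetrics(rmse=rmse, r=r, r2=r2)


@dataclass
class CVResult:
    per_fold: dict[str, list[CVMetrics]]        # model label -> fold metrics
    fold_keys: list = field(default_factory=list)   # fold label per position
    fold_ids: np.ndarray | None = None              # assignment per table row
    median: dict[str, CVMetrics] = field(default_factory=dict)

    def __post_init__(self):
        for label, ms in self.per_fold.items():
            self.median[label] = CVMetrics(
                rmse=float(np.median([m.rmse for m in ms])),
                r=float(np.median([m.r for m in ms])),
                r2=float(np.median([m.r2 for m in ms])))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({label: {"rmse": m.rmse, "r": m.r, "r2": m.r2}
                             for label, m in self.median.items()}).T


def _run_folds(table: pd.DataFrame, fold_ids: np.ndarray,
               specs: list[ModelSpec], response: str) -> CVResult:
    labels = [s.label for s in specs] + ["Ensemble"]
    per_fold: dict[str, list[CVMetrics]] = {lb: [] for lb in labels}
    fold_keys = list(np.unique(fold_ids))
    for fid in np.unique(fold_ids):
        test = fold_ids == fid
        train_tab, test_tab = table[~test], table[test]
        obs = test_tab[response].to_numpy(dtype=float)
        fitted = [fit_model(s, train_tab, response) for s in specs]
        preds = []
        for s, m in zip(specs, fitted):
            p = m.predict(test_tab)
            preds.append(p)
            per_fold[s.label].append(compute_metrics(obs, p))
        if len(fitted) >= 2:
            mean_pred = np.column_stack(preds).mean(axis=1)
            per_fold["Ensemble"].append(compute_metrics(obs, mean_pred))
    per_fold = {k: v for k, v in per_fold.items() if v}
    return CVResult(per_fold=per_fold, fold_keys=fold_keys, fold_ids=fold_ids)


def kfold_cv(table: pd.DataFrame, specs: list[ModelSpec], k: int = 10,
             seed: int = 0, response: str = "wd3",
             fold_ids: np.ndarray | None = None) -> CVResult:
    """Random k-fold cross-validation with balanced folds (sizes differ by
    at most one), refitting every spec per fold.  A precomputed fold
    assignment may be injected via ``fold_ids``."""
    n = len(table)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if fold_ids is None:
        rng = np.random.default_rng(seed)
        fold_ids = np.resize(np.arange(k), n)
        rng.shuffle(fold_ids)
    else:
        fold_ids = np.asarray(fold_ids)
    return _run_folds(table.reset_index(drop=True), fold_ids, specs, response)


def spatial_cv(table: pd.DataFrame, specs: list[ModelSpec],
               cluster_col: str = "cv_cluster", response: str = "wd3",
               min_cluster_size: int = 20) -> CVResult:
    """Leave-one-cluster-out cross-validation over spatial clusters."""
    clusters = table[cluster_col].to_numpy()
    uniq, counts = np.unique(clusters, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    for u, c in zip(uniq, counts):
        if c < min_cluster_size:
            warnings.warn(f"cluster {u!r} has only {c} plots; using it anyway")
    return _run_folds(table.reset_index(drop=True), clusters, specs, response)


def null_baselines(train_y, test_y, seed: int = 0) -> dict[str, CVMetrics]:
    """Mean-predictor and random-draw baselines evaluated on the test set."""
    train_y = np.asarray(train_y, dtype=float)
    test_y = np.asarray(test_y, dtype=float)
    if train_y.size == 0:
        raise ValueError("empty training vector")
    rng = np.random.default_rng(seed)
    mean_pred = np.full(len(test_y), train_y.mean())
    draw_pred = rng.choice(train_y, size=len(test_y), replace=True)
    return {"mean": compute_metrics(test_y, mean_pred),
            "random_draw": compute_metrics(test_y, draw_pred)}


def residual_autocorrelation(residuals, coords, n_perm: int = 999,
                             seed: int = 0) -> tuple[float, float]:
    """Moran's I with inverse-distance weights and a permutation p-value.

    Weights are 1/d with zero self-weight; coincident points use a distance
    floored at half the minimum nonzero distance.  The p-value is one-sided
    (positive autocorrelation) from ``n_perm`` random permutations of the
    residuals over locations.
    """
    z = np.asarray(residuals, dtype=float)
    xy = np.asarray(coords, dtype=float)
    n = len(z)
    if n < 30:
        raise ValueError("need at least 30 residuals")
    if z.std() == 0:
        raise ValueError("Moran's I undefined for constant residuals")
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    off = d[~np.eye(n, dtype=bool)]
    floor = off[off > 0].min() / 2.0
    d = np.maximum(d, floor)
    W = 1.0 / d
    np.fill_diagonal(W, 0.0)
    s0 = W.sum()
    zc = z - z.mean()
    denom = (zc ** 2).sum()
    i_obs = float(n / s0 * (zc @ W @ zc) / denom)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        zp = rng.permutation(zc)
        i_p = n / s0 * (zp @ W @ zp) / denom
        if i_p >= i_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return i_obs, float(p)


def regional_refit_compare(table: pd.DataFrame, spec: ModelSpec,
                           region_col: str = "display_region",
                           response: str = "wd3",
                           min_region_size: int = 30) -> dict[str, float]:
    """Pearson correlation, per region, between predictions of a model trained
    on that region alone and a model trained on the whole dataset."""
    global_model = fit_model(spec, table, response)
    out: dict[str, float] = {}
    for region, sub in table.groupby(region_col):
        if len(sub) < min_region_size:
            warnings.warn(f"region {region!r} has {len(sub)} < {min_region_size} "
                          "plots; skipped")
            continue
        local_model = fit_model(spec, sub, response)
        pg = global_model.predict(sub)
        pl = local_model.predict(sub)
        if np.std(pg) == 0 or np.std(pl) == 0:
            out[region] = float("nan")
        else:
            out[region] = float(np.corrcoef(pg, pl)[0, 1])
    return out
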