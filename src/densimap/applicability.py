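"""Where can the maps be trusted: subsample sensitivity, range-extrapolation
flags, the dissimilarity index (DI) and the area of applicability (AOA).

The DI of a query point is its scaled-Euclidean distance to the nearest
training point divided by the mean pairwise distance among training points
(features centered and scaled by training statistics, unweighted by
importance).  The AOA threshold is the boxplot whisker rule, Q3 + 1.5 * IQR,
applied to the fold-aware DI of the training points themselves — each
training point measured against the nearest point *outside its own
cross-validation fold*; a literal 1.5 * IQR reading is switchable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from .models import ModelSpec, fit_model


def loess(x, y, x_eval=None, span: float = 0.75, degree: int = 2) -> np.ndarray:
    """Locally-weighted polynomial regression with tricube weights."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xe = x if x_eval is None else np.asarray(x_eval, dtype=float)
    n = len(x)
    q = max(int(np.ceil(span * n)), degree + 2)
    out = np.empty(len(xe))
    for i, x0 in enumerate(xe):
        d = np.abs(x - x0)
        h = np.partition(d, q - 1)[q - 1]
        w = np.clip(1.0 - (d / max(h, 1e-12)) ** 3, 0.0, None) ** 3
        keep = w > 0
        A = np.vander(x[keep] - x0, degree + 1, increasing=True)
        Aw = A * w[keep, None]
        coef, *_ = np.linalg.lstsq(Aw.T @ A, Aw.T @ y[keep], rcond=None)
        out[i] = coef[0]
    return out


@dataclass
class SensitivityResult:
    per_plot_sd: np.ndarray
    smoothed_sd_vs_feature: dict[str, tuple[np.ndarray, np.ndarray]]  # (grid, fit)
    flagged_feature_ranges: dict[str, list[tuple[float, float]]]
    sd_threshold: float
    n_subsamples: int
    subsample_fraction: float


def subsample_sensitivity(table: pd.DataFrame, spec: ModelSpec,
                          n: int = 1000, fraction: float = 0.5,
                          sd_threshold: float = 0.05, seed: int = 0,
                          response: str = "wd3",
                          span: float = 0.75) -> SensitivityResult:
    """Half-sample refitting sensitivity of predictions.

    Draw ``n`` subsamples of ``fraction`` of the plots without replacement,
    refit the model spec on each, predict all plots, and take the SD of the
    ``n`` predictions per plot.  The SD is then related to each explanatory
    variable by locally-weighted polynomial regression, and intervals where
    the fitted curve exceeds ``sd_threshold`` are flagged as poorly
    constrained.
    """
    if n < 2:
        raise ValueError("need at least 2 subsamples")
    N = len(table)
    m = int(np.floor(fraction * N))
    if m < 30:
        raise ValueError("subsample smaller than 30 plots")
    rng = np.random.default_rng(seed)
    table = table.reset_index(drop=True)
    preds = np.empty((n, N))
    for i in range(n):
        idx = rng.choice(N, size=m, replace=False)
        fitted = fit_model(replace(spec, seed=spec.seed + i),
                           table.iloc[idx], response)
        preds[i] = fitted.predict(table)
    sd = preds.std(axis=0, ddof=1)

    curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    flags: dict[str, list[tuple[float, float]]] = {}
    for f in spec.features:
        x = table[f].to_numpy(dtype=float)
        grid = np.linspace(x.min(), x.max(), 60)
        fit = loess(x, sd, grid, span=span, degree=2)
        curves[f] = (grid, fit)
        above = fit > sd_threshold
        intervals: list[tuple[float, float]] = []
        start = None
        for g, a in zip(grid, above):
            if a and start is None:
                start = g
            elif not a and start is not None:
                intervals.append((start, g))
                start = None
        if start is not None:
            intervals.append((start, grid[-1]))
        flags[f] = intervals
    return SensitivityResult(per_plot_sd=sd, smoothed_sd_vs_feature=curves,
                             flagged_feature_ranges=flags,
                             sd_threshold=sd_threshold, n_subsamples=n,
                             subsample_fraction=fraction)


def range_extrapolation(train: pd.DataFrame, query: pd.DataFrame) -> pd.DataFrame:
    """Per-feature flags: query value outside the [min, max] seen in training."""
    missing = [c for c in train.columns if c not in query.columns]
    if missing:
        raise ValueError(f"query lacks features: {missing}")
    out = {}
    for c in train.columns:
        lo, hi = train[c].min(), train[c].max()
        q = query[c].to_numpy(dtype=float)
        out[c] = (q < lo) | (q > hi)
    return pd.DataFrame(out, index=query.index)


def _scale(train: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


def dissimilarity_index(train: pd.DataFrame, query: pd.DataFrame | None = None,
                        fold_ids=None, seed: int = 0,
                        max_exact_pairs_n: int = 2000) -> np.ndarray:
    """DI per query point (or fold-aware DI per training point).

    Features are centered and scaled by training statistics.  With
    ``query=None`` and ``fold_ids`` given, each training point's DI uses its
    nearest training neighbour *not in its own fold* — the quantity the AOA
    threshold is calibrated on.  The normaliser is the mean pairwise distance
    among training points (exact up to ``max_exact_pairs_n`` points, else
    estimated from 10^6 random pairs).
    """
    T = train.to_numpy(dtype=float)
    n = len(T)
    if n < 2:
        raise ValueError("need at least 2 training points")
    mu, sd = _scale(T)
    Ts = (T - mu) / sd
    if n <= max_exact_pairs_n:
        mean_pair = float(pdist(Ts).mean())
    else:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, n, 1_000_000)
        j = rng.integers(0, n, 1_000_000)
        keep = i != j
        mean_pair = float(np.sqrt(((Ts[i[keep]] - Ts[j[keep]]) ** 2).sum(1)).mean())

    if query is not None:
        Qs = (query[train.columns].to_numpy(dtype=float) - mu) / sd
        dmin = cdist(Qs, Ts).min(axis=1)
        return dmin / mean_pair

    if fold_ids is None:
        raise ValueError("provide query points or training fold ids")
    fold_ids = np.asarray(fold_ids)
    D = cdist(Ts, Ts)
    same = fold_ids[:, None] == fold_ids[None, :]
    D[same] = np.inf
    return D.min(axis=1) / mean_pair


def aoa_threshold(train_di, rule: str = "q3+1.5iqr") -> float:
    """AOA cutoff from fold-aware training DI values.

    ``q3+1.5iqr`` (default) is the boxplot whisker rule; ``1.5iqr`` is the
    literal reading of the cited method's phrasing.  Quartiles use linear
    interpolation.
    """
    di = np.asarray(train_di, dtype=float)
    if len(di) < 4:
        raise ValueError("need at least 4 DI values for quartiles")
    q1, q3 = np.quantile(di, [0.25, 0.75])
    iqr = q3 - q1
    if rule == "q3+1.5iqr":
        return float(q3 + 1.5 * iqr)
    if rule == "1.5iqr":
        return float(1.5 * iqr)
    raise ValueError(f"unknown rule {rule!r}")
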