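"""Gridded prediction: per-model, ensemble and uncertainty layers with masks.

Predictions run over the covariate grid's cell centers; masking replaces
non-forest cells with the missing-value code and keeps an unmasked companion
of the ensemble so out-of-applicability areas can still be inspected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace as _dc_replace
from pathlib import Path

import numpy as np
import pandas as pd

from .env import ENV_FEATURES
from .models import FittedModel
from .rasters import NODATA, read_ascii_grid, write_ascii_grid


@dataclass
class PredictionGrid:
    per_model_layers: dict[str, np.ndarray]
    ensemble_mean: np.ndarray
    inter_model_sd: np.ndarray
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    ensemble_unmasked: np.ndarray | None = None
    cell_size: float = 0.0
    origin: tuple[float, float] = (0.0, 0.0)
    metadata: dict = field(default_factory=dict)


def _grid_feature_table(landscape) -> pd.DataFrame:
    """One row per grid cell (cell-center lon/lat plus covariate layers)."""
    from .env import compute_mcwd

    L = landscape.layers
    nrows, ncols = landscape.grid_dims
    lon2d, lat2d = landscape.lonlat_grids()
    cols = {"lon": lon2d.ravel(), "lat": lat2d.ravel()}
    for f in ENV_FEATURES:
        if f == "mcwd":
            continue
        cols[f] = np.asarray(L[f], dtype=float).ravel()
    precip = np.stack([L[f"precip_{m:02d}"] for m in range(1, 13)], axis=-1)
    pet = np.stack([L[f"pet_{m:02d}"] for m in range(1, 13)], axis=-1)
    flatp = precip.reshape(-1, 12)
    flate = pet.reshape(-1, 12)
    cols["mcwd"] = np.array([compute_mcwd(flatp[i], flate[i]).mcwd
                             for i in range(nrows * ncols)])
    return pd.DataFrame(cols)


def predict_grid(models: list[FittedModel], landscape) -> PredictionGrid:
    """Predict every model over all grid cells; no masks applied yet."""
    features = _grid_feature_table(landscape)
    shape = landscape.grid_dims
    for m in models:
        missing = [f for f in m.spec.features if f not in features.columns]
        if missing:
            raise ValueError(f"missing layers for {m.spec.label}: {missing}")
    layers: dict[str, np.ndarray] = {}
    for i, m in enumerate(models):
        label = m.spec.label
        if label in layers:  # disambiguate duplicate specs
            label = f"{label} #{i}"
        layers[label] = m.predict(features).reshape(shape)
    stack = np.stack(list(layers.values()))
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(models) > 1 else np.zeros(shape)
    return PredictionGrid(per_model_layers=layers, ensemble_mean=mean,
                          inter_model_sd=sd, cell_size=landscape.cell_size,
                          origin=landscape.origin,
                          metadata={"models": [m.spec.label for m in models]})


def apply_masks(grid: PredictionGrid, forest_mask: np.ndarray,
                aoa_mask: np.ndarray | None = None,
                extrapolation_flags: np.ndarray | None = None) -> PredictionGrid:
    """Mask non-forest cells to missing; flag forest cells outside the AOA.

    The AOA exclusion is kept separate: `ensemble_unmasked` retains
    forest-masked-only predictions, while `ensemble_mean` additionally blanks
    cells outside the area of applicability.  Idempotent.
    """
    shape = grid.ensemble_mean.shape
    for m, name in ((forest_mask, "forest"), (aoa_mask, "aoa"),
                    (extrapolation_flags, "extrapolation")):
        if m is not None and np.asarray(m).shape != shape:
            raise ValueError(f"{name} mask geometry does not match the grid")
    forest = np.asarray(forest_mask, dtype=bool)
    aoa = np.ones(shape, dtype=bool) if aoa_mask is None else np.asarray(aoa_mask, dtype=bool)

    def blank(a: np.ndarray, keep: np.ndarray) -> np.ndarray:
        out = a.astype(float).copy()
        out[~keep] = np.nan
        return out

    unmasked = grid.ensemble_unmasked if grid.ensemble_unmasked is not None \
        else grid.ensemble_mean
    masks = {"forest": forest, "aoa": aoa}
    if extrapolation_flags is not None:
        masks["extrapolation"] = np.asarray(extrapolation_flags, dtype=bool)
    return _dc_replace(
        grid,
        per_model_layers={k: blank(v, forest) for k, v in grid.per_model_layers.items()},
        ensemble_unmasked=blank(unmasked, forest),
        ensemble_mean=blank(unmasked, forest & aoa),
        inter_model_sd=blank(grid.inter_model_sd, forest),
        masks=masks,
    )


def save_prediction_grid(grid: PredictionGrid, directory: str | Path) -> dict:
    """Write all layers as ASCII rasters plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    def w(name: str, arr: np.ndarray):
        write_ascii_grid(directory / f"{name}.asc", np.asarray(arr, dtype=float),
                         grid.origin, grid.cell_size)
        written.append(f"{name}.asc")

    for label, layer in grid.per_model_layers.items():
        w(label.replace(" ", "_").replace("-", "").lower(), layer)
    w("ensemble_mean", grid.ensemble_mean)
    w("inter_model_sd", grid.inter_model_sd)
    if grid.ensemble_unmasked is not None:
        w("ensemble_unmasked", grid.ensemble_unmasked)
    for name, mask in grid.masks.items():
        w(f"mask_{name}", np.asarray(mask, dtype=float))
    manifest = {"layers": written, "cell_size": grid.cell_size,
                "origin": list(grid.origin), "nodata": NODATA,
                "metadata": grid.metadata}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_layer(path: str | Path) -> np.ndarray:
    grid, _, _ = read_ascii_grid(path)
    return grid
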