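"""Read exported synthetic fixtures back into in-memory objects."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .density import PlotInventory, StemRecord
from .rasters import read_ascii_grid
from .synthetic import ReferenceTaxonomy, SyntheticLandscape, TruthParams


def load_world(directory: Path):
    """Load (landscape, reference, plots) from a fixture directory."""
    layer_dir = directory / "layers"
    layers = {}
    origin = (0.0, 0.0)
    cell = 1.0
    for p in sorted(layer_dir.glob("*.asc")):
        grid, origin, cell = read_ascii_grid(p)
        layers[p.stem] = grid
    true_surface = layers.pop("true_surface", None)
    if "forest_mask" in layers:
        layers["forest_mask"] = layers["forest_mask"] > 0.5
    if "region_id" in layers:
        layers["region_id"] = layers["region_id"].astype(int)
    some = next(iter(layers.values()))
    landscape = SyntheticLandscape(grid_dims=some.shape, cell_size=cell,
                                   origin=origin, layers=layers,
                                   true_surface=true_surface,
                                   truth_params=TruthParams())

    reference = ReferenceTaxonomy.from_frame(
        pd.read_csv(directory / "reference.tsv", sep="\t", keep_default_na=False))

    stems = pd.read_csv(directory / "stems.tsv", sep="\t", keep_default_na=False)
    plots: list[PlotInventory] = []
    for pid, grp in stems.groupby("plot_id", sort=False):
        first = grp.iloc[0]
        recs = [StemRecord(plot_id=pid, family=str(r.family), genus=str(r.genus),
                           species=str(r.species), dbh_cm=float(r.dbh_cm))
                for r in grp.itertuples()]
        plots.append(PlotInventory(plot_id=pid, lon=float(first.lon),
                                   lat=float(first.lat),
                                   area_ha=float(first.area_ha), stems=recs))
    return landscape, reference, plots
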