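"""End-to-end helpers wiring the pipeline stages together.

`build_plot_table` runs the inventory side — census filters, density
matching, stand summaries, covariate extraction, region assignment — and
returns the modelling table every downstream stage consumes.
"""

from __future__ import annotations

import pandas as pd

from .density import (PlotInventory, filter_plots, match_wood_density,
                      summaries_to_frame, summarize_stand)
from .env import features_at_plots
from .validation import assign_regions


def build_plot_table(plots: list[PlotInventory], reference, landscape,
                     ) -> tuple[pd.DataFrame, list[PlotInventory]]:
    """Filter, match and summarise plots; join covariates and regions.

    Returns the per-plot modelling table (wd metrics + covariates +
    display_region / cv_cluster) and the filtered, density-matched plots in
    the same order.
    """
    kept, _ = filter_plots(plots)
    matched = [match_wood_density(p, reference) for p in kept]
    summaries = [summarize_stand(p) for p in matched]
    table = summaries_to_frame(matched, summaries).drop(columns=["region_id"])
    feats = features_at_plots(landscape, matched)  # carries grid region_id
    table = table.merge(feats.drop(columns=["lon", "lat"]), on="plot_id")
    table = assign_regions(table)
    return table, matched
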