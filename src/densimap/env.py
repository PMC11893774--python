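"""Derived environmental covariates and the collinearity screen.

The maximum cumulative water deficit (MCWD) follows the standard tropical
water-balance recurrence: starting in the wettest month, each month's balance
is (precipitation - potential evapotranspiration) plus the previous month's
balance when that was negative; MCWD is the most negative balance over the
year (clamped at zero by default, so a year with surplus every month reports
no deficit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Canonical covariate order used for tie-breaks in the collinearity screen.
TABLE1_ORDER = [
    "mat", "annual_precip", "mcwd", "wind", "cloud", "lightning",
    "cec", "ph", "depth_rock", "texture1", "texture2",
    "rugosity", "slope", "hand", "lon", "lat",
]

#: Covariates entering models after screening (slope and annual precipitation
#: are discarded by the default forced drops).
ENV_FEATURES = ["mat", "mcwd", "wind", "cloud", "lightning", "cec", "ph",
                "depth_rock", "texture1", "texture2", "rugosity", "hand"]


@dataclass
class MonthlyWaterBalance:
    precip: np.ndarray
    pet: np.ndarray
    wb: np.ndarray       # running balance, indexed by calendar month
    mcwd: float
    start_month: int     # wettest calendar month (0-based; ties -> earliest)


@dataclass
class ScreeningReport:
    pairwise_r: pd.DataFrame
    dropped: list[tuple[str, str]]   # (variable, partner that triggered the drop)
    retained: list[str]
    vif: dict[str, float]
    vif_flagged: list[str]


def compute_mcwd(precip, pet, clamp: bool = True) -> MonthlyWaterBalance:
    """Run the monthly water-balance recurrence from the wettest month.

    wb[start] = P - PET there; for each subsequent month in cyclic order
    wb[m] = (P[m] - PET[m]) + min(wb[m-1], 0). MCWD is min over months of
    min(wb, 0) when ``clamp`` (default), else the raw minimum balance.
    """
    precip = np.asarray(precip, dtype=float)
    pet = np.asarray(pet, dtype=float)
    if precip.shape != (12,) or pet.shape != (12,):
        raise ValueError("precip and pet must each have 12 monthly values")
    if not (np.isfinite(precip).all() and np.isfinite(pet).all()):
        raise ValueError("non-finite monthly values")
    if (precip < 0).any() or (pet < 0).any():
        raise ValueError("monthly values must be non-negative")

    start = int(np.argmax(precip))  # argmax takes the earliest of tied months
    wb = np.empty(12)
    wb[start] = precip[start] - pet[start]
    for k in range(1, 12):
        m = (start + k) % 12
        prev = wb[(start + k - 1) % 12]
        wb[m] = (precip[m] - pet[m]) + min(prev, 0.0)
    mcwd = float(np.minimum(wb, 0.0).min()) if clamp else float(wb.min())
    return MonthlyWaterBalance(precip=precip, pet=pet, wb=wb, mcwd=mcwd,
                               start_month=start)


def compute_texture(sand: float, silt: float, clay: float) -> tuple[float, float]:
    """Texture1 = ln(sand/clay), Texture2 = ln(silt/clay); inputs in percent."""
    if min(sand, silt, clay) <= 0:
        raise ValueError("sand, silt and clay must all be positive")
    return float(np.log(sand / clay)), float(np.log(silt / clay))


def compute_topography(elevation_window: np.ndarray, cell_size_m: float,
                       buffer_radius_m: float = 100.0) -> tuple[float, float]:
    """Mean slope (degrees) and rugosity (SD of elevation, m) within a
    circular buffer around the window center.

    Slope per cell is from central differences on the full window; the buffer
    holds cells whose centers lie within ``buffer_radius_m`` of the center
    cell's center.
    """
    elev = np.asarray(elevation_window, dtype=float)
    if elev.ndim != 2:
        raise ValueError("elevation window must be 2-D")
    nr, nc = elev.shape
    half_r, half_c = (nr - 1) // 2, (nc - 1) // 2
    if min(half_r, half_c) * cell_size_m < buffer_radius_m:
        raise ValueError("elevation window does not cover the buffer radius")
    gy, gx = np.gradient(elev, cell_size_m)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    rr, cc = np.meshgrid(np.arange(nr) - half_r, np.arange(nc) - half_c,
                         indexing="ij")
    inside = (rr ** 2 + cc ** 2) * cell_size_m ** 2 <= buffer_radius_m ** 2
    return float(slope[inside].mean()), float(elev[inside].std())


def _vif(df: pd.DataFrame) -> dict[str, float]:
    """VIF_j = 1 / (1 - R^2) of each column regressed on the others."""
    out = {}
    X = df.to_numpy(dtype=float)
    for j, name in enumerate(df.columns):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(len(y)), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        tss = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - (resid ** 2).sum() / tss
        out[name] = float(1.0 / max(1.0 - r2, 1e-12))
    return out


def screen_collinearity(features: pd.DataFrame, r_threshold: float = 0.7,
                        vif_threshold: float = 4.0,
                        forced_drops: list[str] | None = None) -> ScreeningReport:
    """Drop collinear covariates, then report VIFs on the retained set.

    After applying ``forced_drops``, while any retained pair has |r| above the
    threshold the member participating in more high-|r| pairs is dropped
    (ties broken toward the variable later in the canonical covariate order).
    Variables with VIF at or above ``vif_threshold`` are flagged, not dropped.
    """
    if features.shape[1] < 3:
        raise ValueError("need at least 3 numeric columns")
    if features.isna().any().any():
        raise ValueError("missing values in feature table")
    std = features.std(ddof=0)
    if (std == 0).any():
        bad = std.index[std == 0].tolist()
        raise ValueError(f"constant columns: {bad}")

    corr = features.corr()
    dropped: list[tuple[str, str]] = []
    retained = list(features.columns)

    for name in (forced_drops or []):
        if name in retained:
            retained.remove(name)
            partners = corr.loc[name, retained].abs()
            dropped.append((name, partners.idxmax() if len(partners) else ""))

    def order_key(v: str) -> int:
        return TABLE1_ORDER.index(v) if v in TABLE1_ORDER else len(TABLE1_ORDER)

    while True:
        sub = corr.loc[retained, retained].abs()
        np.fill_diagonal(sub.values, 0.0)
        if (sub.values <= r_threshold).all():
            break
        counts = (sub > r_threshold).sum(axis=1)
        worst = counts.max()
        candidates = sorted(counts.index[counts == worst], key=order_key)
        victim = candidates[-1]  # tie -> later in canonical order
        partner = sub.loc[victim].idxmax()
        retained.remove(victim)
        dropped.append((victim, partner))

    vif = _vif(features[retained])
    flagged = [v for v, x in vif.items() if x >= vif_threshold]
    return ScreeningReport(pairwise_r=corr, dropped=dropped, retained=retained,
                           vif=vif, vif_flagged=flagged)


def features_at_plots(landscape, plots) -> pd.DataFrame:
    """Extract the covariate vector for each plot from the landscape layers
    (nearest cell center; plots generated on the landscape carry their cell).

    MCWD is computed from the monthly precipitation and PET layers via the
    water-balance recurrence.
    """
    L = landscape.layers
    rows = []
    for p in plots:
        if p.cell is not None:
            r, c = p.cell
        else:
            c = int(np.clip(round((p.lon - landscape.origin[0]) / landscape.cell_size - 0.5),
                            0, landscape.grid_dims[1] - 1))
            r = int(np.clip(round((p.lat - landscape.origin[1]) / landscape.cell_size - 0.5),
                            0, landscape.grid_dims[0] - 1))
        precip = np.array([L[f"precip_{m:02d}"][r, c] for m in range(1, 13)])
        pet = np.array([L[f"pet_{m:02d}"][r, c] for m in range(1, 13)])
        mcwd = compute_mcwd(precip, pet).mcwd
        rows.append({
            "plot_id": p.plot_id, "lon": p.lon, "lat": p.lat,
            "mat": L["mat"][r, c], "annual_precip": L["annual_precip"][r, c],
            "mcwd": mcwd, "wind": L["wind"][r, c], "cloud": L["cloud"][r, c],
            "lightning": L["lightning"][r, c], "cec": L["cec"][r, c],
            "ph": L["ph"][r, c], "depth_rock": L["depth_rock"][r, c],
            "texture1": L["texture1"][r, c], "texture2": L["texture2"][r, c],
            "rugosity": L["rugosity"][r, c], "slope": L["slope"][r, c],
            "hand": L["hand"][r, c], "elevation": L["elevation"][r, c],
            "region_id": int(L["region_id"][r, c]),
        })
    return pd.DataFrame(rows)
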