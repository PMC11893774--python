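"""Synthetic reference databases, landscapes and inventories with known truth.

The generator emulates the statistical structure a continental wood-density
mapping analysis assumes: spatially autocorrelated environmental covariates on
a small lon/lat grid, a true community wood-density surface driven by a
longitude gradient plus soil effects, hierarchical taxon pools with
species/genus/family mean densities, and per-plot stem lists with lognormal
diameters above a 10 cm census threshold.  Every plot records the value of the
true surface at its cell so downstream recovery can be verified.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .density import PlotInventory, StemRecord
from .rasters import write_ascii_grid

__all__ = [
    "ReferenceTaxonomy",
    "TruthParams",
    "SyntheticLandscape",
    "GenerationConfig",
    "REGION_LABELS",
    "generate_reference_db",
    "generate_landscape",
    "generate_plots",
    "export_fixtures",
]

#: Display-region labels, one per contiguous landscape block.
REGION_LABELS = (
    "Lowland-NW",
    "Lowland-SW",
    "East-central Amazon",
    "Guiana Shield",
    "Brazilian Shield",
    "Atlantic forest",
    "Andes",
    "Dry forests",
)


@dataclass
class ReferenceTaxonomy:
    """Taxon pools with mean wood density (g cm^-3) at each rank.

    Genus means are the arithmetic mean of member-species means and family
    means the arithmetic mean of member-genus means, mirroring how a trait
    database aggregates upward.
    """

    families: list[str]
    genera: dict[str, str]          # genus -> family
    species: dict[str, str]         # species -> genus
    species_density: dict[str, float]
    genus_density: dict[str, float]
    family_density: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, fam in self.genera.items():
            rows.append(("genus", name, fam, self.genus_density[name]))
        for name, gen in self.species.items():
            rows.append(("species", name, gen, self.species_density[name]))
        for name in self.families:
            rows.append(("family", name, "", self.family_density[name]))
        return pd.DataFrame(rows, columns=["taxon_rank", "taxon_name", "parent_name", "wd_gcm3"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReferenceTaxonomy":
        fam = df[df.taxon_rank == "family"]
        gen = df[df.taxon_rank == "genus"]
        spp = df[df.taxon_rank == "species"]
        return cls(
            families=list(fam.taxon_name),
            genera=dict(zip(gen.taxon_name, gen.parent_name)),
            species=dict(zip(spp.taxon_name, spp.parent_name)),
            species_density=dict(zip(spp.taxon_name, spp.wd_gcm3)),
            genus_density=dict(zip(gen.taxon_name, gen.wd_gcm3)),
            family_density=dict(zip(fam.taxon_name, fam.wd_gcm3)),
        )


@dataclass
class TruthParams:
    """Coefficients of the generating model for the true density surface.

    The surface is ``lo + (hi - lo) * logistic(intercept + b_lon*z(lon) +
    b_cec*z(CEC) + b_texture1*z(Texture1))`` with z() standardisation over the
    grid, so densities stay inside (lo, hi).
    """

    intercept: float = 0.0
    b_lon: float = 1.5
    b_cec: float = -0.6
    b_texture1: float = 0.4
    lo: float = 0.3
    hi: float = 0.95


@dataclass
class SyntheticLandscape:
    grid_dims: tuple[int, int]              # (rows, cols)
    cell_size: float                        # degrees
    origin: tuple[float, float]             # (lon, lat) of the lower-left corner
    layers: dict[str, np.ndarray]
    true_surface: np.ndarray
    truth_params: TruthParams

    @property
    def lon(self) -> np.ndarray:
        """Cell-center longitudes, one per column."""
        _, ncols = self.grid_dims
        return self.origin[0] + (np.arange(ncols) + 0.5) * self.cell_size

    @property
    def lat(self) -> np.ndarray:
        """Cell-center latitudes, one per row (row 0 = southernmost)."""
        nrows, _ = self.grid_dims
        return self.origin[1] + (np.arange(nrows) + 0.5) * self.cell_size

    def lonlat_grids(self) -> tuple[np.ndarray, np.ndarray]:
        lon2d, lat2d = np.meshgrid(self.lon, self.lat)
        return lon2d, lat2d


@dataclass
class GenerationConfig:
    """Inventory-sampling configuration.

    Identification probabilities default to the observed continental census
    frequencies (85.1% of stems identified to species, 95.4% to genus).
    """

    seed: int = 0
    n_plots: int = 400
    stems_per_plot: float = 120.0
    id_prob_species: float = 0.851
    id_prob_genus: float = 0.954
    noise_sd: float = 0.05
    plot_area_range: tuple[float, float] = (0.25, 1.0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.id_prob_species <= self.id_prob_genus <= 1.0):
            raise ValueError("need 0 <= id_prob_species <= id_prob_genus <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_plots <= 0 or self.stems_per_plot <= 0:
            raise ValueError("n_plots and stems_per_plot must be positive")


def generate_reference_db(n_families: int, n_genera: int, n_species: int,
                          seed: int) -> ReferenceTaxonomy:
    """Build a hierarchical wood-density reference database.

    Species means are drawn from a normal (mean 0.62, sd 0.15 g cm^-3)
    truncated to (0.1, 1.5); genus and family means are derived upward as
    arithmetic means of their members.
    """
    if min(n_families, n_genera, n_species) <= 0:
        raise ValueError("taxon counts must be positive")
    if not (n_families <= n_genera <= n_species):
        raise ValueError("need n_families <= n_genera <= n_species")
    rng = np.random.default_rng(seed)

    families = [f"Family_{i:03d}" for i in range(n_families)]
    genus_names = [f"Genus_{i:04d}" for i in range(n_genera)]
    species_names = [f"Species_{i:05d}" for i in range(n_species)]

    # every family gets >=1 genus, every genus >=1 species
    gen_fam = np.concatenate([np.arange(n_families),
                              rng.integers(0, n_families, n_genera - n_families)])
    spp_gen = np.concatenate([np.arange(n_genera),
                              rng.integers(0, n_genera, n_species - n_genera)])

    dens = rng.normal(0.62, 0.15, n_species)
    while True:  # truncate by redrawing out-of-range values
        bad = (dens <= 0.1) | (dens >= 1.5)
        if not bad.any():
            break
        dens[bad] = rng.normal(0.62, 0.15, bad.sum())

    species = {s: genus_names[g] for s, g in zip(species_names, spp_gen)}
    species_density = dict(zip(species_names, dens))
    genus_density = {}
    for gi, gname in enumerate(genus_names):
        member = dens[spp_gen == gi]
        genus_density[gname] = float(member.mean())
    genera = {genus_names[g]: families[f] for g, f in zip(range(n_genera), gen_fam)}
    family_density = {}
    gvals = np.array([genus_density[g] for g in genus_names])
    for fi, fname in enumerate(families):
        member = gvals[gen_fam == fi]
        family_density[fname] = float(member.mean())

    return ReferenceTaxonomy(families, genera, species,
                             species_density, genus_density, family_density)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float = 5.0) -> np.ndarray:
    """Spatially autocorrelated field: Gaussian-filtered white noise, z-scored."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def _rescale(f: np.ndarray, lo: float, hi: float) -> np.ndarray:
    fmin, fmax = f.min(), f.max()
    return lo + (f - fmin) / (fmax - fmin) * (hi - lo)


def _region_blocks(shape: tuple[int, int]) -> np.ndarray:
    """Partition the grid into 8 contiguous blocks (2 rows x 4 cols), ids 1-8."""
    nrows, ncols = shape
    rid = np.empty(shape, dtype=np.int32)
    row_edges = [0, nrows // 2, nrows]
    col_edges = np.linspace(0, ncols, 5).astype(int)
    k = 1
    for i in range(2):
        for j in range(4):
            rid[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]] = k
            k += 1
    return rid


def generate_landscape(grid_dims: tuple[int, int] = (60, 60),
                       cell_size: float = 0.05,
                       seed: int = 0,
                       truth_params: TruthParams | None = None,
                       origin: tuple[float, float] = (-75.0, -15.0),
                       ) -> SyntheticLandscape:
    """Generate covariate layers and the true wood-density surface.

    All covariates are smooth autocorrelated fields rescaled to plausible
    field ranges; the Andes block carries an elevation bump above 1200 m and
    the Dry block annual precipitation mostly below 1000 mm, so the
    threshold-based region rules have material to act on.
    """
    nrows, ncols = grid_dims
    if nrows < 10 or ncols < 10:
        raise ValueError("grid dimensions must each be >= 10")
    truth = truth_params if truth_params is not None else TruthParams()
    rng = np.random.default_rng(seed)
    shape = (nrows, ncols)

    region_id = _region_blocks(shape)
    andes = region_id == 7
    dry = region_id == 8

    layers: dict[str, np.ndarray] = {}

    elev = _rescale(_smooth_field(rng, shape), 0.0, 400.0)
    bump = ndimage.gaussian_filter(andes.astype(float), 3.0)
    elev = elev + 1600.0 * bump / bump.max()
    layers["elevation"] = elev

    # monthly climate: smooth annual totals with a seasonal profile
    annual_p = _rescale(_smooth_field(rng, shape), 1400.0, 3200.0)
    annual_p[dry] = _rescale(_smooth_field(rng, shape), 500.0, 1100.0)[dry]
    season_phase = rng.uniform(0, 2 * math.pi)
    amp = _rescale(_smooth_field(rng, shape), 0.3, 0.8)
    months = np.arange(12)
    profile = 1.0 + amp[..., None] * np.cos(2 * math.pi * months / 12 - season_phase)
    precip_m = annual_p[..., None] / 12.0 * profile
    pet_m = _rescale(_smooth_field(rng, shape), 80.0, 140.0)[..., None] * \
        (1.0 + 0.15 * np.cos(2 * math.pi * months / 12 - season_phase - math.pi))
    for m in range(12):
        layers[f"precip_{m + 1:02d}"] = precip_m[..., m]
        layers[f"pet_{m + 1:02d}"] = pet_m[..., m]
    layers["annual_precip"] = precip_m.sum(axis=2)

    mat = _rescale(_smooth_field(rng, shape), 22.0, 28.0) - 0.005 * elev
    layers["mat"] = mat
    layers["wind"] = _rescale(_smooth_field(rng, shape), 1.0, 5.0)
    layers["cloud"] = _rescale(_smooth_field(rng, shape), 0.3, 0.9)
    layers["lightning"] = _rescale(_smooth_field(rng, shape), 0.5, 30.0)
    layers["cec"] = _rescale(_smooth_field(rng, shape), 5.0, 40.0)
    layers["ph"] = _rescale(_smooth_field(rng, shape), 3.8, 6.5)
    layers["depth_rock"] = _rescale(_smooth_field(rng, shape), 40.0, 200.0)

    # soil fractions: three positive smooth fields normalised to 100%
    parts = np.stack([np.exp(_smooth_field(rng, shape) * 0.8) for _ in range(3)])
    parts = parts / parts.sum(axis=0) * 100.0
    layers["sand"], layers["silt"], layers["clay"] = parts[0], parts[1], parts[2]
    layers["texture1"] = np.log(parts[0] / parts[2])
    layers["texture2"] = np.log(parts[1] / parts[2])

    layers["hand"] = _rescale(_smooth_field(rng, shape), 0.0, 50.0)

    # terrain derivatives from the elevation layer (grid-scale source)
    cell_m = cell_size * 111_000.0
    gy, gx = np.gradient(elev, cell_m)
    layers["slope"] = np.degrees(np.arctan(np.hypot(gx, gy)))
    mean9 = ndimage.uniform_filter(elev, 3, mode="reflect")
    mean9_sq = ndimage.uniform_filter(elev ** 2, 3, mode="reflect")
    layers["rugosity"] = np.sqrt(np.clip(mean9_sq - mean9 ** 2, 0.0, None))

    forest_score = _smooth_field(rng, shape)
    layers["forest_mask"] = forest_score < np.quantile(forest_score, 0.9)
    layers["region_id"] = region_id

    lon = origin[0] + (np.arange(ncols) + 0.5) * cell_size
    lon2d = np.broadcast_to(lon, shape).copy()

    def z(a: np.ndarray) -> np.ndarray:
        s = a.std()
        return (a - a.mean()) / s if s > 0 else np.zeros_like(a)

    eta = (truth.intercept + truth.b_lon * z(lon2d)
           + truth.b_cec * z(layers["cec"])
           + truth.b_texture1 * z(layers["texture1"]))
    true_surface = truth.lo + (truth.hi - truth.lo) / (1.0 + np.exp(-eta))

    return SyntheticLandscape(grid_dims=grid_dims, cell_size=cell_size,
                              origin=origin, layers=layers,
                              true_surface=true_surface, truth_params=truth)


def _draw_species(rng: np.random.Generator, names: np.ndarray,
                  dens: np.ndarray, target: float, n: int) -> np.ndarray:
    """Sample species indices with weight (|rho - target| + 0.01)^-3.

    The weight increases in 1/|rho - target|, concentrating the community on
    taxa near the local target density so the stand mean converges to it.
    """
    w = (np.abs(dens - target) + 0.01) ** -3
    w = w / w.sum()
    return rng.choice(len(names), size=n, p=w)


def generate_plots(landscape: SyntheticLandscape,
                   reference: ReferenceTaxonomy,
                   cfg: GenerationConfig) -> list[PlotInventory]:
    """Sample plot inventories from forest cells of the landscape.

    Each plot is placed at a distinct forest cell; stems are drawn from the
    reference species pool with selection weights concentrating community
    composition around ``true_surface + N(0, noise_sd)`` at the cell, so the
    expected basal-area-weighted density of a large plot equals the stored
    truth. Diameters are lognormal with a hard 10 cm census threshold.
    Identification level is assigned per stem; unidentified stems keep their
    true species density internally (it contributes to plot truth) but expose
    no taxon to the matching cascade.
    """
    rng = np.random.default_rng(cfg.seed)
    forest = landscape.layers["forest_mask"]
    cells = np.flatnonzero(forest)
    if cfg.n_plots > cells.size:
        raise ValueError(f"n_plots={cfg.n_plots} exceeds {cells.size} forest cells")
    chosen = rng.choice(cells, size=cfg.n_plots, replace=False)
    nrows, ncols = landscape.grid_dims
    rows, cols = np.divmod(chosen, ncols)

    names = np.array(list(reference.species_density))
    dens = np.array([reference.species_density[s] for s in names])
    lonv, latv = landscape.lon, landscape.lat
    region = landscape.layers["region_id"]

    p_sp = cfg.id_prob_species
    p_gn = cfg.id_prob_genus
    plots: list[PlotInventory] = []
    for i in range(cfg.n_plots):
        r, c = rows[i], cols[i]
        truth = float(landscape.true_surface[r, c])
        target = truth + rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else truth
        target = float(np.clip(target, 0.15, 1.2))
        n_stems = max(int(rng.poisson(cfg.stems_per_plot)), 5)
        idx = _draw_species(rng, names, dens, target, n_stems)
        # lognormal truncated at the 10 cm census threshold (folded normal on
        # the log scale: mass decays away from the threshold)
        dbh = 10.0 * np.exp(np.abs(rng.normal(0.0, 0.5, n_stems)))
        u = rng.uniform(size=n_stems)
        half = rng.uniform(size=n_stems) < 0.5  # split remainder family-only / unknown
        area = float(rng.uniform(*cfg.plot_area_range))
        pid = f"P{i:04d}"
        stems = []
        for j in range(n_stems):
            sp = names[idx[j]]
            gn = reference.species[sp]
            fam = reference.genera[gn]
            if u[j] < p_sp:
                species, genus, family = sp, gn, fam
            elif u[j] < p_gn:
                species, genus, family = "", gn, fam
            elif half[j]:
                species, genus, family = "", "", fam
            else:
                species = genus = family = ""
            stems.append(StemRecord(plot_id=pid, family=family, genus=genus,
                                    species=species, dbh_cm=float(dbh[j]),
                                    true_wd=float(dens[idx[j]])))
        plots.append(PlotInventory(plot_id=pid, lon=float(lonv[c]), lat=float(latv[r]),
                                   area_ha=area, region_id=int(region[r, c]),
                                   stems=stems, census_index=0,
                                   true_wd=truth, cell=(int(r), int(c))))
    return plots


def plots_to_stem_frame(plots: list[PlotInventory]) -> pd.DataFrame:
    rows = []
    for p in plots:
        for s in p.stems:
            rows.append((p.plot_id, p.lon, p.lat, p.area_ha,
                         s.family, s.genus, s.species, s.dbh_cm))
    return pd.DataFrame(rows, columns=["plot_id", "lon", "lat", "area_ha",
                                       "family", "genus", "species", "dbh_cm"])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def export_fixtures(landscape: SyntheticLandscape,
                    plots: list[PlotInventory],
                    reference: ReferenceTaxonomy,
                    directory: str | Path) -> dict:
    """Write stem/reference tables and one raster per layer; return a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    stems_path = directory / "stems.tsv"
    plots_to_stem_frame(plots).to_csv(stems_path, sep="\t", index=False)
    files["stems.tsv"] = _sha256(stems_path)

    ref_path = directory / "reference.tsv"
    reference.to_frame().to_csv(ref_path, sep="\t", index=False)
    files["reference.tsv"] = _sha256(ref_path)

    layer_dir = directory / "layers"
    layer_dir.mkdir(exist_ok=True)
    for name, layer in landscape.layers.items():
        p = layer_dir / f"{name}.asc"
        write_ascii_grid(p, np.asarray(layer, dtype=float),
                         origin=landscape.origin, cell_size=landscape.cell_size)
        files[f"layers/{name}.asc"] = _sha256(p)
    p = layer_dir / "true_surface.asc"
    write_ascii_grid(p, landscape.true_surface,
                     origin=landscape.origin, cell_size=landscape.cell_size)
    files["layers/true_surface.asc"] = _sha256(p)

    manifest = {"n_plots": len(plots), "grid_dims": list(landscape.grid_dims),
                "files": files}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
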