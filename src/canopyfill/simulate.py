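"""Synthetic Sardinilla-like stands, point clouds, and productivity.

Everything the pipeline ingests can be generated here with known
ground truth:

* an experimental design of 45 x 45 m plots on a 3 m planting grid —
  monocultures, three-species mixtures (one species per growth guild)
  and six-species mixtures, four quadrant subplots per plot. The
  default design (two monoculture plots per species over six species,
  six three-species and six six-species mixtures, with the
  high-mortality pioneer's monocultures removed) has 22 plots and 88
  subplots;
* tree lists with diameters and heights at two censuses drawn from
  guild-level growth distributions, plus survival;
* per-plot point clouds sampled uniformly inside ellipsoidal crowns at
  a species-specific density (Poisson counts), with optional stem and
  ground returns;
* subplot productivity, in two modes:
  - *generative*: AWP drawn from the gamma log-link mixed model with
    known coefficients — the surface for parameter-recovery tests;
  - *mechanistic*: AWP computed from the simulated growth through the
    productivity module — exercises the full pipeline with a
    CSFI-AWP coupling of realistic but unknown strength.

All draws flow from a single :class:`numpy.random.Generator`; a fixed
seed reproduces every stage bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .pointcloud import PlotGeometry, PointCloud

__all__ = [
    "SpeciesTraits",
    "DEFAULT_SPECIES",
    "PlotSpec",
    "ExperimentDesign",
    "SimulationParams",
    "make_design",
    "simulate_stand",
    "sample_point_cloud",
    "simulate_csfi_table",
    "generate_awp",
]

GUILDS = ("pioneer", "intermediate", "shade_tolerant")

RNGLike = Union[int, np.random.Generator]


def _rng(seed: RNGLike) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class SpeciesTraits:
    """Growth and crown parameters of one species.

    Heights in m, diameters in cm, growth rates per year; crown
    semi-axes are fractions of total height; ``point_density`` is the
    expected laser-return density inside the crown (points per m^3).
    """

    code: str
    guild: str
    h1_mean: float
    h1_sd: float
    h_growth: float          # m / yr
    h_growth_sd: float
    d1_mean: float
    d1_sd: float
    d_growth: float          # cm / yr
    d_growth_sd: float
    crown_radius_frac: float  # horizontal semi-axis / height
    crown_base_frac: float    # crown base height / height
    point_density: float      # points per m^3 of crown


# Six species spanning the three growth guilds (two each): fast-growing
# pioneers (the second with historically poor monoculture survival),
# light-intermediate species and slow-growing shade-tolerant species.
# Magnitudes are plausible for a ~15-year-old tropical plantation.
DEFAULT_SPECIES: dict[str, SpeciesTraits] = {
    "LUSE": SpeciesTraits("LUSE", "pioneer", 11.0, 1.8, 0.80, 0.25, 14.0, 3.0, 1.00, 0.30, 0.14, 0.42, 40.0),
    "COAL": SpeciesTraits("COAL", "pioneer", 12.0, 2.0, 0.85, 0.25, 13.0, 3.0, 0.95, 0.30, 0.12, 0.48, 35.0),
    "ANEX": SpeciesTraits("ANEX", "intermediate", 9.0, 1.5, 0.60, 0.20, 12.0, 2.5, 0.85, 0.25, 0.16, 0.38, 45.0),
    "HUCR": SpeciesTraits("HUCR", "intermediate", 8.5, 1.5, 0.55, 0.20, 11.0, 2.5, 0.80, 0.25, 0.17, 0.36, 45.0),
    "CEOD": SpeciesTraits("CEOD", "shade_tolerant", 7.0, 1.2, 0.40, 0.15, 9.0, 2.0, 0.60, 0.20, 0.18, 0.32, 50.0),
    "TARO": SpeciesTraits("TARO", "shade_tolerant", 6.5, 1.2, 0.38, 0.15, 8.5, 2.0, 0.55, 0.20, 0.18, 0.30, 50.0),
}

HIGH_MORTALITY_SPECIES = "COAL"


@dataclass(frozen=True)
class PlotSpec:
    plot_id: str
    composition: tuple[str, ...]
    plot_type: str  # mono | mix3 | mix6


@dataclass(frozen=True)
class ExperimentDesign:
    plots: tuple[PlotSpec, ...]
    geometry: PlotGeometry = PlotGeometry()
    spacing: float = 3.0

    @property
    def n_plots(self) -> int:
        return len(self.plots)

    @property
    def n_subplots(self) -> int:
        return 4 * len(self.plots)


@dataclass(frozen=True)
class SimulationParams:
    """Ground-truth parameters of a simulation.

    ``beta0``..``beta3`` are the link-scale coefficients of the
    generative AWP model (intercept, CSFI effect, mixture main effect,
    CSFI x mixture interaction); ``sigma_plot`` the random-intercept
    SD; ``shape`` the gamma shape. ``mortality`` is the per-tree
    probability of dying between censuses; ``density_scale``
    multiplies every species' crown point density.
    """

    beta0: float = 12.0
    beta1: float = 3.0
    beta2: float = 0.0
    beta3: float = 0.0
    sigma_plot: float = 0.3
    shape: float = 5.0
    mode: str = "generative"  # generative | mechanistic
    mortality: float = 0.03
    density_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.shape <= 0:
            raise ValueError("gamma shape must be positive")
        if self.sigma_plot < 0:
            raise ValueError("sigma_plot must be non-negative")
        if not 0 <= self.mortality <= 1:
            raise ValueError("mortality must be a probability")
        if self.mode not in ("generative", "mechanistic"):
            raise ValueError("mode must be 'generative' or 'mechanistic'")


def make_design(
    n_mono_per_species: int = 2,
    n_mix3: int = 6,
    n_mix6: int = 6,
    exclude: Sequence[str] = (HIGH_MORTALITY_SPECIES,),
    seed: RNGLike = 0,
    species: Mapping[str, SpeciesTraits] = DEFAULT_SPECIES,
) -> ExperimentDesign:
    """Build the experimental design, then drop the monoculture plots
    of excluded species.

    Each three-species mixture draws exactly one species from each of
    the three guilds. Deterministic given the seed. The default call
    yields 22 plots (88 subplots).
    """
    rng = _rng(seed)
    by_guild: dict[str, list[str]] = {g: [] for g in GUILDS}
    for code in sorted(species):
        by_guild[species[code].guild].append(code)
    for g in GUILDS:
        if not by_guild[g]:
            raise ValueError(f"three-species mixtures need at least one species in guild {g!r}")

    plots: list[PlotSpec] = []
    i = 1
    for code in sorted(species):
        for _ in range(n_mono_per_species):
            plots.append(PlotSpec(f"P{i:02d}", (code,), "mono"))
            i += 1
    for _ in range(n_mix3):
        combo = tuple(sorted(str(rng.choice(by_guild[g])) for g in GUILDS))
        plots.append(PlotSpec(f"P{i:02d}", combo, "mix3"))
        i += 1
    all_species = tuple(sorted(species))
    for _ in range(n_mix6):
        plots.append(PlotSpec(f"P{i:02d}", all_species, "mix6"))
        i += 1

    excluded = set(exclude)
    kept = tuple(p for p in plots
                 if not (p.plot_type == "mono" and p.composition[0] in excluded))
    return ExperimentDesign(plots=kept)


def _subplot_label(x: float, y: float, geom: PlotGeometry) -> str:
    """Quadrant of the full plot footprint (half-open midlines)."""
    x0, y0 = geom.origin
    mx = x0 + geom.side_x / 2.0
    my = y0 + geom.side_y / 2.0
    ew = "E" if x >= mx else "W"
    ns = "N" if y >= my else "S"
    return ns + ew


def simulate_stand(
    design: ExperimentDesign,
    params: SimulationParams = SimulationParams(),
    seed: RNGLike = 0,
    species: Mapping[str, SpeciesTraits] = DEFAULT_SPECIES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant, grow, and (partially) kill trees on every plot.

    Returns ``(records, crowns)``:

    * ``records`` — the two-census inventory (one row per tree) in the
      format :func:`canopyfill.productivity.read_inventory` validates;
    * ``crowns`` — per *surviving* tree: position, the ellipsoid crown
      (centre height, vertical/horizontal semi-axes, all from the
      second-census height, when the stand is scanned) and the species'
      point density.

    Trees are planted on the 3 m grid (15 x 15 positions for a 45 m
    plot) with species assigned round-robin through the plot's
    composition; growth rates are drawn per tree from guild
    distributions and applied over the census interval.
    """
    rng = _rng(seed)
    geom = design.geometry
    coords = np.arange(design.spacing / 2.0, geom.side_x, design.spacing)
    interval = 5.0  # census interval, years
    rec_rows = []
    crown_rows = []
    for plot in design.plots:
        comp = tuple(sorted(plot.composition))
        k = 0
        for yi in coords:
            for xi in coords:
                tr = species[comp[k % len(comp)]]
                k += 1
                h1 = max(1.0, rng.normal(tr.h1_mean, tr.h1_sd))
                d1 = max(0.5, rng.normal(tr.d1_mean, tr.d1_sd))
                h2 = h1 + interval * max(0.0, rng.normal(tr.h_growth, tr.h_growth_sd))
                d2 = d1 + interval * max(0.0, rng.normal(tr.d_growth, tr.d_growth_sd))
                alive2 = bool(rng.random() >= params.mortality)
                tree_id = f"{plot.plot_id}-T{len(rec_rows):05d}"
                sub = _subplot_label(xi, yi, geom)
                rec_rows.append({
                    "tree_id": tree_id, "plot_id": plot.plot_id,
                    "subplot_id": sub, "species": tr.code,
                    "D1_cm": round(d1, 3), "H1_m": round(h1, 3), "alive_t1": True,
                    "D2_cm": round(d2, 3), "H2_m": round(h2, 3), "alive_t2": alive2,
                })
                if alive2:
                    base = tr.crown_base_frac * h2
                    crown_rows.append({
                        "tree_id": tree_id, "plot_id": plot.plot_id,
                        "subplot_id": sub, "species": tr.code,
                        "x": xi, "y": yi,
                        "z_centre": 0.5 * (base + h2),
                        "semi_v": 0.5 * (h2 - base),
                        "semi_h": tr.crown_radius_frac * h2,
                        "crown_base": base, "height": h2,
                        "density": tr.point_density,
                    })
    records = pd.DataFrame(rec_rows)
    crowns = pd.DataFrame(crown_rows)
    return records, crowns


def sample_point_cloud(
    crowns: pd.DataFrame,
    seed: RNGLike = 0,
    density_scale: float = 1.0,
    stem_points_per_m: float = 10.0,
    ground_density: float = 0.0,
    geometry: PlotGeometry = PlotGeometry(),
) -> dict[str, PointCloud]:
    """Sample one point cloud per plot from the crown ellipsoids.

    Crown point counts are Poisson with mean density x crown volume;
    points are uniform inside each ellipsoid. Optional vertical stem
    lines (``stem_points_per_m`` along the stem below the crown base)
    and uniform ground returns (``ground_density`` points per m^2 at
    z = 0) can be added.
    """
    rng = _rng(seed)
    out: dict[str, PointCloud] = {}
    for plot_id, grp in crowns.groupby("plot_id", sort=True):
        chunks = []
        for row in grp.itertuples(index=False):
            a, c = row.semi_h, row.semi_v
            vol = 4.0 / 3.0 * np.pi * a * a * c
            n = rng.poisson(row.density * density_scale * vol)
            if n > 0:
                u = rng.normal(size=(n, 3))
                u /= np.linalg.norm(u, axis=1, keepdims=True)
                r = rng.random(n) ** (1.0 / 3.0)
                pts = u * r[:, None] * np.array([a, a, c])
                pts += np.array([row.x, row.y, row.z_centre])
                chunks.append(pts)
            if stem_points_per_m > 0 and row.crown_base > 0:
                ns = max(1, int(round(stem_points_per_m * row.crown_base)))
                z = np.linspace(0.0, row.crown_base, ns, endpoint=False)
                stem = np.column_stack([np.full(ns, row.x), np.full(ns, row.y), z])
                chunks.append(stem)
        if ground_density > 0:
            area = geometry.side_x * geometry.side_y
            ng = rng.poisson(ground_density * area)
            gx = rng.random(ng) * geometry.side_x + geometry.origin[0]
            gy = rng.random(ng) * geometry.side_y + geometry.origin[1]
            chunks.append(np.column_stack([gx, gy, np.zeros(ng)]))
        xyz = np.vstack(chunks) if chunks else np.empty((0, 3))
        out[str(plot_id)] = PointCloud(xyz, source_id=str(plot_id))
    return out


def simulate_csfi_table(
    design: ExperimentDesign,
    seed: RNGLike = 0,
    mono_mean: float = 0.30,
    mono_sd: float = 0.07,
    mix_mean: float = 0.33,
    mix_sd: float = 0.07,
) -> pd.DataFrame:
    """Draw per-subplot CSFI values directly (no point clouds).

    CSFI is drawn from a truncated normal per mixture type, clipped to
    (0.01, 0.99). Used as the driver of the generative AWP model when
    the geometric pipeline is not under test; separate means/SDs let
    experiments give mixtures a wider CSFI signal.
    """
    rng = _rng(seed)
    rows = []
    for plot in design.plots:
        mixed = plot.plot_type != "mono"
        mean, sd = (mix_mean, mix_sd) if mixed else (mono_mean, mono_sd)
        for sub in ("SW", "SE", "NW", "NE"):
            val = float(np.clip(rng.normal(mean, sd), 0.01, 0.99))
            rows.append({
                "plot_id": plot.plot_id, "subplot_id": sub,
                "mixture_type": "mixture" if mixed else "monoculture",
                "richness": len(plot.composition),
                "csfi": val,
            })
    return pd.DataFrame(rows)


def generate_awp(
    csfi_table: pd.DataFrame,
    params: SimulationParams = SimulationParams(),
    seed: RNGLike = 0,
) -> tuple[pd.DataFrame, dict]:
    """Draw subplot AWP from the gamma log-link mixed model.

    ``csfi_table`` needs columns plot_id, subplot_id, mixture_type and
    csfi (one row per subplot, any single canopy definition as driver).
    Returns the table with an ``awp_cm3_yr`` column appended and a
    ground-truth dict (all coefficients plus the realised per-plot
    random intercepts) for recovery tests.
    """
    rng = _rng(seed)
    tab = csfi_table.copy()
    plots = np.unique(tab["plot_id"].to_numpy())
    b = rng.normal(0.0, params.sigma_plot, size=plots.size)
    b_map = dict(zip(plots.tolist(), b.tolist()))
    mix = (tab["mixture_type"].astype(str) == "mixture").to_numpy(dtype=float)
    csfi = tab["csfi"].to_numpy(dtype=float)
    eta = (params.beta0 + params.beta1 * csfi + params.beta2 * mix
           + params.beta3 * csfi * mix
           + np.array([b_map[p] for p in tab["plot_id"]]))
    mu = np.exp(eta)
    tab["awp_cm3_yr"] = rng.gamma(shape=params.shape, scale=mu / params.shape)
    truth = {
        "beta0": params.beta0, "beta1": params.beta1,
        "beta2": params.beta2, "beta3": params.beta3,
        "sigma_plot": params.sigma_plot, "shape": params.shape,
        "plot_intercepts": b_map,
    }
    return tab, truth
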