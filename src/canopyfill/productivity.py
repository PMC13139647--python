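"""Tree wood volumes and subplot annual wood productivity (AWP).

Stem volume treats the stem as a cylinder from diameter at breast
height and total height, scaled by a dimensionless form factor
(default 0.4):

    V = pi * (D/100)^2 / 4 * H * f      [D in cm, H in m, V in m^3]

Subplot AWP is the sum over trees alive at both censuses of the
annualised volume increment, reported in cm^3 per year:

    AWP_j = sum_i (V_i2 - V_i1) / (t2 - t1) * 1e6

Trees that died between censuses contribute nothing (their terminal
volume is unobserved). Negative increments from measurement noise are
kept at the tree level; subplots whose summed AWP is non-positive are
flagged so the gamma-model stage can exclude them (gamma support is
strictly positive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "VolumeParams",
    "wood_volume",
    "subplot_awp",
    "awp_table",
    "read_inventory",
    "INVENTORY_COLUMNS",
]

logger = logging.getLogger(__name__)

INVENTORY_COLUMNS = [
    "tree_id", "plot_id", "subplot_id", "species",
    "D1_cm", "H1_m", "alive_t1", "D2_cm", "H2_m", "alive_t2",
]

M3_TO_CM3 = 1e6


@dataclass(frozen=True)
class VolumeParams:
    """Form factor and census years for volume/AWP computation."""

    form_factor: float = 0.4
    t1: int = 2012
    t2: int = 2017

    def __post_init__(self) -> None:
        if not 0 < self.form_factor <= 1:
            raise ValueError("form factor must be in (0, 1]")
        if self.t2 <= self.t1:
            raise ValueError("t2 must be after t1")

    @property
    def interval_years(self) -> int:
        return self.t2 - self.t1


def wood_volume(d_cm: float, h_m: float, form_factor: float = 0.4):
    """Stem volume in m^3 from DBH (cm) and height (m).

    Accepts scalars or arrays; every D and H must be positive.
    """
    d = np.asarray(d_cm, dtype=float)
    h = np.asarray(h_m, dtype=float)
    if np.any(d <= 0) or np.any(h <= 0):
        raise ValueError("diameter and height must be positive")
    v = np.pi * (d / 100.0) ** 2 / 4.0 * h * form_factor
    return float(v) if v.ndim == 0 else v


def subplot_awp(records: pd.DataFrame, params: VolumeParams = VolumeParams()) -> tuple[float, int]:
    """AWP (cm^3 yr^-1) and contributing tree count for one subplot.

    ``records`` must hold the inventory columns for a single subplot;
    only trees alive at both censuses contribute. Returns (0.0, 0) when
    no tree survives. Raises on duplicated tree ids or mixed subplots.
    """
    if records["subplot_id"].nunique() > 1:
        raise ValueError("records span more than one subplot")
    if records["tree_id"].duplicated().any():
        dupes = records.loc[records["tree_id"].duplicated(), "tree_id"].tolist()
        raise ValueError(f"duplicated tree_id(s): {dupes}")
    alive = records[records["alive_t1"].astype(bool) & records["alive_t2"].astype(bool)]
    if alive.empty:
        return 0.0, 0
    v1 = wood_volume(alive["D1_cm"].to_numpy(), alive["H1_m"].to_numpy(), params.form_factor)
    v2 = wood_volume(alive["D2_cm"].to_numpy(), alive["H2_m"].to_numpy(), params.form_factor)
    awp = float(np.sum(v2 - v1) / params.interval_years * M3_TO_CM3)
    return awp, int(len(alive))


def awp_table(records: pd.DataFrame, params: VolumeParams = VolumeParams()) -> pd.DataFrame:
    """Subplot-level AWP table from a validated inventory.

    Columns: plot_id, subplot_id, mixture_type, richness, n_trees,
    awp_cm3_yr, positive. Mixture type and richness derive from the
    number of distinct species planted in the subplot's *plot*
    (1 -> monoculture, else mixture).
    """
    richness = records.groupby("plot_id")["species"].nunique()
    rows = []
    for (plot, subplot), grp in records.groupby(["plot_id", "subplot_id"], sort=True):
        awp, n = subplot_awp(grp, params)
        r = int(richness[plot])
        rows.append({
            "plot_id": plot,
            "subplot_id": subplot,
            "mixture_type": "monoculture" if r == 1 else "mixture",
            "richness": r,
            "n_trees": n,
            "awp_cm3_yr": awp,
            "positive": awp > 0,
        })
    out = pd.DataFrame(rows)
    n_nonpos = int((~out["positive"]).sum())
    if n_nonpos:
        logger.warning("%d subplot(s) with non-positive AWP (excluded from gamma fits)", n_nonpos)
    return out


def read_inventory(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a two-census tree inventory CSV.

    Expected columns: tree_id, plot_id, subplot_id, species, D1_cm,
    H1_m, alive_t1, D2_cm, H2_m, alive_t2. Diameters (cm) and heights
    (m) must be present and positive for every census at which the tree
    is alive. Raises ``ValueError`` listing every offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in INVENTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"inventory is missing column(s): {missing}")
    problems = []
    for census in ("1", "2"):
        alive = df[f"alive_t{census}"].astype(bool)
        for col in (f"D{census}_cm", f"H{census}_m"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = alive & (vals.isna() | (vals <= 0))
            for idx in df.index[bad]:
                problems.append(
                    f"row {idx}: tree {df.at[idx, 'tree_id']} alive at t{census} "
                    f"but {col} = {df.at[idx, col]!r}"
                )
    if problems:
        raise ValueError("invalid inventory rows:\n" + "\n".join(problems))
    dup = df.duplicated(subset=["tree_id"], keep=False)
    if dup.any():
        raise ValueError(f"duplicated tree_id(s): {sorted(df.loc[dup, 'tree_id'].unique().tolist())}")
    return df
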