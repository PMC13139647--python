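"""Canopy boundary heights, canopy-space definitions, and the CSFI.

The canopy space filling index (CSFI) of a subplot is the fraction of
occupied voxels within a vertical slab of its voxelised canopy space.
Four slab definitions are supported, built from three boundary heights:

* ``H_max`` — top face of the highest occupied voxel layer (highest
  tree top);
* ``LGB``  — height of the lowest green branch: either supplied from
  field data, or derived from the grid as the bottom face of the lowest
  occupied layer whose bottom face clears a ground-exclusion height
  (default 0.3 m, to keep ground returns and herb-layer hits out of
  the canopy), else 0;
* ``h10``  — scanning from the top layer downward, the top face of the
  first layer whose occupancy fraction reaches the threshold tau
  (default 10%). Undefined when no layer reaches tau.

Definitions (slabs are ``[z_lo, z_hi]``):

=======  ==========================  =============================
name     lower bound                 upper bound
=======  ==========================  =============================
total    LGB                         H_max
top      (2/3) * H_max               H_max
mid      (1/3) * H_max               h10
main     LGB                         h10
=======  ==========================  =============================

A grid layer contributes to a slab when its centre height lies in the
closed slab interval; fractional boundaries thus snap deterministically
to the voxel lattice. Degenerate subplots (no layer reaches tau, or an
inverted slab) yield flagged invalid results instead of exceptions so
batch runs always complete.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .voxel import LayerProfile, VoxelGrid, layer_profile, occupied_in_slab

__all__ = [
    "DEFINITIONS",
    "CanopyBounds",
    "CSFIResult",
    "detect_bounds",
    "slab_for_definition",
    "csfi",
    "csfi_all_definitions",
    "csfi_table",
    "definition_correlations",
]

DEFINITIONS = ("total", "top", "mid", "main")
DEFAULT_TAU = 0.10
DEFAULT_GROUND_EXCLUSION = 0.3


@dataclass(frozen=True)
class CanopyBounds:
    """The three per-subplot boundary heights (m). ``h10`` is None when
    no layer reaches the occupancy threshold."""

    h_max: float
    lgb: float
    h10: Optional[float]

    def __post_init__(self) -> None:
        if not (0 <= self.lgb <= self.h_max):
            raise ValueError(f"require 0 <= LGB <= H_max, got LGB={self.lgb}, H_max={self.h_max}")
        if self.h10 is not None and not (0 < self.h10 <= self.h_max):
            raise ValueError(f"require 0 < h10 <= H_max, got h10={self.h10}, H_max={self.h_max}")


@dataclass(frozen=True)
class CSFIResult:
    """CSFI of one subplot under one canopy-space definition."""

    subplot_id: str
    definition: str
    z_lo: float
    z_hi: float
    layer_lo: int  # inclusive
    layer_hi: int  # inclusive
    occupied: int
    total: int
    csfi: float
    valid: bool
    reason: str = ""

    @classmethod
    def invalid(cls, subplot_id: str, definition: str, reason: str,
                z_lo: float = float("nan"), z_hi: float = float("nan")) -> "CSFIResult":
        return cls(subplot_id, definition, z_lo, z_hi, -1, -1, 0, 0, float("nan"), False, reason)


def detect_bounds(
    grid: VoxelGrid,
    profile: Optional[LayerProfile] = None,
    tau: float = DEFAULT_TAU,
    lgb_override: Optional[float] = None,
    ground_exclusion: float = DEFAULT_GROUND_EXCLUSION,
) -> CanopyBounds:
    """Derive the canopy boundary heights from a voxel grid.

    Raises ``ValueError("empty canopy")`` when no voxel is occupied.
    ``h10`` is returned as None (not an error) when no layer reaches
    ``tau``; the mid/main definitions then come out flagged invalid.
    """
    if not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")
    if profile is None:
        profile = layer_profile(grid)
    occ_layers = np.flatnonzero(profile.occupancy > 0)
    if occ_layers.size == 0:
        raise ValueError("empty canopy: grid has no occupied voxel")
    spec = grid.spec
    h_max = spec.layer_z(int(occ_layers[-1]))[1]

    # top-down scan for the 10%-occupancy boundary
    h10: Optional[float] = None
    reach = np.flatnonzero(profile.occupancy >= tau)
    if reach.size:
        h10 = spec.layer_z(int(reach[-1]))[1]

    if lgb_override is not None:
        lgb = float(lgb_override)
    else:
        lgb = 0.0
        for k in occ_layers:
            bottom = spec.layer_z(int(k))[0]
            if bottom >= ground_exclusion:
                lgb = bottom
                break
    lgb = min(lgb, h_max)
    return CanopyBounds(h_max=h_max, lgb=lgb, h10=h10)


def slab_for_definition(bounds: CanopyBounds, definition: str) -> tuple[float, float]:
    """The [z_lo, z_hi] slab of one definition.

    Raises ``ValueError`` for an unknown definition, an undefined h10
    (mid/main), or an inverted/empty slab; batch entry points catch
    these and emit flagged records instead.
    """
    if definition not in DEFINITIONS:
        raise ValueError(f"unknown definition {definition!r}; expected one of {DEFINITIONS}")
    if definition == "total":
        z_lo, z_hi = bounds.lgb, bounds.h_max
    elif definition == "top":
        z_lo, z_hi = 2.0 / 3.0 * bounds.h_max, bounds.h_max
    else:
        if bounds.h10 is None:
            raise ValueError("h10 undefined: no layer reaches the occupancy threshold")
        if definition == "mid":
            z_lo, z_hi = 1.0 / 3.0 * bounds.h_max, bounds.h10
        else:  # main
            z_lo, z_hi = bounds.lgb, bounds.h10
    if z_lo >= z_hi:
        raise ValueError(f"empty slab: z_lo={z_lo:.4g} >= z_hi={z_hi:.4g}")
    return z_lo, z_hi


def _layers_in_slab(grid: VoxelGrid, z_lo: float, z_hi: float) -> Optional[range]:
    """Layers whose centre falls in the closed slab, or None if none do."""
    spec = grid.spec
    centres = spec.origin[2] + (np.arange(spec.nz) + 0.5) * spec.edge
    inside = np.flatnonzero((centres >= z_lo) & (centres <= z_hi))
    if inside.size == 0:
        return None
    return range(int(inside[0]), int(inside[-1]) + 1)


def csfi(grid: VoxelGrid, slab: tuple[float, float], subplot_id: str = "",
         definition: str = "") -> CSFIResult:
    """CSFI over a vertical slab: occupied / total voxels of the layers
    whose centre lies in the closed slab interval."""
    z_lo, z_hi = slab
    if z_lo >= z_hi:
        return CSFIResult.invalid(subplot_id, definition, "empty slab", z_lo, z_hi)
    layers = _layers_in_slab(grid, z_lo, z_hi)
    if layers is None:
        return CSFIResult.invalid(subplot_id, definition, "no layer centre in slab", z_lo, z_hi)
    occ, total = occupied_in_slab(grid, layers)
    return CSFIResult(
        subplot_id=subplot_id,
        definition=definition,
        z_lo=z_lo,
        z_hi=z_hi,
        layer_lo=layers.start,
        layer_hi=layers.stop - 1,
        occupied=occ,
        total=total,
        csfi=occ / total,
        valid=True,
    )


def csfi_all_definitions(
    grid: VoxelGrid,
    subplot_id: str = "",
    tau: float = DEFAULT_TAU,
    lgb_override: Optional[float] = None,
    ground_exclusion: float = DEFAULT_GROUND_EXCLUSION,
    definitions: Sequence[str] = DEFINITIONS,
) -> list[CSFIResult]:
    """CSFI of one subplot under each requested definition.

    Degenerate definitions yield flagged invalid records; an entirely
    empty canopy flags all requested definitions.
    """
    for d in definitions:
        if d not in DEFINITIONS:
            raise ValueError(f"unknown definition {d!r}; expected one of {DEFINITIONS}")
    try:
        bounds = detect_bounds(grid, tau=tau, lgb_override=lgb_override,
                               ground_exclusion=ground_exclusion)
    except ValueError as exc:
        return [CSFIResult.invalid(subplot_id, d, str(exc)) for d in definitions]
    out = []
    for d in definitions:
        try:
            slab = slab_for_definition(bounds, d)
        except ValueError as exc:
            out.append(CSFIResult.invalid(subplot_id, d, str(exc)))
            continue
        out.append(csfi(grid, slab, subplot_id=subplot_id, definition=d))
    return out


def csfi_table(
    grids: Mapping[str, VoxelGrid],
    tau: float = DEFAULT_TAU,
    lgb_overrides: Optional[Mapping[str, float]] = None,
    ground_exclusion: float = DEFAULT_GROUND_EXCLUSION,
    definitions: Sequence[str] = DEFINITIONS,
) -> pd.DataFrame:
    """Long-format CSFI table over a batch of subplot grids.

    Columns: subplot_id, definition, z_lo, z_hi, occupied, total, csfi,
    valid, reason.
    """
    rows = []
    for sid, grid in grids.items():
        override = None if lgb_overrides is None else lgb_overrides.get(sid)
        for res in csfi_all_definitions(grid, subplot_id=sid, tau=tau,
                                        lgb_override=override,
                                        ground_exclusion=ground_exclusion,
                                        definitions=definitions):
            rows.append({
                "subplot_id": res.subplot_id,
                "definition": res.definition,
                "z_lo": res.z_lo,
                "z_hi": res.z_hi,
                "occupied": res.occupied,
                "total": res.total,
                "csfi": res.csfi,
                "valid": res.valid,
                "reason": res.reason,
            })
    return pd.DataFrame(rows)


def definition_correlations(table: pd.DataFrame,
                            definitions: Sequence[str] = DEFINITIONS) -> Optional[pd.DataFrame]:
    """Pairwise Pearson correlations of CSFI across definitions.

    Uses subplots where every requested definition is valid. Returns a
    symmetric matrix with unit diagonal, or None (with a warning) when
    fewer than two such subplots exist.
    """
    valid = table[table["valid"]]
    wide = valid.pivot(index="subplot_id", columns="definition", values="csfi")
    missing = [d for d in definitions if d not in wide.columns]
    if missing:
        wide = wide.reindex(columns=list(definitions))
    wide = wide[list(definitions)].dropna()
    if len(wide) < 2:
        warnings.warn("fewer than 2 fully valid subplots; correlations omitted")
        return None
    corr = wide.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr
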