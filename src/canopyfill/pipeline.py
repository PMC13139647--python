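"""End-to-end orchestration: clouds + inventory -> CSFI -> AWP -> models.

The pipeline stages are: read plot clouds, strip the edge buffer,
split into quadrant subplots, voxelise each subplot, detect canopy
bounds, compute CSFI under the four canopy-space definitions, compute
subplot AWP from the two-census inventory, join, and fit the gamma
mixed models per definition and stratum. Every stage writes its table
to the output directory and a manifest records configuration, row
counts and dropped-record tallies, so a rerun with the same config and
seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import canopy, glmm, productivity, voxel
from .pointcloud import PlotGeometry, clip_buffer, read_cloud, split_subplots

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "compute_csfi_tables", "load_config"]

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


@dataclass
class RunConfig:
    """Configuration of a pipeline run.

    Defaults follow the study protocol: 45 x 45 m plots with a 2 m
    buffer, 0.40 m voxels, 10% occupancy threshold, form factor 0.4,
    censuses 2012 and 2017.
    """

    clouds_dir: str = "clouds"
    inventory: str = "inventory.csv"
    out_dir: str = "out"
    side: float = 45.0
    buffer: float = 2.0
    edge: float = 0.40
    tau: float = 0.10
    min_points: int = 1
    ground_exclusion: float = 0.3
    lgb_overrides: Optional[str] = None   # CSV: plot_id, subplot_id, lgb_m
    form_factor: float = 0.4
    t1: int = 2012
    t2: int = 2017
    definitions: tuple[str, ...] = canopy.DEFINITIONS
    include_interaction: bool = True
    resid_variance: str = "trigamma"
    seed: int = 0

    def validate(self) -> None:
        if self.edge <= 0:
            raise ValueError("voxel edge must be positive")
        if not 0 < self.tau < 1:
            raise ValueError("tau must be in (0, 1)")
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")
        if not 0 < self.form_factor <= 1:
            raise ValueError("form factor must be in (0, 1]")
        if self.t2 <= self.t1:
            raise ValueError("census years must satisfy t2 > t1")
        for d in self.definitions:
            if d not in canopy.DEFINITIONS:
                raise ValueError(
                    f"unknown definition {d!r}; expected one of {canopy.DEFINITIONS}")
        PlotGeometry(side_x=self.side, side_y=self.side, buffer=self.buffer)

    @property
    def geometry(self) -> PlotGeometry:
        return PlotGeometry(side_x=self.side, side_y=self.side, buffer=self.buffer)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: Union[str, Path]) -> RunConfig:
    """Read a YAML config file; unknown keys raise."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "definitions" in data:
        data["definitions"] = tuple(data["definitions"])
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


@dataclass
class PipelineResult:
    csfi: pd.DataFrame
    correlations: Optional[pd.DataFrame]
    awp: pd.DataFrame
    report: Optional[glmm.ComparisonReport]
    manifest: dict


def _load_lgb_overrides(path: Optional[str]) -> dict[tuple[str, str], float]:
    if path is None:
        return {}
    df = pd.read_csv(path)
    need = {"plot_id", "subplot_id", "lgb_m"}
    if not need <= set(df.columns):
        raise ValueError(f"LGB override table must have columns {sorted(need)}")
    return {(str(r.plot_id), str(r.subplot_id)): float(r.lgb_m)
            for r in df.itertuples(index=False)}


def compute_csfi_tables(
    config: RunConfig,
    cloud_paths: Optional[Sequence[Path]] = None,
) -> tuple[pd.DataFrame, dict]:
    """Clouds -> per-subplot CSFI table (long format, all definitions).

    Returns the table (with separate plot_id / subplot_id columns) and
    a stage-stats dict (point and out-of-bounds tallies per plot).
    """
    geom = config.geometry
    if cloud_paths is None:
        cloud_paths = sorted(Path(config.clouds_dir).glob("*.xyz"))
    if not cloud_paths:
        raise FileNotFoundError(f"no .xyz clouds found under {config.clouds_dir!r}")
    overrides = _load_lgb_overrides(config.lgb_overrides)
    x_lo, y_lo, x_hi, y_hi = geom.inner_bounds
    stats: dict = {"plots": {}, "n_out_of_bounds": 0}
    rows = []
    for path in cloud_paths:
        plot_id = path.stem
        cloud = read_cloud(path)
        clipped = clip_buffer(cloud, geom)
        subclouds = split_subplots(clipped, geom)
        stats["plots"][plot_id] = {"n_points": len(cloud), "n_clipped": len(clipped)}
        for label, sub in subclouds.items():
            sx_lo, sy_lo, sx_hi, sy_hi = geom.subplot_bounds(label)
            max_z = float(sub.xyz[:, 2].max()) if len(sub) else 0.0
            spec = voxel.spec_for_footprint(
                sx_hi - sx_lo, sy_hi - sy_lo, max_z, edge=config.edge,
                origin=(sx_lo, sy_lo, 0.0), min_points=config.min_points)
            grid = voxel.voxelize(sub, spec)
            stats["n_out_of_bounds"] += grid.n_out_of_bounds
            results = canopy.csfi_all_definitions(
                grid, subplot_id=f"{plot_id}:{label}", tau=config.tau,
                lgb_override=overrides.get((plot_id, label)),
                ground_exclusion=config.ground_exclusion,
                definitions=config.definitions)
            for res in results:
                rows.append({
                    "plot_id": plot_id, "subplot_id": label,
                    "definition": res.definition,
                    "z_lo": res.z_lo, "z_hi": res.z_hi,
                    "occupied": res.occupied, "total": res.total,
                    "csfi": res.csfi, "valid": res.valid, "reason": res.reason,
                })
    return pd.DataFrame(rows), stats


def join_for_models(csfi_df: pd.DataFrame, awp_df: pd.DataFrame,
                    definitions: Sequence[str]) -> dict[str, pd.DataFrame]:
    """Per-definition joined tables of valid CSFI and positive AWP."""
    usable_awp = awp_df[awp_df["positive"]]
    tables = {}
    for d in definitions:
        sub = csfi_df[(csfi_df["definition"] == d) & csfi_df["valid"]]
        joined = sub.merge(usable_awp, on=["plot_id", "subplot_id"], how="inner")
        tables[d] = joined[["plot_id", "subplot_id", "csfi", "awp_cm3_yr",
                            "mixture_type", "richness"]]
    return tables


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage and write all outputs to ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
        "warnings": [],
    }

    csfi_df, cloud_stats = compute_csfi_tables(config)
    n_invalid = int((~csfi_df["valid"]).sum())
    manifest["stages"]["csfi"] = {
        "rows": len(csfi_df), "invalid": n_invalid, **cloud_stats}
    if n_invalid:
        manifest["warnings"].append(f"{n_invalid} invalid CSFI record(s)")
    csfi_df.to_csv(out / "csfi.csv", index=False, float_format=FLOAT_FORMAT)

    combined = csfi_df.assign(
        subplot_id=csfi_df["plot_id"] + ":" + csfi_df["subplot_id"])
    corr = canopy.definition_correlations(combined, definitions=config.definitions)
    if corr is not None:
        corr.to_csv(out / "csfi_correlations.csv", float_format=FLOAT_FORMAT)

    params = productivity.VolumeParams(config.form_factor, config.t1, config.t2)
    records = productivity.read_inventory(config.inventory)
    awp_df = productivity.awp_table(records, params)
    n_nonpos = int((~awp_df["positive"]).sum())
    manifest["stages"]["awp"] = {"rows": len(awp_df), "non_positive": n_nonpos}
    if n_nonpos:
        manifest["warnings"].append(f"{n_nonpos} non-positive AWP subplot(s) excluded from fits")
    awp_df.to_csv(out / "awp.csv", index=False, float_format=FLOAT_FORMAT)

    tables = join_for_models(csfi_df, awp_df, config.definitions)
    manifest["stages"]["join"] = {d: len(t) for d, t in tables.items()}
    report: Optional[glmm.ComparisonReport] = None
    if all(len(t) >= 8 for t in tables.values()):
        report = glmm.definition_comparison(tables, resid_variance=config.resid_variance)
        report.coefficients.to_csv(out / "model_coefficients.csv", index=False,
                                   float_format=FLOAT_FORMAT)
        report.interactions.to_csv(out / "model_interactions.csv", index=False,
                                   float_format=FLOAT_FORMAT)
    else:
        manifest["warnings"].append("too few joined rows; model stage skipped")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(csfi_df, corr, awp_df, report, manifest)
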