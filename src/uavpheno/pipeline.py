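"""End-to-end orchestration: simulate -> segment -> indices -> aggregate
-> ethanol -> associate -> rank.

A :class:`RunConfig` fully determines a run; rerunning with an identical
config (and ``run_name``) reproduces byte-identical CSV outputs.  The
plot-level CSV tables written between stages are the inter-stage
contract — any stage can be re-run standalone on externally produced
tables, so real UAV exports can replace the simulation at the
plot-table boundary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import rank_accessions, scan_models
from .design import GeometryParams, generate_trial_design
from .indices import VI_NAMES, add_vi_columns
from .rasters import write_plots, write_raster, write_table
from .scenarios import ts1, ts2, ts3
from .segmentation import EmptyPlotError, classify_plot_vegetation, extract_plot_spectra
from .synthetic import (
    FLIGHT_DATES,
    ReflectanceModel,
    generate_phenology,
    generate_phenotypes,
    render_orthomosaic,
)

__all__ = ["RunConfig", "run_pipeline", "segment_raster", "PipelineError"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; message names the stage and offending plot/date."""


@dataclass
class RunConfig:
    """Configuration of a full simulated run.

    ``seed`` drives every random stage; ``dates`` must be strictly
    increasing DAS values.  Reflectance-model and geometry parameters
    accept keyword overrides of the package defaults.
    """

    seed: int
    outdir: str = "runs"
    run_name: str | None = None
    dates: tuple[int, ...] = FLIGHT_DATES
    n_accessions: int = 66
    n_blocks: int = 3
    plots_per_block: int = 78
    gsd: float = 0.01
    feature: str = "exg"
    n_bins: int = 256
    min_object_size: int = 4
    min_fraction: float = 0.005
    ts1_dates: tuple[int, ...] | None = None  # None = all flight dates
    write_rasters: bool = False
    reflectance: dict = field(default_factory=dict)
    geometry: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for simulate runs")
        dates = tuple(int(d) for d in self.dates)
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError(f"dates must be strictly increasing, got {dates}")
        self.dates = dates
        if self.feature.lower() not in ("exg", "ndvi"):
            raise ValueError(f"unknown segmentation feature {self.feature!r}")
        bad = set(self.reflectance) - {f.name for f in dataclasses.fields(ReflectanceModel)}
        if bad:
            raise ValueError(f"unknown reflectance-model parameters: {sorted(bad)}")
        bad = set(self.geometry) - {f.name for f in dataclasses.fields(GeometryParams)}
        if bad:
            raise ValueError(f"unknown geometry parameters: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dates"] = list(self.dates)
        if self.ts1_dates is not None:
            d["ts1_dates"] = list(self.ts1_dates)
        return d

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    def reflectance_model(self) -> ReflectanceModel:
        return ReflectanceModel(**self.reflectance)

    def geometry_params(self) -> GeometryParams:
        return GeometryParams(**self.geometry)


def segment_raster(raster, design, feature="exg", n_bins=256, min_object_size=4,
                   min_fraction=0.005, include_empty=True) -> pd.DataFrame:
    """Segment every plot of one raster and extract vegetation spectra.

    By default all plot positions are exported (the full trial table,
    one row per plot and date); empty positions and plots whose polygon
    misses the raster get rows with missing band means rather than being
    dropped — bare plots flag themselves low-cover through the class
    separation floor.
    """
    rows = []
    for plot in design.plots if include_empty else design.occupied:
        c = plot.polygon.centroid
        base = {
            "plot_id": plot.plot_id,
            "accession_id": plot.accession_id,
            "species": plot.species,
            "block": plot.block,
            "row": plot.row,
            "order_in_row": plot.order_in_row,
            "center_x": c.x,
            "center_y": c.y,
            "date_das": raster.date_das,
        }
        try:
            mask = classify_plot_vegetation(
                raster, plot.polygon, plot_id=plot.plot_id, feature=feature,
                n_bins=n_bins, min_object_size=min_object_size, min_fraction=min_fraction,
            )
        except EmptyPlotError:
            base.update({"vegetation_fraction": np.nan, "low_cover": True})
            rows.append(base)
            continue
        rec = extract_plot_spectra(raster, mask)
        base.update(rec.drop("plot_id").to_dict())
        rows.append(base)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline; returns the manifest (also written to disk)."""
    name = config.run_name or datetime.now(timezone.utc).strftime("run-%Y%m%dT%H%M%S")
    rundir = Path(config.outdir) / name
    rundir.mkdir(parents=True, exist_ok=True)
    log.info("pipeline run %s -> %s (config %s)", name, rundir, config.digest())

    manifest: dict = {
        "run_name": name,
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "package_version": __version__,
        "stages": {},
    }

    # -- simulate -----------------------------------------------------------
    try:
        design = generate_trial_design(
            config.n_accessions, config.n_blocks, config.plots_per_block,
            geometry=config.geometry_params(), seed=config.seed,
        )
        phenotypes = generate_phenotypes(design, seed=config.seed)
        phenology = generate_phenology(design, seed=config.seed)
    except Exception as err:
        raise PipelineError(f"stage simulate: {err}") from err
    write_plots(design, rundir / "plots.geojson")
    write_table(design.to_frame(), rundir / "design.csv")
    write_table(phenotypes, rundir / "phenotypes.csv")
    write_table(phenology, rundir / "phenology.csv")
    manifest["stages"]["simulate"] = {
        "n_plots": len(design),
        "n_occupied": len(design.occupied),
        "n_accessions": len(design.accessions),
    }

    # -- render + segment + indices -----------------------------------------
    model = config.reflectance_model()
    tables = []
    n_rasters = 0
    for date in config.dates:
        try:
            raster = render_orthomosaic(
                design, phenotypes, phenology, date, model=model,
                gsd=config.gsd, seed=config.seed,
            )
        except Exception as err:
            raise PipelineError(f"stage render, date {date} DAS: {err}") from err
        n_rasters += 1
        if config.write_rasters:
            write_raster(raster, rundir / f"ortho_{date:03d}das.tif")
        try:
            tab = segment_raster(
                raster, design, feature=config.feature, n_bins=config.n_bins,
                min_object_size=config.min_object_size, min_fraction=config.min_fraction,
            )
        except Exception as err:
            raise PipelineError(f"stage segment, date {date} DAS: {err}") from err
        tables.append(tab)
    plot_table = add_vi_columns(pd.concat(tables, ignore_index=True))
    write_table(plot_table, rundir / "plot_table.csv")
    manifest["stages"]["imagery"] = {"n_rasters": n_rasters, "plot_table_rows": len(plot_table)}

    # -- temporal scenarios --------------------------------------------------
    scenario_tables: dict[str, pd.DataFrame] = {}
    for d in config.ts1_dates or config.dates:
        scenario_tables[f"TS1@{d}"] = ts1(plot_table, d)
    scenario_tables["TS2"] = ts2(plot_table, phenology)
    scenario_tables["TS3"] = ts3(plot_table)
    for label, tab in scenario_tables.items():
        write_table(tab, rundir / f"scenario_{label.replace('@', '_').lower()}.csv")
    manifest["stages"]["scenarios"] = {k: len(v) for k, v in scenario_tables.items()}

    # -- associate + rank ----------------------------------------------------
    models = scan_models(scenario_tables, phenotypes)
    write_table(models, rundir / "models.csv")
    pivot = models.pivot_table(index=["phenotype", "vi"], columns="scenario", values="r2")
    pivot.to_csv(rundir / "models_r2_pivot.csv")

    rankings = {}
    for ph in ("biomass", "sugar", "ethanol"):
        sub = models[models["phenotype"] == ph]
        if sub.empty:
            continue
        best = sub.iloc[0]
        from .association import VIPhenotypeModel

        res = VIPhenotypeModel.from_tables(
            scenario_tables[best["scenario"]], phenotypes, best["vi"], ph,
            scenario=best["scenario"],
        ).fit()
        ranking = rank_accessions(res, scenario_tables[best["scenario"]], phenotypes)
        write_table(ranking.table, rundir / f"ranking_{ph}.csv")
        rankings[ph] = {
            "vi": best["vi"],
            "scenario": best["scenario"],
            "r2": float(best["r2"]),
            "rmse": ranking.rmse,
            "n_accessions": len(ranking.table),
        }
    manifest["stages"]["association"] = {"n_models": len(models), "best": rankings}

    (rundir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
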