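"""Replicated field-trial layouts (randomized complete block designs).

A trial is a grid of small rectangular plots grouped into replicate
blocks.  Within each block every accession occupies exactly one plot;
plot positions are assigned by a seeded random permutation, and any
surplus positions are kept as *empty* plots that downstream analysis
ignores.  All geometry is planar, in meters, with the origin at the
top-left of the (future) raster and y increasing downward.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

__all__ = [
    "GeometryParams",
    "Plot",
    "TrialDesign",
    "generate_trial_design",
    "load_reference_accessions",
]

#: Species names used throughout the package.
SPECIES = ("T. aestivum", "T. durum", "H. vulgare", "x Triticosecale")


def load_reference_accessions() -> pd.DataFrame:
    """Return the bundled cereal accession panel (species, id, name, number).

    The panel covers four species — bread wheat, durum wheat, barley and
    triticale — with two accessions (Cayuga, Caledonia) present twice
    under distinct plot IDs, as they were planted in duplicate.
    """
    ref = importlib.resources.files("uavpheno.data") / "reference_accessions.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


@dataclass(frozen=True)
class GeometryParams:
    """Plot and layout geometry in meters.

    Defaults give a desk-scale trial: 0.6 m x 0.45 m plots separated by
    0.30 m within a row and 0.50 m between rows, blocks stacked
    vertically with a 1 m gap, and a 1 m soil margin around everything.
    """

    plot_width: float = 0.60
    plot_height: float = 0.45
    inter_plot: float = 0.30
    inter_row: float = 0.50
    rows_per_block: int = 10
    block_gap: float = 1.0
    margin: float = 1.0

    def __post_init__(self) -> None:
        for name in ("plot_width", "plot_height", "margin"):
            if getattr(self, name) <= 0 and name != "margin":
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.rows_per_block < 1:
            raise ValueError("rows_per_block must be >= 1")


@dataclass(frozen=True)
class Plot:
    """One plot position in the trial.

    ``accession_id``/``species`` are ``None`` for empty positions.
    """

    plot_id: str
    accession_id: str | None
    species: str | None
    block: int
    row: int
    order_in_row: int
    polygon: BaseGeometry

    @property
    def is_empty(self) -> bool:
        return self.accession_id is None


@dataclass
class TrialDesign:
    """A replicated block layout of rectangular plots.

    Attributes
    ----------
    plots
        All plot positions, including empty ones.
    extent
        ``(width, height)`` of the surrounding soil rectangle in meters,
        margin included; rasters rendered from this design cover exactly
        this extent with the origin at (0, 0).
    """

    plots: list[Plot]
    extent: tuple[float, float]
    n_blocks: int
    seed: int | None = None
    geometry: GeometryParams = field(default_factory=GeometryParams)

    @property
    def occupied(self) -> list[Plot]:
        return [p for p in self.plots if not p.is_empty]

    @property
    def accessions(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.occupied:
            seen.setdefault(p.accession_id, None)
        return list(seen)

    def species_of(self, accession_id: str) -> str:
        for p in self.occupied:
            if p.accession_id == accession_id:
                return p.species
        raise KeyError(accession_id)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view, one row per plot position (empty plots included)."""
        rows = []
        for p in self.plots:
            c = p.polygon.centroid
            rows.append(
                {
                    "plot_id": p.plot_id,
                    "accession_id": p.accession_id,
                    "species": p.species,
                    "block": p.block,
                    "row": p.row,
                    "order_in_row": p.order_in_row,
                    "center_x": c.x,
                    "center_y": c.y,
                }
            )
        return pd.DataFrame(rows)

    def __len__(self) -> int:
        return len(self.plots)


def _accession_panel(n_accessions: int) -> pd.DataFrame:
    """First ``n_accessions`` unique accessions from the bundled panel,
    extended with synthetic entries if more are requested."""
    ref = load_reference_accessions().drop_duplicates("accession_name")
    ref = ref.rename(columns={"id": "accession_id"})[["accession_id", "species"]]
    if n_accessions <= len(ref):
        return ref.iloc[:n_accessions].reset_index(drop=True)
    extra = [
        {"accession_id": f"ACC{i:03d}", "species": SPECIES[i % len(SPECIES)]}
        for i in range(n_accessions - len(ref))
    ]
    return pd.concat([ref, pd.DataFrame(extra)], ignore_index=True)


def generate_trial_design(
    n_accessions: int,
    n_blocks: int,
    plots_per_block: int,
    geometry: GeometryParams | None = None,
    seed: int = 0,
    accession_table: pd.DataFrame | None = None,
) -> TrialDesign:
    """Generate a randomized complete block design.

    Within each block the ``n_accessions`` accessions are placed on a
    seeded random subset of the ``plots_per_block`` positions (a fresh
    permutation per block); remaining positions stay empty.  Accession
    identities default to the bundled reference panel.

    Parameters
    ----------
    accession_table
        Optional frame with columns ``accession_id`` and ``species``
        overriding the default panel.
    seed
        Integer seed; the same seed reproduces the layout exactly.
    """
    if n_accessions > plots_per_block:
        raise ValueError(
            f"n_accessions ({n_accessions}) exceeds plots_per_block "
            f"({plots_per_block}); every accession needs a position in each block"
        )
    if n_accessions < 1 or n_blocks < 1:
        raise ValueError("n_accessions and n_blocks must be >= 1")
    geom = geometry or GeometryParams()
    if accession_table is None:
        accession_table = _accession_panel(n_accessions)
    if len(accession_table) < n_accessions:
        raise ValueError("accession_table has fewer rows than n_accessions")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    plots_per_row = math.ceil(plots_per_block / geom.rows_per_block)
    pitch_x = geom.plot_width + geom.inter_plot
    pitch_y = geom.plot_height + geom.inter_row
    block_height = geom.rows_per_block * pitch_y - geom.inter_row

    plots: list[Plot] = []
    for b in range(1, n_blocks + 1):
        perm = rng.permutation(plots_per_block)
        assignment: dict[int, int] = {int(pos): i for i, pos in enumerate(perm[:n_accessions])}
        y_block = geom.margin + (b - 1) * (block_height + geom.block_gap)
        for pos in range(plots_per_block):
            row = pos // plots_per_row
            col = pos % plots_per_row
            x0 = geom.margin + col * pitch_x
            y0 = y_block + row * pitch_y
            poly = box(x0, y0, x0 + geom.plot_width, y0 + geom.plot_height)
            if pos in assignment:
                acc = accession_table.iloc[assignment[pos]]
                acc_id, species = str(acc["accession_id"]), str(acc["species"])
            else:
                acc_id = species = None
            plots.append(
                Plot(
                    plot_id=f"B{b}P{pos + 1:02d}",
                    accession_id=acc_id,
                    species=species,
                    block=b,
                    row=row + 1,
                    order_in_row=col + 1,
                    polygon=poly,
                )
            )

    width = geom.margin * 2 + plots_per_row * pitch_x - geom.inter_plot
    height = geom.margin * 2 + n_blocks * (block_height + geom.block_gap) - geom.block_gap
    return TrialDesign(
        plots=plots,
        extent=(width, height),
        n_blocks=n_blocks,
        seed=int(seed),
        geometry=geom,
    )
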