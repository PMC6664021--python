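"""Raster, vector and table I/O.

Rasters are six-band float32 reflectance images stored as multi-page
TIFF (band-interleaved-by-plane) with a JSON metadata block carrying the
geotransform (planar origin + pixel size, y down), the band wavelengths
and the acquisition date in days after sowing (DAS).  Plot layouts are
GeoJSON FeatureCollections in the same planar coordinates.  CSV (comma,
UTF-8, header row, empty field = missing) is the canonical table format.

Reading never rescales values: reflectance stays on the [0, 1] scale it
was written with, and NaN pixels survive the round trip (they are
treated as masked downstream).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import mapping, shape

from .design import GeometryParams, Plot, TrialDesign
from .indices import BAND_WAVELENGTHS

__all__ = [
    "MultiSpectralRaster",
    "RasterFormatError",
    "read_raster",
    "write_raster",
    "read_plots",
    "write_plots",
    "write_table",
    "read_table",
]

N_BANDS = 6


class RasterFormatError(ValueError):
    """Raised when a raster file violates the six-band reflectance contract."""


@dataclass
class MultiSpectralRaster:
    """Six-band reflectance image for one flight date.

    ``pixels`` has shape (rows, cols, 6), float32, reflectance in [0, 1]
    (NaN = masked).  World coordinates: x = origin_x + (col + 0.5) * px,
    y = origin_y + (row + 0.5) * px for pixel centers, y increasing
    downward.
    """

    pixels: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    wavelengths: tuple[int, ...] = BAND_WAVELENGTHS
    date_das: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != N_BANDS:
            n = self.pixels.shape[2] if self.pixels.ndim == 3 else self.pixels.ndim
            raise RasterFormatError(f"expected {N_BANDS} bands, got {n}")
        if self.pixel_size <= 0:
            raise RasterFormatError(f"pixel_size must be > 0, got {self.pixel_size}")
        wl = tuple(int(w) for w in self.wavelengths)
        if len(wl) != N_BANDS or any(b <= a for a, b in zip(wl, wl[1:])):
            raise RasterFormatError(f"wavelengths must be {N_BANDS} strictly increasing values, got {wl}")
        self.wavelengths = wl

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def window_for_bounds(self, minx: float, miny: float, maxx: float, maxy: float):
        """Pixel window (r0, r1, c0, c1) whose pixel centers fall inside
        the given world bounds, clipped to the raster; half-open."""
        px, (ox, oy) = self.pixel_size, self.origin
        c0 = int(np.ceil((minx - ox) / px - 0.5))
        c1 = int(np.floor((maxx - ox) / px - 0.5)) + 1
        r0 = int(np.ceil((miny - oy) / px - 0.5))
        r1 = int(np.floor((maxy - oy) / px - 0.5)) + 1
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, self.pixels.shape[0]), min(c1, self.pixels.shape[1])
        return r0, r1, c0, c1

    def pixel_centers(self, r0: int, r1: int, c0: int, c1: int):
        """Meshgrid of world x/y coordinates of pixel centers in a window."""
        px, (ox, oy) = self.pixel_size, self.origin
        xs = ox + (np.arange(c0, c1) + 0.5) * px
        ys = oy + (np.arange(r0, r1) + 0.5) * px
        return np.meshgrid(xs, ys)


def write_raster(raster: MultiSpectralRaster, path) -> None:
    """Write a raster as a band-planar float32 TIFF with JSON metadata."""
    meta = {
        "pixel_size": raster.pixel_size,
        "origin": list(raster.origin),
        "wavelengths_nm": list(raster.wavelengths),
        "date_das": raster.date_das,
        "units": "reflectance",
    }
    planar = np.ascontiguousarray(np.moveaxis(raster.pixels, 2, 0))
    tifffile.imwrite(str(path), planar, metadata=meta, photometric="minisblack")


def read_raster(path) -> MultiSpectralRaster:
    """Read a raster written by :func:`write_raster`.

    Raises :class:`RasterFormatError` if the file does not carry exactly
    six bands; warns (and leaves ``date_das`` unset) when the DAS tag is
    missing — stages that need a time axis will then refuse the raster.
    """
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if data.ndim == 2:
        raise RasterFormatError(f"expected {N_BANDS} bands, got 1")
    if data.ndim != 3:
        raise RasterFormatError(f"unsupported raster dimensionality {data.ndim}")
    # band axis may be first (planar) or last (interleaved)
    if data.shape[0] <= data.shape[2]:
        n_bands = data.shape[0]
        pixels = np.moveaxis(data, 0, 2)
    else:
        n_bands = data.shape[2]
        pixels = data
    if n_bands != N_BANDS:
        raise RasterFormatError(f"expected {N_BANDS} bands, got {n_bands}")
    date_das = meta.get("date_das")
    if date_das is None:
        warnings.warn(
            f"{path}: no DAS (days-after-sowing) tag; temporal stages will require one",
            stacklevel=2,
        )
    return MultiSpectralRaster(
        pixels=pixels.astype(np.float32),
        pixel_size=float(meta.get("pixel_size", 1.0)),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
        wavelengths=tuple(meta.get("wavelengths_nm", BAND_WAVELENGTHS)),
        date_das=None if date_das is None else int(date_das),
    )


def write_plots(design: TrialDesign, path) -> None:
    """Write the plot layout as a GeoJSON FeatureCollection."""
    features = []
    for p in design.plots:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(p.polygon),
                "properties": {
                    "plot_id": p.plot_id,
                    "accession_id": p.accession_id,
                    "species": p.species,
                    "block": p.block,
                    "row": p.row,
                    "order_in_row": p.order_in_row,
                },
            }
        )
    doc = {
        "type": "FeatureCollection",
        "features": features,
        "properties": {
            "extent": list(design.extent),
            "n_blocks": design.n_blocks,
            "seed": design.seed,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_plots(path) -> TrialDesign:
    """Read a plot layout from GeoJSON; rejects duplicate plot ids."""
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    plots: list[Plot] = []
    seen: set[str] = set()
    for feat in doc["features"]:
        props = feat.get("properties", {})
        pid = props.get("plot_id")
        if pid is None:
            raise ValueError(f"{path}: feature without plot_id property")
        if pid in seen:
            raise ValueError(f"{path}: duplicate plot_id {pid!r}")
        seen.add(pid)
        plots.append(
            Plot(
                plot_id=str(pid),
                accession_id=props.get("accession_id"),
                species=props.get("species"),
                block=int(props.get("block", 1)),
                row=int(props.get("row", 0)),
                order_in_row=int(props.get("order_in_row", 0)),
                polygon=shape(feat["geometry"]),
            )
        )
    top = doc.get("properties", {})
    if "extent" in top:
        extent = tuple(float(v) for v in top["extent"])
    else:
        minx = min(p.polygon.bounds[0] for p in plots)
        miny = min(p.polygon.bounds[1] for p in plots)
        maxx = max(p.polygon.bounds[2] for p in plots)
        maxy = max(p.polygon.bounds[3] for p in plots)
        extent = (maxx + minx, maxy + miny)
    n_blocks = int(top.get("n_blocks", max(p.block for p in plots)))
    seed = top.get("seed")
    return TrialDesign(
        plots=plots,
        extent=extent,
        n_blocks=n_blocks,
        seed=None if seed is None else int(seed),
        geometry=GeometryParams(),
    )


def write_table(table: pd.DataFrame, path) -> None:
    """Write a CSV table; missing values become empty fields."""
    table.to_csv(path, index=False, na_rep="")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
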