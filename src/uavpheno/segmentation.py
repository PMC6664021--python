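"""Per-plot vegetation segmentation and vegetation-only spectral extraction.

Each trial plot is thresholded independently on a per-pixel greenness
feature (excess green by default, NDVI selectable) using Otsu's method:
the histogram cut maximizing the between-class variance.  The class
with the higher mean feature value is labeled vegetation, tiny isolated
objects are dropped (object-based behavior), and plots whose two
classes are barely separated — bare soil, emergence failures — are
flagged low-cover and propagate missing values instead of biased means.

Plots are processed independently, so results do not depend on
processing order, and identical pixels always yield identical masks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely import contains_xy
from shapely.geometry.base import BaseGeometry

from .indices import BAND_COLUMNS, compute_vis
from .rasters import MultiSpectralRaster

__all__ = [
    "DegenerateInputError",
    "EmptyPlotError",
    "VegetationMask",
    "otsu_threshold",
    "pixel_feature",
    "remove_small_patches",
    "classify_plot_vegetation",
    "extract_plot_spectra",
]

log = logging.getLogger(__name__)

SEGMENTATION_FEATURES = ("exg", "ndvi")


def remove_small_patches(mask: np.ndarray, min_size: int) -> np.ndarray:
    """Drop connected components (8-connectivity) smaller than ``min_size`` pixels.

    Components of exactly ``min_size`` pixels are kept.
    """
    if min_size <= 1 or not mask.any():
        return mask
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[labels]


class DegenerateInputError(ValueError):
    """Sample has no spread; no threshold separates two classes."""


class EmptyPlotError(ValueError):
    """Polygon does not intersect the raster."""


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's automatic threshold of a 1-D sample.

    The sample is histogrammed into ``n_bins`` equal-width bins over its
    observed range and every interior bin edge is scored by the
    between-class variance ``w0 * w1 * (mu0 - mu1)^2`` of the two classes
    it induces; the best edge is returned (ties broken by the lower
    edge).  Deterministic for fixed input and ``n_bins``.

    Raises
    ------
    DegenerateInputError
        If fewer than two distinct finite values are present.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 2 or np.min(v) == np.max(v):
        raise DegenerateInputError("need at least 2 distinct finite values for Otsu thresholding")
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    counts, edges = np.histogram(v, bins=n_bins, range=(float(v.min()), float(v.max())))
    counts = counts.astype(float)
    total = counts.sum()

    # cumulative class weights/means for a cut below bin k (k = 1..n_bins-1)
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    centers = (edges[:-1] + edges[1:]) / 2.0
    cum_mass = np.cumsum(counts * centers)[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mass / w0
        mu1 = (cum_mass[-1] + counts[-1] * centers[-1] - cum_mass) / w1
        score = w0 * w1 * (mu0 - mu1) ** 2
    score[~np.isfinite(score)] = -np.inf
    k = int(np.argmax(score))  # argmax returns first (lowest) maximizer
    return float(edges[k + 1])


def pixel_feature(pixels: np.ndarray, feature: str = "exg") -> np.ndarray:
    """Per-pixel segmentation feature from a (rows, cols, 6) window."""
    feature = feature.lower()
    if feature not in SEGMENTATION_FEATURES:
        raise ValueError(f"unknown segmentation feature {feature!r}; choose from {SEGMENTATION_FEATURES}")
    b, g, r1, r2, nir1, nir2 = (pixels[..., i].astype(float) for i in range(6))
    vis = compute_vis(b, g, r1, r2, nir1, nir2)
    return vis["ExG"] if feature == "exg" else vis["NDVI"]


@dataclass
class VegetationMask:
    """Vegetation/background decision for one plot on one date.

    ``mask`` is true on vegetation pixels within ``window`` (raster
    coordinates, half-open); ``inside`` marks pixels whose centers fall
    inside the plot polygon; ``fraction`` is the vegetation share of
    valid in-polygon pixels.  ``low_cover`` masks are all background.
    """

    plot_id: str
    window: tuple[int, int, int, int]
    mask: np.ndarray
    inside: np.ndarray
    threshold: float | None
    fraction: float
    low_cover: bool = False

    @property
    def n_vegetation(self) -> int:
        return int(self.mask.sum())


def classify_plot_vegetation(
    raster: MultiSpectralRaster,
    polygon: BaseGeometry,
    plot_id: str = "",
    feature: str = "exg",
    n_bins: int = 256,
    min_fraction: float = 0.005,
    min_object_size: int = 4,
    min_separation: float = 0.10,
) -> VegetationMask:
    """Threshold one plot into vegetation and background.

    The per-pixel feature is computed inside the polygon (pixel-center
    rule), split by Otsu's threshold, and the higher-feature class taken
    as vegetation (greenness features increase with vegetation).  The
    plot is flagged low-cover — all-background mask, missing spectra
    downstream — when the two class means are closer than
    ``min_separation``, when the sample is degenerate, or when the
    vegetation fraction ends up below ``min_fraction``.  Objects smaller
    than ``min_object_size`` pixels (8-connectivity) are removed.
    """
    r0, r1, c0, c1 = raster.window_for_bounds(*polygon.bounds)
    if r1 <= r0 or c1 <= c0:
        raise EmptyPlotError(f"plot {plot_id!r}: polygon does not intersect the raster")
    window = raster.pixels[r0:r1, c0:c1]
    xs, ys = raster.pixel_centers(r0, r1, c0, c1)
    inside = contains_xy(polygon, xs, ys)
    if not inside.any():
        raise EmptyPlotError(f"plot {plot_id!r}: no pixel centers inside polygon")

    feat = pixel_feature(window, feature)
    valid = inside & np.isfinite(feat)
    empty = np.zeros_like(inside, dtype=bool)

    def _low_cover(threshold=None):
        return VegetationMask(
            plot_id=plot_id, window=(r0, r1, c0, c1), mask=empty, inside=inside,
            threshold=threshold, fraction=0.0, low_cover=True,
        )

    if valid.sum() < 2:
        return _low_cover()
    sample = feat[valid]
    try:
        thr = otsu_threshold(sample, n_bins=n_bins)
    except DegenerateInputError:
        return _low_cover()

    hi = valid & (feat >= thr)
    lo = valid & ~hi
    if not hi.any() or not lo.any():
        return _low_cover(thr)
    if abs(float(feat[hi].mean()) - float(feat[lo].mean())) < min_separation:
        return _low_cover(thr)

    veg = remove_small_patches(hi.copy(), min_object_size)
    fraction = float(veg.sum()) / float(valid.sum())
    if fraction < min_fraction:
        return _low_cover(thr)
    return VegetationMask(
        plot_id=plot_id, window=(r0, r1, c0, c1), mask=veg, inside=inside,
        threshold=thr, fraction=fraction,
    )


def extract_plot_spectra(raster: MultiSpectralRaster, mask: VegetationMask) -> pd.Series:
    """Vegetation-only mean reflectance per band for one plot.

    Means are arithmetic over vegetation pixels; NaN pixels are dropped
    from both numerator and count, band by band.  Zero vegetation pixels
    yield missing means (never zero-filled).
    """
    r0, r1, c0, c1 = mask.window
    window = raster.pixels[r0:r1, c0:c1]
    veg = mask.mask
    rec: dict[str, object] = {
        "plot_id": mask.plot_id,
        "vegetation_fraction": mask.fraction,
        "n_vegetation_px": int(veg.sum()),
        "threshold": mask.threshold if mask.threshold is not None else np.nan,
        "low_cover": bool(mask.low_cover),
    }
    if veg.any():
        sub = window[veg].astype(np.float64)  # (n_veg, 6)
        with np.errstate(invalid="ignore"):
            means = np.nanmean(sub, axis=0)
    else:
        means = np.full(6, np.nan)
    for col, m in zip(BAND_COLUMNS, means):
        rec[col] = float(m) if np.isfinite(m) else np.nan
    return pd.Series(rec)
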