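"""Vegetation indices from six-band reflectance.

Band symbols map to the camera's filter set: B = 450 nm, G = 530 nm,
R1 = 670 nm (red), R2 = 700 nm (red edge), NIR1 = 740 nm, NIR2 = 780 nm.
Seven indices are computed; three use only visible bands (ExG, VIgreen,
TCI) and four include a near-infrared band (NDVI, GNDVI, MCARI, MSR).
Note that NDVI here pairs NIR1 with the red-edge band R2 and MCARI is
built on NIR1/R2/G — both follow the camera's filter set rather than the
red/green wavelengths of the classical literature forms.

Ratio indices require strictly positive denominator bands; where a band
is non-positive or missing the affected index is NaN and the others are
still computed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "BAND_WAVELENGTHS",
    "BAND_COLUMNS",
    "VI_NAMES",
    "VISIBLE_VIS",
    "NIR_VIS",
    "compute_vis",
    "add_vi_columns",
]

#: Fixed band order (nm) of every raster and band-mean table.
BAND_WAVELENGTHS = (450, 530, 670, 700, 740, 780)

#: Column names used for per-plot band means.
BAND_COLUMNS = tuple(f"b{w}" for w in BAND_WAVELENGTHS)

VI_NAMES = ("ExG", "VIgreen", "TCI", "NDVI", "GNDVI", "MCARI", "MSR")
VISIBLE_VIS = frozenset({"ExG", "VIgreen", "TCI"})
NIR_VIS = frozenset({"NDVI", "GNDVI", "MCARI", "MSR"})


def _safe_div(num, den):
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, np.asarray(num, dtype=float) / np.where(den > 0, den, 1.0), np.nan)
    return out


def compute_vis(b, g, r1, r2, nir1, nir2) -> dict[str, np.ndarray | float]:
    """Compute the seven vegetation indices from band reflectances.

    Accepts scalars or broadcastable arrays.  Ratio indices (VIgreen,
    NDVI, GNDVI, MCARI, MSR, and the square-root term of TCI) yield NaN
    wherever a denominator band is non-positive; ExG is defined for any
    finite inputs.
    """
    b = np.asarray(b, dtype=float)
    g = np.asarray(g, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    nir1 = np.asarray(nir1, dtype=float)
    nir2 = np.asarray(nir2, dtype=float)

    def _require_positive(value, *bands):
        ok = np.ones(np.broadcast(b, g, r1, r2, nir1, nir2).shape, dtype=bool)
        for band in bands:
            ok &= np.asarray(band) > 0
        return np.where(ok, value, np.nan)

    exg = 2.0 * g - r1 - b
    vigreen = _require_positive(_safe_div(g - r1, g + r1), g, r1)
    with np.errstate(invalid="ignore"):
        tci = _require_positive(
            1.2 * (r2 - g) - 1.5 * (r1 - g) * np.sqrt(_safe_div(r2, r1)), g, r1, r2
        )
    ndvi = _require_positive(_safe_div(nir1 - r2, nir1 + r2), nir1, r2)
    gndvi = _require_positive(_safe_div(nir2 - g, nir2 + g), nir2, g)
    ratio = _safe_div(nir1, r2)
    with np.errstate(invalid="ignore"):
        mcari = _require_positive(((nir1 - r2) - 0.2 * (nir1 - g)) * ratio, g, nir1, r2)
        msr = _require_positive(
            np.where(ratio >= 0, (ratio - 1.0) / (np.sqrt(np.abs(ratio)) + 1.0), np.nan), nir1, r2
        )

    out = {
        "ExG": exg,
        "VIgreen": vigreen,
        "TCI": tci,
        "NDVI": ndvi,
        "GNDVI": gndvi,
        "MCARI": mcari,
        "MSR": msr,
    }
    if np.broadcast(b, g, r1, r2, nir1, nir2).ndim == 0:
        out = {k: float(v) for k, v in out.items()}
    return out


def add_vi_columns(table: pd.DataFrame, band_columns=BAND_COLUMNS) -> pd.DataFrame:
    """Append the seven VI columns to a table of per-plot band means.

    Indices are computed on the (vegetation-only) plot-mean reflectances
    — mean-then-index.  Rows with missing band means get missing VIs.
    """
    missing = [c for c in band_columns if c not in table.columns]
    if missing:
        raise KeyError(f"band columns absent from table: {missing}")
    bands = [table[c].to_numpy(dtype=float) for c in band_columns]
    vis = compute_vis(*bands)
    out = table.copy()
    for name in VI_NAMES:
        out[name] = vis[name]
    return out
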