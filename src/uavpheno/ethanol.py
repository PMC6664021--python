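"""Theoretical ethanol yield from biomass and saccharification sugar release.

The conversion uses the glucose-to-ethanol stoichiometric factor 0.511
(NREL standard): with sugar release S in ul glucose per mg straw and
total biomass dry weight W in kg/m2,

    E = S * 0.511 * (W * 10000 kg/ha) / 1000

reported on the m3/ha scale used for field comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EthanolParams", "DEFAULT_ETHANOL_PARAMS", "theoretical_ethanol_yield", "add_ethanol_column"]


@dataclass(frozen=True)
class EthanolParams:
    """Constants of the ethanol-yield conversion.

    ``conversion_factor`` is the stoichiometric glucose-to-ethanol mass
    ratio (0.511, dimensionless); ``area_factor`` converts biomass from
    kg/m2 to kg/ha; ``output_divisor`` scales the product onto the
    per-hectare yield scale.  All three are overridable for sensitivity
    analyses but default to the standard values.
    """

    conversion_factor: float = 0.511
    area_factor: float = 10000.0
    output_divisor: float = 1000.0


DEFAULT_ETHANOL_PARAMS = EthanolParams()


def theoretical_ethanol_yield(sugar_release, biomass, params: EthanolParams = DEFAULT_ETHANOL_PARAMS):
    """Theoretical ethanol yield (m3/ha) from sugar release and biomass.

    Parameters
    ----------
    sugar_release
        ul glucose released per mg straw (scalar or array), >= 0.
    biomass
        Total biomass dry weight in kg/m2 (scalar or array), >= 0.

    Returns
    -------
    Scalar or array on the m3/ha scale; bilinear in its two inputs.
    """
    s = np.asarray(sugar_release, dtype=float)
    w = np.asarray(biomass, dtype=float)
    if np.any(s[np.isfinite(s)] < 0):
        raise ValueError("sugar_release must be non-negative")
    if np.any(w[np.isfinite(w)] < 0):
        raise ValueError("biomass must be non-negative")
    e = s * params.conversion_factor * (w * params.area_factor) / params.output_divisor
    if np.isscalar(sugar_release) and np.isscalar(biomass):
        return float(e)
    return e


def add_ethanol_column(
    phenotypes: pd.DataFrame,
    params: EthanolParams = DEFAULT_ETHANOL_PARAMS,
    sugar_col: str = "sugar_release_ul_mg",
    biomass_col: str = "biomass_kg_m2",
    out_col: str = "ethanol_yield_m3_ha",
) -> pd.DataFrame:
    """Return a copy of ``phenotypes`` with the ethanol-yield column (re)computed."""
    out = phenotypes.copy()
    out[out_col] = theoretical_ethanol_yield(
        out[sugar_col].to_numpy(), out[biomass_col].to_numpy(), params
    )
    return out
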