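"""Synthetic field-trial phenotypes, phenology and multi-band imagery.

The generator emulates a cereal bioethanol trial: a replicated block
layout of small plots, per-plot ground truth for biomass (kg/m2) and
saccharification sugar release (ul glucose / mg straw), per-accession
anthesis windows, and a seven-date series of six-band reflectance
orthomosaics whose temporal statistics follow what such trials show in
the field — near-infrared indices tracing a bell-shaped curve peaking
around anthesis, visible indices roughly flat until a marked rise at the
final (senescent) date.

The optical model is deliberately simple (two endmember spectra mixed by
scalar state variables plus i.i.d. Gaussian pixel noise); it is a
statistical stand-in for canopy optics, not a radiative-transfer model.
Three state variables drive a plot's appearance:

``greenness``
    Phenological state in [0, 1]: logistic rise through tillering,
    plateau near 1 during anthesis, exponential decline (senescence)
    after the anthesis window closes.
``pigment``
    Greenness modulated upward by the plot's sugar-release rank —
    sugar-rich plots are greener in the visible bands.
``structure``
    A near-infrared gain increasing with the plot's biomass rank —
    denser canopies scatter more NIR.

Canopy cover (the fraction of plot pixels that are vegetation) follows
its own logistic curve scaled by the biomass rank; vegetation pixels are
placed with a spatially smoothed random field so canopies form patches
rather than salt-and-pepper noise.

Randomness: one integer seed is expanded into independent substreams
per stage (design / phenotypes / phenology / per-date rendering), so
each stage is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import correlate1d
from scipy.special import expit, ndtr

from .design import SPECIES, TrialDesign
from .ethanol import DEFAULT_ETHANOL_PARAMS, EthanolParams, theoretical_ethanol_yield
from .rasters import MultiSpectralRaster
from .segmentation import remove_small_patches

__all__ = [
    "SpeciesParams",
    "DEFAULT_SPECIES_PARAMS",
    "ReflectanceModel",
    "generate_phenotypes",
    "generate_phenology",
    "render_orthomosaic",
    "FLIGHT_DATES",
]

#: Default flight schedule in days after sowing.
FLIGHT_DATES = (94, 104, 119, 130, 143, 161, 175)

# substream tags (arbitrary fixed integers, one per stage)
_STREAM_PHENOTYPES = 211
_STREAM_PHENOLOGY = 307
_STREAM_RENDER = 401


@dataclass(frozen=True)
class SpeciesParams:
    """Ground-truth distribution for one species.

    ``biomass_mean``/``sugar_mean`` are species means; ``*_accession_sd``
    the between-accession spread (a shared accession effect across
    blocks) and ``*_block_sd`` the residual plot-to-plot noise.
    """

    biomass_mean: float
    biomass_accession_sd: float = 0.20
    biomass_block_sd: float = 0.07
    sugar_mean: float = 1.0
    sugar_accession_sd: float = 0.10
    sugar_block_sd: float = 0.05

    def __post_init__(self) -> None:
        for name in ("biomass_accession_sd", "biomass_block_sd", "sugar_accession_sd", "sugar_block_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")


#: Species means match the observed field ordering: durum wheat the
#: heaviest, barley the most saccharifiable, triticale lowest on both.
DEFAULT_SPECIES_PARAMS: dict[str, SpeciesParams] = {
    "T. aestivum": SpeciesParams(biomass_mean=0.67, sugar_mean=0.98),
    "T. durum": SpeciesParams(biomass_mean=0.83, sugar_mean=0.98),
    "H. vulgare": SpeciesParams(biomass_mean=0.71, sugar_mean=1.16),
    "x Triticosecale": SpeciesParams(biomass_mean=0.52, sugar_mean=0.94),
}


def generate_phenotypes(
    design: TrialDesign,
    species_params: dict[str, SpeciesParams] | None = None,
    seed: int = 0,
    ethanol_params: EthanolParams = DEFAULT_ETHANOL_PARAMS,
) -> pd.DataFrame:
    """Draw per-plot biomass and sugar release; derive ethanol yield.

    Each accession gets a normal accession effect around its species
    mean, shared across blocks; plots add independent block noise and
    are truncated at zero.  The ethanol column is computed exactly from
    the biomass and sugar columns.

    Returns a frame with one row per occupied plot: ``plot_id``,
    ``accession_id``, ``species``, ``block``, ``biomass_kg_m2``,
    ``sugar_release_ul_mg``, ``ethanol_yield_m3_ha``.
    """
    params = species_params or DEFAULT_SPECIES_PARAMS
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_PHENOTYPES]))

    effects: dict[str, tuple[float, float]] = {}
    for acc in design.accessions:
        sp = design.species_of(acc)
        try:
            p = params[sp]
        except KeyError:
            raise KeyError(f"no species parameters for {sp!r}") from None
        effects[acc] = (
            p.biomass_mean + p.biomass_accession_sd * rng.standard_normal(),
            p.sugar_mean + p.sugar_accession_sd * rng.standard_normal(),
        )

    rows = []
    for plot in design.occupied:
        p = params[plot.species]
        w_eff, s_eff = effects[plot.accession_id]
        w = max(w_eff + p.biomass_block_sd * rng.standard_normal(), 0.0)
        s = max(s_eff + p.sugar_block_sd * rng.standard_normal(), 0.0)
        rows.append(
            {
                "plot_id": plot.plot_id,
                "accession_id": plot.accession_id,
                "species": plot.species,
                "block": plot.block,
                "biomass_kg_m2": w,
                "sugar_release_ul_mg": s,
            }
        )
    table = pd.DataFrame(rows)
    table["ethanol_yield_m3_ha"] = theoretical_ethanol_yield(
        table["sugar_release_ul_mg"].to_numpy(),
        table["biomass_kg_m2"].to_numpy(),
        ethanol_params,
    )
    return table


def generate_phenology(
    design: TrialDesign,
    seed: int = 0,
    start_range: tuple[int, int] = (110, 160),
    window_range: tuple[int, int] = (10, 20),
) -> pd.DataFrame:
    """Draw an anthesis window per accession.

    Start dates are uniform integers on ``start_range`` (inclusive) and
    window lengths uniform on ``window_range``, both in days after
    sowing.  Returns ``accession_id``, ``anthesis_start``,
    ``anthesis_end``.
    """
    if start_range[0] > start_range[1] or window_range[0] > window_range[1]:
        raise ValueError("ranges must be (low, high) with low <= high")
    if window_range[0] < 1:
        raise ValueError("anthesis window must be at least 1 day")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_PHENOLOGY]))
    accs = design.accessions
    starts = rng.integers(start_range[0], start_range[1] + 1, size=len(accs))
    lengths = rng.integers(window_range[0], window_range[1] + 1, size=len(accs))
    return pd.DataFrame(
        {
            "accession_id": accs,
            "anthesis_start": starts.astype(int),
            "anthesis_end": (starts + lengths).astype(int),
        }
    )


@dataclass(frozen=True)
class ReflectanceModel:
    """Endmember spectra and temporal dynamics of the scene.

    Band order everywhere: 450, 530, 670, 700, 740, 780 nm.  Vegetation
    visible bands interpolate between a senescent (straw + background)
    endmember and a fully green endmember by the pigment scalar; NIR
    bands interpolate by greenness and are multiplied by the structure
    gain.  All spectra are config-overridable; defaults were chosen so
    the seven indices reproduce the qualitative temporal profiles seen
    in multi-date cereal trials.
    """

    soil: tuple[float, ...] = (0.20, 0.22, 0.25, 0.26, 0.28, 0.30)
    veg_senescent_vis: tuple[float, ...] = (0.08, 0.30, 0.12, 0.20)  # B G R1 R2
    veg_green_vis: tuple[float, ...] = (0.04, 0.12, 0.05, 0.15)
    nir_senescent: tuple[float, float] = (0.30, 0.32)  # NIR1 NIR2
    nir_green: tuple[float, float] = (0.45, 0.50)
    noise_sd: float = 0.015
    # canopy cover dynamics
    cover_base: float = 0.45
    cover_gain: float = 0.50
    cover_midpoint_offset: float = -30.0  # days relative to anthesis start
    cover_scale: float = 6.0  # logistic scale, days
    cover_senescence_floor: float = 0.75
    cover_senescence_days: float = 30.0
    canopy_texture_sigma: float = 1.5  # pixels; patchiness of the canopy
    # greenness dynamics
    green_midpoint_offset: float = -25.0
    green_scale: float = 8.0
    senescence_days: float = 25.0
    min_patch_px: int = 4  # vegetation patches smaller than this are not rendered
    # couplings to ground truth
    pigment_base: float = 0.60
    pigment_sugar_gain: float = 0.40
    structure_base: float = 0.85
    structure_biomass_gain: float = 0.30
    # state noise uncorrelated with the phenotypes: a persistent per-plot
    # component (canopy architecture, position effects — does not average
    # out over dates) and an independent per-date component (illumination,
    # wind — shrinks under temporal averaging)
    pigment_jitter_plot: float = 0.06
    pigment_jitter_date: float = 0.08
    structure_jitter_plot: float = 0.06
    structure_jitter_date: float = 0.04

    def greenness(self, das, anthesis_start, anthesis_end):
        """Phenological greenness in [0, 1] at a given date."""
        das = np.asarray(das, dtype=float)
        rise = expit((das - (anthesis_start + self.green_midpoint_offset)) / self.green_scale)
        plateau = expit((anthesis_end - (anthesis_start + self.green_midpoint_offset)) / self.green_scale)
        decay = plateau * np.exp(-(das - anthesis_end) / self.senescence_days)
        out = np.where(das <= anthesis_end, rise, decay)
        return float(out) if out.ndim == 0 else out

    def canopy_cover(self, das, anthesis_start, anthesis_end, biomass_rank):
        """Expected vegetation fraction of a plot at a given date.

        ``biomass_rank`` in [0, 1] scales the asymptotic cover; cover
        rises logistically through the vegetative phase and relaxes
        toward ``cover_senescence_floor`` of its peak after anthesis.
        """
        das = np.asarray(das, dtype=float)
        top = np.clip(self.cover_base + self.cover_gain * biomass_rank, 0.0, 1.0)
        rise = expit((das - (anthesis_start + self.cover_midpoint_offset)) / self.cover_scale)
        f = self.cover_senescence_floor
        late = f + (1.0 - f) * np.exp(-np.maximum(das - anthesis_end, 0.0) / self.cover_senescence_days)
        out = top * rise * np.where(das > anthesis_end, late, 1.0)
        return float(out) if out.ndim == 0 else out

    def vegetation_spectrum(self, greenness, sugar_rank, biomass_rank,
                            pigment_offset: float = 0.0, structure_offset: float = 0.0) -> np.ndarray:
        """Six-band vegetation reflectance for one plot state."""
        pigment = float(
            np.clip(greenness * (self.pigment_base + self.pigment_sugar_gain * sugar_rank) + pigment_offset, 0.0, 1.0)
        )
        structure = max(self.structure_base + self.structure_biomass_gain * biomass_rank + structure_offset, 0.0)
        vis = np.asarray(self.veg_senescent_vis) + pigment * (
            np.asarray(self.veg_green_vis) - np.asarray(self.veg_senescent_vis)
        )
        nir = (
            np.asarray(self.nir_senescent)
            + float(greenness) * (np.asarray(self.nir_green) - np.asarray(self.nir_senescent))
        ) * structure
        return np.clip(np.concatenate([vis, nir]), 0.0, 1.0)


def _rank_fraction(values: pd.Series) -> pd.Series:
    """Average ranks mapped to [0, 1] (0 = smallest, 1 = largest)."""
    if len(values) == 1:
        return pd.Series([0.5], index=values.index)
    r = values.rank(method="average")
    return (r - 1.0) / (len(values) - 1.0)


def _smooth_uniform_field(shape: tuple[int, int], sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Spatially correlated field with exactly uniform [0, 1] marginals.

    White Gaussian noise is smoothed with a wrapped Gaussian kernel
    (wrapping keeps the field stationary so the per-pixel variance is
    known exactly) and mapped through the normal CDF.
    """
    z = rng.standard_normal(shape)
    if sigma <= 0:
        return ndtr(z)
    radius = max(int(4.0 * sigma + 0.5), 1)
    x = np.arange(-radius, radius + 1, dtype=float)
    w = np.exp(-0.5 * (x / sigma) ** 2)
    w /= w.sum()
    f = correlate1d(z, w, axis=0, mode="wrap")
    f = correlate1d(f, w, axis=1, mode="wrap")
    sd = float(np.sum(w**2))  # variance of separable smooth = (sum w^2)^2
    return ndtr(f / sd)


def render_orthomosaic(
    design: TrialDesign,
    phenotypes: pd.DataFrame,
    phenology: pd.DataFrame,
    date: int,
    model: ReflectanceModel | None = None,
    gsd: float = 0.01,
    seed: int = 0,
    return_truth: bool = False,
):
    """Render the trial as a six-band reflectance orthomosaic.

    Every occupied plot's interior pixels are vegetation with
    probability equal to that plot's canopy cover at ``date`` (patchy
    via a smoothed random field, monotone in cover under a fixed seed;
    fragments below ``model.min_patch_px`` pixels are suppressed);
    vegetation pixels take the plot's state-dependent spectrum, all
    other pixels the soil spectrum.  Gaussian noise (sd
    ``model.noise_sd``) is added per band and the result clipped to
    [0, 1].

    Parameters
    ----------
    date
        Days after sowing; any value in a plausible season works, the
        default flight schedule is :data:`FLIGHT_DATES`.
    gsd
        Ground sampling distance in m/pixel (> 0).
    return_truth
        If true, also return ``{plot_id: (window, truth_mask, cover)}``
        with ``window = (r0, r1, c0, c1)``.

    Returns
    -------
    :class:`MultiSpectralRaster`, optionally with the truth dict.
    """
    if gsd <= 0:
        raise ValueError(f"gsd must be > 0, got {gsd}")
    model = model or ReflectanceModel()
    date = int(date)

    width, height = design.extent
    n_cols = max(int(round(width / gsd)), 1)
    n_rows = max(int(round(height / gsd)), 1)
    pixels = np.empty((n_rows, n_cols, 6), dtype=np.float32)
    pixels[:] = np.asarray(model.soil, dtype=np.float32)

    pheno = phenotypes.set_index("plot_id")
    phen = phenology.set_index("accession_id")
    b_rank = _rank_fraction(pheno["biomass_kg_m2"])
    s_rank = _rank_fraction(pheno["sugar_release_ul_mg"])

    raster = MultiSpectralRaster(pixels=pixels, pixel_size=gsd, origin=(0.0, 0.0), date_das=date)
    truth: dict[str, tuple[tuple[int, int, int, int], np.ndarray, float]] = {}

    for idx, plot in enumerate(design.occupied):
        if plot.plot_id not in pheno.index:
            continue
        acc = plot.accession_id
        if acc not in phen.index:
            raise KeyError(f"no phenology record for accession {acc!r}")
        a0 = int(phen.loc[acc, "anthesis_start"])
        a1 = int(phen.loc[acc, "anthesis_end"])
        cover = float(model.canopy_cover(date, a0, a1, float(b_rank[plot.plot_id])))
        g = float(model.greenness(date, a0, a1))

        r0, r1, c0, c1 = raster.window_for_bounds(*plot.polygon.bounds)
        if r1 <= r0 or c1 <= c0:
            continue
        persist_rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_RENDER, 777, idx]))
        plot_rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_RENDER, date, idx]))
        p_off = model.pigment_jitter_plot * persist_rng.standard_normal() + (
            model.pigment_jitter_date * plot_rng.standard_normal()
        )
        s_off = model.structure_jitter_plot * persist_rng.standard_normal() + (
            model.structure_jitter_date * plot_rng.standard_normal()
        )
        spectrum = model.vegetation_spectrum(
            g, float(s_rank[plot.plot_id]), float(b_rank[plot.plot_id]), p_off, s_off
        )
        u = _smooth_uniform_field((r1 - r0, c1 - c0), model.canopy_texture_sigma, plot_rng)
        veg = remove_small_patches(u < cover, model.min_patch_px)
        window = pixels[r0:r1, c0:c1]
        window[veg] = spectrum.astype(np.float32)
        truth[plot.plot_id] = ((r0, r1, c0, c1), veg, cover)

    if model.noise_sd > 0:
        noise_rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_RENDER, date, 999983]))
        pixels += noise_rng.normal(0.0, model.noise_sd, size=pixels.shape).astype(np.float32)
    np.clip(pixels, 0.0, 1.0, out=pixels)

    if return_truth:
        return raster, truth
    return raster
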