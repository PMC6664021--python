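"""Relating vegetation indices to bioethanol phenotypes.

The central object is :class:`VIPhenotypeModel`, a simple linear
regression of one phenotype (biomass, sugar release or ethanol yield)
on one scenario-aggregated vegetation index at the plot level; its
:meth:`~VIPhenotypeModel.fit` returns a :class:`VIPhenotypeResults`
carrying slope, intercept, R^2 (squared Pearson correlation), RMSE,
confidence intervals and a text ``summary()``.  Around it sit

* :func:`scan_models` — the full VI x scenario x phenotype grid of fits,
* :func:`species_anova` — one-way ANOVA with Tukey HSD grouping letters,
* :func:`rank_accessions` — accession ranking by model-predicted value.

Correlation strength is categorized with the conventional thresholds
low (R^2 < 0.50), moderate (0.50 <= R^2 < 0.60), high (R^2 >= 0.60).
Per-model slope p-values are reported raw: no multiple-testing
correction is applied across the grid, so treat significance stars on
the 100+ fitted cells as descriptive, not confirmatory.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "categorize_r2",
    "VIPhenotypeModel",
    "VIPhenotypeResults",
    "scan_models",
    "species_anova",
    "AnovaResult",
    "rank_accessions",
    "RankingResult",
    "PHENOTYPE_COLUMNS",
]

log = logging.getLogger(__name__)

#: Phenotype short name -> column in phenotype tables.
PHENOTYPE_COLUMNS = {
    "biomass": "biomass_kg_m2",
    "sugar": "sugar_release_ul_mg",
    "ethanol": "ethanol_yield_m3_ha",
}


def categorize_r2(r2: float) -> str:
    """Correlation category: low < 0.50 <= moderate < 0.60 <= high."""
    if r2 >= 0.60:
        return "high"
    if r2 >= 0.50:
        return "moderate"
    return "low"


class VIPhenotypeModel:
    """Plot-level simple linear regression of a phenotype on a VI.

    Pairs with a missing value in either variable are dropped; at least
    three complete pairs and non-zero spread in the VI are required.

    Parameters
    ----------
    x, y
        VI values and phenotype values per plot (aligned 1-D arrays).
    vi_name, scenario, phenotype_name
        Labels carried through to results and summary tables.
    """

    def __init__(self, x, y, *, vi_name: str = "x", scenario: str = "",
                 phenotype_name: str = "y", plot_ids=None):
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("x and y must have the same length")
        keep = np.isfinite(x) & np.isfinite(y)
        self.x, self.y = x[keep], y[keep]
        self.plot_ids = None if plot_ids is None else np.asarray(plot_ids)[keep]
        if self.x.size < 3:
            raise ValueError(f"need >= 3 complete observations, got {self.x.size}")
        if np.ptp(self.x) == 0:
            raise ValueError("x has zero variance; slope undefined")
        self.vi_name, self.scenario, self.phenotype_name = vi_name, scenario, phenotype_name

    @classmethod
    def from_tables(cls, scenario_table: pd.DataFrame, phenotypes: pd.DataFrame,
                    vi: str, phenotype: str, scenario: str | None = None) -> "VIPhenotypeModel":
        """Build from a scenario VI table and a phenotype table, joined on plot_id."""
        col = PHENOTYPE_COLUMNS.get(phenotype, phenotype)
        merged = scenario_table.drop(columns=[col], errors="ignore").merge(
            phenotypes[["plot_id", col]], on="plot_id", how="inner"
        )
        label = scenario or (str(merged["scenario"].iloc[0]) if "scenario" in merged else "")
        return cls(
            merged[vi].to_numpy(), merged[col].to_numpy(),
            vi_name=vi, scenario=label, phenotype_name=phenotype,
            plot_ids=merged["plot_id"].to_numpy(),
        )

    def fit(self) -> "VIPhenotypeResults":
        """Ordinary least squares fit."""
        X = sm.add_constant(self.x)
        res = sm.OLS(self.y, X).fit()
        resid = self.y - res.fittedvalues
        rmse = float(np.sqrt(np.mean(resid**2)))
        return VIPhenotypeResults(model=self, _sm=res, rmse=rmse)


@dataclass
class VIPhenotypeResults:
    """Fitted VI-phenotype regression.

    ``rsquared`` equals the squared Pearson correlation of x and y;
    ``rmse`` is the root mean squared residual in phenotype units (it
    scales with those units, while R^2 is invariant to affine rescaling
    of the VI).
    """

    model: VIPhenotypeModel
    _sm: object
    rmse: float

    @property
    def intercept(self) -> float:
        return float(self._sm.params[0])

    @property
    def slope(self) -> float:
        return float(self._sm.params[1])

    @property
    def rsquared(self) -> float:
        # squared Pearson correlation; 0 by convention for a flat response
        y = self.model.y
        if np.ptp(y) == 0:
            return 0.0
        return float(np.corrcoef(self.model.x, y)[0, 1] ** 2)

    @property
    def pvalue_slope(self) -> float:
        return float(self._sm.pvalues[1])

    @property
    def n(self) -> int:
        return int(self.model.x.size)

    @property
    def category(self) -> str:
        return categorize_r2(self.rsquared)

    @property
    def significant(self) -> bool:
        """Slope t-test at the conventional 5% level (the table asterisk)."""
        return self.pvalue_slope < 0.05

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = np.asarray(self._sm.conf_int(alpha=alpha))
        return pd.DataFrame(ci, index=["intercept", "slope"], columns=["lower", "upper"])

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.intercept + self.slope * x

    def to_dict(self) -> dict:
        return {
            "vi": self.model.vi_name,
            "scenario": self.model.scenario,
            "phenotype": self.model.phenotype_name,
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.rsquared,
            "rmse": self.rmse,
            "p_slope": self.pvalue_slope,
            "n": self.n,
            "category": self.category,
            "significant": self.significant,
        }

    def summary(self) -> str:
        d = self.to_dict()
        lines = [
            f"Linear fit: {d['phenotype']} ~ {d['vi']} ({d['scenario'] or 'raw'})",
            f"  n plots            {d['n']:>10d}",
            f"  slope              {d['slope']:>10.4f}  (95% CI {self.conf_int().loc['slope', 'lower']:.4f}, {self.conf_int().loc['slope', 'upper']:.4f})",
            f"  intercept          {d['intercept']:>10.4f}",
            f"  R^2                {d['r2']:>10.3f}  [{d['category']}]",
            f"  RMSE               {d['rmse']:>10.4f}",
            f"  slope p-value      {d['p_slope']:>10.2e}{' *' if d['significant'] else ''}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, **scatter_kw):
        """Scatter of plots with the fitted line (matplotlib axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.model.x, self.model.y, s=12, alpha=0.6, **scatter_kw)
        xs = np.linspace(self.model.x.min(), self.model.x.max(), 50)
        ax.plot(xs, self.predict(xs), color="crimson",
                label=f"$R^2$={self.rsquared:.2f}, RMSE={self.rmse:.2f}")
        ax.set_xlabel(f"{self.model.vi_name} ({self.model.scenario})")
        ax.set_ylabel(self.model.phenotype_name)
        ax.legend()
        return ax


def scan_models(
    scenario_tables: dict[str, pd.DataFrame],
    phenotypes: pd.DataFrame,
    vis: tuple[str, ...] | None = None,
    phenotype_names: tuple[str, ...] = ("biomass", "sugar", "ethanol"),
) -> pd.DataFrame:
    """Fit the full grid of VI x scenario x phenotype regressions.

    ``scenario_tables`` maps scenario labels (e.g. ``"TS1@143"``,
    ``"TS2"``, ``"TS3"``) to plot-level VI tables.  VI columns that are
    entirely missing in a table are skipped with a log message.  Returns
    one row per fitted model, sorted by phenotype then descending R^2.
    """
    from .indices import VI_NAMES

    rows = []
    for scen, table in scenario_tables.items():
        names = vis or tuple(c for c in VI_NAMES if c in table.columns)
        for vi in names:
            if vi not in table.columns or table[vi].dropna().empty:
                log.warning("scenario %s: VI %s entirely missing; skipped", scen, vi)
                continue
            for ph in phenotype_names:
                try:
                    res = VIPhenotypeModel.from_tables(table, phenotypes, vi, ph, scenario=scen).fit()
                except ValueError as err:
                    log.warning("scenario %s, %s vs %s: %s", scen, vi, ph, err)
                    continue
                rows.append(res.to_dict())
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values(["phenotype", "r2"], ascending=[True, False]).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# species-level ANOVA with compact letter display


@dataclass
class AnovaResult:
    """One-way ANOVA across species with Tukey HSD grouping letters."""

    table: pd.DataFrame  # species, n, mean, letters (sorted by mean desc)
    f_statistic: float
    p_value: float
    alpha: float = 0.05

    def __str__(self) -> str:
        head = f"One-way ANOVA: F = {self.f_statistic:.3f}, p = {self.p_value:.3g}\n"
        return head + self.table.to_string(index=False)


def _compact_letters(groups: list[str], distinct: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``groups`` are ordered by descending mean; ``distinct`` holds pairs
    that are significantly different.  Groups sharing a letter are not
    significantly different; the highest mean gets letter 'a'.
    """
    columns: list[set[str]] = [set(groups)]
    for i, j in distinct:
        for col in list(columns):
            if i in col and j in col:
                columns.remove(col)
                a, b = col - {i}, col - {j}
                for new in (a, b):
                    if new and not any(new <= other for other in columns):
                        columns.append(new)
    # absorb: drop columns contained in others
    columns = [c for c in columns if not any(c < other for other in columns)]
    order = {g: k for k, g in enumerate(groups)}
    columns.sort(key=lambda c: min(order[g] for g in c))
    letters = {g: "" for g in groups}
    for idx, col in enumerate(columns):
        for g in col:
            letters[g] += chr(ord("a") + idx)
    return {g: "".join(sorted(s)) for g, s in letters.items()}


def species_anova(values, labels, alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA of a plot-level variable across species.

    Species with fewer than two plots are excluded with a warning.
    Pairwise comparisons use Tukey's HSD at ``alpha``; letters follow
    the compact letter display convention with 'a' on the highest mean.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "species": np.asarray(labels)})
    df = df.dropna()
    counts = df["species"].value_counts()
    small = counts[counts < 2].index.tolist()
    if small:
        warnings.warn(f"species with < 2 plots excluded from ANOVA: {small}", stacklevel=2)
        df = df[~df["species"].isin(small)]
    species = sorted(df["species"].unique())
    if len(species) < 2:
        raise ValueError("need at least 2 species with >= 2 plots each")

    samples = [df.loc[df["species"] == s, "value"].to_numpy() for s in species]
    f_stat, p_val = stats.f_oneway(*samples)

    means = df.groupby("species")["value"].mean().sort_values(ascending=False)
    ordered = list(means.index)
    if len(species) == 2:
        distinct = {(ordered[0], ordered[1])} if p_val < alpha else set()
    else:
        tk = pairwise_tukeyhsd(df["value"].to_numpy(), df["species"].to_numpy(), alpha=alpha)
        from itertools import combinations

        distinct = {
            (str(g1), str(g2))
            for (g1, g2), rej in zip(combinations(tk.groupsunique, 2), tk.reject)
            if bool(rej)
        }
    letters = _compact_letters(ordered, distinct)
    table = pd.DataFrame(
        {
            "species": ordered,
            "n": [int(counts[s]) for s in ordered],
            "mean": [float(means[s]) for s in ordered],
            "letters": [letters[s] for s in ordered],
        }
    )
    return AnovaResult(table=table, f_statistic=float(f_stat), p_value=float(p_val), alpha=alpha)


# ---------------------------------------------------------------------------
# accession ranking


@dataclass
class RankingResult:
    """Accessions ordered by model-predicted phenotype value.

    ``table`` has one row per accession: predicted mean (descending),
    observed mean, and rank 1..n.  ``rmse`` is the plot-level prediction
    RMSE of the underlying model.
    """

    table: pd.DataFrame
    rmse: float
    vi_name: str
    scenario: str
    phenotype_name: str

    def spearman(self, column: str = "observed_mean") -> float:
        """Spearman correlation between predicted ranking and a reference column."""
        rho, _ = stats.spearmanr(self.table["predicted_mean"], self.table[column])
        return float(rho)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        ax.scatter(self.table["predicted_mean"], self.table["observed_mean"], s=14)
        ax.set_xlabel(f"predicted {self.phenotype_name} ({self.vi_name}, {self.scenario})")
        ax.set_ylabel(f"observed {self.phenotype_name}")
        return ax


def rank_accessions(
    results: VIPhenotypeResults,
    scenario_table: pd.DataFrame,
    phenotypes: pd.DataFrame,
) -> RankingResult:
    """Rank accessions by the mean model-predicted phenotype.

    Plot-level predictions from the fitted model are averaged per
    accession across blocks and sorted descending (ties broken by
    accession id).  Observed accession means are attached for
    validation; accessions with no non-missing plots are omitted with a
    log message.
    """
    vi = results.model.vi_name
    col = PHENOTYPE_COLUMNS.get(results.model.phenotype_name, results.model.phenotype_name)
    merged = scenario_table.drop(columns=[col], errors="ignore").merge(
        phenotypes[["plot_id", col]], on="plot_id", how="left"
    )
    if "accession_id" not in merged.columns:
        raise KeyError("scenario_table needs an accession_id column for ranking")
    merged["predicted"] = results.predict(merged[vi].to_numpy())

    rows = []
    for acc, grp in merged.groupby("accession_id", sort=True):
        pred = grp["predicted"].dropna()
        if pred.empty:
            log.warning("accession %s: no non-missing plots; omitted from ranking", acc)
            continue
        rows.append(
            {
                "accession_id": acc,
                "species": grp["species"].iloc[0] if "species" in grp else None,
                "n_plots": int(pred.size),
                "predicted_mean": float(pred.mean()),
                "observed_mean": float(grp[col].mean()),
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["predicted_mean", "accession_id"], ascending=[False, True]
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return RankingResult(
        table=table,
        rmse=results.rmse,
        vi_name=vi,
        scenario=results.model.scenario,
        phenotype_name=results.model.phenotype_name,
    )
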