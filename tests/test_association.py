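import numpy as np
import pandas as pd
import pytest
from scipy import stats

from uavpheno.association import (
    VIPhenotypeModel,
    categorize_r2,
    rank_accessions,
    scan_models,
    species_anova,
)


def closed_form_ols(x, y):
    """Normal-equations oracle computed with plain Python sums."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = [yi - intercept - slope * xi for xi, yi in zip(x, y)]
    rmse = (sum(r * r for r in resid) / n) ** 0.5
    ybar = sy / n
    ss_tot = sum((yi - ybar) ** 2 for yi in y)
    r2 = 1 - sum(r * r for r in resid) / ss_tot
    return slope, intercept, r2, rmse


class TestFit:
    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        res = VIPhenotypeModel(x, 2 * x + 1).fit()
        assert res.slope == pytest.approx(2.0, abs=1e-10)
        assert res.intercept == pytest.approx(1.0, abs=1e-10)
        assert res.rsquared == pytest.approx(1.0, abs=1e-12)
        assert res.rmse == pytest.approx(0.0, abs=1e-10)

    def test_constant_response_has_zero_r2(self):
        res = VIPhenotypeModel(np.arange(6.0), np.full(6, 3.0)).fit()
        assert res.rsquared == pytest.approx(0.0, abs=1e-12)

    def test_five_point_set_matches_normal_equations(self):
        x = [0.2, 0.5, 0.9, 1.3, 2.0]
        y = [1.1, 0.8, 1.9, 2.4, 3.1]
        res = VIPhenotypeModel(np.array(x), np.array(y)).fit()
        slope, intercept, r2, rmse = closed_form_ols(x, y)
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.intercept == pytest.approx(intercept, abs=1e-10)
        assert res.rsquared == pytest.approx(r2, abs=1e-10)
        assert res.rmse == pytest.approx(rmse, abs=1e-10)

    def test_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        res = VIPhenotypeModel(x, y).fit()
        r, _ = stats.pearsonr(x, y)
        assert res.rsquared == pytest.approx(r**2, abs=1e-12)

    def test_pairwise_missing_dropped(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([1.0, np.nan, 3.0, 4.0, 5.0])
        m = VIPhenotypeModel(x, y)
        assert m.x.size == 3

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            VIPhenotypeModel(np.ones(5), np.arange(5.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            VIPhenotypeModel(np.array([1.0, 2.0]), np.array([1.0, 2.0]))

    def test_r2_invariant_under_affine_x_rescale(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        a = VIPhenotypeModel(x, y).fit()
        b = VIPhenotypeModel(3.0 * x - 7.0, y).fit()
        assert a.rsquared == pytest.approx(b.rsquared, abs=1e-12)
        assert a.rmse == pytest.approx(b.rmse, abs=1e-12)


def test_category_thresholds_are_inclusive_at_boundaries():
    assert categorize_r2(0.49) == "low"
    assert categorize_r2(0.50) == "moderate"
    assert categorize_r2(0.5999) == "moderate"
    assert categorize_r2(0.60) == "high"


def test_slope_ci_covers_truth_at_nominal_rate():
    """95% CI coverage of a planted slope over 500 seeded replicates."""
    rng = np.random.default_rng(77)
    n, slope_true = 234, 2.5
    hits = 0
    for _ in range(500):
        x = rng.uniform(0.2, 0.8, size=n)
        y = 1.0 + slope_true * x + rng.normal(0, 0.5, size=n)
        ci = VIPhenotypeModel(x, y).fit().conf_int().loc["slope"]
        hits += ci["lower"] <= slope_true <= ci["upper"]
    assert hits / 500 == pytest.approx(0.95, abs=0.025)


class TestScan:
    def test_grid_cardinality(self):
        rng = np.random.default_rng(3)
        plots = [f"p{i}" for i in range(20)]
        tables = {
            scen: pd.DataFrame({"plot_id": plots, "NDVI": rng.uniform(0.2, 0.8, 20)})
            for scen in ("TS2", "TS3")
        }
        phen = pd.DataFrame({"plot_id": plots, "biomass_kg_m2": rng.uniform(0.3, 1.2, 20)})
        out = scan_models(tables, phen, vis=("NDVI",), phenotype_names=("biomass",))
        assert len(out) == 2

    def test_all_missing_vi_column_skipped(self):
        plots = [f"p{i}" for i in range(10)]
        tables = {"TS3": pd.DataFrame({"plot_id": plots, "NDVI": np.nan,
                                       "ExG": np.linspace(0.1, 0.5, 10)})}
        phen = pd.DataFrame({"plot_id": plots, "biomass_kg_m2": np.linspace(0.4, 1.0, 10)})
        out = scan_models(tables, phen, vis=("NDVI", "ExG"), phenotype_names=("biomass",))
        assert set(out["vi"]) == {"ExG"}

    def test_planted_nir_biomass_signal_tops_the_scan(self, scenario_tables, phenotypes):
        from uavpheno.indices import NIR_VIS

        out = scan_models(scenario_tables, phenotypes)
        best_biomass = out[out["phenotype"] == "biomass"].iloc[0]
        assert best_biomass["vi"] in NIR_VIS
        best_sugar = out[out["phenotype"] == "sugar"].iloc[0]
        assert best_sugar["vi"] in {"ExG", "VIgreen", "TCI"}


class TestAnova:
    def test_well_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(4)
        vals = np.concatenate([rng.normal(10, 0.1, 10), rng.normal(0, 0.1, 10)])
        labs = ["hi"] * 10 + ["lo"] * 10
        res = species_anova(vals, labs)
        t = res.table.set_index("species")
        assert t.loc["hi", "letters"] == "a"
        assert t.loc["lo", "letters"] == "b"

    def test_identical_groups_share_a_letter(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(1, 0.5, 12), rng.normal(1, 0.5, 12)])
        labs = ["x"] * 12 + ["y"] * 12
        res = species_anova(vals, labs)
        assert set(res.table["letters"]) == {"a"}

    def test_table4_like_means_isolate_lowest_species(self):
        """Four species at realistic ethanol means, tiny spread: the
        lowest species is alone in the last letter class."""
        means = {"T. aestivum": 3.49, "T. durum": 4.14, "H. vulgare": 4.21,
                 "x Triticosecale": 2.54}
        rng = np.random.default_rng(6)
        vals, labs = [], []
        for sp, mu in means.items():
            vals.extend(rng.normal(mu, 0.01, 12))
            labs.extend([sp] * 12)
        res = species_anova(np.array(vals), labs)
        t = res.table.set_index("species")
        last_letter = max("".join(t["letters"]))
        in_last = [sp for sp, row in t.iterrows() if last_letter in row["letters"]]
        assert in_last == ["x Triticosecale"]
        assert t.loc["H. vulgare", "letters"] == "a"
        # verified against an independent Tukey run
        tuk = stats.tukey_hsd(*[np.array(vals)[np.array(labs) == sp] for sp in means])
        assert (tuk.pvalue < 0.05).sum() == len(means) * (len(means) - 1)  # all pairs differ

    def test_tiny_species_excluded_with_warning(self):
        vals = [1.0, 1.1, 1.2, 5.0, 5.1, 9.0]
        labs = ["a", "a", "a", "b", "b", "c"]
        with pytest.warns(UserWarning, match="c"):
            res = species_anova(vals, labs)
        assert set(res.table["species"]) == {"a", "b"}


class TestRanking:
    def test_perfect_model_reproduces_observed_ranking(self, scenario_tables, phenotypes):
        table = scenario_tables["TS3"][["plot_id", "accession_id", "species"]].copy()
        merged = table.merge(phenotypes[["plot_id", "ethanol_yield_m3_ha"]], on="plot_id")
        merged["NDVI"] = merged["ethanol_yield_m3_ha"] / 10.0  # perfect predictor
        res = VIPhenotypeModel.from_tables(merged, phenotypes, "NDVI", "ethanol",
                                           scenario="TS3").fit()
        assert res.rsquared == pytest.approx(1.0, abs=1e-12)
        ranking = rank_accessions(res, merged, phenotypes)
        obs_sorted = ranking.table.sort_values("observed_mean", ascending=False)
        assert list(ranking.table["accession_id"]) == list(obs_sorted["accession_id"])
        assert ranking.spearman() == pytest.approx(1.0)

    def test_ranks_are_a_permutation(self, scenario_tables, phenotypes):
        res = VIPhenotypeModel.from_tables(
            scenario_tables["TS3"], phenotypes, "NDVI", "ethanol", scenario="TS3"
        ).fit()
        ranking = rank_accessions(res, scenario_tables["TS3"], phenotypes)
        assert sorted(ranking.table["rank"]) == list(range(1, len(ranking.table) + 1))

    def test_single_accession_rank_list(self):
        plots = pd.DataFrame({
            "plot_id": ["p1", "p2", "p3"], "accession_id": ["A", "A", "A"],
            "species": ["s", "s", "s"], "NDVI": [0.3, 0.5, 0.7],
        })
        phen = pd.DataFrame({"plot_id": ["p1", "p2", "p3"],
                             "ethanol_yield_m3_ha": [2.0, 3.0, 4.0]})
        res = VIPhenotypeModel.from_tables(plots, phen, "NDVI", "ethanol", scenario="x").fit()
        ranking = rank_accessions(res, plots, phen)
        assert len(ranking.table) == 1 and ranking.table.loc[0, "rank"] == 1

    def test_moderate_noise_ranking_recovery(self, scenario_tables, phenotypes):
        """Best NDVI model recovers the accession ordering (rho >= 0.8)."""
        res = VIPhenotypeModel.from_tables(
            scenario_tables["TS2"], phenotypes, "NDVI", "ethanol", scenario="TS2"
        ).fit()
        ranking = rank_accessions(res, scenario_tables["TS2"], phenotypes)
        assert ranking.spearman() >= 0.8
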