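"""Three-step quality control: rules, Holm outliers, weather-index years."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from histphen.data import HistoricalDataset
from histphen.qc import (
    PlausibilityRuleSet,
    detect_outliers,
    fit_weather_index,
    flag_outlier_years,
    outlier_pass,
    plausibility_filter,
    qc_pipeline,
    winter_wheat_rules,
    year_cv,
)
from histphen.reml import ModelSpec, fit
from histphen.simulate import (
    GeneratorConfig,
    inject_outliers,
    simulate,
    _simulate_weather,
)


def _toy_ds():
    phen = pd.DataFrame(
        {
            "accession": ["A1", "A2", "A3", "A4"],
            "year": [1990, 1990, 1990, 1990],
            "trait": "FT",
            "value": [150.0, 400.0, 155.0, 160.0],
            "sowing_date": ["1989-10-15", "1989-10-15", "1989-05-01", "1989-10-15"],
            "taxon": [
                "Triticum aestivum",
                "Triticum aestivum",
                "Triticum aestivum",
                "Triticum durum",
            ],
        }
    )
    passport = pd.DataFrame(
        {
            "accession": ["A1", "A2", "A3", "A4"],
            "origin_country": "DEU",
            "acquisition_year": 1950,
            "available": True,
        }
    )
    return HistoricalDataset(phenotypes=phen, passport=passport)


class TestPlausibility:
    def test_rules_applied_in_order_with_first_rule_id(self):
        ds = _toy_ds()
        clean, decisions = plausibility_filter(ds, winter_wheat_rules())
        assert decisions["rule"].tolist() == ["", "bounds[FT]", "sowing_time", "taxon"]
        assert clean.n_records == 1

    def test_idempotence_on_conforming_data(self, small_dataset):
        ds, _, _ = small_dataset
        clean, decisions = plausibility_filter(ds, winter_wheat_rules())
        assert decisions["keep"].all()
        again, decisions2 = plausibility_filter(clean, winter_wheat_rules())
        assert again.n_records == clean.n_records

    def test_unavailable_accessions_dropped_when_required(self):
        ds = _toy_ds()
        ds.passport.loc[0, "available"] = False
        _, decisions = plausibility_filter(
            ds, PlausibilityRuleSet(require_available=True)
        )
        assert decisions["rule"].tolist()[0] == "availability"

    def test_unbounded_trait_kept(self):
        ds = _toy_ds()
        rules = PlausibilityRuleSet(trait_bounds={"PH": (20.0, 200.0)})
        clean, _ = plausibility_filter(ds, rules)
        assert clean.n_records == 4  # FT has no bounds configured -> kept

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            PlausibilityRuleSet(trait_bounds={"FT": (220.0, 100.0)})


def _holm_bruteforce(p, alpha):
    """Independent oracle: textbook Holm step-down."""
    order = np.argsort(p)
    reject = np.zeros(len(p), dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (len(p) - rank):
            reject[idx] = True
        else:
            break
    return reject


class TestHolmOutliers:
    def test_single_contaminant_among_null_residuals(self):
        rng = np.random.default_rng(123)
        t = np.concatenate([rng.standard_normal(100), [10.0]])
        table = detect_outliers(t, alpha=0.05)
        assert table["flag"].sum() == 1
        assert table["flag"].iloc[-1]
        # agreement with the brute-force Holm oracle on the same p-values
        p = 2 * stats.norm.sf(np.abs(t))
        np.testing.assert_array_equal(table["flag"], _holm_bruteforce(p, 0.05))

    def test_matches_bruteforce_on_random_pvalues(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            t = rng.standard_normal(50) * rng.uniform(0.5, 3)
            p = 2 * stats.norm.sf(np.abs(t))
            table = detect_outliers(t, alpha=0.1)
            np.testing.assert_array_equal(table["flag"], _holm_bruteforce(p, 0.1))

    def test_all_zero_residuals_never_flag(self):
        table = detect_outliers(np.zeros(40), alpha=0.05)
        assert not table["flag"].any()

    def test_flags_invariant_to_record_order(self):
        rng = np.random.default_rng(5)
        t = np.concatenate([rng.standard_normal(60), [6.0, -7.0]])
        flags = detect_outliers(t, 0.05)["flag"].to_numpy()
        perm = rng.permutation(len(t))
        flags_perm = detect_outliers(t[perm], 0.05)["flag"].to_numpy()
        np.testing.assert_array_equal(flags_perm, flags[perm])

    def test_alpha_domain(self):
        with pytest.raises(ValueError):
            detect_outliers(np.zeros(3), alpha=1.5)

    def test_outlier_pass_bookkeeping_and_recall(self, full_grid_dataset):
        ds, truth, _ = full_grid_dataset
        contaminated, flags = inject_outliers(
            ds, 0.01, 8.0, seed=31, sigma2_by_year=truth.sigma2_e_by_year
        )
        result = outlier_pass(contaminated, "FT", alpha=0.05)
        n = contaminated.n_records
        assert result.removed_fraction == pytest.approx(
            result.decisions["flag"].sum() / n
        )
        detected = result.decisions.index[result.decisions["flag"]]
        true_idx = flags.index[flags]
        recall = len(set(detected) & set(true_idx)) / max(len(true_idx), 1)
        false_frac = len(set(detected) - set(true_idx)) / n
        assert recall >= 0.9
        assert false_frac <= 0.001
        # removing gross errors shrinks the pooled residual variance
        assert result.fit_after.mean_residual_variance(
            weighted=True
        ) < result.fit_before.mean_residual_variance(weighted=True)


class TestYearCV:
    def test_cv_definition_and_consistency(self, full_grid_dataset):
        ds, _, _ = full_grid_dataset
        res = fit(
            ds.for_trait("FT").reset_index(drop=True),
            ModelSpec.historical_year_effects(heterogeneous=True),
        )
        cv = year_cv(res)
        ye = res.fixed_estimates["year"]["estimate"]
        for year in cv.index:
            assert cv[year] == pytest.approx(
                np.sqrt(res.residual_variances[year]) / ye[year]
            )
        assert (cv > 0).all()

    def test_negative_year_level_is_undefined(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "accession": np.repeat([f"A{i}" for i in range(20)], 3),
                "year": np.tile([1, 2, 3], 20),
                "value": rng.normal(-50.0, 2.0, 60),
            }
        )
        res = fit(df, ModelSpec(fixed=("year",), random=("accession",),
                                residual_by="year"))
        with pytest.raises(ValueError, match="CV undefined"):
            year_cv(res)


class TestWeatherIndex:
    def _weather(self, years, seed=0):
        rng = np.random.default_rng(seed)
        return _simulate_weather(list(years), rng)

    def test_known_driver_selected_first_with_positive_sign(self):
        years = range(1970, 2000)
        weather = self._weather(years, seed=1)
        april = weather[weather["month"] == 4].set_index("year")["rainfall"]
        z = (april - april.mean()) / april.std(ddof=1)
        rng = np.random.default_rng(2)
        ye = 0.8 * z + 0.1 * rng.standard_normal(len(z))
        model = fit_weather_index(ye, weather)
        assert model.selected_terms[0] == (4, "rainfall")
        assert model.coefficients["rainfall_04"] > 0
        assert model.r_squared > 0.9

    def test_zero_variance_predictor_never_selected(self):
        years = range(1980, 2000)
        weather = self._weather(years, seed=3)
        weather.loc[weather["month"] == 7, "humidity"] = 70.0  # constant
        rng = np.random.default_rng(4)
        ye = pd.Series(rng.standard_normal(20), index=list(years))
        model = fit_weather_index(ye, weather)
        assert (7, "humidity") not in model.selected_terms

    def test_pure_noise_rarely_retains_terms(self):
        years = list(range(1975, 2000))
        hits = 0
        for seed in range(10):
            weather = self._weather(years, seed=seed)
            rng = np.random.default_rng(1000 + seed)
            ye = pd.Series(rng.standard_normal(len(years)), index=years)
            model = fit_weather_index(ye, weather)
            if not model.selected_terms:
                hits += 1
        assert hits >= 9

    def test_overfit_guard(self):
        years = range(1990, 2000)
        weather = self._weather(years, seed=5)
        ye = pd.Series(np.arange(10.0), index=list(years))
        with pytest.raises(ValueError, match="overfit"):
            fit_weather_index(ye, weather, max_terms=9)
        with pytest.raises(ValueError, match="need >="):
            fit_weather_index(ye.iloc[:5], weather)


class TestFlagOutlierYears:
    def test_identical_years_not_flagged(self):
        cv = pd.Series(0.02, index=range(1990, 2000))
        w = pd.Series(0.0, index=range(1990, 2000))
        table = flag_outlier_years(cv, w)
        assert not table["flag"].any()

    def test_conjunction_requires_both_criteria(self):
        years = list(range(1990, 2000))
        cv = pd.Series(0.02, index=years)
        cv[1995] = 0.09  # strongly inflated CV
        rng = np.random.default_rng(1)
        w = pd.Series(rng.standard_normal(10) * 0.5, index=years)
        table = flag_outlier_years(cv, w)
        assert table.loc[1995, "cv_inflated"]
        assert not table.loc[1995, "flag"]  # weather unremarkable
        w[1995] = 30.0
        table = flag_outlier_years(cv, w)
        assert table.loc[1995, "flag"]
        assert table["flag"].sum() == 1

    def test_needs_three_years(self):
        with pytest.raises(ValueError):
            flag_outlier_years(pd.Series([0.1, 0.2]), pd.Series([0.0, 1.0]))


class TestPipeline:
    def test_empty_dataset_is_a_no_op(self):
        ds = HistoricalDataset(phenotypes=pd.DataFrame(columns=["accession", "year", "trait", "value"]))
        clean, report = qc_pipeline(ds, "FT")
        assert clean.n_records == 0
        assert report.counts["input"] == 0

    def test_clean_data_survives_nearly_untouched(self):
        cfg = GeneratorConfig(
            n_accessions=150, years=tuple(range(1985, 2000)),
            years_observed_per_block=5, seed=77,
        )
        ds, _ = simulate(cfg)
        clean, report = qc_pipeline(ds, "FT")
        assert report.counts["output"] / report.counts["input"] >= 0.998
        assert report.h2_after == pytest.approx(report.h2_before, abs=0.02)

    def test_fractions_are_exact_count_ratios(self, full_grid_dataset):
        ds, truth, _ = full_grid_dataset
        contaminated, _ = inject_outliers(
            ds, 0.02, 8.0, seed=13, sigma2_by_year=truth.sigma2_e_by_year
        )
        clean, report = qc_pipeline(contaminated, "FT", min_years_for_step3=99)
        c = report.counts
        assert c["input"] - c["step1_removed"] - c["step2_removed"] - c["step3_removed"] == c["output"]
        assert report.fractions["step2"] == pytest.approx(
            c["step2_removed"] / (c["input"] - c["step1_removed"])
        )
        assert clean.n_records == c["output"]

    def test_report_serializes(self, tmp_path, full_grid_dataset):
        ds, _, _ = full_grid_dataset
        _, report = qc_pipeline(ds, "FT", min_years_for_step3=99)
        out = tmp_path / "qc.json"
        report.to_json(out)
        import json

        payload = json.loads(out.read_text())
        assert payload["schema_version"] == 1
        assert payload["counts"]["input"] == report.counts["input"]
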