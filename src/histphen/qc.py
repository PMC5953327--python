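"""Three-step quality control for historical regeneration phenotypes.

Step 1 -- plausibility: rule-based screening that only records from the
intended taxa, autumn sowing windows and physiologically possible trait
ranges enter the statistical analysis.

Step 2 -- record-level outliers: studentized residuals from the mixed model
(fixed accession, random year, year-specific residual variances) tested
against the standard normal, with Bonferroni-Holm control of the
family-wise error rate across all records of a trait.  Flagged records are
removed and the model refitted once.

Step 3 -- year-level outliers: the coefficient of variation of the
year-specific error variance, CV_j = sqrt(sigma2_e*j) / YE_j, is compared
with an aggregated weather-parameter index (a stepwise regression of year
effects on standardized monthly weather variables).  A year is excluded
only when its CV is inflated *and* its weather index is anomalous --
statistical noise alone never removes a season.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import HistoricalDataset
from .reml import (
    FitOptions,
    FitResult,
    ModelSpec,
    estimate_components,
    fit,
    heritability,
    studentized_residuals,
)

__all__ = [
    "PlausibilityRuleSet",
    "winter_wheat_rules",
    "QCReport",
    "WeatherIndexModel",
    "plausibility_filter",
    "detect_outliers",
    "outlier_pass",
    "year_cv",
    "fit_weather_index",
    "flag_outlier_years",
    "qc_pipeline",
]


# ---------------------------------------------------------------------------
# step 1: plausibility rules


@dataclass(frozen=True)
class PlausibilityRuleSet:
    """Configurable record-plausibility rules.

    ``trait_bounds`` maps trait labels to inclusive (min, max) physiological
    limits; ``sowing_window`` is a day-of-year interval (autumn sowing);
    ``allowed_taxa`` restricts the taxon field; ``require_available`` drops
    records of accessions flagged unavailable in the passport.
    Rules are applied in the order taxon, availability, sowing, bounds and a
    record carries the first violated rule id.
    """

    allowed_taxa: Optional[tuple[str, ...]] = None
    sowing_window: Optional[tuple[int, int]] = None
    trait_bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    require_available: bool = False
    drop_missing_taxon: bool = False

    def __post_init__(self) -> None:
        for trait, (lo, hi) in self.trait_bounds.items():
            if not lo < hi:
                raise ValueError(f"trait_bounds for {trait!r}: min must be < max")


def winter_wheat_rules() -> PlausibilityRuleSet:
    """Default rules for autumn-sown hexaploid winter wheat regeneration data.

    Bounds: FT 100-220 d after Jan 1, PH 20-200 cm, TGW 10-80 g; sowing
    between September 1 (day 244) and November 30 (day 334).
    """
    return PlausibilityRuleSet(
        allowed_taxa=("Triticum aestivum",),
        sowing_window=(244, 334),
        trait_bounds={"FT": (100.0, 220.0), "PH": (20.0, 200.0), "TGW": (10.0, 80.0)},
        require_available=True,
    )


def _sowing_doy(dates: pd.Series) -> pd.Series:
    parsed = pd.to_datetime(dates, errors="coerce", format="ISO8601")
    return parsed.dt.dayofyear


def plausibility_filter(
    ds: HistoricalDataset, rules: PlausibilityRuleSet
) -> tuple[HistoricalDataset, pd.DataFrame]:
    """Apply the plausibility rules; returns (clean dataset, decision table).

    The decision table is record-aligned with columns ``keep`` and ``rule``
    (the first violated rule id, empty when kept).  Applying the filter to
    its own output changes nothing (idempotence).  Traits present in the
    data but absent from ``trait_bounds`` only trigger a warning column,
    never a drop.
    """
    phen = ds.phenotypes
    rule = pd.Series("", index=phen.index, dtype=object)

    if rules.allowed_taxa is not None:
        taxa = phen["taxon"]
        bad = ~taxa.isin(rules.allowed_taxa)
        if not rules.drop_missing_taxon:
            bad &= taxa.notna()
        rule[bad & (rule == "")] = "taxon"

    if rules.require_available and ds.passport is not None:
        avail = ds.passport.set_index("accession")["available"]
        bad = ~phen["accession"].map(avail).fillna(False).astype(bool)
        rule[bad & (rule == "")] = "availability"

    if rules.sowing_window is not None:
        doy = _sowing_doy(phen["sowing_date"])
        lo, hi = rules.sowing_window
        bad = doy.notna() & ((doy < lo) | (doy > hi))
        rule[bad & (rule == "")] = "sowing_time"

    if rules.trait_bounds:
        for trait, (lo, hi) in rules.trait_bounds.items():
            sel = phen["trait"] == trait
            bad = sel & ((phen["value"] < lo) | (phen["value"] > hi))
            rule[bad & (rule == "")] = f"bounds[{trait}]"

    decisions = pd.DataFrame({"keep": rule == "", "rule": rule}, index=phen.index)
    clean = ds.replace_phenotypes(phen[decisions["keep"]])
    return clean, decisions


# ---------------------------------------------------------------------------
# step 2: studentized-residual outliers with Bonferroni-Holm


def detect_outliers(
    result_or_residuals: "FitResult | pd.Series | np.ndarray", alpha: float = 0.05
) -> pd.DataFrame:
    """Holm step-down outlier test on studentized residuals.

    Two-sided p-values come from the standard normal reference; the family
    is the full set of records entering the fit.  Returns a record-aligned
    table with columns ``studentized``, ``p``, ``p_adjusted``, ``flag``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if isinstance(result_or_residuals, FitResult):
        t = studentized_residuals(result_or_residuals)
    else:
        t = pd.Series(np.asarray(result_or_residuals, dtype=float))
    p = 2.0 * stats.norm.sf(np.abs(t.to_numpy()))
    if len(p) == 0:
        return pd.DataFrame(columns=["studentized", "p", "p_adjusted", "flag"])
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return pd.DataFrame(
        {"studentized": t.to_numpy(), "p": p, "p_adjusted": p_adj, "flag": reject},
        index=t.index,
    )


@dataclass
class OutlierPassResult:
    clean: HistoricalDataset
    decisions: pd.DataFrame
    fit_before: FitResult
    fit_after: FitResult
    removed_fraction: float


def outlier_pass(
    ds: HistoricalDataset,
    trait: str,
    alpha: float = 0.05,
    heterogeneous: bool = True,
    options: FitOptions = FitOptions(),
) -> OutlierPassResult:
    """Single outlier pass: fit, flag, remove, refit once.

    Uses the BLUE model (fixed accession, random year).  Returns the cleaned
    dataset together with the before/after fits so variance-component deltas
    can be compared.
    """
    df = ds.for_trait(trait)
    before = fit(df.reset_index(drop=True), ModelSpec.historical_blues(heterogeneous), options)
    table = detect_outliers(before, alpha)
    table.index = df.index
    kept_idx = df.index[~table["flag"].to_numpy()]
    phen = ds.phenotypes
    clean = ds.replace_phenotypes(
        phen[(phen["trait"] != trait) | (phen.index.isin(kept_idx))]
    )
    after = fit(
        clean.for_trait(trait).reset_index(drop=True),
        ModelSpec.historical_blues(heterogeneous),
        options,
    )
    return OutlierPassResult(
        clean=clean,
        decisions=table,
        fit_before=before,
        fit_after=after,
        removed_fraction=float(table["flag"].mean()),
    )


# ---------------------------------------------------------------------------
# step 3: year-level CV and weather-parameter index


def year_cv(result: FitResult, year_factor: str = "year") -> pd.Series:
    """CV_j = sqrt(sigma2_e*j) / YE_j per year from a heterogeneous fit.

    ``result`` must come from a model with fixed year effects (cell means,
    so YE_j is the expected trait level of year j) and year-grouped residual
    variances.  Raises when any YE_j <= 0, where the CV is undefined.
    """
    if year_factor not in result.fixed_estimates:
        raise ValueError(
            f"fit has no fixed {year_factor!r} effects; use the year-effect model"
        )
    ye = result.fixed_estimates[year_factor]["estimate"]
    if (ye <= 0).any():
        bad = list(ye.index[ye <= 0])
        raise ValueError(f"year effects <= 0 for {bad}; CV undefined")
    s2 = pd.Series(result.residual_variances)
    cv = np.sqrt(s2.reindex(ye.index).astype(float)) / ye
    cv.name = "cv"
    return cv


@dataclass
class WeatherIndexModel:
    """Forward-stepwise weather regression of year effects."""

    selected_terms: list[tuple[int, str]]  # (month, variable)
    coefficients: dict[str, float]  # term label -> coefficient (standardized scale)
    intercept: float
    r_squared: float
    index: pd.Series  # year -> fitted weather index W_j
    criterion: str = "aicc"

    def __post_init__(self) -> None:
        if not 0 <= self.r_squared <= 1:
            raise ValueError("r_squared outside [0, 1]")


def _weather_predictors(weather: pd.DataFrame, years: Sequence[int]) -> pd.DataFrame:
    from .simulate import _standardized_weather

    zw = _standardized_weather(weather)
    zw = zw.reindex(list(years))
    # predictors with any missing year are excluded from the candidate set
    zw = zw.dropna(axis=1)
    # re-standardize on the analysis years
    sd = zw.std(ddof=1)
    keep = sd > 0
    zw = (zw.loc[:, keep] - zw.loc[:, keep].mean()) / sd[keep]
    return zw


def _aicc(rss: float, n: int, k: int) -> float:
    # k = number of estimated coefficients incl. intercept
    if n - k - 1 <= 0:
        return np.inf
    return n * np.log(max(rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_weather_index(
    year_effects: "pd.Series | Mapping[int, float]",
    weather: pd.DataFrame,
    *,
    criterion: str = "f_enter",
    alpha_enter: Optional[float] = None,
    max_terms: Optional[int] = None,
    min_years: int = 8,
) -> WeatherIndexModel:
    """Forward-stepwise regression of year effects on standardized weather.

    Candidate predictors are all month x variable combinations with complete
    records over the analysis years, standardized to mean 0 / SD 1.  With
    few years and dozens of candidates, greedy selection chases noise, so
    the default entry rule (``criterion="f_enter"``) admits a term only when
    its partial F-test p-value clears a Bonferroni-corrected threshold
    across the candidate pool (``alpha_enter``, default 0.05 / n_candidates,
    i.e. a per-step family-wise entry level of 0.05);
    ``criterion="aicc"`` instead adds terms while the small-sample
    information criterion decreases.  Selected terms are capped at
    ``n_years // 3`` by default; asking for more than ``n_years - 2`` terms
    is refused outright.  The returned index W_j is the fitted linear
    combination per year.
    """
    ye = pd.Series(dict(year_effects)).astype(float).sort_index()
    n = len(ye)
    if n < min_years:
        raise ValueError(f"need >= {min_years} years with year effects, got {n}")
    if criterion not in ("f_enter", "aicc"):
        raise ValueError("criterion must be 'f_enter' or 'aicc'")
    cap = n - 2
    if max_terms is None:
        max_terms = max(1, min(n // 3, cap))
    if max_terms > cap:
        raise ValueError(f"max_terms={max_terms} exceeds the overfit guard n_years-2={cap}")

    Z = _weather_predictors(weather, ye.index)
    if alpha_enter is None:
        alpha_enter = 0.05 / max(1, Z.shape[1])
    y = ye.to_numpy()
    selected: list[str] = []
    current_cols: list[np.ndarray] = []
    rss0 = float(np.sum((y - y.mean()) ** 2))
    best_crit = _aicc(rss0, n, 1)
    rss_current = rss0

    def rss_with(cols: list[np.ndarray]) -> tuple[float, np.ndarray]:
        X = np.column_stack([np.ones(n)] + cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid), beta

    while len(selected) < max_terms:
        best = None
        for name in Z.columns:
            if name in selected:
                continue
            rss, _ = rss_with(current_cols + [Z[name].to_numpy()])
            crit = _aicc(rss, n, len(selected) + 2)
            if best is None or crit < best[0]:
                best = (crit, name, rss)
        if best is None:
            break
        if criterion == "aicc":
            if best[0] >= best_crit - 1e-12:
                break
        else:
            df_resid = n - len(selected) - 2
            if df_resid <= 0 or best[2] <= 0:
                break
            f_stat = (rss_current - best[2]) / (best[2] / df_resid)
            p_enter = float(stats.f.sf(f_stat, 1, df_resid))
            if p_enter >= alpha_enter:
                break
        best_crit = best[0]
        rss_current = best[2]
        selected.append(best[1])
        current_cols.append(Z[best[1]].to_numpy())

    rss, beta = rss_with(current_cols) if selected else (rss0, np.array([y.mean()]))
    fitted = (
        np.column_stack([np.ones(n)] + current_cols) @ beta if selected
        else np.full(n, y.mean())
    )
    r2 = 1.0 - rss / rss0 if rss0 > 0 else 0.0
    terms = []
    for name in selected:
        var, month = name.rsplit("_", 1)
        terms.append((int(month), var))
    return WeatherIndexModel(
        selected_terms=terms,
        coefficients={name: float(b) for name, b in zip(selected, beta[1:])},
        intercept=float(beta[0]),
        r_squared=float(max(0.0, min(1.0, r2))),
        index=pd.Series(fitted, index=ye.index, name="weather_index"),
    )


def flag_outlier_years(
    cv: pd.Series,
    index: "WeatherIndexModel | pd.Series",
    k_cv: float = 2.0,
    k_weather: float = 3.0,
) -> pd.DataFrame:
    """Conjunction rule for year exclusion.

    A year is flagged when its CV exceeds ``k_cv`` times the mean CV of all
    other years AND its weather index deviates from the other-years mean by
    more than ``k_weather`` of their standard deviations.  Returns a
    per-year table with the two criteria and the final flag.
    """
    if len(cv) < 3:
        raise ValueError("need at least 3 years to flag outlier years")
    w = index.index if isinstance(index, WeatherIndexModel) else index
    w = pd.Series(w).astype(float)
    years = [y for y in cv.index if y in w.index]
    rows = []
    for year in years:
        cv_others = cv.drop(index=year).mean()
        cv_ratio = cv[year] / cv_others if cv_others > 0 else np.inf
        others = w.drop(index=year)
        sd = others.std(ddof=1)
        w_dev = abs(w[year] - others.mean()) / sd if sd > 0 else 0.0
        rows.append(
            {
                "year": year,
                "cv": cv[year],
                "cv_ratio": cv_ratio,
                "weather_index": w[year],
                "weather_dev": w_dev,
                "cv_inflated": cv_ratio > k_cv,
                "weather_anomalous": w_dev > k_weather,
                "flag": (cv_ratio > k_cv) and (w_dev > k_weather),
            }
        )
    return pd.DataFrame(rows).set_index("year")


# ---------------------------------------------------------------------------
# consolidated pipeline


@dataclass
class QCReport:
    """Per-record and per-year decisions of the three QC steps."""

    trait: Optional[str]
    step1: Optional[pd.DataFrame]
    step2: Optional[pd.DataFrame]
    step3: Optional[pd.DataFrame]
    weather_model: Optional[WeatherIndexModel]
    counts: dict[str, int]
    fractions: dict[str, float]
    components_before: dict[str, float]
    components_after: dict[str, float]
    h2_before: Optional[float]
    h2_after: Optional[float]
    flagged_years: list

    SCHEMA_VERSION = 1

    def to_dict(self) -> dict:
        def df_dict(df):
            return None if df is None else json.loads(df.to_json(orient="split"))

        return {
            "schema_version": self.SCHEMA_VERSION,
            "trait": self.trait,
            "counts": self.counts,
            "fractions": self.fractions,
            "components_before": self.components_before,
            "components_after": self.components_after,
            "h2_before": self.h2_before,
            "h2_after": self.h2_after,
            "flagged_years": [int(y) for y in self.flagged_years],
            "weather_terms": (
                None
                if self.weather_model is None
                else {
                    "selected": self.weather_model.selected_terms,
                    "coefficients": self.weather_model.coefficients,
                    "r_squared": self.weather_model.r_squared,
                }
            ),
            "step1": df_dict(self.step1),
            "step2": df_dict(self.step2),
            "step3": df_dict(self.step3),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)


def _empty_report(trait=None) -> QCReport:
    return QCReport(
        trait=trait,
        step1=None,
        step2=None,
        step3=None,
        weather_model=None,
        counts={"input": 0, "step1_removed": 0, "step2_removed": 0, "step3_removed": 0,
                "output": 0},
        fractions={},
        components_before={},
        components_after={},
        h2_before=None,
        h2_after=None,
        flagged_years=[],
    )


def qc_pipeline(
    ds: HistoricalDataset,
    trait: str,
    rules: Optional[PlausibilityRuleSet] = None,
    alpha: float = 0.05,
    k_cv: float = 2.0,
    k_weather: float = 3.0,
    heterogeneous: bool = True,
    options: FitOptions = FitOptions(),
    min_years_for_step3: int = 8,
) -> tuple[HistoricalDataset, QCReport]:
    """Run the three QC steps in order and report every decision.

    Step 3 runs only when a weather table is available and enough years
    remain; otherwise it is skipped and noted in the report.  After the
    final removals the variance-component model (accession and year random)
    is refitted and entry-mean heritabilities before (post-plausibility)
    and after QC are reported.
    """
    if rules is None:
        rules = winter_wheat_rules()
    if ds.n_records == 0 or trait not in ds.traits():
        return ds, _empty_report(trait)

    n_input = len(ds.for_trait(trait))

    # step 1
    step1_ds, step1 = plausibility_filter(ds, rules)
    trait_mask = ds.phenotypes["trait"] == trait
    step1_removed = int((~step1.loc[trait_mask, "keep"]).sum())
    if trait not in step1_ds.traits():
        report = _empty_report(trait)
        report.step1 = step1
        report.counts.update({"input": n_input, "step1_removed": step1_removed})
        return step1_ds, report

    # variance components before record-level cleaning
    comp_before = estimate_components(step1_ds, trait, heterogeneous, options)
    inc_before = step1_ds.for_trait(trait).groupby("accession")["year"].nunique().mean()
    h2_before = heritability(
        comp_before.variance_components["accession"],
        comp_before.mean_residual_variance(),
        float(inc_before),
    )

    # step 2
    pass2 = outlier_pass(step1_ds, trait, alpha, heterogeneous, options)
    step2_removed = int(pass2.decisions["flag"].sum())
    step2_ds = pass2.clean

    # step 3
    step3_table = None
    weather_model = None
    flagged_years: list = []
    step3_removed = 0
    n_years = step2_ds.for_trait(trait)["year"].nunique()
    if ds.weather is not None and n_years >= max(3, min_years_for_step3) and heterogeneous:
        ye_fit = fit(
            step2_ds.for_trait(trait).reset_index(drop=True),
            ModelSpec.historical_year_effects(heterogeneous=True),
            options,
        )
        cv = year_cv(ye_fit)
        ye = ye_fit.fixed_estimates["year"]["estimate"]
        weather_model = fit_weather_index(ye - ye.mean(), ds.weather)
        step3_table = flag_outlier_years(cv, weather_model.index, k_cv, k_weather)
        flagged_years = list(step3_table.index[step3_table["flag"]])
        if flagged_years:
            phen = step2_ds.phenotypes
            drop = (phen["trait"] == trait) & phen["year"].isin(flagged_years)
            step3_removed = int(drop.sum())
            step2_ds = step2_ds.replace_phenotypes(phen[~drop])

    clean_ds = step2_ds
    comp_after = estimate_components(clean_ds, trait, heterogeneous, options)
    inc_after = clean_ds.for_trait(trait).groupby("accession")["year"].nunique().mean()
    h2_after = heritability(
        comp_after.variance_components["accession"],
        comp_after.mean_residual_variance(),
        float(inc_after),
    )

    n_after_step1 = n_input - step1_removed
    n_after_step2 = n_after_step1 - step2_removed
    counts = {
        "input": n_input,
        "step1_removed": step1_removed,
        "step2_removed": step2_removed,
        "step3_removed": step3_removed,
        "output": n_after_step2 - step3_removed,
    }
    fractions = {
        "step1": step1_removed / n_input if n_input else 0.0,
        "step2": step2_removed / n_after_step1 if n_after_step1 else 0.0,
        "step3": step3_removed / n_after_step2 if n_after_step2 else 0.0,
    }
    report = QCReport(
        trait=trait,
        step1=step1,
        step2=pass2.decisions,
        step3=step3_table,
        weather_model=weather_model,
        counts=counts,
        fractions=fractions,
        components_before={
            "sigma2_G": comp_before.variance_components["accession"],
            "sigma2_Y": comp_before.variance_components["year"],
            "sigma2_e": comp_before.mean_residual_variance(),
        },
        components_after={
            "sigma2_G": comp_after.variance_components["accession"],
            "sigma2_Y": comp_after.variance_components["year"],
            "sigma2_e": comp_after.mean_residual_variance(),
        },
        h2_before=h2_before,
        h2_after=h2_after,
        flagged_years=flagged_years,
    )
    return clean_ds, report
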