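"""Synthetic historical regeneration datasets with known ground truth.

The generator draws from the additive model underlying the whole pipeline,

    y_ij = mu + g_i + a_j + e_ij,

with accession effects ``g_i ~ N(origin shift, sigma2_G)``, year effects
composed of a deterministic temporal trend, a weather-driven linear
component and an independent normal term ``N(0, sigma2_Y)``, and residuals
``e_ij ~ N(0, sigma2_e*j)`` whose variances differ between years (log-normal
around ``sigma2_e_mean``).  Defaults are calibrated to a flowering-time-like
trait of a winter wheat collection regenerated over seven decades:
mu = 160 d, sigma2_Y = 72, sigma2_G = 15.6, mean sigma2_e = 6.5, with
roughly 4 regeneration years per accession out of 70 (>= 93 % of the
accession x year matrix empty).

Missingness patterns mirror genebank regeneration practice: whole blocks of
accessions (by origin, or of the same sizes with random membership)
regenerated in a shared subset of years, versus fully independent
(missing-completely-at-random) year subsets per accession.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data import HistoricalDataset, WEATHER_VARIABLES

__all__ = [
    "Origin",
    "GeneratorConfig",
    "Truth",
    "simulate",
    "apply_missingness",
    "inject_outliers",
    "simulate_validation",
    "DEFAULT_SCENARIO_ORIGINS",
    "SCENARIO_YEARS",
    "scenario_config",
]

MISSINGNESS_PATTERNS = ("block_by_origin", "block_random", "mcar", "full")

#: monthly climatology of a central-German regeneration site
#: (mean, SD) per variable; t_min/t_max are offsets from t_avg
_CLIMATE = {
    "rainfall": (
        [35, 30, 35, 40, 52, 62, 55, 52, 40, 35, 40, 45],
        [16, 14, 16, 18, 24, 28, 26, 24, 18, 16, 18, 20],
    ),
    "humidity": (
        [86, 82, 77, 70, 68, 68, 70, 72, 79, 84, 87, 88],
        [4, 4, 5, 6, 6, 6, 6, 6, 5, 4, 4, 4],
    ),
    "t_avg": (
        [0.0, 0.8, 4.4, 8.9, 13.8, 16.9, 18.8, 18.4, 14.4, 9.5, 4.6, 1.4],
        [2.6, 2.4, 1.9, 1.5, 1.4, 1.3, 1.5, 1.4, 1.4, 1.5, 1.8, 2.3],
    ),
}


@dataclass(frozen=True)
class Origin:
    """One origin group: label, number of accessions and mean trait shift."""

    label: str
    count: int
    shift: float = 0.0


#: the eight-origin block structure of the balanced 160-accession subset used
#: in the missing-pattern scenario study (counts as reported for that subset).
#: Shifts express origin-linked flowering-time differentiation in days in a
#: central-European common garden: southern landraces (Greece, Afghanistan,
#: Albania) flower up to ~2.5 weeks earlier than Scandinavian material.
DEFAULT_SCENARIO_ORIGINS: tuple[Origin, ...] = (
    Origin("DEU", 51, 0.0),
    Origin("USA", 42, 4.5),
    Origin("SWE", 27, 12.0),
    Origin("GRC", 15, -18.0),
    Origin("FRA", 7, -4.5),
    Origin("AFG", 6, -13.5),
    Origin("ALB", 6, -13.5),
    Origin("GBR", 6, 4.5),
)

SCENARIO_YEARS: tuple[int, ...] = (1951, 1953, 1956, 1959, 1964, 1970)

#: fixed per-year residual variances of the scenario-study base dataset:
#: six seasons of distinctly different data quality (~7x spread, mean ~6.9),
#: the year-heteroscedasticity that makes block-wise regeneration costly
SCENARIO_YEAR_VARIANCES: dict[int, float] = {
    1951: 2.0, 1953: 3.5, 1956: 5.0, 1959: 7.0, 1964: 10.0, 1970: 14.0,
}


@dataclass
class GeneratorConfig:
    """Study conditions of one synthetic historical dataset."""

    n_accessions: int = 1000
    years: Sequence[int] = tuple(range(1946, 2016))
    mu: float = 160.0
    sigma2_G: float = 15.6
    sigma2_Y: float = 72.0
    sigma2_e_mean: float = 6.5
    sigma_e_dispersion: float = 0.3  # log-SD of the per-year residual variances
    sigma2_e_by_year: Optional[Mapping[int, float]] = None  # overrides the log-normal draw
    origins: Optional[Sequence[Origin]] = None
    trend_per_year: float = 0.0  # days/year added to year effects (negative = earlier)
    weather_model: Sequence[tuple[int, str, float]] = ()  # (month, variable, coeff per SD)
    outlier_rate: float = 0.0
    outlier_magnitude: float = 8.0  # in residual SDs of the record's year
    missingness: str = "mcar"
    years_observed_per_block: int = 4
    bad_year: Optional[int] = None
    bad_year_inflation: float = 8.0  # multiplies sigma2_e of the bad year
    bad_year_weather: Optional[tuple[int, str, float]] = None  # (month, var, offset in SDs)
    trait: str = "FT"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma2_G < 0 or self.sigma2_Y < 0 or self.sigma2_e_mean < 0:
            raise ValueError("variances must be >= 0")
        if not 0 <= self.outlier_rate < 1:
            raise ValueError("outlier_rate must lie in [0, 1)")
        if self.missingness not in MISSINGNESS_PATTERNS:
            raise ValueError(f"missingness must be one of {MISSINGNESS_PATTERNS}")
        if self.origins is not None:
            total = sum(o.count for o in self.origins)
            if total != self.n_accessions:
                raise ValueError(
                    f"origin counts sum to {total}, expected n_accessions={self.n_accessions}"
                )


@dataclass
class Truth:
    """Ground truth carried alongside a simulated dataset."""

    mu: float
    g: pd.Series  # accession -> true genetic effect (incl. origin shift)
    a: pd.Series  # year -> true year effect
    sigma2_e_by_year: pd.Series
    trend_component: pd.Series
    weather_component: pd.Series
    outlier_flags: pd.Series  # aligned with the phenotype table index
    config: GeneratorConfig

    @property
    def sigma2_G_realized(self) -> float:
        return float(self.g.var(ddof=1))


def _simulate_weather(years: Sequence[int], rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for year in years:
        for month in range(1, 13):
            rec = {"year": year, "month": month}
            for var in ("rainfall", "humidity", "t_avg"):
                mean, sd = _CLIMATE[var]
                rec[var] = mean[month - 1] + sd[month - 1] * rng.standard_normal()
            rec["t_min"] = rec["t_avg"] - 4.5 + 1.2 * rng.standard_normal()
            rec["t_max"] = rec["t_avg"] + 5.5 + 1.2 * rng.standard_normal()
            rows.append(rec)
    df = pd.DataFrame(rows)
    df["rainfall"] = df["rainfall"].clip(lower=0.0)
    return df


def _standardized_weather(weather: pd.DataFrame) -> pd.DataFrame:
    """Year x (variable, month) matrix standardized to mean 0, SD 1 over years."""
    wide = weather.pivot(index="year", columns="month")[WEATHER_VARIABLES]
    wide.columns = [f"{var}_{month:02d}" for var, month in wide.columns]
    std = wide.std(ddof=1)
    std = std.replace(0.0, np.nan)
    return (wide - wide.mean()) / std


def simulate(config: GeneratorConfig) -> tuple[HistoricalDataset, Truth]:
    """Draw one historical-style dataset; identical seeds give identical output."""
    rng = np.random.default_rng(config.seed)
    years = np.asarray(sorted(config.years), dtype=int)
    n_years = len(years)

    # accessions and origins
    ids = np.array([f"ACC{i + 1:05d}" for i in range(config.n_accessions)])
    if config.origins is not None:
        origin_labels = np.repeat([o.label for o in config.origins],
                                  [o.count for o in config.origins])
        shifts = np.repeat([o.shift for o in config.origins],
                           [o.count for o in config.origins])
    else:
        origin_labels = np.repeat("UNK", config.n_accessions)
        shifts = np.zeros(config.n_accessions)
    g = shifts + np.sqrt(config.sigma2_G) * rng.standard_normal(config.n_accessions)

    # weather and year effects
    weather = _simulate_weather(years, rng)
    if config.bad_year_weather is not None:
        if config.bad_year is None:
            raise ValueError("bad_year_weather requires bad_year")
        month, var, offset_sd = config.bad_year_weather
        _, sds = _CLIMATE.get(var, _CLIMATE["t_avg"])
        sd = sds[month - 1] if var in _CLIMATE else 1.2
        sel = (weather["year"] == config.bad_year) & (weather["month"] == month)
        weather.loc[sel, var] += offset_sd * sd
        weather["rainfall"] = weather["rainfall"].clip(lower=0.0)

    zw = _standardized_weather(weather)
    wcomp = np.zeros(n_years)
    for month, var, coef in config.weather_model:
        wcomp += coef * zw[f"{var}_{month:02d}"].reindex(years).to_numpy()
    trend = config.trend_per_year * (years - years.mean())
    a = trend + wcomp + np.sqrt(config.sigma2_Y) * rng.standard_normal(n_years)

    # per-year residual variances: explicit map, or log-normal with mean sigma2_e_mean
    if config.sigma2_e_by_year is not None:
        missing = [int(y) for y in years if y not in config.sigma2_e_by_year]
        if missing:
            raise ValueError(f"sigma2_e_by_year lacks years {missing}")
        s2e = np.array([float(config.sigma2_e_by_year[y]) for y in years])
        if (s2e < 0).any():
            raise ValueError("sigma2_e_by_year values must be >= 0")
    elif config.sigma2_e_mean > 0:
        d = config.sigma_e_dispersion
        log_mu = np.log(config.sigma2_e_mean) - d ** 2 / 2.0
        s2e = np.exp(log_mu + d * rng.standard_normal(n_years))
    else:
        s2e = np.zeros(n_years)
    s2e_by_year = pd.Series(s2e, index=years)
    if config.bad_year is not None:
        if config.bad_year not in s2e_by_year.index:
            raise ValueError(f"bad_year {config.bad_year} not among simulated years")
        s2e_by_year.loc[config.bad_year] *= config.bad_year_inflation

    # full grid
    acc_idx = np.repeat(np.arange(config.n_accessions), n_years)
    year_idx = np.tile(np.arange(n_years), config.n_accessions)
    e = np.sqrt(s2e_by_year.to_numpy()[year_idx]) * rng.standard_normal(len(acc_idx))
    values = config.mu + g[acc_idx] + a[year_idx] + e

    phen = pd.DataFrame(
        {
            "accession": ids[acc_idx],
            "year": years[year_idx],
            "trait": config.trait,
            "value": values,
            "sowing_date": [f"{y - 1}-10-15" for y in years[year_idx]],
            "taxon": "Triticum aestivum",
            "plot_id": pd.NA,
        }
    )
    passport = pd.DataFrame(
        {
            "accession": ids,
            "origin_country": origin_labels,
            "acquisition_year": int(years[0]),
            "available": True,
        }
    )
    ds = HistoricalDataset(phenotypes=phen, passport=passport, weather=weather)

    if config.missingness != "full":
        ds = apply_missingness(
            ds,
            config.missingness,
            config.years_observed_per_block,
            seed=int(rng.integers(2 ** 31 - 1)),
        )

    flags = pd.Series(False, index=ds.phenotypes.index)
    if config.outlier_rate > 0:
        ds, flags = inject_outliers(
            ds,
            config.outlier_rate,
            config.outlier_magnitude,
            seed=int(rng.integers(2 ** 31 - 1)),
            sigma2_by_year=s2e_by_year,
        )

    truth = Truth(
        mu=config.mu,
        g=pd.Series(g, index=ids),
        a=pd.Series(a, index=years),
        sigma2_e_by_year=s2e_by_year,
        trend_component=pd.Series(trend, index=years),
        weather_component=pd.Series(wcomp, index=years),
        outlier_flags=flags,
        config=config,
    )
    return ds, truth


def apply_missingness(
    ds: HistoricalDataset,
    pattern: str,
    years_per_block: int,
    seed: int,
    *,
    block_sizes: Sequence[int] | None = None,
) -> HistoricalDataset:
    """Reduce a dataset to the year subsets a regeneration schedule would keep.

    ``block_by_origin`` keeps, per origin block (from the passport), one
    random subset of years shared by all block members; ``block_random`` uses
    blocks of the same sizes but with randomly assigned membership;
    ``mcar`` draws an independent year subset per accession; ``full`` is the
    identity.
    """
    if pattern not in MISSINGNESS_PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}")
    if pattern == "full":
        return ds
    rng = np.random.default_rng(seed)
    phen = ds.phenotypes
    years = np.sort(phen["year"].unique())
    if years_per_block > len(years):
        raise ValueError(
            f"years_per_block={years_per_block} exceeds the {len(years)} available years"
        )
    accessions = np.sort(phen["accession"].unique())

    if pattern == "mcar":
        keep_years = {
            acc: set(rng.choice(years, size=years_per_block, replace=False))
            for acc in accessions
        }
    else:
        if pattern == "block_by_origin":
            if ds.passport is None:
                raise ValueError("block_by_origin requires a passport table")
            origin = ds.passport.set_index("accession")["origin_country"]
            blocks = [
                list(members.index)
                for _, members in origin.loc[accessions].groupby(origin, sort=True)
            ]
        else:  # block_random
            if block_sizes is None:
                if ds.passport is not None:
                    counts = (
                        ds.passport.set_index("accession")
                        .loc[accessions]["origin_country"]
                        .value_counts()
                    )
                    block_sizes = counts.sort_index().tolist()
                else:
                    raise ValueError("block_random requires block_sizes or a passport")
            if sum(block_sizes) != len(accessions):
                raise ValueError("block sizes must sum to the number of accessions")
            perm = rng.permutation(accessions)
            blocks, start = [], 0
            for size in block_sizes:
                blocks.append(list(perm[start:start + size]))
                start += size
        keep_years = {}
        for block in blocks:
            chosen = set(rng.choice(years, size=years_per_block, replace=False))
            for acc in block:
                keep_years[acc] = chosen

    mask = np.fromiter(
        (row.year in keep_years[row.accession] for row in phen.itertuples()),
        dtype=bool,
        count=len(phen),
    )
    return ds.replace_phenotypes(phen[mask])


def inject_outliers(
    ds: HistoricalDataset,
    rate: float,
    magnitude: float,
    seed: int,
    *,
    sigma2_by_year: pd.Series | None = None,
) -> tuple[HistoricalDataset, pd.Series]:
    """Add +-magnitude * sigma_e*j gross errors to a random fraction of records.

    Returns the contaminated dataset and the true contamination flags
    (aligned with the new phenotype index).  With ``magnitude == 0`` the
    values are unchanged but flags are still drawn.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    phen = ds.phenotypes.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    n = len(phen)
    flags = pd.Series(rng.random(n) < rate, index=phen.index)
    if sigma2_by_year is None:
        within = phen.groupby("year")["value"].transform(lambda v: v.var(ddof=1))
        sigma = np.sqrt(within.fillna(within.mean()).to_numpy())
    else:
        sigma = np.sqrt(sigma2_by_year.reindex(phen["year"]).to_numpy())
    signs = rng.choice([-1.0, 1.0], size=n)
    values = phen["value"].to_numpy(copy=True)
    values[flags.to_numpy()] += (signs * magnitude * sigma)[flags.to_numpy()]
    out = phen.copy()
    out["value"] = values
    return ds.replace_phenotypes(out), flags


def scenario_config(
    *,
    origins: Sequence[Origin] = DEFAULT_SCENARIO_ORIGINS,
    years: Sequence[int] = SCENARIO_YEARS,
    sigma2_G: float = 15.6,
    sigma2_Y: float = 72.0,
    sigma2_e_mean: float = 6.5,
    seed: int = 0,
    zero_shifts: bool = False,
) -> GeneratorConfig:
    """Config of the orthogonal 160-accession x 6-year scenario-study dataset."""
    if zero_shifts:
        origins = tuple(dataclasses.replace(o, shift=0.0) for o in origins)
    sigma2_e_by_year = (
        dict(SCENARIO_YEAR_VARIANCES) if tuple(years) == SCENARIO_YEARS else None
    )
    return GeneratorConfig(
        n_accessions=sum(o.count for o in origins),
        years=tuple(years),
        sigma2_G=sigma2_G,
        sigma2_Y=sigma2_Y,
        sigma2_e_mean=sigma2_e_mean,
        sigma2_e_by_year=sigma2_e_by_year,
        origins=tuple(origins),
        missingness="full",
        seed=seed,
    )


def simulate_validation(
    g: pd.Series,
    *,
    n_envs: int = 5,
    n_reps: int = 2,
    n_checks: int = 15,
    block_size: int = 25,
    mu: float = 156.0,
    sigma2_env: float = 40.0,
    sigma2_gxe: float = 2.0,
    sigma2_trial: float = 1.0,
    sigma2_rep: float = 0.5,
    sigma2_block: float = 1.0,
    sigma2_e: float = 4.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate an orthogonal multi-environment validation trial for known g.

    Accessions are split over two trials connected through ``n_checks``
    common check accessions grown in both; every accession is replicated
    ``n_reps`` times per environment, with plots grouped into incomplete
    blocks within each replicate.  Returns a long table with columns
    accession, env, trial, rep, block, value suitable for the multi-factor
    random model.
    """
    rng = np.random.default_rng(seed)
    accessions = np.asarray(g.index)
    gvals = g.to_numpy()
    envs = [f"E{j + 1}" for j in range(n_envs)]
    env_eff = np.sqrt(sigma2_env) * rng.standard_normal(n_envs)
    gxe = np.sqrt(sigma2_gxe) * rng.standard_normal((len(accessions), n_envs))
    is_check = np.arange(len(accessions)) < n_checks
    trial_of = np.where(np.arange(len(accessions)) % 2 == 0, "T1", "T2")
    trial_eff = {"T1": np.sqrt(sigma2_trial) * rng.standard_normal(),
                 "T2": np.sqrt(sigma2_trial) * rng.standard_normal()}

    rows = []
    for j, env in enumerate(envs):
        for trial in ("T1", "T2"):
            members = np.where((trial_of == trial) | is_check)[0]
            for rep in range(1, n_reps + 1):
                rep_eff = np.sqrt(sigma2_rep) * rng.standard_normal()
                order = rng.permutation(members)
                n_blocks = max(1, int(np.ceil(len(order) / block_size)))
                block_eff = np.sqrt(sigma2_block) * rng.standard_normal(n_blocks)
                for pos, i in enumerate(order):
                    b = pos // block_size
                    value = (
                        mu
                        + gvals[i]
                        + env_eff[j]
                        + gxe[i, j]
                        + trial_eff[trial]
                        + rep_eff
                        + block_eff[b]
                        + np.sqrt(sigma2_e) * rng.standard_normal()
                    )
                    rows.append(
                        (accessions[i], env, trial, f"{trial}R{rep}", f"{trial}R{rep}B{b + 1}", value)
                    )
    return pd.DataFrame(rows, columns=["accession", "env", "trial", "rep", "block", "value"])
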