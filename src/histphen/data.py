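"""Data model and delimited-text I/O for historical genebank phenotypes.

Phenotypes collected during seed regeneration live in long format: one row
per plot observation of one trait on one accession in one year.  Passport
tables carry the accession-level descriptors (origin country, acquisition
year, availability) and weather tables hold one row per year x month of the
regeneration site.  All files are comma-separated UTF-8 with a header; legacy
column names are absorbed through a configurable :class:`ColumnMap`.

The core traits are FT (flowering time, days after January 1), PH (plant
height, cm) and TGW (thousand grain weight, g), but any trait label is
accepted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ColumnMap",
    "DataLoadError",
    "LoadDiagnostics",
    "HistoricalDataset",
    "IncidenceSummary",
    "read_phenotypes",
    "read_passport",
    "read_weather",
    "write_blues",
    "read_blues",
    "incidence_summary",
]

#: canonical internal column order of the phenotype table
PHENOTYPE_COLUMNS = ["accession", "year", "trait", "value", "sowing_date", "taxon", "plot_id"]
PASSPORT_COLUMNS = ["accession", "origin_country", "acquisition_year", "available"]
WEATHER_VARIABLES = ["rainfall", "humidity", "t_avg", "t_min", "t_max"]
WEATHER_COLUMNS = ["year", "month"] + WEATHER_VARIABLES


class DataLoadError(ValueError):
    """Raised when a file cannot be interpreted at all (e.g. missing column)."""


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from the canonical column roles to the header names in a file."""

    accession: str = "accession"
    year: str = "year"
    trait: str = "trait"
    value: str = "value"
    sowing_date: str = "sowing_date"
    taxon: str = "taxon"
    plot_id: str = "plot_id"

    def mandatory(self) -> dict[str, str]:
        return {
            "accession": self.accession,
            "year": self.year,
            "trait": self.trait,
            "value": self.value,
        }

    def optional(self) -> dict[str, str]:
        return {
            "sowing_date": self.sowing_date,
            "taxon": self.taxon,
            "plot_id": self.plot_id,
        }


@dataclass
class LoadDiagnostics:
    """Row-level bookkeeping of a phenotype load."""

    n_rows: int
    n_kept: int
    rejections: pd.DataFrame  # columns: row, reason

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)

    def reasons(self) -> pd.Series:
        return self.rejections["reason"].value_counts()


@dataclass
class HistoricalDataset:
    """Phenotype records plus optional passport and weather tables.

    ``phenotypes`` has the canonical columns of :data:`PHENOTYPE_COLUMNS`;
    at most one record per (accession, year, trait).
    """

    phenotypes: pd.DataFrame
    passport: pd.DataFrame | None = None
    weather: pd.DataFrame | None = None
    diagnostics: LoadDiagnostics | None = None

    def __post_init__(self) -> None:
        df = self.phenotypes
        for col in PHENOTYPE_COLUMNS:
            if col not in df.columns:
                df[col] = pd.NA if col != "value" else np.nan
        self.phenotypes = df[PHENOTYPE_COLUMNS].reset_index(drop=True)

    # -- basic structure -------------------------------------------------
    @property
    def n_records(self) -> int:
        return len(self.phenotypes)

    def traits(self) -> list[str]:
        return sorted(self.phenotypes["trait"].dropna().unique().tolist())

    def for_trait(self, trait: str) -> pd.DataFrame:
        out = self.phenotypes[self.phenotypes["trait"] == trait]
        if out.empty:
            raise KeyError(f"no records for trait {trait!r}")
        return out

    def replace_phenotypes(self, phenotypes: pd.DataFrame) -> "HistoricalDataset":
        return HistoricalDataset(
            phenotypes=phenotypes.reset_index(drop=True),
            passport=self.passport,
            weather=self.weather,
        )

    def validate(self, year_range: tuple[int, int] = (1900, 2100)) -> None:
        """Check the dataset invariants; raise ``ValueError`` on violation."""
        df = self.phenotypes
        if df["value"].isna().any() or not np.isfinite(df["value"].astype(float)).all():
            raise ValueError("non-finite phenotype values present")
        years = df["year"].astype(int)
        if ((years < year_range[0]) | (years > year_range[1])).any():
            raise ValueError(f"years outside configured range {year_range}")
        dup = df.duplicated(subset=["accession", "year", "trait"])
        if dup.any():
            raise ValueError(f"{int(dup.sum())} duplicate (accession, year, trait) records")
        if self.passport is not None and len(self.passport):
            known = set(self.passport["accession"])
            missing = set(df["accession"]) - known
            if missing:
                raise ValueError(
                    f"{len(missing)} accessions missing from passport (e.g. {sorted(missing)[:3]})"
                )
        if self.weather is not None and len(self.weather):
            w = self.weather
            if ((w["month"] < 1) | (w["month"] > 12)).any():
                raise ValueError("weather month outside 1..12")
            if w.duplicated(subset=["year", "month"]).any():
                raise ValueError("duplicate (year, month) weather records")


@dataclass
class IncidenceSummary:
    """Observation-count structure of the accession x year incidence matrix."""

    trait: str
    n_records: int
    n_accessions: int
    n_years: int
    per_accession: pd.Series
    per_year: pd.Series
    fill_fraction: float
    mean_obs_per_accession: float


# ---------------------------------------------------------------------------
# readers


def _require_columns(df: pd.DataFrame, names: Sequence[str], path) -> None:
    missing = [c for c in names if c not in df.columns]
    if missing:
        raise DataLoadError(f"{path}: missing mandatory column(s) {missing}")


def read_phenotypes(
    path,
    columns: ColumnMap = ColumnMap(),
    *,
    year_range: tuple[int, int] = (1900, 2100),
    passport: pd.DataFrame | None = None,
    weather: pd.DataFrame | None = None,
    on_duplicate: str = "reject",
) -> HistoricalDataset:
    """Read a long-format phenotype CSV into a :class:`HistoricalDataset`.

    Unparseable or duplicate rows are recorded in ``diagnostics`` and
    dropped, never raised; a missing mandatory column raises
    :class:`DataLoadError`.  ``on_duplicate`` is ``"reject"`` (keep the first
    record of a duplicated (accession, year, trait) triple) or ``"mean"``
    (average duplicates, with a warning in the diagnostics).
    """
    if on_duplicate not in ("reject", "mean"):
        raise ValueError("on_duplicate must be 'reject' or 'mean'")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, list(columns.mandatory().values()), path)

    df = pd.DataFrame(index=raw.index)
    for role, name in columns.mandatory().items():
        df[role] = raw[name].str.strip()
    for role, name in columns.optional().items():
        df[role] = raw[name].str.strip() if name in raw.columns else ""

    reasons: list[tuple[int, str]] = []
    bad = pd.Series(False, index=df.index)

    def flag(mask: pd.Series, reason: str) -> None:
        nonlocal bad
        for idx in df.index[mask & ~bad]:
            reasons.append((int(idx), reason))
        bad |= mask

    flag(df["accession"] == "", "missing accession")
    flag(df["trait"] == "", "missing trait")
    year = pd.to_numeric(df["year"], errors="coerce")
    flag(df["year"] == "", "missing year")
    flag(year.isna(), "unparseable year")
    flag((year < year_range[0]) | (year > year_range[1]), "year out of range")
    value = pd.to_numeric(df["value"], errors="coerce")
    flag(df["value"] == "", "missing value")
    flag(value.isna() | ~np.isfinite(value.fillna(np.nan)), "unparseable value")

    kept = df[~bad].copy()
    kept["year"] = year[~bad].astype(int)
    kept["value"] = value[~bad].astype(float)

    dup = kept.duplicated(subset=["accession", "year", "trait"], keep="first")
    if dup.any():
        if on_duplicate == "reject":
            for idx in kept.index[dup]:
                reasons.append((int(idx), "duplicate"))
            kept = kept[~dup]
        else:
            reasons.append((-1, "duplicates averaged"))
            kept = (
                kept.groupby(["accession", "year", "trait"], as_index=False)
                .agg(
                    value=("value", "mean"),
                    sowing_date=("sowing_date", "first"),
                    taxon=("taxon", "first"),
                    plot_id=("plot_id", "first"),
                )
            )

    kept = kept.replace({"": pd.NA})
    kept["value"] = kept["value"].astype(float)
    diagnostics = LoadDiagnostics(
        n_rows=len(raw),
        n_kept=len(kept),
        rejections=pd.DataFrame(reasons, columns=["row", "reason"]),
    )
    ds = HistoricalDataset(
        phenotypes=kept.reset_index(drop=True),
        passport=passport,
        weather=weather,
        diagnostics=diagnostics,
    )
    return ds


def read_passport(path, columns: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a passport CSV (accession, origin_country, acquisition_year, available)."""
    colmap = {c: c for c in PASSPORT_COLUMNS}
    if columns:
        colmap.update(columns)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, [colmap["accession"]], path)
    out = pd.DataFrame()
    out["accession"] = raw[colmap["accession"]].str.strip()
    out["origin_country"] = (
        raw[colmap["origin_country"]].replace({"": pd.NA})
        if colmap["origin_country"] in raw.columns
        else pd.NA
    )
    out["acquisition_year"] = (
        pd.to_numeric(raw[colmap["acquisition_year"]], errors="coerce").astype("Int64")
        if colmap["acquisition_year"] in raw.columns
        else pd.NA
    )
    if colmap["available"] in raw.columns:
        out["available"] = raw[colmap["available"]].str.lower().isin(["1", "true", "yes", "y"])
    else:
        out["available"] = True
    if out["accession"].duplicated().any():
        raise DataLoadError(f"{path}: duplicated accession ids in passport")
    return out


def read_weather(path) -> pd.DataFrame:
    """Read a monthly weather CSV; any observation column may be missing."""
    raw = pd.read_csv(path)
    _require_columns(raw, ["year", "month"], path)
    out = pd.DataFrame()
    out["year"] = raw["year"].astype(int)
    out["month"] = raw["month"].astype(int)
    for var in WEATHER_VARIABLES:
        out[var] = pd.to_numeric(raw[var], errors="coerce") if var in raw.columns else np.nan
    if ((out["month"] < 1) | (out["month"] > 12)).any():
        raise DataLoadError(f"{path}: month outside 1..12")
    if out.duplicated(subset=["year", "month"]).any():
        raise DataLoadError(f"{path}: duplicate (year, month) rows")
    return out


# ---------------------------------------------------------------------------
# BLUE table round-trip

BLUE_COLUMNS = ["accession_id", "trait", "blue", "standard_error", "n_years"]


def write_blues(table: pd.DataFrame, path, precision: int = 6) -> None:
    """Write a BLUE table (one row per accession x trait) to CSV.

    Missing standard errors are written as empty fields, never as zero.
    """
    if table.empty:
        raise ValueError("refusing to write an empty BLUE table")
    out = table.copy()
    rename = {"accession": "accession_id", "se": "standard_error"}
    out = out.rename(columns={k: v for k, v in rename.items() if k in out.columns})
    missing = [c for c in BLUE_COLUMNS if c not in out.columns]
    if missing:
        raise ValueError(f"BLUE table lacks columns {missing}")
    out = out[BLUE_COLUMNS]
    out.to_csv(path, index=False, float_format=f"%.{precision}f")


def read_blues(path) -> pd.DataFrame:
    raw = pd.read_csv(path)
    _require_columns(raw, BLUE_COLUMNS, path)
    raw["blue"] = raw["blue"].astype(float)
    raw["standard_error"] = pd.to_numeric(raw["standard_error"], errors="coerce")
    raw["n_years"] = raw["n_years"].astype(int)
    return raw


# ---------------------------------------------------------------------------
# incidence structure


def incidence_summary(ds: HistoricalDataset, trait: str) -> IncidenceSummary:
    """Observation counts and fill fraction of the accession x year matrix.

    The mean number of observations per accession is the ``Year`` quantity
    entering the entry-mean heritability formula.
    """
    df = ds.for_trait(trait)
    per_accession = df.groupby("accession").size().sort_index()
    per_year = df.groupby("year").size().sort_index()
    n_acc = len(per_accession)
    n_years = len(per_year)
    return IncidenceSummary(
        trait=trait,
        n_records=len(df),
        n_accessions=n_acc,
        n_years=n_years,
        per_accession=per_accession,
        per_year=per_year,
        fill_fraction=len(df) / float(n_acc * n_years),
        mean_obs_per_accession=float(per_accession.mean()),
    )
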