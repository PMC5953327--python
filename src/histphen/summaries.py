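"""Post-estimation summaries: panel comparisons, ranks and temporal trends.

Cross-dataset BLUE correlations (e.g. historical series versus designed
multi-environment validation trials), the normalized-rank-product (NRP)
comparator, ordinary-least-squares temporal trends of year effects, and
variance-ratio diversity comparisons between accession panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .data import HistoricalDataset

__all__ = [
    "PanelComparison",
    "correlate_blues",
    "normalized_rank_product",
    "temporal_trend",
    "panel_variance_ratio",
]


@dataclass
class PanelComparison:
    """Agreement/diversity measures between two accession panels."""

    n_common: int
    pearson: Optional[float] = None
    spearman: Optional[float] = None
    variance_ratio: Optional[float] = None  # sigma2_G panel / sigma2_G reference
    range_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        for r in (self.pearson, self.spearman):
            if r is not None and not -1.0 - 1e-12 <= r <= 1.0 + 1e-12:
                raise ValueError("correlation outside [-1, 1]")


def correlate_blues(a: pd.DataFrame, b: pd.DataFrame) -> PanelComparison:
    """Pearson and Spearman correlation of two BLUE tables over common accessions.

    Both tables need columns ``accession_id`` and ``blue``; at least three
    overlapping accessions are required.
    """
    merged = a.merge(b, on="accession_id", suffixes=("_a", "_b"))
    n = len(merged)
    if n < 3:
        raise ValueError(f"only {n} overlapping accessions; need >= 3 for a correlation")
    pear = float(stats.pearsonr(merged["blue_a"], merged["blue_b"])[0])
    spear = float(stats.spearmanr(merged["blue_a"], merged["blue_b"])[0])
    return PanelComparison(n_common=n, pearson=pear, spearman=spear)


def normalized_rank_product(
    ds: "HistoricalDataset | pd.DataFrame",
    trait: str,
    mean: Literal["geometric", "arithmetic"] = "geometric",
) -> pd.Series:
    """Normalized rank product of each accession across its observed years.

    Within every year, accessions are ranked ascending (ties get average
    ranks) and ranks are scaled to (0, 1] by the year's panel size.  An
    accession's NRP is the geometric (default) or arithmetic mean of its
    scaled ranks over the years it was observed, hence NRP is in (0, 1] and
    invariant to monotone within-year transformations of the trait.
    """
    if isinstance(ds, HistoricalDataset):
        df = ds.for_trait(trait)
    else:
        df = ds
        if "trait" in df.columns:
            df = df[df["trait"] == trait]
    scaled = df.groupby("year")["value"].rank(method="average") / df.groupby("year")[
        "value"
    ].transform("size")
    frame = pd.DataFrame({"accession": df["accession"], "scaled_rank": scaled})
    if mean == "geometric":
        out = frame.groupby("accession")["scaled_rank"].apply(
            lambda s: float(np.exp(np.mean(np.log(s))))
        )
    elif mean == "arithmetic":
        out = frame.groupby("accession")["scaled_rank"].mean()
    else:
        raise ValueError("mean must be 'geometric' or 'arithmetic'")
    out.name = "nrp"
    return out


def temporal_trend(
    year_effects: "pd.Series | Mapping[int, float]", min_years: int = 10
) -> tuple[float, float]:
    """OLS slope (with standard error) of year effects on calendar year.

    Negative slope means the trait level declines over time (for flowering
    time: accessions flower earlier in later years).  Requires at least
    ``min_years`` years.
    """
    ye = pd.Series(dict(year_effects)).astype(float).sort_index()
    if len(ye) < min_years:
        raise ValueError(f"need >= {min_years} years of year effects, got {len(ye)}")
    x = ye.index.to_numpy(dtype=float)
    y = ye.to_numpy()
    res = stats.linregress(x, y)
    return float(res.slope), float(res.stderr)


def panel_variance_ratio(
    panel_sigma2_G: float,
    reference_sigma2_G: float,
    panel_blues: Optional[pd.DataFrame] = None,
    reference_blues: Optional[pd.DataFrame] = None,
) -> PanelComparison:
    """Genetic-variance and BLUE-range ratios of a panel vs a reference.

    Ratios are percentages of the reference.  The reference genetic
    variance must be positive; a panel whose variance is not estimable
    (fewer than two accessions) raises.
    """
    if reference_sigma2_G <= 0:
        raise ValueError("reference sigma2_G must be > 0")
    if panel_sigma2_G < 0:
        raise ValueError("panel sigma2_G must be >= 0")
    range_ratio = None
    n_common = 0
    if panel_blues is not None and reference_blues is not None:
        if len(panel_blues) < 2:
            raise ValueError("panel has fewer than 2 accessions; range not estimable")
        pb = panel_blues["blue"]
        rb = reference_blues["blue"]
        ref_range = float(rb.max() - rb.min())
        if ref_range <= 0:
            raise ValueError("reference BLUE range is zero")
        range_ratio = 100.0 * float(pb.max() - pb.min()) / ref_range
        n_common = len(
            set(panel_blues["accession_id"]) & set(reference_blues["accession_id"])
        )
    return PanelComparison(
        n_common=n_common,
        variance_ratio=100.0 * panel_sigma2_G / reference_sigma2_G,
        range_ratio=range_ratio,
    )
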