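"""Resampling study of missing-data patterns in regeneration schedules.

Starting from an orthogonal accession x year dataset, each replicate keeps
only the year subsets a given regeneration policy would have produced and
refits the mixed model:

* Scenario A -- blocks of accessions defined by geographic origin, every
  block evaluated in a shared random subset of years (missing at random
  only if blocks are random samples, which origin blocks are not);
* Scenario B -- blocks of the same sizes but randomly composed;
* Scenario C -- no blocks, an independent year subset per accession
  (missing completely at random).

Across replicates the study summarizes bias (relative to the full-data
reference fit) and precision (SD of the estimates) of the genetic and
residual variance components and of the accession BLUEs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import HistoricalDataset
from .reml import ConvergenceError, FitOptions, ModelSpec, RemlError, estimate_blues, fit
from .simulate import apply_missingness

__all__ = ["ScenarioSpec", "ScenarioResult", "run_scenario", "compare_scenarios"]

_PATTERN_OF = {
    "A": "block_by_origin",
    "B": "block_random",
    "C": "mcar",
}


@dataclass(frozen=True)
class ScenarioSpec:
    """One resampling scenario: pattern, block structure and replication."""

    scenario: str  # "A" | "B" | "C"
    years_per_block: int = 3
    n_replicates: int = 100
    seed: int = 0
    block_sizes: Optional[tuple[int, ...]] = None  # required for B without passport
    heterogeneous: bool = False
    compute_blues: bool = True
    max_failure_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.scenario not in _PATTERN_OF:
            raise ValueError("scenario must be 'A', 'B' or 'C'")


@dataclass
class ScenarioResult:
    """Per-replicate estimates and their summaries for one scenario."""

    spec: ScenarioSpec
    reference: dict[str, float]  # full-data fit: sigma2_G, sigma2_Y, sigma2_e
    reference_blues: pd.Series
    sigma2_G: np.ndarray
    sigma2_Y: np.ndarray
    sigma2_e: np.ndarray
    blues: pd.DataFrame  # replicates x accessions
    n_failed: int
    truth: Optional[dict[str, float]] = None

    @property
    def n_effective(self) -> int:
        return len(self.sigma2_G)

    def summary(self) -> pd.DataFrame:
        """Mean, SD and bias (%) of each parameter across replicates."""
        rows = []
        for name, draws in (
            ("sigma2_G", self.sigma2_G),
            ("sigma2_Y", self.sigma2_Y),
            ("sigma2_e", self.sigma2_e),
        ):
            ref = self.reference[name]
            rows.append(
                {
                    "parameter": name,
                    "reference": ref,
                    "mean": float(np.mean(draws)),
                    "sd": float(np.std(draws, ddof=1)) if len(draws) > 1 else 0.0,
                    "bias_pct": 100.0 * (float(np.mean(draws)) - ref) / ref if ref else np.nan,
                }
            )
        if not self.blues.empty:
            blue_dev = self.blues - self.reference_blues
            rows.append(
                {
                    "parameter": "blues",
                    "reference": float(self.reference_blues.mean()),
                    "mean": float(self.blues.to_numpy().mean()),
                    "sd": float(self.blues.std(ddof=1).mean()) if len(self.blues) > 1 else 0.0,
                    "bias_pct": 100.0
                    * float(blue_dev.to_numpy().mean())
                    / float(self.reference_blues.mean()),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")


def _component_fit(df: pd.DataFrame, heterogeneous: bool, options: FitOptions):
    spec = ModelSpec.historical_components(heterogeneous)
    res = fit(df, spec, options)
    return {
        "sigma2_G": res.variance_components["accession"],
        "sigma2_Y": res.variance_components["year"],
        "sigma2_e": res.mean_residual_variance(),
    }


def run_scenario(
    full_ds: HistoricalDataset,
    spec: ScenarioSpec,
    trait: Optional[str] = None,
    options: FitOptions = FitOptions(),
    truth: Optional[dict[str, float]] = None,
) -> ScenarioResult:
    """Run one missing-pattern scenario against the full-data reference fit.

    ``full_ds`` must be orthogonal (every accession observed in every year)
    so that the reference fit is the natural benchmark.  Replicates that
    fail to converge are recorded and skipped; more than
    ``max_failure_fraction`` failures abort the run.
    """
    trait = trait or full_ds.traits()[0]
    df_full = full_ds.for_trait(trait).reset_index(drop=True)
    counts = df_full.groupby("accession")["year"].nunique()
    if counts.nunique() != 1 or counts.iloc[0] != df_full["year"].nunique():
        raise ValueError("full_ds must be orthogonal over accessions x years")

    reference = _component_fit(df_full, spec.heterogeneous, options)
    ref_blues, _ = estimate_blues(df_full, trait, spec.heterogeneous, options)
    ref_blues = ref_blues.set_index("accession_id")["blue"]

    pattern = _PATTERN_OF[spec.scenario]
    block_sizes = spec.block_sizes
    draws_G, draws_Y, draws_e, blue_rows = [], [], [], []
    n_failed = 0
    for rep in range(spec.n_replicates):
        rep_seed = (spec.seed * 100003 + rep) % (2 ** 31 - 1)
        sub = apply_missingness(
            full_ds, pattern, spec.years_per_block, rep_seed, block_sizes=block_sizes
        )
        sub_df = sub.for_trait(trait).reset_index(drop=True)
        try:
            comps = _component_fit(sub_df, spec.heterogeneous, options)
            if spec.compute_blues:
                blues, _ = estimate_blues(sub_df, trait, spec.heterogeneous, options)
        except (RemlError, ConvergenceError):
            n_failed += 1
            continue
        draws_G.append(comps["sigma2_G"])
        draws_Y.append(comps["sigma2_Y"])
        draws_e.append(comps["sigma2_e"])
        if spec.compute_blues:
            blue_rows.append(blues.set_index("accession_id")["blue"])
    if n_failed > spec.max_failure_fraction * spec.n_replicates:
        raise RemlError(
            f"{n_failed}/{spec.n_replicates} replicates failed to converge "
            f"in scenario {spec.scenario}"
        )

    blues_df = pd.DataFrame(blue_rows).reindex(columns=ref_blues.index)
    return ScenarioResult(
        spec=spec,
        reference=reference,
        reference_blues=ref_blues,
        sigma2_G=np.asarray(draws_G),
        sigma2_Y=np.asarray(draws_Y),
        sigma2_e=np.asarray(draws_e),
        blues=blues_df,
        n_failed=n_failed,
        truth=truth,
    )


def compare_scenarios(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Bias and precision of each scenario, with SD ratios against Scenario C.

    All results must share the same reference fit (same full dataset).
    """
    if not results:
        raise ValueError("no scenario results supplied")
    ref0 = results[0].reference
    for res in results[1:]:
        for key, val in ref0.items():
            if abs(res.reference[key] - val) > 1e-8 * (abs(val) + 1.0):
                raise ValueError("scenario results have mismatched reference fits")

    by_scenario = {res.spec.scenario: res for res in results}
    base = by_scenario.get("C", results[-1])
    base_summary = base.summary()
    rows = []
    for res in results:
        summ = res.summary()
        for parameter in summ.index:
            sd = summ.loc[parameter, "sd"]
            base_sd = base_summary.loc[parameter, "sd"]
            rows.append(
                {
                    "scenario": res.spec.scenario,
                    "parameter": parameter,
                    "mean": summ.loc[parameter, "mean"],
                    "sd": sd,
                    "bias_pct": summ.loc[parameter, "bias_pct"],
                    "sd_ratio_vs_C": sd / base_sd if base_sd > 0 else np.inf,
                }
            )
    return pd.DataFrame(rows)
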