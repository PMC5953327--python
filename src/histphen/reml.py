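"""REML estimation for crossed/nested mixed models on sparse incidence data.

The models handled here are variance-component models of the form

    y = X b + Z_1 u_1 + ... + Z_K u_K + e,
    u_k ~ N(0, sigma2_k I),   e ~ N(0, R),

where every fixed or random term is a grouping factor (one-hot incidence
matrix) and the residual covariance ``R`` is diagonal, either with a single
variance or with one variance per residual group (typically the trial
year, the "variances heterogeneous across years" assumption of historical
regeneration series).

Restricted maximum likelihood is maximized by an expectation-maximization
warm start followed by L-BFGS-B refinement on the log-variance scale with
analytic gradients.  All linear algebra runs through the mixed-model
equations; the largest factor's block of the coefficient matrix is diagonal
(a level occurs once per record) and is absorbed through a Schur
complement, so fits with thousands of accession equations stay cheap.

The heritability here is on an entry-mean basis,
``h2 = sigma2_G / (sigma2_G + sigma2_e / n_years)`` with ``n_years`` the
average number of years each accession was tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .data import HistoricalDataset

__all__ = [
    "ModelSpec",
    "FitOptions",
    "FitResult",
    "RemlError",
    "ConvergenceError",
    "fit",
    "estimate_blues",
    "estimate_components",
    "heritability",
    "studentized_residuals",
]

_LOG2PI = float(np.log(2.0 * np.pi))


class RemlError(RuntimeError):
    """Base class for model-fitting failures."""


class ConvergenceError(RemlError):
    """REML iterations did not reach the convergence criteria."""

    def __init__(self, message: str, trajectory: Sequence[float] = ()):  # noqa: D107
        super().__init__(message)
        self.trajectory = list(trajectory)


@dataclass(frozen=True)
class ModelSpec:
    """Declaration of the fixed/random grouping factors of one model.

    ``fixed`` and ``random`` name columns of the record table; ``"a:b"``
    denotes the crossed/nested combination of two columns.  The first fixed
    factor is coded as cell means (so its estimates live on the trait
    scale, intercept absorbed); additional fixed factors are coded with a
    dropped reference level.  Without fixed factors an intercept is fitted.
    ``residual_by`` names the residual-variance grouping factor (``None``
    for a single homogeneous residual variance).
    """

    response: str = "value"
    fixed: tuple[str, ...] = ()
    random: tuple[str, ...] = ()
    residual_by: Optional[str] = None

    def __post_init__(self) -> None:
        overlap = set(self.fixed) & set(self.random)
        if overlap:
            raise ValueError(f"factors cannot be both fixed and random: {sorted(overlap)}")

    # -- canonical models -------------------------------------------------
    @staticmethod
    def historical_blues(heterogeneous: bool = True) -> "ModelSpec":
        """Fixed accession, random year: the BLUE/outlier-testing model."""
        return ModelSpec(fixed=("accession",), random=("year",),
                         residual_by="year" if heterogeneous else None)

    @staticmethod
    def historical_components(heterogeneous: bool = True) -> "ModelSpec":
        """Random accession and year: the variance-component model."""
        return ModelSpec(fixed=(), random=("accession", "year"),
                         residual_by="year" if heterogeneous else None)

    @staticmethod
    def historical_year_effects(heterogeneous: bool = True) -> "ModelSpec":
        """Fixed year, random accession: year-effect (YE) estimation."""
        return ModelSpec(fixed=("year",), random=("accession",),
                         residual_by="year" if heterogeneous else None)

    @staticmethod
    def validation() -> "ModelSpec":
        """Fixed accession; random environment, GxE, trial, rep and block."""
        return ModelSpec(
            fixed=("accession",),
            random=("env", "accession:env", "trial", "env:rep", "env:block"),
            residual_by=None,
        )


@dataclass(frozen=True)
class FitOptions:
    """Numerical controls of the REML fit."""

    max_iter: int = 200
    em_iter: int = 15
    rel_tol: float = 1e-8
    grad_tol: float = 1e-6
    var_floor_frac: float = 1e-6  # floor for variances, relative to var(y)
    min_residual_group: int = 5  # smaller groups share a pooled variance
    min_residual_df: float = 10.0  # groups with fewer effective df are pooled too
    tie_residual_groups: bool = False  # force a single residual variance


@dataclass
class FitResult:
    """REML estimates, effects and residual diagnostics of one model fit."""

    spec: ModelSpec
    n_records: int
    variance_components: dict[str, float]
    residual_variances: dict[object, float]
    residual_group_of: dict[object, object]
    fixed_estimates: dict[str, pd.DataFrame]
    random_predictions: dict[str, pd.Series]
    residuals: pd.DataFrame  # raw, leverage, sigma2, group (record-aligned)
    log_restricted_likelihood: float
    n_iter: int
    final_grad_norm: float
    converged: bool
    trajectory: list[float]
    boundary: list[str]
    diagnostics: dict[str, object] = field(default_factory=dict)

    def mean_residual_variance(self, weighted: bool = False) -> float:
        """Average residual variance (the sigma2_e entering h2).

        Unweighted: plain mean of the per-group (per-year) variances.
        Weighted: record-weighted mean, i.e. the pooled residual variance.
        """
        if weighted:
            return float(self.residuals["sigma2"].mean())
        values = np.array(list(self.residual_variances.values()), dtype=float)
        return float(values.mean())


# ---------------------------------------------------------------------------
# design construction


def _column(df: pd.DataFrame, name: str) -> pd.Series:
    if ":" in name:
        parts = name.split(":")
        out = df[parts[0]].astype(str)
        for p in parts[1:]:
            out = out + ":" + df[p].astype(str)
        return out
    return df[name]


def _codes(df: pd.DataFrame, name: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        values = _column(df, name)
    except KeyError as exc:
        raise RemlError(f"model factor {name!r} not found in the data") from exc
    codes, levels = pd.factorize(values, sort=True)
    if (codes < 0).any():
        raise RemlError(f"factor {name!r} has missing values")
    return codes.astype(np.int64), np.asarray(levels)


def _n_connected(codes_a: np.ndarray, codes_b: np.ndarray, na: int, nb: int) -> int:
    """Connected components of the bipartite factor-a x factor-b graph."""
    parent = np.arange(na + nb)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in zip(codes_a, codes_b + na):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    roots = {find(i) for i in np.unique(np.concatenate([codes_a, codes_b + na]))}
    return len(roots)


class _Block:
    """One factor block of the design: name, per-record codes, level labels."""

    def __init__(self, name, codes, levels, kind, drop_first=False):
        self.name = name
        self.kind = kind  # "fixed" | "random" | "intercept"
        self.drop_first = drop_first
        self.codes = codes
        self.levels = levels
        self.n_cols = len(levels) - (1 if drop_first else 0)


class _Problem:
    """Pre-assembled quantities of one REML problem."""

    def __init__(self, df: pd.DataFrame, spec: ModelSpec, options: FitOptions):
        self.spec = spec
        self.options = options
        y = df[spec.response].to_numpy(dtype=float)
        if not np.isfinite(y).all():
            raise RemlError("response contains non-finite values")
        self.y = y
        n = len(y)
        if n == 0:
            raise RemlError("empty dataset")

        blocks: list[_Block] = []
        if spec.fixed:
            for i, name in enumerate(spec.fixed):
                codes, levels = _codes(df, name)
                blocks.append(_Block(name, codes, levels, "fixed", drop_first=(i > 0)))
        else:
            blocks.append(_Block("(Intercept)", np.zeros(n, dtype=np.int64),
                                 np.array(["(Intercept)"]), "intercept"))
        for name in spec.random:
            codes, levels = _codes(df, name)
            if len(levels) < 2:
                warnings.warn(f"random factor {name!r} has a single level; "
                              "its variance is not identifiable", stacklevel=3)
            blocks.append(_Block(name, codes, levels, "random"))
        self.blocks = blocks
        self.n_fixed_cols = sum(b.n_cols for b in blocks if b.kind != "random")

        # absorb the factor with the most columns (its MME block is diagonal)
        self.absorbed = max(blocks, key=lambda b: b.n_cols)
        if self.absorbed.drop_first:  # keep absorption trivial: full coding only
            self.absorbed = blocks[0]
        rest = [b for b in blocks if b is not self.absorbed]
        self.rest = rest

        # rest design matrix
        cols, data, rows = [], [], []
        offset = 0
        self.rest_slices: dict[str, slice] = {}
        for b in rest:
            codes = b.codes
            if b.drop_first:
                mask = codes > 0
                rows.append(np.nonzero(mask)[0])
                cols.append(codes[mask] - 1 + offset)
                data.append(np.ones(mask.sum()))
            else:
                rows.append(np.arange(n))
                cols.append(codes + offset)
                data.append(np.ones(n))
            self.rest_slices[b.name] = slice(offset, offset + b.n_cols)
            offset += b.n_cols
        self.mr = offset
        if self.mr:
            self.Wr = sp.csr_matrix(
                (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
                shape=(n, self.mr),
            )
        else:
            self.Wr = sp.csr_matrix((n, 0))
        self.acodes = self.absorbed.codes
        self.nA = self.absorbed.n_cols
        self.Aind = sp.csr_matrix(
            (np.ones(n), (np.arange(n), self.acodes)), shape=(n, self.nA)
        )

        # variance parameter layout: random factors first, then residual groups
        self.random_names = [b.name for b in blocks if b.kind == "random"]
        self.K = len(self.random_names)
        self._rand_index = {name: i for i, name in enumerate(self.random_names)}

        if spec.residual_by is not None and not options.tie_residual_groups:
            gvalues = _column(df, spec.residual_by)
            counts = gvalues.value_counts()
            # effective residual df per group: each record of an
            # (accession-side) level with k records contributes ~(1 - 1/k)
            # df; one df goes to the group's own mean/variance. Groups too
            # thin to estimate a variance are tied to a pooled estimate.
            others = [b for b in blocks if b.name != spec.residual_by]
            donor = max(others, key=lambda b: b.n_cols) if others else self.absorbed
            k_level = np.bincount(donor.codes)[donor.codes]
            contrib = pd.Series(1.0 - 1.0 / k_level, index=gvalues.values)
            df_g = contrib.groupby(level=0).sum() - 1.0
            small = set(counts.index[counts < options.min_residual_group])
            small |= set(df_g.index[df_g < options.min_residual_df])
            # if no group is estimable on its own, they all share one variance
            mapped = gvalues.where(~gvalues.isin(small), other="__pooled__")
            self.group_of = dict(zip(gvalues, mapped))
            gcodes, glevels = pd.factorize(mapped, sort=False)
            self.gcodes = gcodes.astype(np.int64)
            self.glevels = np.asarray(glevels, dtype=object)
        else:
            self.gcodes = np.zeros(n, dtype=np.int64)
            self.glevels = np.array(["(all)"], dtype=object)
            if spec.residual_by is not None:
                gvalues = _column(df, spec.residual_by)
                self.group_of = {g: "(all)" for g in gvalues.unique()}
            else:
                self.group_of = {"(all)": "(all)"}
        self.L = len(self.glevels)
        self.group_n = np.bincount(self.gcodes, minlength=self.L).astype(float)
        self.n = n

        vy = float(np.var(y))
        self.scale = vy if vy > 0 else 1.0
        self.var_floor = options.var_floor_frac * self.scale

    # -- parameter helpers -------------------------------------------------
    @property
    def n_params(self) -> int:
        return self.K + self.L

    def initial_params(self) -> np.ndarray:
        s0 = max(self.scale, 10 * self.var_floor)
        rand = np.full(self.K, s0 / (2 * max(self.K, 1)))
        res = np.full(self.L, s0 / 2)
        return np.concatenate([rand, res])

    # -- core evaluation ---------------------------------------------------
    def _assemble(self, s2):
        s2r, s2g = s2[: self.K], s2[self.K:]
        rinv = 1.0 / s2g[self.gcodes]
        D = np.asarray(self.Aind.T @ rinv).ravel()
        if self.absorbed.kind == "random":
            D = D + 1.0 / s2r[self._rand_index[self.absorbed.name]]
        RW = self.Wr.multiply(rinv[:, None]).tocsc()
        B = np.asarray((self.Aind.T @ RW).todense()) if self.mr else np.zeros((self.nA, 0))
        E = np.asarray((self.Wr.T @ RW).todense()) if self.mr else np.zeros((0, 0))
        for b in self.rest:
            if b.kind == "random":
                sl = self.rest_slices[b.name]
                idx = np.arange(sl.start, sl.stop)
                E[idx, idx] += 1.0 / s2r[self._rand_index[b.name]]
        yR = rinv * self.y
        rhsA = np.asarray(self.Aind.T @ yR).ravel()
        rhsR = np.asarray(self.Wr.T @ yR).ravel()
        Q = B / D[:, None]
        S = E - B.T @ Q
        S = 0.5 * (S + S.T)
        try:
            cS = cho_factor(S, lower=True) if self.mr else None
        except LinAlgError as exc:
            raise RemlError(
                "singular mixed-model equations: the fixed-effect design is "
                "rank deficient (aliased levels) or a variance collapsed"
            ) from exc
        return s2r, s2g, rinv, D, B, Q, S, cS, yR, rhsA, rhsR

    def neg2ll(self, s2, want_grad=False, want_state=False):
        s2r, s2g, rinv, D, B, Q, S, cS, yR, rhsA, rhsR = self._assemble(s2)
        if self.mr:
            tR = cho_solve(cS, rhsR - B.T @ (rhsA / D))
        else:
            tR = np.zeros(0)
        tA = (rhsA - B @ tR) / D
        yhat = tA[self.acodes] + (self.Wr @ tR if self.mr else 0.0)
        resid = self.y - yhat
        yPy = float(self.y @ yR - (rhsA @ tA + rhsR @ tR))
        logdetC = float(np.sum(np.log(D)))
        if self.mr:
            logdetC += 2.0 * float(np.sum(np.log(np.diag(cS[0]))))
        logdetR = float(self.group_n @ np.log(s2g))
        logdetG = 0.0
        for b in self.blocks:
            if b.kind == "random":
                logdetG += b.n_cols * np.log(s2r[self._rand_index[b.name]])
        neg2 = ((self.n - self.n_fixed_cols) * _LOG2PI
                + logdetR + logdetG + logdetC + yPy)
        if not (want_grad or want_state):
            return neg2

        # shared gradient quantities
        if self.mr:
            Sinv = cho_solve(cS, np.eye(self.mr))
            QS = Q @ Sinv  # nA x mr
            diagC_A = 1.0 / D + np.einsum("ij,ij->i", QS, Q)
            # h_i = w_i' Cinv w_i = 1/D_a + (q_a - r_i)' Sinv (q_a - r_i)
            Zraw = np.asarray(Q[self.acodes, :] - self.Wr.todense())
            H = 1.0 / D[self.acodes] + np.einsum("ij,ij->i", Zraw, Zraw @ Sinv)
        else:
            Sinv = np.zeros((0, 0))
            diagC_A = 1.0 / D
            H = 1.0 / D[self.acodes]
        sse = np.bincount(self.gcodes, weights=resid ** 2, minlength=self.L)
        Tg = np.bincount(self.gcodes, weights=H, minlength=self.L)

        tr_k = np.zeros(self.K)
        usq_k = np.zeros(self.K)
        for b in self.blocks:
            if b.kind != "random":
                continue
            k = self._rand_index[b.name]
            if b is self.absorbed:
                tr_k[k] = float(diagC_A.sum())
                usq_k[k] = float(tA @ tA)
            else:
                sl = self.rest_slices[b.name]
                tr_k[k] = float(np.trace(Sinv[sl, sl]))
                usq_k[k] = float(tR[sl.start: sl.stop] @ tR[sl.start: sl.stop])

        q_k = np.array([b.n_cols for b in self.blocks if b.kind == "random"], dtype=float)
        # d(neg2ll) / d log sigma2
        grad_rand = q_k - (tr_k + usq_k) / s2r if self.K else np.zeros(0)
        grad_res = self.group_n - (Tg + sse) / s2g
        grad = np.concatenate([grad_rand, grad_res])

        if not want_state:
            return neg2, grad
        state = {
            "tA": tA, "tR": tR, "resid": resid, "H": H, "sse": sse, "Tg": Tg,
            "tr_k": tr_k, "usq_k": usq_k, "q_k": q_k, "diagC_A": diagC_A,
            "Sinv": Sinv, "D": D, "neg2": neg2,
        }
        return neg2, grad, state

    def em_step(self, s2):
        """One EM update of all variance parameters (monotone in lR)."""
        neg2, _, st = self.neg2ll(s2, want_grad=True, want_state=True)
        new = s2.copy()
        if self.K:
            new[: self.K] = (st["usq_k"] + st["tr_k"]) / st["q_k"]
        new[self.K:] = (st["sse"] + st["Tg"]) / self.group_n
        return np.maximum(new, self.var_floor), neg2


# ---------------------------------------------------------------------------
# public fitting API


def fit(
    data: "HistoricalDataset | pd.DataFrame",
    spec: ModelSpec,
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Fit ``spec`` to the records by REML and assemble a :class:`FitResult`.

    ``data`` may be a :class:`HistoricalDataset` (its phenotype table is
    used) or any record DataFrame containing the referenced columns.
    Variance components are constrained non-negative; components that end on
    the lower floor are listed in ``result.boundary``.
    """
    df = data.phenotypes if isinstance(data, HistoricalDataset) else data
    df = df.reset_index(drop=True)
    prob = _Problem(df, spec, options)

    s2 = prob.initial_params()
    trajectory: list[float] = []
    for _ in range(options.em_iter):
        s2, neg2 = prob.em_step(s2)
        trajectory.append(-0.5 * neg2)
        if len(trajectory) >= 2 and abs(trajectory[-1] - trajectory[-2]) <= (
            options.rel_tol * (abs(trajectory[-2]) + 1.0)
        ):
            break

    lo = np.log(prob.var_floor)
    hi = np.log(1e6 * prob.scale)
    x0 = np.clip(np.log(s2), lo, hi)

    def objective(x):
        val, grad = prob.neg2ll(np.exp(x), want_grad=True)
        return val, grad

    success = False
    for attempt in range(3):
        opt = scipy.optimize.minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(lo, hi)] * prob.n_params,
            options={"maxiter": options.max_iter, "ftol": 1e-12, "gtol": options.grad_tol},
        )
        s2 = np.exp(opt.x)
        if opt.success:
            success = True
            break
        # line-search stall: polish with EM steps and restart once or twice
        for _ in range(10):
            s2, _ = prob.em_step(s2)
        x0 = np.clip(np.log(s2), lo, hi)
    neg2, grad, st = prob.neg2ll(s2, want_grad=True, want_state=True)
    trajectory.append(-0.5 * neg2)
    x_final = np.clip(np.log(s2), lo, hi)
    free = (x_final > lo + 1e-6) & (x_final < hi - 1e-6)
    grad_norm = float(np.max(np.abs(grad[free]))) if free.any() else 0.0
    converged = success or grad_norm < 0.1
    if not converged:
        raise ConvergenceError(
            f"REML did not converge within {options.max_iter} iterations "
            f"(|grad|={grad_norm:.3g}): {opt.message}",
            trajectory,
        )

    # ---- assemble result -------------------------------------------------
    s2r, s2g = s2[: prob.K], s2[prob.K:]
    variance_components = {name: float(s2r[i]) for i, name in enumerate(prob.random_names)}
    group_var = {g: float(s2g[i]) for i, g in enumerate(prob.glevels)}
    residual_variances = {
        orig: group_var[mapped] for orig, mapped in sorted(
            prob.group_of.items(), key=lambda kv: str(kv[0])
        )
    }
    boundary = [
        name for i, name in enumerate(prob.random_names) if s2r[i] <= 10 * prob.var_floor
    ]
    boundary += [
        f"residual[{g}]" for i, g in enumerate(prob.glevels) if s2g[i] <= 10 * prob.var_floor
    ]

    fixed_estimates: dict[str, pd.DataFrame] = {}
    random_predictions: dict[str, pd.Series] = {}
    for b in prob.blocks:
        if b is prob.absorbed:
            est = st["tA"]
            se = np.sqrt(np.maximum(st["diagC_A"], 0.0))
            if b.kind == "random":
                random_predictions[b.name] = pd.Series(est, index=b.levels, name=b.name)
            elif b.kind == "fixed":
                fixed_estimates[b.name] = pd.DataFrame(
                    {"estimate": est, "se": se}, index=b.levels
                )
            else:
                fixed_estimates[b.name] = pd.DataFrame(
                    {"estimate": est, "se": se}, index=b.levels
                )
        else:
            sl = prob.rest_slices[b.name]
            est = st["tR"][sl.start: sl.stop]
            se = np.sqrt(np.maximum(np.diag(st["Sinv"])[sl.start: sl.stop], 0.0))
            if b.kind == "random":
                random_predictions[b.name] = pd.Series(est, index=b.levels, name=b.name)
            else:
                levels = b.levels[1:] if b.drop_first else b.levels
                fixed_estimates[b.name] = pd.DataFrame(
                    {"estimate": est, "se": se}, index=levels
                )

    residuals = pd.DataFrame(
        {
            "raw": st["resid"],
            "leverage": st["H"],
            "sigma2": s2g[prob.gcodes],
            "group": prob.glevels[prob.gcodes],
        },
        index=df.index,
    )

    diagnostics: dict[str, object] = {
        "n_params": prob.n_params,
        "n_em_iter": options.em_iter,
        "var_floor": prob.var_floor,
    }
    fixed_factor = prob.spec.fixed[0] if prob.spec.fixed else None
    rand_factor = prob.spec.random[0] if prob.spec.random else None
    if fixed_factor and rand_factor and ":" not in fixed_factor and ":" not in rand_factor:
        ca, la = _codes(df, fixed_factor)
        cb, lb = _codes(df, rand_factor)
        ncc = _n_connected(ca, cb, len(la), len(lb))
        diagnostics["n_connected_components"] = ncc
        if ncc > 1:
            warnings.warn(
                f"design of {fixed_factor} x {rand_factor} splits into {ncc} "
                "disconnected groups; estimates are only comparable within groups",
                stacklevel=2,
            )

    return FitResult(
        spec=spec,
        n_records=prob.n,
        variance_components=variance_components,
        residual_variances=residual_variances,
        residual_group_of=dict(prob.group_of),
        fixed_estimates=fixed_estimates,
        random_predictions=random_predictions,
        residuals=residuals,
        log_restricted_likelihood=-0.5 * neg2,
        n_iter=int(opt.nit) + len(trajectory),
        final_grad_norm=grad_norm,
        converged=converged,
        trajectory=trajectory,
        boundary=boundary,
        diagnostics=diagnostics,
    )


def estimate_blues(
    ds: "HistoricalDataset | pd.DataFrame",
    trait: str,
    heterogeneous: bool = True,
    options: FitOptions = FitOptions(),
) -> tuple[pd.DataFrame, FitResult]:
    """BLUEs of all accessions for one trait (fixed accession, random year).

    Returns the BLUE table (accession_id, trait, blue, se, n_years) and the
    underlying fit.  BLUEs are on the trait's metric scale; adding a
    constant to all observations shifts every BLUE by that constant.
    """
    df = ds.phenotypes if isinstance(ds, HistoricalDataset) else ds
    df = df[df["trait"] == trait] if "trait" in df.columns else df
    if df.empty:
        raise RemlError(f"no records for trait {trait!r}")
    result = fit(df.reset_index(drop=True), ModelSpec.historical_blues(heterogeneous), options)
    est = result.fixed_estimates["accession"]
    n_years = df.groupby("accession")["year"].nunique()
    table = pd.DataFrame(
        {
            "accession_id": est.index,
            "trait": trait,
            "blue": est["estimate"].to_numpy(),
            "se": est["se"].to_numpy(),
            "n_years": n_years.reindex(est.index).to_numpy(),
        }
    ).reset_index(drop=True)
    return table, result


def estimate_components(
    ds: "HistoricalDataset | pd.DataFrame",
    trait: str,
    heterogeneous: bool = True,
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Variance components for one trait (accession and year both random)."""
    df = ds.phenotypes if isinstance(ds, HistoricalDataset) else ds
    df = df[df["trait"] == trait] if "trait" in df.columns else df
    if df.empty:
        raise RemlError(f"no records for trait {trait!r}")
    return fit(df.reset_index(drop=True), ModelSpec.historical_components(heterogeneous), options)


def heritability(sigma2_G: float, sigma2_e_mean: float, mean_years: float) -> float:
    """Entry-mean heritability ``sigma2_G / (sigma2_G + sigma2_e / n_years)``."""
    if sigma2_G < 0 or sigma2_e_mean < 0:
        raise ValueError("variance components must be >= 0")
    if mean_years <= 0:
        raise ValueError("mean_years must be positive")
    denom = sigma2_G + sigma2_e_mean / mean_years
    if denom == 0:
        return 0.0
    return float(sigma2_G / denom)


def studentized_residuals(result: FitResult, untestable_rel_var: float = 1e-6) -> pd.Series:
    """Residuals scaled by their estimated conditional standard deviation.

    Each raw residual is divided by ``sqrt(sigma2_group - leverage)``, the
    model-based variance of the observed-minus-fitted value, so the
    statistics are approximately standard normal under the model.  Records
    whose conditional variance is numerically zero relative to the group
    variance (e.g. an accession observed only once, fitted exactly) carry no
    outlier information and get a studentized residual of 0.
    """
    res = result.residuals
    sigma2 = res["sigma2"].to_numpy()
    floor = 20.0 * float(result.diagnostics.get("var_floor", 0.0)) + 1e-300
    counts = res.groupby("group", observed=True).size()
    for g, cnt in counts.items():
        gvar = res.loc[res["group"] == g, "sigma2"].iloc[0]
        if cnt > 1 and gvar <= floor:
            raise RemlError(
                f"residual group {g!r} has zero estimated variance with "
                f"{cnt} records; studentized residuals are degenerate"
            )
    cond = sigma2 - res["leverage"].to_numpy()
    rel = cond / np.where(sigma2 > 0, sigma2, 1.0)
    t = np.zeros(len(res))
    testable = rel > untestable_rel_var
    t[testable] = res["raw"].to_numpy()[testable] / np.sqrt(cond[testable])
    return pd.Series(t, index=res.index, name="studentized")
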