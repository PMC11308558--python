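"""Multivariate screening of the predictor space: structural associations,
correlation matrices, rank-vs-moment discrepancies, variable clustering,
variance inflation factors and redundancy analysis.

The outcome variable is never used in this module; every statistic concerns
the joint distribution of the predictors only.

Correlation matrices are estimated pairwise-complete (entries with fewer
than ``min_pairs`` complete pairs are flagged unreliable). Collinearity is
quantified by the variance inflation factor VIF_j = 1/(1 - R^2_j): on the
linear basis it is the j-th diagonal of the inverse correlation matrix of the
complete-case predictors; on the additive basis each continuous predictor is
expanded in a restricted-cubic-spline basis and a generalized VIF is computed
per predictor group via the determinant formula, scaled by the
GVIF^{1/(2 df)} convention for comparability across basis dimensions.
Redundancy analysis iteratively removes any predictor whose additive fit on
the remaining predictors exceeds the plan's R^2 threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import AnalysisDataset, DataDictionary, IDAPlan, Role, Scale
from .missingness import Dendrogram, cluster_missingness, DiscordanceMatrix
from .univariate import summarize_continuous

__all__ = [
    "CorrelationMatrix",
    "VifResult",
    "RedundancyResult",
    "spearman_matrix",
    "pearson_matrix",
    "correlation_discrepancies",
    "structural_association_table",
    "interaction_screen",
    "variable_clusters",
    "vif",
    "redundancy_analysis",
    "rcs_basis",
]

#: Reported in place of a VIF whose correlation matrix is numerically singular.
VIF_SINGULAR = float("inf")
_COND_GUARD = 1e12


@dataclass
class CorrelationMatrix:
    variables: list[str]
    method: str  # "spearman" | "pearson"
    r: np.ndarray
    n_pairs: np.ndarray
    min_pairs: int = 30

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.variables, columns=self.variables)

    def pair(self, a: str, b: str) -> float:
        i, j = self.variables.index(a), self.variables.index(b)
        return float(self.r[i, j])

    def unreliable_mask(self) -> np.ndarray:
        m = self.n_pairs < self.min_pairs
        np.fill_diagonal(m, False)
        return m

    def to_long(self) -> pd.DataFrame:
        """Long format: one row per unordered pair."""
        rows = []
        for i, a in enumerate(self.variables):
            for j in range(i + 1, len(self.variables)):
                rows.append({
                    "var1": a, "var2": self.variables[j], "method": self.method,
                    "r": float(self.r[i, j]), "n_pairs": int(self.n_pairs[i, j]),
                })
        return pd.DataFrame(rows)


@dataclass
class VifResult:
    model_set: str
    basis: str  # "linear" | "additive"
    vif: dict[str, float]          # scaled GVIF^(1/df): comparable across df
    gvif: dict[str, float]         # raw generalized VIF
    df_per_variable: dict[str, int]
    n_complete: int


@dataclass
class RedundancyResult:
    model_set: str
    r_squared: dict[str, float]               # final-pass R^2 per remaining predictor
    removal_sequence: list[tuple[str, float]]  # (variable, R^2 at removal)
    notices: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# numeric design helpers
# ---------------------------------------------------------------------------

def _numeric_column(ds: AnalysisDataset, spec) -> pd.Series:
    """Screening-grade numeric view of one variable: continuous/ordinal pass
    through; two-level categoricals map to 0/1 in sorted level order."""
    col = ds.df[spec.name]
    if spec.scale in (Scale.CONTINUOUS, Scale.ORDINAL):
        return col.astype(float)
    levels = sorted(col.dropna().unique(), key=str)
    if len(levels) > 2:
        raise ValueError(
            f"{spec.name}: {len(levels)}-level categorical has no scalar encoding")
    mapping = {lev: float(k) for k, lev in enumerate(levels)}
    return col.map(mapping).astype(float)


def _indicator_columns(col: pd.Series, name: str) -> pd.DataFrame:
    """Reference-coded indicators for a categorical column (first level
    sorted lexically is the reference)."""
    levels = sorted(col.dropna().unique(), key=str)
    out = pd.DataFrame(index=col.index)
    for lev in levels[1:]:
        out[f"{name}={lev}"] = (col == lev).astype(float).where(col.notna())
    return out


def rcs_basis(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """Restricted cubic spline basis (truncated-power form).

    Returns k-1 columns for k knots: the identity plus k-2 nonlinear terms
    that are linear beyond the boundary knots; nonlinear terms are normalized
    by (t_k - t_1)^2 to keep columns on comparable scales.
    """
    t = np.asarray(sorted(knots), dtype=float)
    k = t.size
    if k < 3:
        return x[:, None].astype(float)
    norm = (t[-1] - t[0]) ** 2

    def pos3(v):
        return np.maximum(v, 0.0) ** 3

    cols = [x.astype(float)]
    denom = t[-1] - t[-2]
    for j in range(k - 2):
        term = (pos3(x - t[j])
                - pos3(x - t[-2]) * (t[-1] - t[j]) / denom
                + pos3(x - t[-1]) * (t[-2] - t[j]) / denom)
        cols.append(term / norm)
    return np.column_stack(cols)


def _quantile_knots(x: np.ndarray, n_knots: int) -> np.ndarray:
    """Knots at equally spaced quantiles between 0.05 and 0.95."""
    probs = np.linspace(0.05, 0.95, n_knots)
    return np.quantile(x, probs)


def _spline_df(spec, dictionary: DataDictionary) -> int:
    """Flexibility hierarchy: key predictors get 4 knots, others 3."""
    return 4 if spec.role is Role.KEY else 3


# ---------------------------------------------------------------------------
# V2 / VE1: correlation matrices
# ---------------------------------------------------------------------------

def _corr_matrix(
    ds: AnalysisDataset,
    variables: Sequence[str],
    dictionary: DataDictionary,
    method: str,
    min_pairs: int,
) -> CorrelationMatrix:
    variables = list(variables)
    if len(variables) < 2:
        raise ValueError("correlation matrix requires >= 2 variables")
    cols = {v: _numeric_column(ds, dictionary[v]) for v in variables}
    X = pd.DataFrame(cols)
    notna = X.notna().to_numpy(dtype=float)
    n_pairs = (notna.T @ notna).astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = X.corr(method=method, min_periods=2).to_numpy()
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(variables=variables, method=method, r=r,
                             n_pairs=n_pairs, min_pairs=min_pairs)


def spearman_matrix(
    ds: AnalysisDataset,
    variables: Sequence[str],
    dictionary: DataDictionary,
    min_pairs: int = 30,
) -> CorrelationMatrix:
    """Pairwise-complete Spearman rank correlations (average ranks for ties)."""
    return _corr_matrix(ds, variables, dictionary, "spearman", min_pairs)


def pearson_matrix(
    ds: AnalysisDataset,
    variables: Sequence[str],
    dictionary: DataDictionary,
    min_pairs: int = 30,
) -> CorrelationMatrix:
    """Pairwise-complete Pearson product-moment correlations."""
    return _corr_matrix(ds, variables, dictionary, "pearson", min_pairs)


def correlation_discrepancies(
    S: CorrelationMatrix, P: CorrelationMatrix, delta: float = 0.1
) -> pd.DataFrame:
    """Pairs whose Spearman and Pearson correlations differ by more than
    ``delta`` units, sorted by decreasing discrepancy. Such pairs deserve a
    scatterplot review: outliers inflate Pearson, curvature inflates Spearman.
    """
    if S.variables != P.variables:
        raise ValueError("matrices cover different variable sets")
    rows = []
    for i, a in enumerate(S.variables):
        for j in range(i + 1, len(S.variables)):
            rs, rp = S.r[i, j], P.r[i, j]
            if np.isnan(rs) or np.isnan(rp):
                continue
            gap = abs(rs - rp)
            if gap > delta:
                rows.append({"var1": a, "var2": S.variables[j],
                             "spearman": float(rs), "pearson": float(rp),
                             "discrepancy": float(gap)})
    out = pd.DataFrame(rows, columns=["var1", "var2", "spearman", "pearson", "discrepancy"])
    return out.sort_values("discrepancy", ascending=False, ignore_index=True) if len(out) else out


# ---------------------------------------------------------------------------
# V1: associations with structural variables
# ---------------------------------------------------------------------------

def structural_association_table(
    ds: AnalysisDataset,
    dictionary: DataDictionary,
    plan: IDAPlan,
    transformed: AnalysisDataset | None = None,
) -> pd.DataFrame:
    """Association of each predictor with the structural variables.

    For a continuous structural variable: Spearman correlation with each
    predictor within strata of the categorical structural variables (or
    overall when none exist). For a categorical structural variable: per-level
    median/IQR of each predictor. Strata with fewer than ``min_pairs``
    complete pairs are flagged.
    """
    structural = dictionary.structural
    predictors = [v for v in dictionary.predictors
                  if v.role is not Role.STRUCTURAL and v.name in ds.df.columns]
    cat_struct = [v for v in structural if v.is_categorical]
    rows = []

    def strata_iter():
        if not cat_struct:
            yield "all", pd.Series(True, index=ds.df.index)
            return
        sv = cat_struct[0]
        for lev in sorted(ds.df[sv.name].dropna().unique(), key=str):
            yield f"{sv.name}={lev}", ds.df[sv.name] == lev

    for v in structural:
        if v.scale is Scale.CONTINUOUS:
            s = ds.df[v.name].astype(float)
            for p in predictors:
                if not p.is_categorical:
                    x = ds.df[p.name].astype(float)
                    for label, mask in strata_iter():
                        pairs = mask & s.notna() & x.notna()
                        n = int(pairs.sum())
                        if n >= 2:
                            rho = s[pairs].corr(x[pairs], method="spearman")
                        else:
                            rho = np.nan
                        rows.append({
                            "structural": v.name, "predictor": p.name,
                            "stratum": label, "statistic": "spearman",
                            "value": float(rho) if rho == rho else np.nan,
                            "n": n, "low_n": n < plan.min_pairs,
                        })
        else:
            for p in predictors:
                if p.is_categorical:
                    continue
                for lev in sorted(ds.df[v.name].dropna().unique(), key=str):
                    sub = ds.df[p.name][ds.df[v.name] == lev].dropna()
                    rows.append({
                        "structural": v.name, "predictor": p.name,
                        "stratum": f"{v.name}={lev}", "statistic": "median",
                        "value": float(sub.median()) if len(sub) else np.nan,
                        "n": int(len(sub)), "low_n": len(sub) < plan.min_pairs,
                    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# V3: declared interactions
# ---------------------------------------------------------------------------

def interaction_screen(
    ds: AnalysisDataset,
    plan: IDAPlan,
    dictionary: DataDictionary,
    transformed: AnalysisDataset | None = None,
) -> list[dict]:
    """Joint-distribution summaries for declared interaction pairs: Spearman
    correlation plus a 4x4 quantile-bin sparsity grid on the (transformed
    where chosen) scale."""
    src = transformed if transformed is not None else ds
    out = []
    for a, b in plan.interactions:
        ca = f"t_{a}" if transformed is not None and f"t_{a}" in src.df else a
        cb = f"t_{b}" if transformed is not None and f"t_{b}" in src.df else b
        xa = _numeric_column(src, dictionary[a]) if ca == a else src.df[ca].astype(float)
        xb = _numeric_column(src, dictionary[b]) if cb == b else src.df[cb].astype(float)
        mask = xa.notna() & xb.notna()
        xa, xb = xa[mask], xb[mask]
        rho = float(xa.corr(xb, method="spearman")) if mask.sum() >= 2 else np.nan

        def qbin(x: pd.Series) -> pd.Series:
            edges = np.unique(np.quantile(x, [0, 0.25, 0.5, 0.75, 1.0]))
            if edges.size < 2:
                return pd.Series(0, index=x.index)
            return pd.cut(x, bins=edges, labels=False, include_lowest=True)

        grid = pd.crosstab(qbin(xa), qbin(xb)).reindex(
            index=range(4), columns=range(4), fill_value=0).to_numpy()
        out.append({
            "pair": (a, b), "x_column": ca, "y_column": cb,
            "spearman": rho, "n_pairs": int(mask.sum()),
            "sparsity_grid": grid,
        })
    return out


# ---------------------------------------------------------------------------
# VE2: variable clustering
# ---------------------------------------------------------------------------

def variable_clusters(
    S: CorrelationMatrix, plan: IDAPlan
) -> tuple[Dendrogram, pd.DataFrame, list[str]]:
    """Cluster predictors on 1 - rho_S^2 (average linkage) and list pairs with
    Spearman correlation above the plan's ``high_corr`` threshold.

    Squared correlation as similarity captures negative association too.
    Variables with undefined matrix entries are excluded with a notice.
    Returns (dendrogram, high-correlation pair table, exclusion notices).
    """
    r = S.r.copy()
    bad = np.isnan(r).any(axis=1)
    notices = [f"{S.variables[i]} excluded: undefined correlation entries"
               for i in np.flatnonzero(bad)]
    keep = ~bad
    vars_ = [v for v, k in zip(S.variables, keep) if k]
    rk = r[np.ix_(keep, keep)]
    dist = 1.0 - rk ** 2
    np.fill_diagonal(dist, 0.0)
    dendro = cluster_missingness(
        DiscordanceMatrix(variables=vars_, d=dist), method="average")
    dendro.linkage_method = "average"

    rows = []
    for i, a in enumerate(vars_):
        for j in range(i + 1, len(vars_)):
            if rk[i, j] > plan.thresholds.high_corr:
                rows.append({"var1": a, "var2": vars_[j], "spearman": float(rk[i, j])})
    pairs = pd.DataFrame(rows, columns=["var1", "var2", "spearman"])
    if len(pairs):
        pairs = pairs.sort_values("spearman", ascending=False, ignore_index=True)
    return dendro, pairs, notices


# ---------------------------------------------------------------------------
# VE3: variance inflation factors
# ---------------------------------------------------------------------------

def _group_design(
    ds_cc: pd.DataFrame,
    specs,
    dictionary: DataDictionary,
    basis: str,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Design matrix on complete cases, with a named column group per
    predictor. Continuous predictors expand to an RCS basis under the
    additive basis; categoricals become indicator sets."""
    blocks: list[pd.DataFrame] = []
    groups: dict[str, list[str]] = {}
    for spec in specs:
        col = ds_cc[spec.name]
        if spec.is_categorical:
            levels = col.dropna().unique()
            if len(levels) <= 2:
                sub = pd.DataFrame({spec.name: _numeric_series_cc(col)})
            else:
                sub = _indicator_columns(col, spec.name)
        else:
            x = col.to_numpy(dtype=float)
            if basis == "additive":
                knots = _quantile_knots(x, _spline_df(spec, dictionary))
                B = rcs_basis(x, knots)
                sub = pd.DataFrame(
                    B, index=col.index,
                    columns=[spec.name] + [f"{spec.name}'{k}" for k in range(1, B.shape[1])])
            else:
                sub = pd.DataFrame({spec.name: x}, index=col.index)
        # drop constant columns (degenerate spline terms on spiky data)
        sub = sub.loc[:, sub.nunique() > 1]
        if sub.shape[1] == 0:
            groups[spec.name] = []
            continue
        blocks.append(sub)
        groups[spec.name] = list(sub.columns)
    X = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=ds_cc.index)
    return X, groups


def _numeric_series_cc(col: pd.Series) -> pd.Series:
    levels = sorted(col.dropna().unique(), key=str)
    return col.map({lev: float(k) for k, lev in enumerate(levels)}).astype(float)


def vif(
    ds: AnalysisDataset,
    model_set: Sequence[str],
    dictionary: DataDictionary,
    plan: IDAPlan,
    basis: str = "linear",
    set_name: str = "",
) -> VifResult:
    """Variance inflation factors on the complete cases of a candidate set.

    ``basis="linear"``: VIF_j is the j-th diagonal of the inverse correlation
    matrix of the predictors. ``basis="additive"``: continuous predictors are
    expanded in restricted-cubic-spline bases (4 knots for key predictors, 3
    otherwise, knots at equally spaced quantiles) and a generalized VIF is
    computed per predictor group; the reported ``vif`` is GVIF^(1/df) — the
    square of the GVIF^{1/(2 df)} convention — so that single-column groups
    reproduce the ordinary VIF. The outcome is never part of the design.

    A numerically singular correlation matrix yields ``inf`` markers, not an
    exception.
    """
    members = [dictionary[m] for m in model_set]
    cc = ds.df[list(model_set)].dropna()
    if len(cc) < len(model_set) + 2:
        raise ValueError("too few complete cases for VIF")
    X, groups = _group_design(cc, members, dictionary, basis)
    Xv = X.to_numpy(dtype=float)
    R = np.corrcoef(Xv, rowvar=False)
    R = np.atleast_2d(R)

    singular = np.linalg.cond(R) > _COND_GUARD
    sign_all, logdet_all = np.linalg.slogdet(R)
    col_index = {c: k for k, c in enumerate(X.columns)}

    vifs: dict[str, float] = {}
    gvifs: dict[str, float] = {}
    dfs: dict[str, int] = {}
    for name, cols in groups.items():
        if not cols:
            vifs[name] = np.nan
            gvifs[name] = np.nan
            dfs[name] = 0
            continue
        dfs[name] = len(cols)
        if singular or sign_all <= 0:
            vifs[name] = VIF_SINGULAR
            gvifs[name] = VIF_SINGULAR
            continue
        idx = [col_index[c] for c in cols]
        rest = [k for k in range(R.shape[0]) if k not in idx]
        s1, ld1 = np.linalg.slogdet(R[np.ix_(idx, idx)])
        if rest:
            s2, ld2 = np.linalg.slogdet(R[np.ix_(rest, rest)])
        else:
            s2, ld2 = 1.0, 0.0
        if s1 <= 0 or s2 <= 0:
            vifs[name] = VIF_SINGULAR
            gvifs[name] = VIF_SINGULAR
            continue
        log_gvif = ld1 + ld2 - logdet_all
        gvif = float(np.exp(log_gvif))
        gvifs[name] = gvif
        vifs[name] = float(np.exp(log_gvif / len(cols)))  # GVIF^(1/df)
    return VifResult(model_set=set_name or ",".join(model_set), basis=basis,
                     vif=vifs, gvif=gvifs, df_per_variable=dfs, n_complete=len(cc))


# ---------------------------------------------------------------------------
# VE3: redundancy analysis
# ---------------------------------------------------------------------------

def _fit_r2(y: np.ndarray, X: np.ndarray) -> float:
    """R^2 of an OLS fit with intercept."""
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot <= 0:
        return np.nan
    return float(max(0.0, min(1.0, 1.0 - np.sum(resid ** 2) / ss_tot)))


def redundancy_analysis(
    ds: AnalysisDataset,
    model_set: Sequence[str],
    dictionary: DataDictionary,
    plan: IDAPlan,
    set_name: str = "",
) -> RedundancyResult:
    """Iterative redundancy screen on the complete cases of a candidate set.

    Each remaining predictor is fit on all others with the additive
    (restricted-cubic-spline) basis; the predictor with the largest R^2 is
    removed while that R^2 exceeds the plan's ``redundancy_r2`` threshold.
    Categorical predictors enter as indicator sets; a categorical target's
    R^2 is the maximum over its indicators. Degenerate fits are skipped with
    a notice.
    """
    thr = plan.thresholds.redundancy_r2
    cc = ds.df[list(model_set)].dropna()
    if len(cc) < len(model_set) + 2:
        raise ValueError("too few complete cases for redundancy analysis")
    remaining = list(model_set)
    removal: list[tuple[str, float]] = []
    notices: list[str] = []
    r2_final: dict[str, float] = {}

    while len(remaining) >= 2:
        specs = {m: dictionary[m] for m in remaining}
        r2: dict[str, float] = {}
        for target in remaining:
            others = [specs[m] for m in remaining if m != target]
            X, _ = _group_design(cc, others, dictionary, basis="additive")
            if X.shape[1] == 0:
                notices.append(f"{target}: no usable regressors, skipped")
                continue
            Xv = X.to_numpy(dtype=float)
            tspec = specs[target]
            if tspec.is_categorical:
                col = cc[target]
                levels = sorted(col.dropna().unique(), key=str)
                if len(levels) < 2:
                    notices.append(f"{target}: constant on complete cases, skipped")
                    continue
                vals = [_fit_r2((col == lev).to_numpy(dtype=float), Xv)
                        for lev in levels[1:]]
                val = np.nanmax(vals)
            else:
                y = cc[target].to_numpy(dtype=float)
                if np.ptp(y) == 0:
                    notices.append(f"{target}: constant on complete cases, skipped")
                    continue
                val = _fit_r2(y, Xv)
            if np.isnan(val):
                notices.append(f"{target}: fit did not converge, skipped")
                continue
            r2[target] = val
        if not r2:
            break
        worst = max(r2, key=r2.get)
        if r2[worst] > thr:
            removal.append((worst, r2[worst]))
            remaining.remove(worst)
        else:
            r2_final = r2
            break
    return RedundancyResult(model_set=set_name or ",".join(model_set),
                            r_squared=r2_final, removal_sequence=removal,
                            notices=notices)
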