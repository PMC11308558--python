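"""Missing-value screening: unit and item missingness, complete-case
cascades, stratified patterns, and the missingness-discordance dendrogram.

The central pattern summary is the discordance matrix: for two variables i
and j, d(i, j) is the exact fraction of rows in which exactly one of the two
is missing. d is a genuine distance on missingness indicators (d(i,i)=0,
symmetric, and bounded by |p_i - p_j| <= d(i,j) <= min(1, p_i + p_j) where p
are the marginal missing proportions). Hierarchical clustering on d groups
variables that tend to be missing together — e.g. members of one lab panel
ordered as a block — which matters when choosing between predictor omission
and imputation: variables with near-identical missingness cannot impute each
other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .data_model import AnalysisDataset, DataDictionary, IDAPlan, Role, Scale

__all__ = [
    "MissingSummary",
    "CascadeRow",
    "DiscordanceMatrix",
    "Dendrogram",
    "unit_missingness_summary",
    "item_missingness",
    "complete_case_cascade",
    "stratified_complete_cases",
    "missingness_discordance_matrix",
    "cluster_missingness",
    "compare_missingness_groups",
    "age_decade_bins",
]

NOT_EVALUABLE = "not evaluable"


@dataclass(frozen=True)
class MissingSummary:
    variable: str
    n_total: int
    n_missing: int
    by_reason: Mapping[str, int] | None = None

    @property
    def proportion(self) -> float:
        return self.n_missing / self.n_total


@dataclass(frozen=True)
class CascadeRow:
    set_name: str
    variables: tuple[str, ...]
    n_total: int
    n_complete: int

    @property
    def proportion_complete(self) -> float:
        return self.n_complete / self.n_total


@dataclass
class DiscordanceMatrix:
    variables: list[str]
    d: np.ndarray  # symmetric, zero diagonal, fractions in [0, 1]

    def pair(self, a: str, b: str) -> float:
        i, j = self.variables.index(a), self.variables.index(b)
        return float(self.d[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.variables, columns=self.variables)


@dataclass
class Dendrogram:
    """Binary merge tree from agglomerative clustering.

    ``merge_matrix`` is the scipy linkage encoding; ``leaf_annotations``
    carries per-leaf display values (e.g. missing percentages).
    """

    leaves: list[str]
    merge_matrix: np.ndarray
    linkage_method: str
    leaf_annotations: dict[str, float] = field(default_factory=dict)

    @property
    def heights(self) -> np.ndarray:
        return self.merge_matrix[:, 2]

    def merge_table(self) -> pd.DataFrame:
        """Plain-table merge list: one row per internal node."""
        return pd.DataFrame({
            "left": self.merge_matrix[:, 0].astype(int),
            "right": self.merge_matrix[:, 1].astype(int),
            "height": self.merge_matrix[:, 2],
            "size": self.merge_matrix[:, 3].astype(int),
        })

    def merge_height_of_pair(self, a: str, b: str) -> float:
        """Height of the first merge joining the clusters containing a and b."""
        ia, ib = self.leaves.index(a), self.leaves.index(b)
        n = len(self.leaves)
        members: dict[int, set[int]] = {i: {i} for i in range(n)}
        for k, (l, r, h, _) in enumerate(self.merge_matrix):
            merged = members[int(l)] | members[int(r)]
            members[n + k] = merged
            if ia in merged and ib in merged:
                return float(h)
        raise RuntimeError("pair never merged")  # pragma: no cover

    def cut(self, height: float) -> dict[str, int]:
        """Flat cluster labels obtained by cutting the tree at ``height``."""
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(self.merge_matrix, t=height, criterion="distance")
        return dict(zip(self.leaves, (int(x) for x in labels)))

    def to_newick(self, precision: int = 6) -> str:
        """Serialize as Newick; branch lengths are height differences."""
        tree = to_tree(self.merge_matrix)

        def fmt(name: str) -> str:
            ann = self.leaf_annotations.get(name)
            return f"{name}" if ann is None else f"{name} ({100 * ann:.0f}%)".replace(" ", "_")

        def walk(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{fmt(self.leaves[node.id])}:{length:.{precision}f}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.{precision}f}"

        return walk(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# M1: unit (participant) missingness
# ---------------------------------------------------------------------------

def unit_missingness_summary(
    counts: Mapping[str, int] | None,
) -> pd.DataFrame | str:
    """Attrition table from enrollment counts, or the explicit marker
    ``"not evaluable"`` when no counts were supplied (e.g. registry exports
    contain only performed analyses).

    ``counts`` keys: ``eligible``, ``assessed``, ``recruited`` (any prefix of
    this chain). Attrition fractions are computed between consecutive stages.
    """
    if not counts:
        return NOT_EVALUABLE
    order = [k for k in ("eligible", "assessed", "recruited", "contributed") if k in counts]
    values = [int(counts[k]) for k in order]
    if any(v < 0 for v in values):
        raise ValueError("enrollment counts must be non-negative")
    for (sa, va), (sb, vb) in zip(zip(order, values), zip(order[1:], values[1:])):
        if vb > va:
            raise ValueError(f"{sb} count {vb} exceeds {sa} count {va}")
    rows = []
    for i, (stage, v) in enumerate(zip(order, values)):
        attr = np.nan if i == 0 else (values[i - 1] - v) / values[i - 1]
        rows.append({"stage": stage, "n": v, "attrition_from_previous": attr})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# M2: item missingness
# ---------------------------------------------------------------------------

def item_missingness(
    ds: AnalysisDataset, dictionary: DataDictionary
) -> list[MissingSummary]:
    """Missing count and proportion per variable (outcome and structural
    variables included; identifiers excluded)."""
    out = []
    for v in dictionary:
        if v.role is Role.IDENTIFIER or v.name not in ds.df.columns:
            continue
        col = ds.df[v.name]
        out.append(MissingSummary(
            variable=v.name, n_total=len(col), n_missing=int(col.isna().sum())
        ))
    return out


# ---------------------------------------------------------------------------
# M3: complete-case cascade
# ---------------------------------------------------------------------------

def _n_complete(ds: AnalysisDataset, variables: Sequence[str]) -> int:
    return int((~ds.df[list(variables)].isna().any(axis=1)).sum())


def complete_case_cascade(
    ds: AnalysisDataset, plan: IDAPlan, dictionary: DataDictionary
) -> list[CascadeRow]:
    """Complete observations for the outcome alone and for outcome + each
    model set. A row is complete for a set iff neither the outcome nor any
    set member is missing; rows with a missing outcome are incomplete in
    every cascade entry."""
    outcome = dictionary.outcome.name
    rows = [CascadeRow("outcome", (outcome,), ds.n_rows, _n_complete(ds, [outcome]))]
    for name, members in plan.model_sets.items():
        if not members:
            raise ValueError(f"model set {name!r} is empty")
        vars_ = (outcome, *members)
        rows.append(CascadeRow(name, tuple(members), ds.n_rows, _n_complete(ds, vars_)))
    return rows


def age_decade_bins(values: pd.Series) -> pd.Series:
    """Decade bins clipped to the observed range — the default stratification
    for a continuous structural variable such as age."""
    lo = int(np.floor(values.min() / 10.0) * 10)
    hi = int(np.ceil((values.max() + 1) / 10.0) * 10)
    edges = np.arange(lo, hi + 1, 10)
    return pd.cut(values, bins=edges, right=False, include_lowest=True)


def _structural_strata(
    ds: AnalysisDataset, dictionary: DataDictionary, plan: IDAPlan
) -> pd.Series:
    """Combined stratum label across all structural variables."""
    parts = []
    for v in dictionary.structural:
        col = ds.df[v.name]
        if v.scale is Scale.CONTINUOUS:
            rule = plan.structural_strata.get(v.name, "decades")
            if isinstance(rule, str):
                binned = age_decade_bins(col)
            else:
                binned = pd.cut(col, bins=list(rule), include_lowest=True)
            parts.append(binned.astype(str).radd(f"{v.name}="))
        else:
            parts.append(col.astype(str).radd(f"{v.name}="))
    if not parts:
        raise ValueError("no structural variables to stratify by")
    out = parts[0]
    for p in parts[1:]:
        out = out.str.cat(p, sep=" / ")
    return out


def stratified_complete_cases(
    ds: AnalysisDataset,
    plan: IDAPlan,
    dictionary: DataDictionary,
    min_stratum_size: int = 10,
) -> pd.DataFrame:
    """Complete-case cascade repeated within each structural stratum (M4).

    Returns a long table (stratum, set_name, n_total, n_complete,
    proportion_complete, small_stratum flag).
    """
    strata = _structural_strata(ds, dictionary, plan)
    records = []
    for stratum, idx in ds.df.groupby(strata, observed=True).groups.items():
        sub = AnalysisDataset(df=ds.df.loc[idx])
        for row in complete_case_cascade(sub, plan, dictionary):
            records.append({
                "stratum": stratum,
                "set_name": row.set_name,
                "n_total": row.n_total,
                "n_complete": row.n_complete,
                "proportion_complete": row.proportion_complete,
                "small_stratum": row.n_total < min_stratum_size,
            })
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# M4: discordance matrix + dendrogram
# ---------------------------------------------------------------------------

def missingness_discordance_matrix(
    ds: AnalysisDataset, variables: Sequence[str]
) -> DiscordanceMatrix:
    """Exact pairwise discordance of missingness indicators."""
    variables = list(variables)
    if len(variables) < 2:
        raise ValueError("discordance requires at least 2 variables")
    ind = ds.df[variables].isna().to_numpy(dtype=float)
    n = ind.shape[0]
    # d(i,j) = mean |I_i - I_j|; computed via inner products:
    # sum |a-b| = sum a + sum b - 2 sum ab for 0/1 indicators
    s = ind.sum(axis=0)
    cross = ind.T @ ind
    d = (s[:, None] + s[None, :] - 2.0 * cross) / n
    np.fill_diagonal(d, 0.0)
    return DiscordanceMatrix(variables=variables, d=d)


def cluster_missingness(
    m: DiscordanceMatrix,
    method: str = "average",
    missing_proportions: Mapping[str, float] | None = None,
) -> Dendrogram:
    """Agglomerative clustering of missingness indicators on discordance.

    ``method`` is the linkage ("average" default; "complete"/"single"
    selectable). Leaves are annotated with per-variable missing proportions
    when supplied.
    """
    if len(m.variables) < 2:
        raise ValueError("clustering requires at least 2 leaves")
    condensed = squareform(m.d, checks=False)
    Z = linkage(condensed, method=method)
    return Dendrogram(
        leaves=list(m.variables),
        merge_matrix=Z,
        linkage_method=method,
        leaf_annotations=dict(missing_proportions or {}),
    )


# ---------------------------------------------------------------------------
# ME1: predictors of missingness
# ---------------------------------------------------------------------------

DEGENERATE_SPLIT = "degenerate split"


def compare_missingness_groups(
    ds: AnalysisDataset,
    model_set: Sequence[str],
    dictionary: DataDictionary,
) -> pd.DataFrame | str:
    """Contrast complete vs incomplete cases (for a model set) on the
    structural variables.

    Continuous structural variables get a standardized mean difference
    (difference of group means over the pooled SD); categorical ones get
    per-level proportion differences. No hypothesis tests: screening must not
    generate inferential leakage. Returns the ``"degenerate split"`` marker
    when either group is empty.
    """
    outcome = dictionary.outcome.name
    complete = ~ds.df[[outcome, *model_set]].isna().any(axis=1)
    n1, n0 = int(complete.sum()), int((~complete).sum())
    if n1 == 0 or n0 == 0:
        return DEGENERATE_SPLIT

    records = []
    for v in dictionary.structural:
        col = ds.df[v.name]
        if v.scale is Scale.CONTINUOUS:
            a, b = col[complete], col[~complete]
            va = a.var(ddof=1) if len(a) > 1 else 0.0
            vb = b.var(ddof=1) if len(b) > 1 else 0.0
            pooled = np.sqrt(((len(a) - 1) * va + (len(b) - 1) * vb)
                             / max(len(a) + len(b) - 2, 1))
            smd = (a.mean() - b.mean()) / pooled if pooled > 0 else 0.0
            records.append({
                "variable": v.name, "level": None,
                "mean_complete": float(a.mean()), "mean_incomplete": float(b.mean()),
                "standardized_difference": float(smd),
            })
        else:
            levels = sorted(col.dropna().unique(), key=str)
            for lev in levels:
                pa = float((col[complete] == lev).mean())
                pb = float((col[~complete] == lev).mean())
                records.append({
                    "variable": v.name, "level": str(lev),
                    "prop_complete": pa, "prop_incomplete": pb,
                    "proportion_difference": pa - pb,
                })
    return pd.DataFrame(records)
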