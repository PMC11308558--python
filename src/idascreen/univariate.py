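"""Univariate descriptions of predictors and outcome.

Continuous variables get the dispersion battery (quantiles, mean, SD, IQR,
Gini mean difference), the five lowest/highest values, the number of distinct
values, and spike diagnostics. The Gini mean difference

    GMD = sum_{i != j} |x_i - x_j| / (n (n - 1))

is computed with the O(n log n) sorted-prefix identity
sum_{i<j} (x_(j) - x_(i)) = sum_i (2i - n - 1) x_(i).

A "spike" is a value concentration: the modal value carries an outsized share
of the observations (e.g. zero counts of rare cell types). The concentration
ratio — modal frequency over the average frequency per distinct value —
quantifies it; the spike flag uses the modal proportion directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import AnalysisDataset, IDAPlan, Scale

__all__ = [
    "CategoricalSummary",
    "ContinuousSummary",
    "SpikeFlag",
    "summarize_categorical",
    "summarize_continuous",
    "gini_mean_difference",
    "concentration_ratio",
    "detect_spikes",
]


@dataclass(frozen=True)
class CategoricalSummary:
    variable: str
    n_total: int
    n_missing: int
    levels: tuple[str, ...]
    counts: tuple[int, ...]
    collapsed_counts: Mapping[str, int] | None = None

    @property
    def n_nonmissing(self) -> int:
        return self.n_total - self.n_missing

    @property
    def proportions(self) -> tuple[float, ...]:
        n = self.n_nonmissing
        return tuple(c / n for c in self.counts) if n else ()


@dataclass(frozen=True)
class ContinuousSummary:
    variable: str
    n_total: int
    n_nonmissing: int
    n_distinct: int
    minimum: float
    maximum: float
    quantiles: Mapping[float, float]
    mean: float
    sd: float
    iqr: float
    gini_mean_difference: float | None
    five_lowest: tuple[float, ...]
    five_highest: tuple[float, ...]
    mode_value: float
    mode_count: int
    top_values: tuple[tuple[float, int], ...]  # five most frequent values

    @property
    def mode_proportion(self) -> float:
        return self.mode_count / self.n_nonmissing

    @property
    def concentration_ratio(self) -> float:
        return self.mode_count / (self.n_nonmissing / self.n_distinct)


@dataclass(frozen=True)
class SpikeFlag:
    variable: str
    mode_value: float
    mode_proportion: float
    concentration_ratio: float
    top_values: tuple[tuple[float, int], ...]


def summarize_categorical(
    ds: AnalysisDataset,
    variable: str,
    scale: Scale,
    collapse_map: Mapping[str, str] | None = None,
) -> CategoricalSummary:
    """Category frequencies and proportions (checklist item U1).

    Missing cells are excluded from denominators but reported. When a
    ``collapse_map`` is supplied, collapsed-category counts are added.
    """
    if scale is Scale.CONTINUOUS:
        raise ValueError(f"{variable}: categorical summary on a continuous variable")
    col = ds.df[variable]
    nonmissing = col.dropna()
    counts = nonmissing.value_counts().sort_index(key=lambda ix: ix.astype(str))
    collapsed = None
    if collapse_map is not None:
        mapped = nonmissing.map(lambda v: collapse_map.get(str(v), str(v)))
        collapsed = {str(k): int(c) for k, c in mapped.value_counts().items()}
    return CategoricalSummary(
        variable=variable,
        n_total=len(col),
        n_missing=int(col.isna().sum()),
        levels=tuple(str(x) for x in counts.index),
        counts=tuple(int(c) for c in counts.to_numpy()),
        collapsed_counts=collapsed,
    )


def gini_mean_difference(values: Sequence[float] | np.ndarray) -> float:
    """Mean absolute difference over all ordered pairs, O(n log n)."""
    x = np.sort(np.asarray(values, dtype=float))
    x = x[~np.isnan(x)]
    n = x.size
    if n < 2:
        raise ValueError("Gini mean difference requires at least 2 values")
    i = np.arange(1, n + 1)
    pair_sum = np.sum((2 * i - n - 1) * x)  # = sum_{i<j} (x_(j) - x_(i))
    return float(2.0 * pair_sum / (n * (n - 1)))


def concentration_ratio(values: Sequence[float] | np.ndarray) -> float:
    """Modal frequency over the average frequency per distinct value.

    Equals 1 both for all-distinct data and for a constant vector; large
    values indicate a spike.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("concentration ratio requires at least 1 value")
    _, counts = np.unique(x, return_counts=True)
    return float(counts.max() / (x.size / counts.size))


def summarize_continuous(
    ds: AnalysisDataset,
    variable: str,
    quantiles: Sequence[float] = (0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95),
) -> ContinuousSummary:
    """Full continuous description (checklist item U2).

    Quantiles follow the linear-interpolation convention of the empirical
    distribution. With a single distinct value the Gini mean difference is
    reported as None when n < 2 (its error path), SD as 0.
    """
    col = ds.df[variable]
    x = col.dropna().to_numpy(dtype=float)
    if x.size == 0:
        raise ValueError(f"{variable}: all values missing")
    xs = np.sort(x)
    uniq, counts = np.unique(xs, return_counts=True)
    # five most frequent values; ties broken by value for determinism
    order = np.lexsort((uniq, -counts))[:5]
    top = tuple((float(uniq[k]), int(counts[k])) for k in order)
    mode_k = order[0]
    qprobs = tuple(float(q) for q in quantiles)
    qvals = np.quantile(xs, qprobs)
    q25, q75 = np.quantile(xs, [0.25, 0.75])
    return ContinuousSummary(
        variable=variable,
        n_total=len(col),
        n_nonmissing=int(x.size),
        n_distinct=int(uniq.size),
        minimum=float(xs[0]),
        maximum=float(xs[-1]),
        quantiles=dict(zip(qprobs, (float(v) for v in qvals))),
        mean=float(xs.mean()),
        sd=float(xs.std(ddof=1)) if x.size > 1 else 0.0,
        iqr=float(q75 - q25),
        gini_mean_difference=gini_mean_difference(xs) if x.size > 1 else None,
        five_lowest=tuple(float(v) for v in xs[:5]),
        five_highest=tuple(float(v) for v in xs[-5:]),
        mode_value=float(uniq[mode_k]),
        mode_count=int(counts[mode_k]),
        top_values=top,
    )


def detect_spikes(summary: ContinuousSummary, plan: IDAPlan) -> SpikeFlag | None:
    """Flag a value concentration when the modal proportion reaches the
    plan's ``spike_mode_prop`` threshold (boundary counts as flagged)."""
    if summary.mode_proportion >= plan.thresholds.spike_mode_prop:
        return SpikeFlag(
            variable=summary.variable,
            mode_value=summary.mode_value,
            mode_proportion=summary.mode_proportion,
            concentration_ratio=summary.concentration_ratio,
            top_values=summary.top_values,
        )
    return None
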