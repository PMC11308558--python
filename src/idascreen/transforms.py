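"""Symmetrizing transformations for skewed predictors and the
normal-scores criterion that selects them.

Laboratory concentrations are typically right-skewed with mass at or near
zero, which rules out a plain logarithm. The pseudo-log

    pseudolog(x; sigma, b) = asinh(x / (2 sigma)) / ln(b)

is defined for all real x, antisymmetric, zero at zero, and approaches
log_b(x) - log_b(sigma) for x >> sigma, so one transformed unit corresponds
approximately to a b-fold change. The signed cube root sign(x)|x|^{1/3} is a
gentler alternative.

Whether a transformation succeeded in symmetrizing a predictor is judged by
the normal-scores correlation: the Pearson correlation of the sorted sample
with standard-normal quantiles at Blom plotting positions (i - 3/8)/(n + 1/4).
A transformation is adopted only when it raises this correlation by more than
the plan's ``normdev_gain`` threshold over the untransformed predictor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import AnalysisDataset, DataDictionary, IDAPlan, Role, Scale

__all__ = [
    "TransformDecision",
    "pseudolog",
    "signed_cube_root",
    "normal_scores_correlation",
    "select_transformations",
    "apply_chosen_transforms",
]


@dataclass(frozen=True)
class TransformDecision:
    variable: str
    r_raw: float | None
    r_pseudolog: float | None
    r_cuberoot: float | None
    chosen: str  # "none" | "pseudolog" | "cuberoot" | "not assessable"
    gain: float
    sigma_used: float
    base_used: float


def pseudolog(x, sigma: float = 1.0, base: float = 10.0):
    """asinh(x / (2 sigma)) / ln(base); total on the reals, strictly
    increasing, antisymmetric, ~ log_base for large |x|."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if base <= 1:
        raise ValueError("base must exceed 1")
    return np.arcsinh(np.asarray(x, dtype=float) / (2.0 * sigma)) / np.log(base)


def signed_cube_root(x):
    """sign(x) * |x|^(1/3); monotone, defined for all reals."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.abs(x) ** (1.0 / 3.0)


def normal_scores_correlation(values) -> float:
    """Correlation of order statistics with expected normal quantiles.

    Ties keep their sorted (stable) order and raw values; the statistic is
    location–scale invariant in the data.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3 or np.unique(x).size < 2:
        raise ValueError(
            "normal-scores correlation requires >= 3 values, not all equal")
    xs = np.sort(x, kind="stable")
    n = xs.size
    pos = (np.arange(1, n + 1) - 0.375) / (n + 0.25)  # Blom plotting positions
    scores = stats.norm.ppf(pos)
    r = np.corrcoef(xs, scores)[0, 1]
    return float(r)


def select_transformations(
    ds: AnalysisDataset, dictionary: DataDictionary, plan: IDAPlan
) -> list[TransformDecision]:
    """Choose a symmetrizing transformation per continuous predictor.

    Pseudolog is chosen iff its normal-scores-correlation gain over the raw
    predictor exceeds ``normdev_gain``; otherwise the cube root iff its gain
    exceeds the threshold and beats pseudolog's; otherwise none. Variables
    with < 3 distinct values are recorded as "not assessable".
    """
    thr = plan.thresholds.normdev_gain
    decisions: list[TransformDecision] = []
    for spec in dictionary.predictors:
        if spec.scale is not Scale.CONTINUOUS or spec.name not in ds.df.columns:
            continue
        sigma = plan.sigma_for(spec.name)
        base = plan.pseudolog_base
        x = ds.df[spec.name].dropna().to_numpy(dtype=float)
        if np.unique(x).size < 3:
            decisions.append(TransformDecision(
                spec.name, None, None, None, "not assessable", 0.0, sigma, base))
            continue
        r_raw = normal_scores_correlation(x)
        r_pl = normal_scores_correlation(pseudolog(x, sigma, base))
        r_cr = normal_scores_correlation(signed_cube_root(x))
        gain_pl, gain_cr = r_pl - r_raw, r_cr - r_raw
        if gain_pl > thr:
            chosen, gain = "pseudolog", gain_pl
        elif gain_cr > thr and gain_cr > gain_pl:
            chosen, gain = "cuberoot", gain_cr
        else:
            chosen, gain = "none", 0.0
        decisions.append(TransformDecision(
            spec.name, r_raw, r_pl, r_cr, chosen, gain, sigma, base))
    return decisions


def apply_chosen_transforms(
    ds: AnalysisDataset, decisions: list[TransformDecision], plan: IDAPlan
) -> AnalysisDataset:
    """Materialize chosen transforms as additional ``t_``-prefixed columns
    (used downstream for scatterplot and clustering inputs)."""
    df = ds.df.copy()
    for dec in decisions:
        if dec.chosen == "pseudolog":
            df[f"t_{dec.variable}"] = pseudolog(
                ds.df[dec.variable], dec.sigma_used, dec.base_used)
        elif dec.chosen == "cuberoot":
            df[f"t_{dec.variable}"] = signed_cube_root(ds.df[dec.variable])
    return AnalysisDataset(df=df, limit_violations=dict(ds.limit_violations))
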