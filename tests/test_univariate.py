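import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idascreen import (
    AnalysisDataset,
    IDAPlan,
    Scale,
    concentration_ratio,
    detect_spikes,
    gini_mean_difference,
    summarize_categorical,
    summarize_continuous,
)


def _ds(values, name="X1"):
    return AnalysisDataset(df=pd.DataFrame({name: values}))


def gmd_brute_force(x):
    x = np.asarray(x, dtype=float)
    n = len(x)
    return np.abs(x[:, None] - x[None, :]).sum() / (n * (n - 1))


# ---------------------------------------------------------------------------
# Gini mean difference
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("values, expected", [
    ([3.0, 3.0, 3.0], 0.0),
    ([1.0, 2.0, 3.0], 4.0 / 3.0),
    ([0.0, 1.0], 1.0),
])
def test_gmd_known_values(values, expected):
    assert gini_mean_difference(values) == pytest.approx(expected)


def test_gmd_fast_equals_brute_force_on_500_vectors():
    rng = np.random.default_rng(314)
    for _ in range(500):
        n = rng.integers(2, 60)
        scale = 10.0 ** rng.integers(-3, 4)
        x = rng.normal(scale=scale, size=n)
        if rng.random() < 0.3:  # inject ties
            x = np.round(x, 1)
        fast, brute = gini_mean_difference(x), gmd_brute_force(x)
        assert fast == pytest.approx(brute, rel=1e-12, abs=1e-12 * scale)


def test_gmd_needs_two_values():
    with pytest.raises(ValueError):
        gini_mean_difference([1.0])


# ---------------------------------------------------------------------------
# concentration ratio
# ---------------------------------------------------------------------------

def test_concentration_ratio_cases():
    assert concentration_ratio(np.arange(50.0)) == pytest.approx(1.0)  # all distinct
    assert concentration_ratio(np.full(50, 7.0)) == pytest.approx(1.0)  # constant
    x = np.array([0.0] * 90 + [1.0] * 10)
    assert concentration_ratio(x) == pytest.approx(1.8)  # 0.9n / (n/2)


# ---------------------------------------------------------------------------
# continuous summary
# ---------------------------------------------------------------------------

def test_summary_fields_on_1_to_100():
    ds = _ds(np.arange(1.0, 101.0))
    s = summarize_continuous(ds, "X1")
    assert s.quantiles[0.50] == pytest.approx(50.5)  # linear interpolation rule
    assert s.n_distinct == 100
    assert s.minimum == 1 and s.maximum == 100
    assert s.iqr == pytest.approx(np.subtract(*np.quantile(np.arange(1, 101), [0.75, 0.25])))
    assert s.five_lowest == (1.0, 2.0, 3.0, 4.0, 5.0)
    assert s.five_highest == (96.0, 97.0, 98.0, 99.0, 100.0)
    assert s.concentration_ratio == pytest.approx(1.0)


def test_summary_single_repeated_value():
    s = summarize_continuous(_ds([2.5] * 8), "X1")
    assert s.n_distinct == 1
    assert s.sd == 0.0
    assert s.gini_mean_difference == 0.0
    assert s.mode_proportion == 1.0


def test_summary_all_missing_errors():
    with pytest.raises(ValueError, match="missing"):
        summarize_continuous(_ds([np.nan, np.nan]), "X1")


def test_summary_quantiles_monotone(study):
    dd, ds, _ = study
    for v in ("WBC", "CRP", "BASO"):
        s = summarize_continuous(ds, v)
        qs = [s.quantiles[p] for p in sorted(s.quantiles)]
        assert all(a <= b for a, b in zip(qs, qs[1:]))
        assert s.minimum <= qs[0] and qs[-1] <= s.maximum


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=100))
def test_summary_invariants_property(xs):
    s = summarize_continuous(_ds(xs), "X1")
    eps = 1e-12 * (abs(s.minimum) + abs(s.maximum) + 1)  # mean rounds within a ULP
    assert s.minimum - eps <= s.mean <= s.maximum + eps
    assert s.mode_count >= int(np.ceil(s.n_nonmissing / s.n_distinct))
    assert s.concentration_ratio >= 1.0 - 1e-12


# ---------------------------------------------------------------------------
# categorical summary
# ---------------------------------------------------------------------------

def test_categorical_counts_and_collapse():
    ds = AnalysisDataset(df=pd.DataFrame(
        {"G": pd.array(["a", "b", "c", "d", "a", None], dtype=object)}))
    s = summarize_categorical(ds, "G", Scale.NOMINAL, collapse_map={"c": "cd", "d": "cd"})
    assert s.levels == ("a", "b", "c", "d")
    assert s.counts == (2, 1, 1, 1)
    assert s.n_missing == 1
    assert sum(s.proportions) == pytest.approx(1.0)
    assert s.collapsed_counts == {"a": 2, "b": 1, "cd": 2}  # additivity


def test_categorical_all_missing():
    ds = AnalysisDataset(df=pd.DataFrame({"G": pd.array([None, None], dtype=object)}))
    s = summarize_categorical(ds, "G", Scale.NOMINAL)
    assert s.levels == () and s.n_nonmissing == 0


def test_categorical_rejects_continuous():
    with pytest.raises(ValueError):
        summarize_categorical(_ds([1.0, 2.0]), "X1", Scale.CONTINUOUS)


# ---------------------------------------------------------------------------
# spike detection
# ---------------------------------------------------------------------------

def test_spike_flag_boundary_and_uniform():
    plan = IDAPlan(model_sets={})
    # exactly at threshold: flagged (>= convention)
    x = np.concatenate([np.zeros(40), np.linspace(1, 2, 60)])
    s = summarize_continuous(_ds(x), "X1")
    assert s.mode_proportion == pytest.approx(0.40)
    flag = detect_spikes(s, plan)
    assert flag is not None and flag.mode_value == 0.0
    assert len(flag.top_values) == 5

    # continuous sample: no spike
    rng = np.random.default_rng(1)
    s2 = summarize_continuous(_ds(rng.uniform(size=1000)), "X1")
    assert detect_spikes(s2, plan) is None


def test_spike_flags_planted_variables_exactly(study, study_plan):
    dd, ds, truth = study
    thr = study_plan.thresholds.spike_mode_prop
    expected = {v for v, p in truth["spike_probabilities"].items() if p >= thr}
    flagged = set()
    for v in dd.predictors:
        if not v.is_categorical:
            s = summarize_continuous(ds, v.name)
            if detect_spikes(s, study_plan):
                flagged.add(v.name)
    assert flagged == expected
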