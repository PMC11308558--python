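import itertools

import numpy as np
import pandas as pd
import pytest

from idascreen import (
    AnalysisDataset,
    IDAPlan,
    cluster_missingness,
    compare_missingness_groups,
    complete_case_cascade,
    item_missingness,
    missingness_discordance_matrix,
    stratified_complete_cases,
    unit_missingness_summary,
)
from idascreen.missingness import DEGENERATE_SPLIT, NOT_EVALUABLE, DiscordanceMatrix
from idascreen.synthetic import default_bacteremia_like_spec, generate_synthetic_study

from conftest import tiny_dataset, tiny_dictionary


# ---------------------------------------------------------------------------
# M1
# ---------------------------------------------------------------------------

def test_unit_missingness_marker_and_arithmetic():
    assert unit_missingness_summary(None) == NOT_EVALUABLE
    assert unit_missingness_summary({}) == NOT_EVALUABLE
    tbl = unit_missingness_summary({"eligible": 100, "assessed": 80, "recruited": 70})
    assert list(tbl["attrition_from_previous"].iloc[1:]) == [0.2, 0.125]
    with pytest.raises(ValueError):
        unit_missingness_summary({"eligible": 100, "assessed": 80, "recruited": 90})
    with pytest.raises(ValueError):
        unit_missingness_summary({"eligible": -1})


# ---------------------------------------------------------------------------
# M2 / M3
# ---------------------------------------------------------------------------

def test_item_missingness_counts(tiny):
    dd, ds = tiny
    df = ds.df.copy()
    df.loc[df.index[:3], "X1"] = np.nan
    summaries = item_missingness(AnalysisDataset(df=df), dd)
    by_var = {m.variable: m for m in summaries}
    assert by_var["X1"].n_missing == 3
    assert by_var["X1"].proportion == 3 / len(df)
    assert by_var["AGE"].n_missing == 0
    assert by_var["Y"].variable == "Y"  # outcome included


def test_cascade_hand_case():
    """5 rows, A missing in rows {0,1}, B in {1,2}: set {A,B} has 2/5 complete."""
    dd = tiny_dictionary(2)
    df = pd.DataFrame({
        "Y": ["yes", "no", "no", "no", "yes"],
        "AGE": [30.0, 40, 50, 60, 70],
        "SEX": ["1", "2", "1", "2", "1"],
        "X1": [np.nan, np.nan, 1.0, 2.0, 3.0],
        "X2": [1.0, np.nan, np.nan, 2.0, 3.0],
    })
    plan = IDAPlan(model_sets={"both": ["X1", "X2"]})
    rows = complete_case_cascade(tiny_dataset(df), plan, dd)
    assert rows[0].set_name == "outcome" and rows[0].n_complete == 5
    assert rows[1].n_complete == 2
    assert rows[1].proportion_complete == 0.4


def test_cascade_no_missing_all_one(tiny, tiny_plan):
    dd, ds = tiny
    rows = complete_case_cascade(ds, tiny_plan, dd)
    assert all(r.proportion_complete == 1.0 for r in rows)


def test_cascade_rejects_empty_set(tiny):
    dd, ds = tiny
    with pytest.raises(ValueError, match="empty"):
        complete_case_cascade(ds, IDAPlan(model_sets={"none": []}), dd)


def test_cascade_matches_brute_force_enumeration():
    """Exact agreement with per-row enumeration on a 200-row instance."""
    rng = np.random.default_rng(42)
    n = 200
    dd = tiny_dictionary(4)
    df = pd.DataFrame({
        "Y": np.where(rng.random(n) < 0.1, "yes", "no").astype(object),
        "AGE": rng.uniform(20, 90, n).round(),
        "SEX": rng.choice(["1", "2"], n).astype(object),
    })
    for k in range(1, 5):
        x = rng.normal(size=n)
        x[rng.random(n) < rng.uniform(0.05, 0.4)] = np.nan
        df[f"X{k}"] = x
    # outcome missing in some rows too: must count as incomplete everywhere
    ymiss = rng.random(n) < 0.05
    df.loc[ymiss, "Y"] = pd.NA

    sets = {"a": ["X1"], "ab": ["X1", "X2"], "abc": ["X1", "X2", "X3"],
            "all": ["X1", "X2", "X3", "X4"], "mixed": ["AGE", "X4", "X2"]}
    rows = complete_case_cascade(tiny_dataset(df), IDAPlan(model_sets=sets), dd)
    by_name = {r.set_name: r for r in rows}
    for name, members in sets.items():
        expected = sum(
            1 for i in range(n)
            if not pd.isna(df.loc[i, "Y"])
            and all(not pd.isna(df.loc[i, m]) for m in members)
        )
        assert by_name[name].n_complete == expected

    # monotonicity over random nested chains
    for _ in range(20):
        chain = list(rng.permutation(["X1", "X2", "X3", "X4", "AGE"]))
        counts = []
        for k in range(1, len(chain) + 1):
            plan = IDAPlan(model_sets={"s": chain[:k]})
            counts.append(complete_case_cascade(tiny_dataset(df), plan, dd)[1].n_complete)
        assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_stratified_cascade_single_stratum_matches_overall():
    dd = tiny_dictionary(1)
    n = 40
    rng = np.random.default_rng(0)
    x = rng.normal(size=n)
    x[:10] = np.nan
    df = pd.DataFrame({
        "Y": ["no"] * n, "AGE": [44.0] * n, "SEX": ["1"] * n, "X1": x,
    })
    plan = IDAPlan(model_sets={"s": ["X1"]})
    tbl = stratified_complete_cases(tiny_dataset(df), plan, dd)
    overall = complete_case_cascade(tiny_dataset(df), plan, dd)
    sub = tbl[tbl.set_name == "s"]
    assert len(sub) == 1
    assert sub.iloc[0]["n_complete"] == overall[1].n_complete


def test_stratified_proportions_bracket_overall():
    """Stratum completeness proportions bracket the overall proportion
    (weighted-average identity)."""
    spec = default_bacteremia_like_spec(seed=3, n_rows=600)
    dd, ds, _ = generate_synthetic_study(spec)
    from idascreen import default_plan

    plan = default_plan(dd)
    tbl = stratified_complete_cases(ds, plan, dd)
    overall = {r.set_name: r.proportion_complete
               for r in complete_case_cascade(ds, plan, dd)}
    for name, p in overall.items():
        props = tbl[(tbl.set_name == name) & ~tbl.small_stratum]["proportion_complete"]
        if len(props) > 1:
            assert props.min() - 1e-12 <= p <= props.max() + 1e-12


# ---------------------------------------------------------------------------
# M4: discordance + dendrogram
# ---------------------------------------------------------------------------

def test_discordance_hand_cases():
    n = 10
    df = pd.DataFrame({
        "A": [np.nan, np.nan] + [1.0] * 8,
        "B": [1.0, 1.0, np.nan] + [1.0] * 7,
        "C": [np.nan, np.nan] + [1.0] * 8,   # identical pattern to A
        "D": [1.0] * 10,                      # never missing
    })
    ds = AnalysisDataset(df=df)
    m = missingness_discordance_matrix(ds, ["A", "B", "C", "D"])
    assert m.pair("A", "B") == pytest.approx(0.3)   # disjoint: 2 + 1 of 10
    assert m.pair("A", "C") == 0.0                   # identical patterns
    assert m.pair("A", "D") == pytest.approx(0.2)    # vs complete: d = p_A
    assert np.allclose(np.diag(m.d), 0)


def test_discordance_matches_brute_force_and_bounds():
    rng = np.random.default_rng(11)
    n, k = 200, 6
    df = pd.DataFrame(rng.normal(size=(n, k)), columns=[f"V{i}" for i in range(k)])
    for c in df.columns:
        df.loc[rng.random(n) < rng.uniform(0, 0.5), c] = np.nan
    ds = AnalysisDataset(df=df)
    m = missingness_discordance_matrix(ds, list(df.columns))
    p = df.isna().mean().to_numpy()
    for i, j in itertools.combinations(range(k), 2):
        brute = float((df.iloc[:, i].isna() != df.iloc[:, j].isna()).mean())
        assert m.d[i, j] == pytest.approx(brute, abs=1e-12)
        assert abs(p[i] - p[j]) - 1e-12 <= m.d[i, j] <= min(1.0, p[i] + p[j]) + 1e-12


def test_cluster_hand_enumeration():
    """d(A,B)=0, d(.,C)=0.4: A,B merge at 0, then C joins at 0.4."""
    d = np.array([[0.0, 0.0, 0.4], [0.0, 0.0, 0.4], [0.4, 0.4, 0.0]])
    m = DiscordanceMatrix(variables=["A", "B", "C"], d=d)
    for method in ("average", "complete", "single"):
        dendro = cluster_missingness(m, method=method)
        assert dendro.merge_height_of_pair("A", "B") == 0.0
        assert dendro.merge_height_of_pair("A", "C") == pytest.approx(0.4)
        assert np.all(np.diff(dendro.heights) >= 0)


def test_cluster_tie_case_all_equal():
    d = np.full((4, 4), 0.25)
    np.fill_diagonal(d, 0.0)
    m = DiscordanceMatrix(variables=list("ABCD"), d=d)
    dendro = cluster_missingness(m)
    assert np.allclose(dendro.heights, 0.25)


def test_cluster_requires_two_leaves():
    m = DiscordanceMatrix(variables=["A"], d=np.zeros((1, 1)))
    with pytest.raises(ValueError):
        cluster_missingness(m)


def test_planted_blocks_merge_below_cross_block(study):
    """Shared-missingness blocks merge strictly below any cross-block merge."""
    dd, ds, truth = study
    blocks = truth["missing_blocks"]
    block_vars = [v for blk in blocks for v in blk]
    m = missingness_discordance_matrix(ds, block_vars)
    dendro = cluster_missingness(m)
    within = [dendro.merge_height_of_pair(a, b)
              for blk in blocks for a, b in itertools.combinations(blk, 2)]
    across = [dendro.merge_height_of_pair(a, b)
              for blk_a, blk_b in itertools.combinations(blocks, 2)
              for a in blk_a for b in blk_b]
    assert max(within) < min(across)


def test_newick_serialization_parses(study):
    dd, ds, truth = study
    m = missingness_discordance_matrix(ds, ["TRIG", "CHOL", "AMY", "LIP"])
    dendro = cluster_missingness(m, missing_proportions={"TRIG": 0.35})
    nwk = dendro.to_newick()
    assert nwk.endswith(";") and "TRIG" in nwk
    # parseable by an independent newick reader
    import io as _io

    from Bio import Phylo

    tree = Phylo.read(_io.StringIO(nwk), "newick")
    assert tree.count_terminals() == 4


# ---------------------------------------------------------------------------
# ME1
# ---------------------------------------------------------------------------

def test_degenerate_split_marker(tiny):
    dd, ds = tiny
    assert compare_missingness_groups(ds, ["X1"], dd) == DEGENERATE_SPLIT


def test_age_dependent_missingness_recovered():
    """Planted logistic age shift in one variable's missingness shows up as a
    standardized age difference of the right sign and magnitude."""
    spec = default_bacteremia_like_spec(seed=21, n_rows=3000)
    spec.missing_structural = {"LDH": ("AGE", 1.2)}
    dd, ds, _ = generate_synthetic_study(spec)
    tbl = compare_missingness_groups(ds, ["LDH"], dd)
    age_row = tbl[(tbl.variable == "AGE")].iloc[0]
    # older patients more often missing: complete cases younger
    assert age_row["standardized_difference"] < -0.3


def test_mcar_missingness_shows_no_structural_contrast():
    spec = default_bacteremia_like_spec(seed=22, n_rows=3000)
    dd, ds, _ = generate_synthetic_study(spec)
    tbl = compare_missingness_groups(ds, ["LDH"], dd)
    age_row = tbl[(tbl.variable == "AGE")].iloc[0]
    assert abs(age_row["standardized_difference"]) < 0.15
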