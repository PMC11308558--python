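import numpy as np
import pandas as pd
import pytest

from idascreen import (
    AnalysisDataset,
    IDAPlan,
    correlation_discrepancies,
    pearson_matrix,
    redundancy_analysis,
    spearman_matrix,
    structural_association_table,
    variable_clusters,
    vif,
)
from idascreen.multivariate import VIF_SINGULAR, interaction_screen, rcs_basis
from idascreen.synthetic import (
    LabSpec,
    SyntheticSpec,
    default_bacteremia_like_spec,
    generate_synthetic_study,
)

from conftest import tiny_dataset, tiny_dictionary


def _make_ds(columns: dict) -> AnalysisDataset:
    n = len(next(iter(columns.values())))
    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        "Y": np.where(rng.random(n) < 0.5, "yes", "no").astype(object),
        "AGE": rng.uniform(20, 90, n).round(),
        "SEX": rng.choice(["1", "2"], n).astype(object),
    })
    for k, v in columns.items():
        df[k] = np.asarray(v, dtype=float)
    return tiny_dataset(df)


# ---------------------------------------------------------------------------
# correlation matrices
# ---------------------------------------------------------------------------

def test_spearman_identity_and_monotone_invariance():
    rng = np.random.default_rng(1)
    x = rng.lognormal(size=100)
    from idascreen import pseudolog

    ds = _make_ds({"X1": x, "X2": pseudolog(x)})
    dd = tiny_dictionary(2)
    S = spearman_matrix(ds, ["X1", "X2"], dd, min_pairs=2)
    assert S.pair("X1", "X1") == 1.0
    assert S.pair("X1", "X2") == pytest.approx(1.0)


def test_spearman_tie_handling_matches_direct_formula():
    # 6-point toy table with one tie: average ranks
    x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
    ds = _make_ds({"X1": x, "X2": y})
    S = spearman_matrix(ds, ["X1", "X2"], tiny_dictionary(2), min_pairs=2)
    from scipy import stats

    rx = stats.rankdata(x)  # average ranks for ties
    ry = stats.rankdata(y)
    expected = np.corrcoef(rx, ry)[0, 1]
    assert S.pair("X1", "X2") == pytest.approx(expected, abs=1e-12)


def test_pearson_exact_linear_cases():
    x = np.linspace(0, 1, 50)
    ds = _make_ds({"X1": x, "X2": 2 * x + 1, "X3": -x})
    P = pearson_matrix(ds, ["X1", "X2", "X3"], tiny_dictionary(3), min_pairs=2)
    assert P.pair("X1", "X2") == pytest.approx(1.0)
    assert P.pair("X1", "X3") == pytest.approx(-1.0)


def test_pearson_recovers_planted_bivariate_normal():
    rng = np.random.default_rng(5)
    n = 10_000
    z1, z2 = rng.standard_normal(n), rng.standard_normal(n)
    x, y = z1, 0.5 * z1 + np.sqrt(1 - 0.25) * z2
    ds = _make_ds({"X1": x, "X2": y})
    P = pearson_matrix(ds, ["X1", "X2"], tiny_dictionary(2), min_pairs=2)
    assert P.pair("X1", "X2") == pytest.approx(0.5, abs=3 / np.sqrt(n))


def test_pairwise_complete_equals_complete_case_when_no_missing():
    rng = np.random.default_rng(8)
    cols = {f"X{k}": rng.normal(size=80) for k in range(1, 5)}
    ds = _make_ds(cols)
    dd = tiny_dictionary(4)
    S = spearman_matrix(ds, list(cols), dd, min_pairs=2)
    cc = ds.df[list(cols)].corr(method="spearman").to_numpy()
    assert np.allclose(S.r, cc)
    assert (S.n_pairs == 80).all()


def test_min_pairs_flags_unreliable_entries():
    rng = np.random.default_rng(3)
    x = rng.normal(size=50)
    y = rng.normal(size=50)
    y[:45] = np.nan  # only 5 complete pairs
    ds = _make_ds({"X1": x, "X2": y})
    S = spearman_matrix(ds, ["X1", "X2"], tiny_dictionary(2), min_pairs=30)
    assert S.unreliable_mask()[0, 1]
    assert S.n_pairs[0, 1] == 5


# ---------------------------------------------------------------------------
# discrepancies
# ---------------------------------------------------------------------------

def test_discrepancies_empty_on_identical_matrices():
    x = np.linspace(0, 1, 60)
    ds = _make_ds({"X1": x, "X2": 3 * x})
    dd = tiny_dictionary(2)
    S = spearman_matrix(ds, ["X1", "X2"], dd, 2)
    P = pearson_matrix(ds, ["X1", "X2"], dd, 2)
    assert len(correlation_discrepancies(S, P, 0.1)) == 0


def test_planted_outlier_pair_flagged():
    rng = np.random.default_rng(4)
    n = 200
    x = rng.normal(size=n)
    y = rng.normal(size=n)  # independent
    x[0], y[0] = 60.0, 60.0  # one extreme point drives Pearson up
    u, v = rng.normal(size=n), rng.normal(size=n)
    ds = _make_ds({"X1": x, "X2": y, "X3": u, "X4": v})
    dd = tiny_dictionary(4)
    S = spearman_matrix(ds, ["X1", "X2", "X3", "X4"], dd, 2)
    P = pearson_matrix(ds, ["X1", "X2", "X3", "X4"], dd, 2)
    flagged = correlation_discrepancies(S, P, 0.1)
    assert {"X1", "X2"} in [set(t) for t in zip(flagged.var1, flagged.var2)]
    assert flagged.iloc[0]["pearson"] > flagged.iloc[0]["spearman"]


# ---------------------------------------------------------------------------
# structural associations & interactions
# ---------------------------------------------------------------------------

def test_structural_association_identity_and_independence():
    rng = np.random.default_rng(6)
    n = 400
    age = rng.uniform(20, 90, n).round()
    ds = _make_ds({"X1": age, "X2": rng.normal(size=n)})
    ds.df["AGE"] = age
    dd = tiny_dictionary(2)
    plan = IDAPlan(model_sets={"k": ["X1", "X2"]}, min_pairs=10)
    tbl = structural_association_table(ds, dd, plan)
    age_rows = tbl[(tbl.structural == "AGE") & (tbl.statistic == "spearman")]
    x1 = age_rows[age_rows.predictor == "X1"]
    assert np.allclose(x1["value"], 1.0)  # rho = 1 in every stratum
    x2 = age_rows[age_rows.predictor == "X2"]
    assert (x2["value"].abs() < 0.2).all()


def test_interaction_screen_grids():
    rng = np.random.default_rng(2)
    n = 1600
    x = rng.normal(size=n)
    ds = _make_ds({"X1": x, "X2": x, "X3": rng.normal(size=n)})
    dd = tiny_dictionary(3)
    plan = IDAPlan(model_sets={"k": ["X1", "X2", "X3"]},
                   interactions=[("X1", "X2"), ("X1", "X3")])
    out = interaction_screen(ds, plan, dd)
    by_pair = {o["pair"]: o for o in out}
    # perfectly correlated pair: mass on the grid diagonal
    g = by_pair[("X1", "X2")]["sparsity_grid"]
    assert np.trace(g) == n
    # independent pair: near-uniform n/16 per cell
    g2 = by_pair[("X1", "X3")]["sparsity_grid"]
    assert abs(g2 - n / 16).max() < 5 * np.sqrt(n / 16)
    assert interaction_screen(ds, IDAPlan(model_sets={}), dd) == []


# ---------------------------------------------------------------------------
# variable clustering
# ---------------------------------------------------------------------------

def test_planted_high_corr_pair_first_merge_and_listed():
    spec = SyntheticSpec(
        n_rows=900,
        labs=[LabSpec(n, 0.0, 1.0) for n in ("A", "B", "C", "D")],
        correlation_plants={("A", "B"): 0.95},
        seed=17,
    )
    dd, ds, _ = generate_synthetic_study(spec)
    plan = IDAPlan(model_sets={"all": ["A", "B", "C", "D"]})
    S = spearman_matrix(ds, ["A", "B", "C", "D"], dd, 2)
    dendro, pairs, notices = variable_clusters(S, plan)
    assert notices == []
    assert dendro.merge_height_of_pair("A", "B") == min(dendro.heights)
    assert [set(t) for t in zip(pairs.var1, pairs.var2)] == [{"A", "B"}]


def test_no_pairs_listed_for_independent_predictors():
    spec = SyntheticSpec(
        n_rows=900, labs=[LabSpec(f"L{k}", 0.0, 0.8) for k in range(6)], seed=23)
    dd, ds, _ = generate_synthetic_study(spec)
    names = [f"L{k}" for k in range(6)]
    S = spearman_matrix(ds, names, dd, 2)
    _, pairs, _ = variable_clusters(S, IDAPlan(model_sets={"all": names}))
    assert len(pairs) == 0


def test_block_structure_recovered_at_cut():
    spec = SyntheticSpec(
        n_rows=1200,
        labs=[LabSpec(n, 0.0, 1.0) for n in ("A", "B", "C", "D", "E", "F")],
        correlation_plants={("A", "B"): 0.9, ("A", "C"): 0.9, ("B", "C"): 0.9,
                            ("D", "E"): 0.9, ("D", "F"): 0.9, ("E", "F"): 0.9},
        seed=31,
    )
    dd, ds, _ = generate_synthetic_study(spec)
    names = list("ABCDEF")
    S = spearman_matrix(ds, names, dd, 2)
    dendro, _, _ = variable_clusters(S, IDAPlan(model_sets={"all": names}))
    labels = dendro.cut(0.5)  # within-block 1-rho^2 ~ 0.2, across ~ 1
    from sklearn.metrics import adjusted_rand_score

    truth = [0, 0, 0, 1, 1, 1]
    assert adjusted_rand_score(truth, [labels[v] for v in names]) == 1.0


# ---------------------------------------------------------------------------
# VIF
# ---------------------------------------------------------------------------

def _two_var_exact_corr(r: float, n: int = 200):
    """Two columns whose sample correlation is exactly r (orthonormal trick)."""
    rng = np.random.default_rng(13)
    A = rng.normal(size=(n, 2))
    A -= A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    u, w = Q[:, 0], Q[:, 1]
    return u, r * u + np.sqrt(1 - r * r) * w


@pytest.mark.parametrize("r", [0.0, 0.3, 0.6, 0.9, 0.99])
def test_vif_closed_form_two_variables(r):
    u, v = _two_var_exact_corr(r)
    ds = _make_ds({"X1": u, "X2": v})
    dd = tiny_dictionary(2)
    res = vif(ds, ["X1", "X2"], dd, IDAPlan(model_sets={}), basis="linear")
    expected = 1.0 / (1.0 - r * r)
    assert res.vif["X1"] == pytest.approx(expected, abs=1e-9)
    assert res.vif["X2"] == pytest.approx(expected, abs=1e-9)
    assert res.vif["X1"] == pytest.approx(res.gvif["X1"])  # df=1: GVIF == VIF


def test_vif_independent_predictors_near_one():
    rng = np.random.default_rng(19)
    cols = {f"X{k}": rng.normal(size=400) for k in range(1, 5)}
    ds = _make_ds(cols)
    res = vif(ds, list(cols), tiny_dictionary(4), IDAPlan(model_sets={}))
    assert all(1.0 <= v < 1.2 for v in res.vif.values())


def test_vif_matches_statsmodels_oracle():
    """Independent cross-check: per-column OLS VIFs from statsmodels."""
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    rng = np.random.default_rng(29)
    n = 300
    z = rng.normal(size=n)
    cols = {
        "X1": z + 0.3 * rng.normal(size=n),
        "X2": z + 0.3 * rng.normal(size=n),
        "X3": rng.normal(size=n),
    }
    ds = _make_ds(cols)
    res = vif(ds, list(cols), tiny_dictionary(3), IDAPlan(model_sets={}))
    X = np.column_stack([np.ones(n)] + [
        (c - c.mean()) / c.std(ddof=1) for c in (cols["X1"], cols["X2"], cols["X3"])])
    for j, name in enumerate(cols, start=1):
        sm_vif = variance_inflation_factor(X, j)
        assert res.vif[name] == pytest.approx(sm_vif, rel=1e-6)


def test_vif_singular_marker_not_exception():
    x = np.linspace(0, 1, 100)
    ds = _make_ds({"X1": x, "X2": 2 * x})  # exact collinearity
    res = vif(ds, ["X1", "X2"], tiny_dictionary(2), IDAPlan(model_sets={}))
    assert res.vif["X1"] == VIF_SINGULAR


def test_additive_vif_runs_and_exceeds_linear_on_composition(study, study_plan):
    dd, ds, _ = study
    members = ["WBC", "NEU", "LYM", "MONO"]
    lin = vif(ds, members, dd, study_plan, basis="linear")
    add = vif(ds, members, dd, study_plan, basis="additive")
    assert lin.vif["WBC"] > study_plan.thresholds.vif_flag  # composition block
    assert add.df_per_variable["WBC"] >= 3  # key predictor: 4 knots
    assert all(v >= 1.0 or v != v for v in add.vif.values())


def test_vif_requires_enough_complete_cases():
    ds = _make_ds({"X1": [1.0, 2.0, np.nan], "X2": [1.0, np.nan, 2.0]})
    with pytest.raises(ValueError, match="complete"):
        vif(ds, ["X1", "X2"], tiny_dictionary(2), IDAPlan(model_sets={}))


# ---------------------------------------------------------------------------
# redundancy
# ---------------------------------------------------------------------------

def test_redundancy_removes_exact_copy():
    rng = np.random.default_rng(41)
    x = rng.normal(size=300)
    ds = _make_ds({"X1": x, "X2": x.copy(), "X3": rng.normal(size=300)})
    res = redundancy_analysis(ds, ["X1", "X2", "X3"], tiny_dictionary(3),
                              IDAPlan(model_sets={}))
    assert len(res.removal_sequence) == 1
    var, r2 = res.removal_sequence[0]
    assert var in ("X1", "X2") and r2 == pytest.approx(1.0, abs=1e-9)


def test_redundancy_empty_for_independent_set():
    rng = np.random.default_rng(43)
    cols = {f"X{k}": rng.normal(size=400) for k in range(1, 5)}
    ds = _make_ds(cols)
    res = redundancy_analysis(ds, list(cols), tiny_dictionary(4),
                              IDAPlan(model_sets={}))
    assert res.removal_sequence == []
    assert all(v < 0.3 for v in res.r_squared.values())


def test_redundancy_flags_composition_block(study, study_plan):
    dd, ds, _ = study
    members = ["WBC", "BASO", "EOS", "NEU", "LYM", "MONO"]
    res = redundancy_analysis(ds, members, dd, study_plan)
    removed = [v for v, _ in res.removal_sequence]
    assert removed, "sum-of-components block must contain a redundant member"
    assert set(removed) <= set(members)
    assert res.removal_sequence[0][1] > study_plan.thresholds.redundancy_r2


# ---------------------------------------------------------------------------
# spline basis sanity
# ---------------------------------------------------------------------------

def test_rcs_basis_linear_in_tails():
    x = np.linspace(-10, 10, 2001)
    B = rcs_basis(x, knots=[-2.0, 0.0, 2.0, 4.0])
    assert B.shape == (2001, 3)
    # beyond the boundary knots every column is affine in x
    tail = x > 6
    for j in range(B.shape[1]):
        slopes = np.diff(B[tail, j]) / np.diff(x[tail])
        assert np.allclose(slopes, slopes[0], atol=1e-8)
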