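import numpy as np
import pandas as pd
import pytest

from idascreen import (
    AnalysisDataset,
    DataDictionary,
    IDAPlan,
    Role,
    Scale,
    VariableSpec,
    default_bacteremia_like_spec,
    default_plan,
    generate_synthetic_study,
    run_screening,
)


@pytest.fixture(scope="session")
def study():
    """Default synthetic study at a size where every screening stage runs."""
    spec = default_bacteremia_like_spec(seed=20240801, n_rows=1200)
    dictionary, ds, truth = generate_synthetic_study(spec)
    return dictionary, ds, truth


@pytest.fixture(scope="session")
def study_plan(study):
    dictionary, _, _ = study
    return default_plan(dictionary, seed=20240801)


@pytest.fixture(scope="session")
def bundle(study, study_plan):
    dictionary, ds, _ = study
    return run_screening(ds, dictionary, study_plan, blind=True)


def tiny_dictionary(n_predictors: int = 3, scales=None) -> DataDictionary:
    """Outcome + AGE/SEX structural + continuous predictors X1..Xk."""
    scales = scales or {}
    specs = [
        VariableSpec("Y", Scale.BINARY, Role.OUTCOME),
        VariableSpec("AGE", Scale.CONTINUOUS, Role.STRUCTURAL),
        VariableSpec("SEX", Scale.BINARY, Role.STRUCTURAL),
    ]
    for k in range(1, n_predictors + 1):
        name = f"X{k}"
        specs.append(VariableSpec(name, scales.get(name, Scale.CONTINUOUS), Role.KEY))
    return DataDictionary(specs)


def tiny_dataset(df: pd.DataFrame) -> AnalysisDataset:
    return AnalysisDataset(df=df)


@pytest.fixture
def tiny():
    """A 12-row fully observed toy study for exact-arithmetic checks."""
    rng = np.random.default_rng(5)
    n = 12
    df = pd.DataFrame({
        "Y": np.where(rng.random(n) < 0.5, "yes", "no").astype(object),
        "AGE": np.arange(30, 30 + n, dtype=float),
        "SEX": np.array(["1", "2"] * (n // 2), dtype=object),
        "X1": rng.normal(size=n),
        "X2": rng.normal(size=n),
        "X3": rng.normal(size=n),
    })
    return tiny_dictionary(), tiny_dataset(df)


@pytest.fixture
def tiny_plan():
    return IDAPlan(model_sets={"key": ["AGE", "SEX", "X1", "X2", "X3"]}, seed=3)
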