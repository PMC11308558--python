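"""Synthetic clinical-laboratory study generator with planted structure.

Emulates the data features that drive regression-oriented screening in a
hospital laboratory cohort, with every planted feature recorded in a ground
truth dictionary so screening output can be checked against construction:

* heavily right-skewed lab concentrations (lognormal margins);
* a part–whole leukocyte block: five cell-type counts drawn as Dirichlet
  shares of a lognormal total, whose noisy sum is recorded as the white
  blood count, plus derived percentage ("ratio") variables;
* spike-at-zero components (rare cell types below the detection limit);
* block-correlated missingness (lab panels measured together fail together);
* planted rank correlations between chosen lab pairs via a Gaussian copula
  on latent normals (Spearman rho maps to latent Pearson r via
  rho = (6/pi) * asin(r/2));
* a low-prevalence binary outcome drawn independently of every predictor —
  honest to the no-association principle of outcome-blind screening — with
  an optional planted effect used solely to test that blinding destroys it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    AnalysisDataset,
    DataDictionary,
    IDAPlan,
    Role,
    Scale,
    VariableSpec,
)

__all__ = [
    "LabSpec",
    "CompositionSpec",
    "MissingBlock",
    "SyntheticSpec",
    "generate_synthetic_study",
    "default_bacteremia_like_spec",
    "default_plan",
]


@dataclass(frozen=True)
class LabSpec:
    name: str
    log_mean: float
    log_sd: float
    role: Role = Role.MINOR
    units: str = "U/L"


@dataclass(frozen=True)
class CompositionSpec:
    """A whole variable recorded as the noisy sum of its components."""

    whole: str
    components: tuple[str, ...]
    shares: tuple[float, ...]          # Dirichlet mean shares, sum to 1
    concentration: float = 60.0        # Dirichlet concentration (share stability)
    total_log_mean: float = np.log(10.0)
    total_log_sd: float = 0.6
    whole_noise_sd: float = 0.05       # multiplicative noise on the recorded sum
    ratio_suffix: str = "R"            # derived percentage variables


@dataclass(frozen=True)
class MissingBlock:
    variables: tuple[str, ...]
    probability: float                 # shared per-row missingness indicator


@dataclass
class SyntheticSpec:
    n_rows: int = 2000
    prevalence: float = 0.08
    labs: list[LabSpec] = field(default_factory=list)
    composition: CompositionSpec | None = None
    spike_probabilities: Mapping[str, float] = field(default_factory=dict)
    missing_blocks: list[MissingBlock] = field(default_factory=list)
    missing_individual: Mapping[str, float] = field(default_factory=dict)
    #: variable -> (structural variable, logistic shift per SD): missingness
    #: probability depends on the structural variable (not MCAR)
    missing_structural: Mapping[str, tuple[str, float]] = field(default_factory=dict)
    correlation_plants: Mapping[tuple[str, str], float] = field(default_factory=dict)
    #: optional planted outcome effect (predictor, point-biserial-ish shift);
    #: exists solely to test that blinding destroys it
    outcome_effect: tuple[str, float] | None = None
    seed: int = 0


def _latent_r(rho_s: float) -> float:
    """Latent normal Pearson r achieving Spearman rho_s under a Gaussian copula."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def generate_synthetic_study(
    spec: SyntheticSpec,
) -> tuple[DataDictionary, AnalysisDataset, dict]:
    """Generate (dictionary, dataset, ground-truth record) from a spec.

    Deterministic in (spec, seed). Raises ``ValueError`` naming the offending
    pair for an infeasible correlation plant (|rho| >= 1, a reference to an
    unknown lab, or a latent correlation matrix that is not positive
    definite).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_rows
    lab_names = [l.name for l in spec.labs]
    lab_index = {name: k for k, name in enumerate(lab_names)}

    # --- validate and build the latent copula correlation matrix ------------
    k = len(lab_names)
    latent = np.eye(k)
    for (a, b), rho in spec.correlation_plants.items():
        if a not in lab_index or b not in lab_index:
            raise ValueError(f"correlation plant ({a}, {b}) references unknown lab")
        if not -1.0 < rho < 1.0:
            raise ValueError(f"correlation plant ({a}, {b}): target {rho} infeasible")
        r = _latent_r(rho)
        latent[lab_index[a], lab_index[b]] = r
        latent[lab_index[b], lab_index[a]] = r
    if k:
        eigmin = np.linalg.eigvalsh(latent).min()
        if eigmin <= 1e-10:
            bad = ", ".join(f"({a},{b})" for a, b in spec.correlation_plants)
            raise ValueError(
                f"correlation plants {bad} are jointly infeasible "
                f"(latent matrix not positive definite)")

    df = pd.DataFrame(index=range(n))

    # --- structural variables -------------------------------------------------
    age = np.clip(np.round(rng.normal(60.0, 18.0, size=n)), 16, 100)
    sex = rng.choice(np.array(["1", "2"], dtype=object), size=n)
    df["AGE"] = age
    df["SEX"] = sex

    # --- lognormal labs with planted rank correlations -------------------------
    if k:
        L = np.linalg.cholesky(latent)
        Z = rng.standard_normal((n, k)) @ L.T
        for lab in spec.labs:
            z = Z[:, lab_index[lab.name]]
            df[lab.name] = np.exp(lab.log_mean + lab.log_sd * z)

    # --- composition block ------------------------------------------------------
    comp = spec.composition
    ratio_names: dict[str, str] = {}
    if comp is not None:
        total = np.exp(comp.total_log_mean
                       + comp.total_log_sd * rng.standard_normal(n))
        alpha = np.asarray(comp.shares, dtype=float) * comp.concentration
        shares = rng.dirichlet(alpha, size=n)
        comps = shares * total[:, None]
        for j, name in enumerate(comp.components):
            pi = spec.spike_probabilities.get(name, 0.0)
            if pi > 0:
                comps[rng.random(n) < pi, j] = 0.0
        comp_sum = comps.sum(axis=1)
        whole = comp_sum * np.exp(comp.whole_noise_sd * rng.standard_normal(n))
        df[comp.whole] = whole
        safe_sum = np.where(comp_sum > 0, comp_sum, np.nan)
        for j, name in enumerate(comp.components):
            df[name] = comps[:, j]
            rname = f"{name}{comp.ratio_suffix}"
            ratio_names[name] = rname
            df[rname] = 100.0 * comps[:, j] / safe_sum

    # --- outcome ----------------------------------------------------------------
    if spec.outcome_effect is None:
        p = np.full(n, spec.prevalence)
    else:
        var, beta = spec.outcome_effect
        x = np.asarray(df[var], dtype=float)
        zstd = (x - np.nanmean(x)) / np.nanstd(x)
        logit0 = np.log(spec.prevalence / (1 - spec.prevalence))
        p = 1.0 / (1.0 + np.exp(-(logit0 + beta * zstd)))
    outcome = np.where(rng.random(n) < p, "yes", "no").astype(object)
    df["BloodCulture"] = outcome

    # --- missingness (imposed last) ----------------------------------------------
    expected_missing: dict[str, float] = {c: 0.0 for c in df.columns}
    miss = pd.DataFrame(False, index=df.index, columns=df.columns)
    for block in spec.missing_blocks:
        ind = rng.random(n) < block.probability
        for v in block.variables:
            miss[v] |= ind
            expected_missing[v] = 1 - (1 - expected_missing[v]) * (1 - block.probability)
    for v, prob in spec.missing_individual.items():
        miss[v] |= rng.random(n) < prob
        expected_missing[v] = 1 - (1 - expected_missing[v]) * (1 - prob)
    for v, (struct, shift) in spec.missing_structural.items():
        base = spec.missing_individual.get(v, 0.1)
        s = np.asarray(df[struct], dtype=float)
        zs = (s - s.mean()) / s.std()
        logit0 = np.log(base / (1 - base))
        pv = 1.0 / (1.0 + np.exp(-(logit0 + shift * zs)))
        miss[v] |= rng.random(n) < pv
        expected_missing[v] = 1 - (1 - expected_missing[v]) * (1 - base)

    for c in df.columns:
        if miss[c].any():
            col = df[c]
            if col.dtype == object:
                df[c] = col.where(~miss[c], other=pd.NA)
            else:
                df[c] = col.mask(miss[c], other=np.nan)

    # --- dictionary ----------------------------------------------------------------
    specs = [
        VariableSpec("BloodCulture", Scale.BINARY, Role.OUTCOME,
                     label="blood culture result", units="no/yes"),
        VariableSpec("AGE", Scale.CONTINUOUS, Role.STRUCTURAL,
                     label="patient age", units="years",
                     plausibility_limits=(0.0, 120.0)),
        VariableSpec("SEX", Scale.BINARY, Role.STRUCTURAL,
                     label="patient sex", units="1=male, 2=female"),
    ]
    if comp is not None:
        specs.append(VariableSpec(comp.whole, Scale.CONTINUOUS, Role.KEY,
                                  label="leukocyte count (whole)", units="G/L"))
        big = comp.components[int(np.argmax(comp.shares))]
        for name in comp.components:
            role = Role.KEY if name == big else Role.MINOR
            specs.append(VariableSpec(name, Scale.CONTINUOUS, role,
                                      label=f"{name} cell count", units="G/L",
                                      component_of=comp.whole))
            specs.append(VariableSpec(ratio_names[name], Scale.CONTINUOUS, Role.MINOR,
                                      label=f"{name} percentage", units="%",
                                      ratio_of=name))
    for lab in spec.labs:
        specs.append(VariableSpec(lab.name, Scale.CONTINUOUS, lab.role,
                                  label=f"{lab.name} concentration", units=lab.units))
    dictionary = DataDictionary(specs)
    df = df[[v.name for v in dictionary if v.name in df.columns]]

    ground_truth = {
        "n_rows": n,
        "prevalence": spec.prevalence,
        "expected_missing": expected_missing,
        "missing_blocks": [list(b.variables) for b in spec.missing_blocks],
        # a zeroed component zeroes its ratio too, so the derived percentage
        # inherits the spike probability
        "spike_probabilities": {
            **dict(spec.spike_probabilities),
            **{ratio_names[v]: p for v, p in spec.spike_probabilities.items()
               if v in ratio_names},
        },
        "planted_spearman": {f"{a}|{b}": rho
                             for (a, b), rho in spec.correlation_plants.items()},
        "composition": None if comp is None else {
            "whole": comp.whole,
            "components": list(comp.components),
            "largest_component": comp.components[int(np.argmax(comp.shares))],
            "ratio_variables": dict(ratio_names),
        },
        "lognormal_log_sd": {l.name: l.log_sd for l in spec.labs},
        "outcome_effect": (list(spec.outcome_effect)
                           if spec.outcome_effect else None),
        "seed": spec.seed,
    }
    return dictionary, AnalysisDataset(df=df), ground_truth


# ---------------------------------------------------------------------------
# the default study
# ---------------------------------------------------------------------------

_DEFAULT_LABS: list[tuple[str, float, float, str]] = [
    # (name, log_mean, log_sd, role) — 38 independent-margin labs; log_sd >= 1
    # marks the heavily skewed acute-phase / enzyme panel
    ("ALB", np.log(35), 0.25, "minor"), ("AMY", np.log(60), 1.0, "minor"),
    ("AP", np.log(80), 0.9, "minor"), ("APTT", np.log(35), 0.35, "minor"),
    ("ASAT", np.log(30), 1.1, "medium"), ("ALAT", np.log(25), 1.1, "medium"),
    ("BUN", np.log(18), 0.7, "key"), ("CA", np.log(2.3), 0.12, "minor"),
    ("CHE", np.log(6), 0.45, "minor"), ("CHOL", np.log(170), 0.35, "minor"),
    ("CK", np.log(90), 1.3, "minor"), ("CREA", np.log(1.0), 0.6, "key"),
    ("CRP", np.log(5), 1.5, "medium"), ("FIB", np.log(400), 0.4, "medium"),
    ("GBIL", np.log(0.8), 1.0, "minor"), ("GGT", np.log(40), 1.2, "medium"),
    ("GLU", np.log(110), 0.35, "minor"), ("HCT", np.log(35), 0.18, "minor"),
    ("HGB", np.log(120), 0.18, "minor"), ("HS", np.log(5), 0.5, "minor"),
    ("LDH", np.log(220), 0.6, "minor"), ("LIP", np.log(40), 1.2, "minor"),
    ("MCH", np.log(30), 0.08, "minor"), ("MCHC", np.log(33), 0.05, "minor"),
    ("MCV", np.log(90), 0.08, "minor"), ("MG", np.log(0.85), 0.15, "minor"),
    ("MPV", np.log(10), 0.15, "minor"), ("NT", np.log(90), 0.3, "minor"),
    ("PAMY", np.log(30), 1.0, "minor"), ("PDW", np.log(12), 0.18, "minor"),
    ("PHOS", np.log(1.1), 0.3, "minor"), ("PLT", np.log(220), 0.5, "key"),
    ("POTASS", np.log(4.1), 0.12, "medium"), ("RBC", np.log(4.2), 0.18, "minor"),
    ("RDW", np.log(14), 0.12, "minor"), ("SODIUM", np.log(138), 0.03, "minor"),
    ("TP", np.log(65), 0.15, "minor"), ("TRIG", np.log(120), 0.6, "minor"),
]


def default_bacteremia_like_spec(seed: int = 0, n_rows: int = 2000) -> SyntheticSpec:
    """The default study conditions: 51 predictors mirroring a hospital
    laboratory cohort — age and sex, a 5-component leukocyte block with
    derived percentages, and 38 lab concentrations — with zero-spiked rare
    cell types (87% / 48%), panel-wise block missingness, planted
    high-correlation pairs, and an 8% outcome independent of all predictors.
    """
    labs = [LabSpec(name, m, s, Role(role)) for name, m, s, role in _DEFAULT_LABS]
    return SyntheticSpec(
        n_rows=n_rows,
        prevalence=0.08,
        labs=labs,
        composition=CompositionSpec(
            whole="WBC",
            components=("BASO", "EOS", "NEU", "LYM", "MONO"),
            shares=(0.01, 0.04, 0.62, 0.25, 0.08),
        ),
        spike_probabilities={"BASO": 0.87, "EOS": 0.48},
        missing_blocks=[
            MissingBlock(("TRIG", "CHOL", "PAMY"), 0.35),
            MissingBlock(("AMY", "LIP"), 0.25),
            MissingBlock(("FIB", "NT", "APTT"), 0.18),
        ],
        missing_individual={
            "GLU": 0.22, "HS": 0.21, "ASAT": 0.12, "ALAT": 0.12, "GGT": 0.15,
            "CRP": 0.05, "BUN": 0.02, "CREA": 0.02, "LDH": 0.10, "CK": 0.14,
            "GBIL": 0.12, "CHE": 0.10, "AP": 0.08, "ALB": 0.15, "CA": 0.05,
            "MG": 0.12, "PHOS": 0.10, "TP": 0.08, "POTASS": 0.03, "SODIUM": 0.03,
        },
        correlation_plants={
            ("RBC", "HGB"): 0.92,
            ("HGB", "HCT"): 0.93,
            ("RBC", "HCT"): 0.86,
            ("MPV", "PDW"): 0.85,
            ("ASAT", "ALAT"): 0.75,
        },
        seed=seed,
    )


def default_plan(dictionary: DataDictionary, seed: int = 0) -> IDAPlan:
    """The shipped IDA plan for a generated study: structural, key,
    key+medium and all-predictor candidate sets, default thresholds, and the
    mid quantile preset."""
    structural = [v.name for v in dictionary.structural]
    key = structural + dictionary.predictor_names("key")
    medium = dictionary.predictor_names("medium")
    all_preds = [v.name for v in dictionary.predictors]
    return IDAPlan(
        model_sets={
            "structural": structural,
            "key": key,
            "key_medium": key + medium,
            "all": all_preds,
        },
        interactions=[("AGE", "BUN"), ("AGE", "PLT")] if "BUN" in all_preds else [],
        seed=seed,
    )
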