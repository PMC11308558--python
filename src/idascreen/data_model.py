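"""Domain types for initial data analysis (IDA) of regression datasets.

The screening pipeline is driven by three coupled inputs:

* a :class:`DataDictionary` — one :class:`VariableSpec` per variable, carrying
  its measurement scale, its role in the intended regression (outcome,
  structural, key/medium/minor predictor, identifier), plausibility limits,
  and structural relations (part–whole composition, derived percentages);
* an :class:`AnalysisDataset` — the rectangular observations table with
  explicit missing cells (data cleaning is assumed done upstream; values
  outside plausibility limits are counted, never altered);
* an :class:`IDAPlan` — candidate model sets, screening thresholds, quantile
  sets, transformation settings and the seed.

``validate_plan`` cross-checks the three before any screening runs, so that
every downstream step can assume a consistent universe of variable names.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Scale",
    "Role",
    "VariableSpec",
    "DataDictionary",
    "AnalysisDataset",
    "Thresholds",
    "IDAPlan",
    "ValidationFinding",
    "ValidationReport",
    "QUANTILE_PRESETS",
    "read_data_dictionary",
    "write_data_dictionary",
    "read_dataset",
    "validate_plan",
]


class Scale(str, Enum):
    CONTINUOUS = "continuous"
    BINARY = "binary"
    NOMINAL = "nominal"
    ORDINAL = "ordinal"


class Role(str, Enum):
    OUTCOME = "outcome"
    STRUCTURAL = "structural"
    KEY = "key"
    MEDIUM = "medium"
    MINOR = "minor"
    IDENTIFIER = "identifier"


#: Quantile probability presets for continuous summaries. ``mid`` is the
#: default screening set; ``wide`` reaches further into the tails.
QUANTILE_PRESETS: dict[str, tuple[float, ...]] = {
    "mid": (0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95),
    "wide": (0.01, 0.05, 0.25, 0.50, 0.75, 0.90, 0.99),
}

_CATEGORICAL_SCALES = {Scale.BINARY, Scale.NOMINAL, Scale.ORDINAL}


@dataclass(frozen=True)
class VariableSpec:
    """Metadata for a single variable.

    ``component_of`` records that this variable is a physical component of
    another (e.g. neutrophils are part of the white blood count);
    ``ratio_of`` records that this variable is a derived percentage of
    another. Both drive the part–whole / ratio redundancy rules.
    """

    name: str
    scale: Scale
    role: Role
    label: str = ""
    units: str = ""
    plausibility_limits: tuple[float, float] | None = None
    component_of: str | None = None
    ratio_of: str | None = None
    collapse_map: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("variable name must be non-empty")
        if self.plausibility_limits is not None:
            lo, hi = self.plausibility_limits
            if lo > hi:
                raise ValueError(
                    f"{self.name}: plausibility lower bound {lo} exceeds upper {hi}"
                )
            if self.scale not in (Scale.CONTINUOUS, Scale.ORDINAL):
                raise ValueError(
                    f"{self.name}: plausibility limits only apply to "
                    "continuous/ordinal variables"
                )

    @property
    def is_categorical(self) -> bool:
        return self.scale in _CATEGORICAL_SCALES


@dataclass
class DataDictionary:
    """Ordered collection of variable specs with cross-reference checks."""

    variables: list[VariableSpec]

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate variable names: {sorted(dupes)}")
        known = set(names)
        for v in self.variables:
            for ref, what in ((v.component_of, "component_of"), (v.ratio_of, "ratio_of")):
                if ref is not None and ref not in known:
                    raise ValueError(f"{v.name}.{what} references unknown variable {ref!r}")
        outcomes = [v for v in self.variables if v.role is Role.OUTCOME]
        if len(outcomes) != 1:
            raise ValueError(f"exactly one outcome variable required, found {len(outcomes)}")

    def __iter__(self):
        return iter(self.variables)

    def __len__(self) -> int:
        return len(self.variables)

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    def __getitem__(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def outcome(self) -> VariableSpec:
        return next(v for v in self.variables if v.role is Role.OUTCOME)

    def by_role(self, *roles: Role) -> list[VariableSpec]:
        return [v for v in self.variables if v.role in roles]

    @property
    def structural(self) -> list[VariableSpec]:
        return self.by_role(Role.STRUCTURAL)

    @property
    def predictors(self) -> list[VariableSpec]:
        """All model-candidate variables: structural + key + medium + minor."""
        return self.by_role(Role.STRUCTURAL, Role.KEY, Role.MEDIUM, Role.MINOR)

    def predictor_names(self, importance: str | None = None) -> list[str]:
        if importance is None:
            return [v.name for v in self.predictors]
        return [v.name for v in self.by_role(Role(importance))]


@dataclass
class AnalysisDataset:
    """Observations table with explicit missing cells.

    ``df`` holds one column per dictionary variable present in the source;
    missing cells are NaN (numeric) / NA (categorical). Plausibility-limit
    violations detected at load time are counted per variable, never fixed.
    """

    df: pd.DataFrame
    limit_violations: dict[str, int] = field(default_factory=dict)
    missing_reasons: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.df) < 1:
            raise ValueError("dataset must contain at least one row")

    @property
    def n_rows(self) -> int:
        return len(self.df)

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def missing_mask(self) -> pd.DataFrame:
        return self.df.isna()


@dataclass(frozen=True)
class Thresholds:
    """Screening thresholds; all overridable in the plan file.

    Proportion-valued thresholds live in (0, 1).
    """

    spearman_pearson_delta: float = 0.1   # |rho_S - r_P| beyond which a pair is flagged
    high_corr: float = 0.8                # Spearman above which a pair is collinear
    normdev_gain: float = 0.2             # normal-scores-correlation gain to adopt a transform
    missing_review: float = 0.20          # item-missingness proportion triggering review
    missing_omit: float = 1.0 / 3.0       # item-missingness proportion suggesting omission
    spike_mode_prop: float = 0.40         # modal proportion at which a spike degenerates
    vif_flag: float = 5.0                 # variance inflation factor worth flagging
    redundancy_r2: float = 0.9            # R^2 above which a predictor is redundant
    discordance_block: float = 0.05       # pairwise discordance below which missingness is shared
    min_level_count: int = 10             # sparse-category threshold for collapse suggestions

    def __post_init__(self) -> None:
        for name in ("spearman_pearson_delta", "high_corr", "normdev_gain",
                     "missing_review", "missing_omit", "spike_mode_prop",
                     "redundancy_r2", "discordance_block"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"threshold {name}={v} must lie in (0, 1)")


@dataclass
class IDAPlan:
    """The pre-specified IDA plan: what to screen and with which settings."""

    model_sets: dict[str, list[str]]
    interactions: list[tuple[str, str]] = field(default_factory=list)
    thresholds: Thresholds = field(default_factory=Thresholds)
    quantiles: tuple[float, ...] = QUANTILE_PRESETS["mid"]
    pseudolog_sigma: float | Mapping[str, float] = 1.0
    pseudolog_base: float = 10.0
    structural_strata: Mapping[str, Sequence[float] | str] = field(default_factory=dict)
    seed: int = 0
    min_pairs: int = 30
    unit_counts: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        qs = tuple(float(q) for q in self.quantiles)
        if any(not 0.0 < q < 1.0 for q in qs):
            raise ValueError("quantile probabilities must lie in (0, 1)")
        if any(b >= a for a, b in zip(qs[1:], qs[:-1])):
            raise ValueError("quantile probabilities must be strictly increasing")
        self.quantiles = qs
        self.model_sets = {k: list(v) for k, v in self.model_sets.items()}

    def sigma_for(self, variable: str) -> float:
        if isinstance(self.pseudolog_sigma, Mapping):
            return float(self.pseudolog_sigma.get(variable, 1.0))
        return float(self.pseudolog_sigma)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = {
            "model_sets": {k: list(v) for k, v in self.model_sets.items()},
            "interactions": [list(p) for p in self.interactions],
            "thresholds": asdict(self.thresholds),
            "quantiles": list(self.quantiles),
            "pseudolog": {
                "sigma": (dict(self.pseudolog_sigma)
                          if isinstance(self.pseudolog_sigma, Mapping)
                          else self.pseudolog_sigma),
                "base": self.pseudolog_base,
            },
            "structural_strata": {k: (list(v) if not isinstance(v, str) else v)
                                  for k, v in self.structural_strata.items()},
            "seed": self.seed,
            "min_pairs": self.min_pairs,
        }
        if self.unit_counts is not None:
            d["unit_counts"] = dict(self.unit_counts)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "IDAPlan":
        pseudolog = d.get("pseudolog", {})
        return cls(
            model_sets={k: list(v) for k, v in d["model_sets"].items()},
            interactions=[tuple(p) for p in d.get("interactions", [])],
            thresholds=Thresholds(**d.get("thresholds", {})),
            quantiles=tuple(d.get("quantiles", QUANTILE_PRESETS["mid"])),
            pseudolog_sigma=pseudolog.get("sigma", 1.0),
            pseudolog_base=float(pseudolog.get("base", 10.0)),
            structural_strata=d.get("structural_strata", {}),
            seed=int(d.get("seed", 0)),
            min_pairs=int(d.get("min_pairs", 30)),
            unit_counts=d.get("unit_counts"),
        )

    def to_yaml(self, stream: IO[str] | None = None) -> str | None:
        return yaml.safe_dump(self.to_dict(), stream, sort_keys=False)

    @classmethod
    def from_yaml(cls, source: str | IO[str]) -> "IDAPlan":
        if isinstance(source, str):
            data = yaml.safe_load(source)
        else:
            data = yaml.safe_load(source.read())
        return cls.from_dict(data)


@dataclass(frozen=True)
class ValidationFinding:
    severity: str  # "error" | "warning"
    code: str
    message: str
    variable: str | None = None


@dataclass
class ValidationReport:
    findings: list[ValidationFinding] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationFinding]:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def warnings(self) -> list[ValidationFinding]:
        return [f for f in self.findings if f.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_DICT_COLUMNS = ["name", "label", "scale", "units", "role", "lower", "upper",
                 "component_of", "ratio_of", "collapse_map"]


def _parse_collapse_map(token: str) -> dict[str, str]:
    # encoded as "orig:collapsed|orig2:collapsed"
    out: dict[str, str] = {}
    for part in token.split("|"):
        orig, _, coll = part.partition(":")
        if not coll:
            raise ValueError(f"malformed collapse_map entry {part!r}")
        out[orig.strip()] = coll.strip()
    return out


def _format_collapse_map(m: Mapping[str, str]) -> str:
    return "|".join(f"{k}:{v}" for k, v in m.items())


def read_data_dictionary(source: str | IO[str], sep: str = ",") -> DataDictionary:
    """Read a data dictionary from a delimited table.

    Mandatory columns: ``name``, ``scale``, ``role``. Optional:
    ``label``, ``units``, ``lower``, ``upper``, ``component_of``,
    ``ratio_of``, ``collapse_map``. Unspecified optional fields stay absent.

    Raises ``ValueError`` on duplicate names or unknown scale/role tokens.
    """
    tbl = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    missing_cols = {"name", "scale", "role"} - set(tbl.columns)
    if missing_cols:
        raise ValueError(f"dictionary is missing required columns: {sorted(missing_cols)}")

    specs: list[VariableSpec] = []
    for _, row in tbl.iterrows():
        try:
            scale = Scale(row["scale"].strip())
        except ValueError:
            raise ValueError(f"unknown scale token {row['scale']!r} for variable {row['name']!r}")
        try:
            role = Role(row["role"].strip())
        except ValueError:
            raise ValueError(f"unknown role token {row['role']!r} for variable {row['name']!r}")

        def _opt(col: str) -> str | None:
            v = row.get(col, "")
            v = v.strip() if isinstance(v, str) else v
            return v if v else None

        limits = None
        lo, hi = _opt("lower"), _opt("upper")
        if lo is not None or hi is not None:
            limits = (float(lo) if lo is not None else -np.inf,
                      float(hi) if hi is not None else np.inf)
        cmap_token = _opt("collapse_map")
        specs.append(VariableSpec(
            name=row["name"].strip(),
            label=row.get("label", "") or "",
            scale=scale,
            units=row.get("units", "") or "",
            role=role,
            plausibility_limits=limits,
            component_of=_opt("component_of"),
            ratio_of=_opt("ratio_of"),
            collapse_map=_parse_collapse_map(cmap_token) if cmap_token else None,
        ))
    return DataDictionary(specs)


def write_data_dictionary(dd: DataDictionary, dest: str | IO[str], sep: str = ",") -> None:
    """Write a dictionary back to the canonical delimited layout."""
    rows = []
    for v in dd:
        lo, hi = ("", "")
        if v.plausibility_limits is not None:
            l, h = v.plausibility_limits
            lo = "" if np.isneginf(l) else repr(float(l))
            hi = "" if np.isposinf(h) else repr(float(h))
        rows.append({
            "name": v.name, "label": v.label, "scale": v.scale.value,
            "units": v.units, "role": v.role.value, "lower": lo, "upper": hi,
            "component_of": v.component_of or "", "ratio_of": v.ratio_of or "",
            "collapse_map": _format_collapse_map(v.collapse_map) if v.collapse_map else "",
        })
    pd.DataFrame(rows, columns=_DICT_COLUMNS).to_csv(dest, sep=sep, index=False)


def read_dataset(
    source: str | IO[str],
    dictionary: DataDictionary,
    sep: str = ",",
    na_tokens: Iterable[str] = ("NA",),
) -> AnalysisDataset:
    """Read observations, resolving columns against the dictionary.

    Empty cells and ``na_tokens`` become explicit missing values. Continuous
    and ordinal columns are parsed as floats ('.' decimal mark); categorical
    columns stay as strings. Values outside declared plausibility limits are
    loaded unchanged but counted in ``limit_violations``.
    """
    raw = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    unknown = [c for c in raw.columns if c not in dictionary]
    if unknown:
        raise ValueError(
            f"columns not in dictionary (data cleaning assumption violated): {unknown}"
        )

    na_set = set(na_tokens) | {""}
    df = pd.DataFrame(index=raw.index)
    violations: dict[str, int] = {}
    for col in raw.columns:
        spec = dictionary[col]
        s = raw[col].where(~raw[col].isin(na_set), other=pd.NA)
        if spec.scale in (Scale.CONTINUOUS, Scale.ORDINAL):
            num = pd.to_numeric(s, errors="raise").astype(float)
            if spec.plausibility_limits is not None:
                lo, hi = spec.plausibility_limits
                bad = ((num < lo) | (num > hi)) & num.notna()
                if bad.any():
                    violations[col] = int(bad.sum())
            df[col] = num
        else:
            df[col] = s.astype(object)
    return AnalysisDataset(df=df, limit_violations=violations)


# ---------------------------------------------------------------------------
# plan validation (checklist item PRE2)
# ---------------------------------------------------------------------------

def validate_plan(
    plan: IDAPlan, dictionary: DataDictionary, ds: AnalysisDataset
) -> ValidationReport:
    """Cross-check plan, dictionary and data before screening.

    Errors: model-set member absent from the data; no outcome column in the
    data; interaction pair degenerate or not both predictors. Warnings:
    structural variable with missing values; model set with < 2 members.
    Pure: identical inputs give identical reports.
    """
    findings: list[ValidationFinding] = []
    data_cols = set(ds.columns)
    predictor_names = {v.name for v in dictionary.predictors}

    if dictionary.outcome.name not in data_cols:
        findings.append(ValidationFinding(
            "error", "NO_OUTCOME",
            f"outcome variable {dictionary.outcome.name!r} absent from data",
            dictionary.outcome.name))

    for set_name, members in plan.model_sets.items():
        for m in members:
            if m not in data_cols:
                findings.append(ValidationFinding(
                    "error", "UNKNOWN_SET_MEMBER",
                    f"model set {set_name!r} member {m!r} absent from data", m))
        if len(members) < 2:
            findings.append(ValidationFinding(
                "warning", "SMALL_MODEL_SET",
                f"model set {set_name!r} has fewer than 2 members"))

    for a, b in plan.interactions:
        if a == b:
            findings.append(ValidationFinding(
                "error", "DEGENERATE_INTERACTION",
                f"interaction pair ({a}, {b}) is degenerate", a))
            continue
        for m in (a, b):
            if m not in predictor_names:
                findings.append(ValidationFinding(
                    "error", "INTERACTION_NOT_PREDICTOR",
                    f"interaction member {m!r} is not a predictor", m))

    for v in dictionary.structural:
        if v.name in data_cols and ds.df[v.name].isna().any():
            findings.append(ValidationFinding(
                "warning", "STRUCTURAL_MISSING",
                f"structural variable {v.name!r} has missing values", v.name))

    return ValidationReport(findings)
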