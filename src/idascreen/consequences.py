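"""Rule engine turning screening results into candidate amendments of the
statistical analysis plan (SAP).

Each rule is deterministic, pre-specified by the plan's thresholds, and emits
a :class:`Finding` with a full evidence trail — the exact statistics, taken
verbatim from the screening bundle, that triggered it. The engine only
recommends; it never drops or recodes a variable itself. No rule evaluates a
predictor–outcome association, so findings computed on blinded and unblinded
data are identical.

Rules:

* ``SPIKE_DEGENERATE`` — modal proportion at/above the spike threshold; such
  a variable (e.g. a cell count that is zero for most patients) is a discard
  candidate because no transformation removes the spike.
* ``HIGH_MISSING_OMIT`` / ``HIGH_MISSING_REVIEW`` — item missingness above
  the omission (default 1/3) or review (default 0.20) proportion.
* ``CORRELATED_MISSINGNESS_BLOCK`` — two or more high-missing variables
  whose pairwise missingness discordance is below the block threshold: they
  are missing together, so they cannot serve each other in imputation models.
* ``COLLINEAR_PAIR`` — Spearman correlation above the high-correlation
  threshold.
* ``PART_WHOLE_REPARAM`` — a collinear pair linked by a part–whole relation;
  emits a derived-variable definition (whole minus component) that removes
  the collinearity while keeping coefficients interpretable.
* ``RATIO_REDUNDANT`` — a derived-percentage variable highly correlated with
  its absolute counterpart.
* ``SPARSE_CATEGORY_COLLAPSE`` — a categorical level below the minimum count,
  with a collapse suggestion when the dictionary provides one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .bundle import ScreeningBundle
from .data_model import DataDictionary, IDAPlan

__all__ = ["Finding", "DerivedVariableDef", "apply_consequence_rules", "amendment_summary"]

RULE_SEVERITY = {
    "SPIKE_DEGENERATE": "discard_candidate",
    "HIGH_MISSING_OMIT": "discard_candidate",
    "HIGH_MISSING_REVIEW": "review",
    "CORRELATED_MISSINGNESS_BLOCK": "review",
    "COLLINEAR_PAIR": "review",
    "PART_WHOLE_REPARAM": "reparameterize",
    "RATIO_REDUNDANT": "discard_candidate",
    "SPARSE_CATEGORY_COLLAPSE": "reparameterize",
}


@dataclass(frozen=True)
class DerivedVariableDef:
    new_name: str
    whole: str
    component: str
    note: str = ""

    @property
    def formula(self) -> str:
        return f"{self.new_name} = {self.whole} - {self.component}"


@dataclass(frozen=True)
class Finding:
    rule_id: str
    variables: tuple[str, ...]
    evidence: Mapping[str, float]
    action: str
    severity: str
    derived: DerivedVariableDef | None = None


def _sorted_key(f: Finding) -> tuple:
    return (f.rule_id, f.variables)


def apply_consequence_rules(
    bundle: ScreeningBundle, dictionary: DataDictionary, plan: IDAPlan
) -> list[Finding]:
    """Evaluate every consequence rule against the screening bundle.

    Deterministic: the returned list is sorted by (rule, variables), so it is
    independent of evaluation order. Rules whose inputs are absent from the
    bundle are skipped (and noted in the bundle provenance by the pipeline).
    """
    thr = plan.thresholds
    findings: list[Finding] = []

    # --- univariate: degenerate spikes -------------------------------------
    for spike in bundle.spikes:
        findings.append(Finding(
            rule_id="SPIKE_DEGENERATE",
            variables=(spike.variable,),
            evidence={
                "mode_value": spike.mode_value,
                "mode_proportion": spike.mode_proportion,
                "concentration_ratio": spike.concentration_ratio,
                "threshold": thr.spike_mode_prop,
            },
            action=(f"consider discarding {spike.variable}: "
                    f"{100 * spike.mode_proportion:.0f}% of non-missing values equal "
                    f"{spike.mode_value:g}; no transformation removes this spike"),
            severity=RULE_SEVERITY["SPIKE_DEGENERATE"],
        ))

    # --- missingness thresholds ---------------------------------------------
    high_missing: list[str] = []
    for ms in bundle.item_missing:
        if ms.variable == dictionary.outcome.name:
            continue
        p = ms.proportion
        if p > thr.missing_omit:
            findings.append(Finding(
                rule_id="HIGH_MISSING_OMIT", variables=(ms.variable,),
                evidence={"missing_proportion": p, "threshold": thr.missing_omit},
                action=(f"consider omitting {ms.variable}: {100 * p:.0f}% missing "
                        f"exceeds the omission threshold"),
                severity=RULE_SEVERITY["HIGH_MISSING_OMIT"],
            ))
            high_missing.append(ms.variable)
        elif p > thr.missing_review:
            findings.append(Finding(
                rule_id="HIGH_MISSING_REVIEW", variables=(ms.variable,),
                evidence={"missing_proportion": p, "threshold": thr.missing_review},
                action=(f"review missing-data handling for {ms.variable}: "
                        f"{100 * p:.0f}% missing"),
                severity=RULE_SEVERITY["HIGH_MISSING_REVIEW"],
            ))
            high_missing.append(ms.variable)

    # --- correlated-missingness blocks --------------------------------------
    if bundle.discordance is not None and len(high_missing) >= 2:
        disc = bundle.discordance
        in_matrix = [v for v in high_missing if v in disc.variables]
        # greedy block growth over the high-missing variables
        blocks: list[list[str]] = []
        for v in in_matrix:
            placed = False
            for blk in blocks:
                if all(disc.pair(v, w) < thr.discordance_block for w in blk):
                    blk.append(v)
                    placed = True
                    break
            if not placed:
                blocks.append([v])
        for blk in blocks:
            if len(blk) >= 2:
                pairs = {f"d({a},{b})": disc.pair(a, b)
                         for i, a in enumerate(blk) for b in blk[i + 1:]}
                findings.append(Finding(
                    rule_id="CORRELATED_MISSINGNESS_BLOCK",
                    variables=tuple(sorted(blk)),
                    evidence={**pairs, "threshold": thr.discordance_block},
                    action=("these high-missing variables are missing together; "
                            "they cannot serve each other in imputation models"),
                    severity=RULE_SEVERITY["CORRELATED_MISSINGNESS_BLOCK"],
                ))

    # --- collinearity, part-whole and ratio redundancy -----------------------
    if len(bundle.high_corr_pairs):
        for _, row in bundle.high_corr_pairs.iterrows():
            a, b, rho = row["var1"], row["var2"], float(row["spearman"])
            sa, sb = dictionary[a], dictionary[b]
            part_whole = None
            if sa.component_of == b:
                part_whole = (b, a)  # (whole, component)
            elif sb.component_of == a:
                part_whole = (a, b)
            ratio = (sa.ratio_of == b) or (sb.ratio_of == a)
            if part_whole is not None:
                whole, comp = part_whole
                new_name = f"{whole}_NO{comp}"
                findings.append(Finding(
                    rule_id="PART_WHOLE_REPARAM", variables=(whole, comp),
                    evidence={"spearman": rho, "threshold": thr.high_corr},
                    action=(f"replace {whole} with {new_name} = {whole} - {comp}: "
                            f"removes the part-whole collinearity while keeping "
                            f"coefficients interpretable"),
                    severity=RULE_SEVERITY["PART_WHOLE_REPARAM"],
                    derived=DerivedVariableDef(
                        new_name=new_name, whole=whole, component=comp,
                        note=f"{comp} is a physical component of {whole}"),
                ))
            elif ratio:
                ratio_var = a if sa.ratio_of == b else b
                findings.append(Finding(
                    rule_id="RATIO_REDUNDANT", variables=(a, b),
                    evidence={"spearman": rho, "threshold": thr.high_corr},
                    action=(f"{ratio_var} is a derived percentage largely collinear "
                            f"with its absolute counterpart; it may not be needed "
                            f"for modeling"),
                    severity=RULE_SEVERITY["RATIO_REDUNDANT"],
                ))
            else:
                findings.append(Finding(
                    rule_id="COLLINEAR_PAIR", variables=(a, b),
                    evidence={"spearman": rho, "threshold": thr.high_corr},
                    action=(f"review the pair ({a}, {b}) in a scatterplot; "
                            f"consider reparameterization or selection"),
                    severity=RULE_SEVERITY["COLLINEAR_PAIR"],
                ))

    # --- sparse categorical levels -------------------------------------------
    outcome = dictionary.outcome.name
    for cs in bundle.categorical:
        if cs.variable == outcome:
            continue  # outcome level sparsity is a modeling-stage concern
        for lev, cnt in zip(cs.levels, cs.counts):
            if cnt < thr.min_level_count:
                spec = dictionary[cs.variable]
                suggestion = ""
                if spec.collapse_map and lev in spec.collapse_map:
                    suggestion = f"; dictionary suggests collapsing into {spec.collapse_map[lev]!r}"
                findings.append(Finding(
                    rule_id="SPARSE_CATEGORY_COLLAPSE",
                    variables=(cs.variable,),
                    evidence={"level_count": float(cnt),
                              "threshold": float(thr.min_level_count)},
                    action=(f"level {lev!r} of {cs.variable} has only {cnt} "
                            f"observations; consider collapsing with another "
                            f"level{suggestion}"),
                    severity=RULE_SEVERITY["SPARSE_CATEGORY_COLLAPSE"],
                ))

    return sorted(findings, key=_sorted_key)


def amendment_summary(
    findings: list[Finding], plan: IDAPlan, dictionary: DataDictionary | None = None
) -> dict:
    """Structured amendment document grouping findings by recommended action.

    Lists, per finding, the pre-specified rule, its threshold, the evidence,
    and the resulting candidate-predictor delta (variables recommended for
    discarding). Findings on the same variable set are merged, citing every
    rule. The document explicitly records that no outcome associations were
    used.
    """
    by_action: dict[str, list[dict]] = {}
    merged: dict[tuple[str, ...], list[Finding]] = {}
    for f in findings:
        merged.setdefault(f.variables, []).append(f)
    for variables, fs in sorted(merged.items()):
        entry = {
            "variables": list(variables),
            "rules": [f.rule_id for f in fs],
            "evidence": {f.rule_id: dict(f.evidence) for f in fs},
            "actions": [f.action for f in fs],
        }
        severity = fs[0].severity if len({f.severity for f in fs}) == 1 else "review"
        by_action.setdefault(severity, []).append(entry)

    discard = sorted({v for f in findings if f.severity == "discard_candidate"
                      for v in f.variables})
    n_predictors = len(dictionary.predictors) if dictionary is not None else None
    delta = {
        "candidate_exclusions": discard,
        "n_candidate_exclusions": len(discard),
    }
    if n_predictors is not None:
        delta["n_predictors_before"] = n_predictors
        delta["n_predictors_after_exclusions"] = n_predictors - len(discard)

    return {
        "status": ("no amendments triggered" if not findings
                   else f"{len(findings)} rule-triggered findings"),
        "outcome_blinded": True,
        "note": "no predictor-outcome associations were evaluated; all findings "
                "derive from pre-specified, outcome-blind screening rules",
        "groups": by_action,
        "predictor_set_delta": delta,
    }
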