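"""Rendering: the screening bundle as a human-readable report (Markdown or
HTML) and a loss-free machine-readable JSON results file, plus the end-to-end
``run_ida`` entry point behind the CLI.

Every checklist item the plan covers appears exactly once as a tagged report
section — computed output or an explicit "not evaluable" marker — so a report
can be audited item by item. Displayed values are rounded to 3 significant
digits; the JSON keeps full precision. Machine-readable output contains no
timestamps, so identical inputs and seed reproduce it byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .bundle import CHECKLIST_ITEMS, ScreeningBundle
from .consequences import amendment_summary
from .data_model import (
    DataDictionary,
    IDAPlan,
    read_data_dictionary,
    read_dataset,
    validate_plan,
)
from .missingness import NOT_EVALUABLE
from .pipeline import run_screening

__all__ = ["bundle_to_dict", "render_report", "run_ida"]

_FORMATS = ("markdown", "html", "json")


# ---------------------------------------------------------------------------
# loss-free JSON encoding
# ---------------------------------------------------------------------------

def _jsonable(obj: Any) -> Any:
    if obj is None or obj is pd.NA:
        return None
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, (str, bool, int)):
        return obj
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        if math.isinf(obj):
            return "inf" if obj > 0 else "-inf"
        return obj
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _jsonable(float(obj))
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, pd.DataFrame):
        return {"columns": list(map(str, obj.columns)),
                "rows": [[_jsonable(v) for v in row]
                         for row in obj.itertuples(index=False, name=None)]}
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (pd.Interval,)):
        return str(obj)
    if hasattr(obj, "value") and isinstance(obj, object) and obj.__class__.__module__ != "builtins":
        try:
            return _jsonable(obj.value)
        except Exception:  # pragma: no cover
            pass
    return str(obj)


def bundle_to_dict(bundle: ScreeningBundle, dictionary: DataDictionary) -> dict:
    """Loss-free dictionary view of the bundle, one entry per checklist item."""
    dendro = bundle.missingness_dendrogram
    vdendro = bundle.variable_dendrogram
    d = {
        "provenance": {
            **_jsonable(bundle.provenance),
            "plan": _jsonable(bundle.plan.to_dict()),
        },
        "PRE2": {"validation": _jsonable(bundle.validation.findings)},
        "PRE3": {"n_variables": len(dictionary),
                 "variables": [v.name for v in dictionary]},
        "M1": {"unit_missingness": _jsonable(bundle.unit_missingness)},
        "M2": {"item_missingness": [
            {"variable": m.variable, "n_total": m.n_total,
             "n_missing": m.n_missing, "proportion": m.proportion}
            for m in bundle.item_missing]},
        "M3": {"cascade": [
            {"set_name": c.set_name, "variables": list(c.variables),
             "n_total": c.n_total, "n_complete": c.n_complete,
             "proportion_complete": c.proportion_complete}
            for c in bundle.cascade]},
        "M4": {
            "stratified_cascade": _jsonable(bundle.stratified_cascade),
            "discordance": (None if bundle.discordance is None else {
                "variables": bundle.discordance.variables,
                "d": _jsonable(bundle.discordance.d)}),
            "dendrogram_newick": dendro.to_newick() if dendro else None,
            "merge_table": _jsonable(dendro.merge_table()) if dendro else None,
        },
        "ME1": {"group_contrasts": _jsonable(bundle.missingness_groups)},
        "U1": {"categorical": _jsonable(bundle.categorical)},
        "U2": {
            "continuous": _jsonable(bundle.continuous),
            "spikes": _jsonable(bundle.spikes),
            "transform_decisions": _jsonable(bundle.transform_decisions),
        },
        "UE1": {"extremes": [
            {"variable": s.variable, "five_lowest": list(s.five_lowest),
             "five_highest": list(s.five_highest)} for s in bundle.continuous]},
        "V1": {"structural_associations": _jsonable(bundle.structural_associations)},
        "V2": {"spearman": _jsonable(bundle.spearman)},
        "V3": {"interactions": _jsonable(bundle.interactions)},
        "VE1": {"pearson": _jsonable(bundle.pearson),
                "discrepant_pairs": _jsonable(bundle.discrepant_pairs)},
        "VE2": {
            "dendrogram_newick": vdendro.to_newick() if vdendro else None,
            "high_corr_pairs": _jsonable(bundle.high_corr_pairs),
            "notices": list(bundle.cluster_notices),
        },
        "VE3": {"vif": _jsonable(bundle.vifs),
                "redundancy": _jsonable(bundle.redundancy)},
        "consequences": {
            "findings": _jsonable(bundle.findings),
            "amendments": _jsonable(
                amendment_summary(bundle.findings, bundle.plan, dictionary)),
        },
    }
    return d


# ---------------------------------------------------------------------------
# human-readable rendering
# ---------------------------------------------------------------------------

def _sig3(x: Any) -> str:
    if x is None:
        return "—"
    if isinstance(x, str):
        return x
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    v = float(x)
    if math.isnan(v):
        return "—"
    if math.isinf(v):
        return "≥ 10⁶"
    return f"{v:.3g}"


def _df_to_md(df: pd.DataFrame, max_rows: int = 40) -> str:
    if df is None or len(df) == 0:
        return "_(empty)_\n"
    show = df.head(max_rows).copy()
    for c in show.columns:
        if show[c].dtype.kind == "f":
            show[c] = show[c].map(_sig3)
    lines = ["| " + " | ".join(map(str, show.columns)) + " |",
             "| " + " | ".join("---" for _ in show.columns) + " |"]
    for row in show.itertuples(index=False, name=None):
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    if len(df) > max_rows:
        lines.append(f"\n_... {len(df) - max_rows} more rows in results.json_")
    return "\n".join(lines) + "\n"


def _render_markdown(bundle: ScreeningBundle, dictionary: DataDictionary,
                     images: dict[str, str] | None = None) -> str:
    images = images or {}
    out: list[str] = ["# Initial data analysis report\n"]
    prov = bundle.provenance
    out.append(f"Outcome-blinded: **{prov.get('blinded')}** · seed {bundle.plan.seed} "
               f"· dataset sha256 `{prov.get('dataset_sha256', '')[:12]}…`\n")

    out.append("## Prerequisites\n")
    out.append("### [PRE2] Plan validation\n")
    if bundle.validation.findings:
        for f in bundle.validation.findings:
            out.append(f"- **{f.severity}** `{f.code}`: {f.message}")
        out.append("")
    else:
        out.append("No issues.\n")
    out.append("### [PRE3] Data dictionary\n")
    out.append(f"{len(dictionary)} variables; outcome `{dictionary.outcome.name}`; "
               f"structural: {', '.join(v.name for v in dictionary.structural)}.\n")

    out.append("## Missing values\n")
    out.append("### [M1] Participant (unit) missingness\n")
    if isinstance(bundle.unit_missingness, str):
        out.append(f"{NOT_EVALUABLE}\n")
    else:
        out.append(_df_to_md(bundle.unit_missingness))
    out.append("### [M2] Item missingness\n")
    m2 = pd.DataFrame([{"variable": m.variable, "n_missing": m.n_missing,
                        "proportion": m.proportion} for m in bundle.item_missing])
    out.append(_df_to_md(m2.sort_values("proportion", ascending=False,
                                        ignore_index=True)))
    out.append("### [M3] Complete cases\n")
    m3 = pd.DataFrame([{"set": c.set_name, "n_complete": c.n_complete,
                        "proportion": c.proportion_complete} for c in bundle.cascade])
    out.append(_df_to_md(m3))
    out.append("### [M4] Missingness patterns\n")
    if bundle.missingness_dendrogram is not None:
        out.append("Discordance dendrogram (Newick):\n")
        out.append("```\n" + bundle.missingness_dendrogram.to_newick() + "\n```\n")
        if "missingness_dendrogram" in images:
            out.append(f"![missingness dendrogram]({images['missingness_dendrogram']})\n")
    else:
        out.append("not evaluable (fewer than 2 variables with missing values)\n")
    out.append(_df_to_md(bundle.stratified_cascade))
    out.append("### [ME1] Predictors of missingness\n")
    for name, tbl in bundle.missingness_groups.items():
        out.append(f"**Set {name}:**\n")
        out.append(tbl + "\n" if isinstance(tbl, str) else _df_to_md(tbl))

    out.append("## Univariate descriptions\n")
    out.append("### [U1] Categorical variables\n")
    u1 = pd.DataFrame([{"variable": c.variable,
                        "levels": "; ".join(f"{l}: {n} ({_sig3(n / c.n_nonmissing)})"
                                            for l, n in zip(c.levels, c.counts))}
                       for c in bundle.categorical])
    out.append(_df_to_md(u1))
    out.append("### [U2] Continuous variables\n")
    u2 = pd.DataFrame([{
        "variable": s.variable, "n": s.n_nonmissing, "distinct": s.n_distinct,
        "min": s.minimum, "median": s.quantiles.get(0.5), "max": s.maximum,
        "mean": s.mean, "sd": s.sd, "GMD": s.gini_mean_difference,
        "mode": s.mode_value, "mode_prop": s.mode_proportion,
    } for s in bundle.continuous])
    out.append(_df_to_md(u2, max_rows=80))
    if bundle.spikes:
        out.append("**Spikes detected:** " + ", ".join(
            f"{s.variable} (mode {_sig3(s.mode_value)}, {_sig3(100 * s.mode_proportion)}%, "
            f"concentration ratio {_sig3(s.concentration_ratio)})"
            for s in bundle.spikes) + "\n")
    out.append("**Transformation decisions** (normal-scores correlation criterion):\n")
    tr = pd.DataFrame([{
        "variable": t.variable, "r_raw": t.r_raw, "r_pseudolog": t.r_pseudolog,
        "r_cuberoot": t.r_cuberoot, "chosen": t.chosen, "gain": t.gain,
    } for t in bundle.transform_decisions])
    out.append(_df_to_md(tr, max_rows=80))
    for img_key in sorted(images):
        if img_key.startswith("combo_"):
            out.append(f"![{img_key}]({images[img_key]})\n")
    out.append("### [UE1] Extreme values\n")
    ue = pd.DataFrame([{"variable": s.variable,
                        "five_lowest": ", ".join(_sig3(v) for v in s.five_lowest),
                        "five_highest": ", ".join(_sig3(v) for v in s.five_highest)}
                       for s in bundle.continuous])
    out.append(_df_to_md(ue, max_rows=80))

    out.append("## Multivariate descriptions\n")
    out.append("### [V1] Associations with structural variables\n")
    out.append(_df_to_md(bundle.structural_associations, max_rows=30))
    out.append("### [V2] Spearman correlation matrix\n")
    if bundle.spearman is not None:
        n = len(bundle.spearman.variables)
        out.append(f"{n} x {n} pairwise-complete matrix "
                   f"({n * (n - 1) // 2} pairs); full matrix in results.json.\n")
        if "correlation_heatmap" in images:
            out.append(f"![correlation heatmap]({images['correlation_heatmap']})\n")
    else:
        out.append("not evaluable\n")
    out.append("### [V3] Declared interactions\n")
    if bundle.interactions:
        v3 = pd.DataFrame([{"pair": f"{i['pair'][0]} x {i['pair'][1]}",
                            "spearman": i["spearman"], "n": i["n_pairs"]}
                           for i in bundle.interactions])
        out.append(_df_to_md(v3))
    else:
        out.append("No interactions declared.\n")
    out.append("### [VE1] Spearman vs Pearson discrepancies\n")
    out.append(_df_to_md(bundle.discrepant_pairs, max_rows=30))
    out.append("### [VE2] Variable clustering\n")
    if bundle.variable_dendrogram is not None:
        out.append("```\n" + bundle.variable_dendrogram.to_newick() + "\n```\n")
        if "variable_dendrogram" in images:
            out.append(f"![variable dendrogram]({images['variable_dendrogram']})\n")
    out.append("High-correlation pairs (Spearman above threshold):\n")
    out.append(_df_to_md(bundle.high_corr_pairs))
    out.append("### [VE3] Variance inflation and redundancy\n")
    for v in bundle.vifs:
        top = sorted(v.vif.items(), key=lambda kv: -(kv[1] if kv[1] == kv[1] else -1))[:5]
        out.append(f"- set **{v.model_set}** ({v.basis} basis, "
                   f"n_complete {v.n_complete}): max VIF "
                   + ", ".join(f"{k}={_sig3(val)}" for k, val in top))
    out.append("")
    for r in bundle.redundancy:
        if r.removal_sequence:
            seq = ", ".join(f"{v} (R²={_sig3(x)})" for v, x in r.removal_sequence)
            out.append(f"- set **{r.model_set}**: removal sequence {seq}")
        else:
            out.append(f"- set **{r.model_set}**: no redundant predictors")
    out.append("")

    out.append("## Consequences\n")
    amend = amendment_summary(bundle.findings, bundle.plan, dictionary)
    out.append(f"**{amend['status']}** — {amend['note']}\n")
    if bundle.findings:
        fdf = pd.DataFrame([{
            "rule": f.rule_id, "variables": ", ".join(f.variables),
            "severity": f.severity, "action": f.action,
        } for f in bundle.findings])
        out.append(_df_to_md(fdf, max_rows=60))
        delta = amend["predictor_set_delta"]
        out.append(f"Candidate exclusions: {delta['n_candidate_exclusions']} "
                   f"({', '.join(delta['candidate_exclusions'])}); predictors "
                   f"{delta.get('n_predictors_before')} → "
                   f"{delta.get('n_predictors_after_exclusions')}.\n")
    return "\n".join(out)


def render_report(
    bundle: ScreeningBundle,
    dictionary: DataDictionary,
    format: str = "markdown",
    images: dict[str, str] | None = None,
) -> str:
    """Render the bundle in the requested format.

    ``markdown``/``html`` round displayed values to 3 significant digits;
    ``json`` is loss-free.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {_FORMATS}")
    if format == "json":
        return json.dumps(bundle_to_dict(bundle, dictionary), indent=2,
                          allow_nan=False)
    md = _render_markdown(bundle, dictionary, images)
    if format == "markdown":
        return md
    # minimal HTML wrapper around the Markdown body
    import html as _html

    return ("<!DOCTYPE html><html><head><meta charset='utf-8'>"
            "<title>IDA report</title></head><body><pre>"
            + _html.escape(md) + "</pre></body></html>")


# ---------------------------------------------------------------------------
# end-to-end run
# ---------------------------------------------------------------------------

def run_ida(
    data_path: str | Path,
    dict_path: str | Path,
    plan_path: str | Path,
    out_dir: str | Path,
    blind: bool = True,
    seed: int | None = None,
    format: str = "markdown",
    plots: bool = False,
) -> int:
    """Read -> validate -> blind -> screen -> consequences -> render.

    Writes ``report.md``/``report.html``, ``results.json`` and tidy tables to
    ``out_dir``. Returns 0 on success, 2 on validation errors (with
    ``validation.json`` written), 1 on any other module failure (partial
    outputs preserved).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    dictionary = read_data_dictionary(str(dict_path))
    ds = read_dataset(str(data_path), dictionary)
    with open(plan_path) as fh:
        plan = IDAPlan.from_yaml(fh)
    if seed is not None:
        plan.seed = seed

    validation = validate_plan(plan, dictionary, ds)
    (out / "validation.json").write_text(
        json.dumps(_jsonable(validation.findings), indent=2))
    if not validation.ok:
        return 2

    try:
        bundle = run_screening(ds, dictionary, plan, blind=blind)
    except Exception as e:  # partial outputs already on disk
        (out / "error.txt").write_text(f"screening failed: {e}\n")
        return 1

    images: dict[str, str] = {}
    if plots:
        from .plots import render_all_plots

        images = render_all_plots(bundle, ds, out)

    (out / "results.json").write_text(
        render_report(bundle, dictionary, "json"))
    suffix = {"markdown": "md", "html": "html", "json": "json"}[format]
    (out / f"report.{suffix}").write_text(
        render_report(bundle, dictionary, format, images))

    # tidy tables
    pd.DataFrame([{"variable": m.variable, "n_total": m.n_total,
                   "n_missing": m.n_missing, "proportion": m.proportion}
                  for m in bundle.item_missing]).to_csv(
        out / "item_missingness.csv", index=False)
    pd.DataFrame([dataclasses.asdict(t) for t in bundle.transform_decisions]
                 ).to_csv(out / "transform_decisions.csv", index=False)
    if bundle.spearman is not None:
        bundle.spearman.to_frame().to_csv(out / "spearman_matrix.csv")
        bundle.spearman.to_long().to_csv(out / "correlations_long.csv", index=False)
    if bundle.missingness_dendrogram is not None:
        (out / "missingness_dendrogram.nwk").write_text(
            bundle.missingness_dendrogram.to_newick())
    if bundle.variable_dendrogram is not None:
        (out / "variable_dendrogram.nwk").write_text(
            bundle.variable_dendrogram.to_newick())
    return 0
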