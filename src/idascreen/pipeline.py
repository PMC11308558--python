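"""Orchestration: run every screening domain in checklist order and collect
the results into a ScreeningBundle.

Order of operations: validate -> blind the outcome (default on) -> missing
values (M1-M4, ME1) -> univariate (U1, U2, UE1) -> transformations ->
multivariate (V1-V3, VE1-VE3) -> consequence rules. The outcome column only
ever enters its own univariate summary and the complete-case definitions.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

from . import missingness as miss
from . import multivariate as mv
from . import univariate as uv
from .blinding import blind_outcome
from .bundle import ScreeningBundle
from .consequences import apply_consequence_rules
from .data_model import (
    AnalysisDataset,
    DataDictionary,
    IDAPlan,
    Role,
    Scale,
    validate_plan,
)
from .transforms import apply_chosen_transforms, select_transformations

__all__ = ["run_screening"]


def _dataset_digest(ds: AnalysisDataset) -> str:
    payload = ds.df.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()


def run_screening(
    ds: AnalysisDataset,
    dictionary: DataDictionary,
    plan: IDAPlan,
    blind: bool = True,
) -> ScreeningBundle:
    """Execute the full IDA screening plan and return the bundle.

    Raises ``ValueError`` when plan validation produces errors; warnings are
    carried in the bundle.
    """
    validation = validate_plan(plan, dictionary, ds)
    if not validation.ok:
        msgs = "; ".join(f.message for f in validation.errors)
        raise ValueError(f"plan validation failed: {msgs}")

    notices: list[str] = []
    blinding_record = None
    original_digest = _dataset_digest(ds)
    if blind:
        ds, blinding_record = blind_outcome(ds, dictionary, plan.seed)

    outcome = dictionary.outcome.name
    screen_vars = [v for v in dictionary
                   if v.role is not Role.IDENTIFIER and v.name in ds.df.columns]
    predictors = [v for v in screen_vars if v.role is not Role.OUTCOME]

    # ---- missing values domain ------------------------------------------------
    unit = miss.unit_missingness_summary(plan.unit_counts)
    item = miss.item_missingness(ds, dictionary)
    cascade = miss.complete_case_cascade(ds, plan, dictionary)
    strat = miss.stratified_complete_cases(ds, plan, dictionary)

    with_missing = [m.variable for m in item
                    if m.n_missing > 0 and m.variable != outcome]
    if len(with_missing) >= 2:
        disc = miss.missingness_discordance_matrix(ds, with_missing)
        props = {m.variable: m.proportion for m in item}
        dendro = miss.cluster_missingness(disc, missing_proportions=props)
    else:
        disc, dendro = None, None
        notices.append("M4: fewer than 2 variables with missing values; "
                       "pattern clustering skipped")

    groups = {name: miss.compare_missingness_groups(ds, members, dictionary)
              for name, members in plan.model_sets.items()}

    # ---- univariate domain ------------------------------------------------------
    categorical = []
    continuous = []
    for v in screen_vars:
        if v.is_categorical:
            categorical.append(uv.summarize_categorical(
                ds, v.name, v.scale, v.collapse_map))
        elif ds.df[v.name].notna().any():
            continuous.append(uv.summarize_continuous(ds, v.name, plan.quantiles))
        else:
            notices.append(f"U2: {v.name} all missing; summary skipped")
    spikes = [f for s in continuous
              if s.variable != outcome and (f := uv.detect_spikes(s, plan))]

    decisions = select_transformations(ds, dictionary, plan)
    transformed = apply_chosen_transforms(ds, decisions, plan)

    # ---- multivariate domain ------------------------------------------------------
    assoc = mv.structural_association_table(ds, dictionary, plan, transformed)

    pairwise_vars = [v.name for v in predictors
                     if not v.is_categorical and v.role is not Role.STRUCTURAL]
    if len(pairwise_vars) >= 2:
        S = mv.spearman_matrix(ds, pairwise_vars, dictionary, plan.min_pairs)
        P = mv.pearson_matrix(ds, pairwise_vars, dictionary, plan.min_pairs)
        discrepant = mv.correlation_discrepancies(
            S, P, plan.thresholds.spearman_pearson_delta)
        var_dendro, high_pairs, cluster_notices = mv.variable_clusters(S, plan)
    else:
        S = P = var_dendro = None
        discrepant = pd.DataFrame(columns=["var1", "var2", "spearman", "pearson",
                                           "discrepancy"])
        high_pairs = pd.DataFrame(columns=["var1", "var2", "spearman"])
        cluster_notices = []
        notices.append("V2: fewer than 2 continuous predictors; matrices skipped")

    interactions = mv.interaction_screen(ds, plan, dictionary, transformed)

    vifs = []
    redundancy = []
    for name, members in plan.model_sets.items():
        for basis in ("linear", "additive"):
            try:
                vifs.append(mv.vif(ds, members, dictionary, plan,
                                   basis=basis, set_name=name))
            except ValueError as e:
                notices.append(f"VE3 vif[{name}/{basis}]: {e}")
        if len(members) <= 25:  # additive refits scale quadratically in set size
            try:
                redundancy.append(mv.redundancy_analysis(
                    ds, members, dictionary, plan, set_name=name))
            except ValueError as e:
                notices.append(f"VE3 redundancy[{name}]: {e}")
        else:
            notices.append(f"VE3 redundancy[{name}]: skipped (set too large; "
                           "VIF covers the full set)")

    bundle = ScreeningBundle(
        plan=plan,
        validation=validation,
        blinding=blinding_record,
        unit_missingness=unit,
        item_missing=item,
        cascade=cascade,
        stratified_cascade=strat,
        discordance=disc,
        missingness_dendrogram=dendro,
        missingness_groups=groups,
        categorical=categorical,
        continuous=continuous,
        spikes=spikes,
        transform_decisions=decisions,
        structural_associations=assoc,
        spearman=S,
        pearson=P,
        discrepant_pairs=discrepant,
        interactions=interactions,
        variable_dendrogram=var_dendro,
        high_corr_pairs=high_pairs,
        cluster_notices=cluster_notices,
        vifs=vifs,
        redundancy=redundancy,
        provenance={
            "dataset_sha256": original_digest,
            "seed": plan.seed,
            "blinded": blind,
            "blinding": (blinding_record.to_provenance()
                         if blinding_record else None),
            "notices": notices,
        },
    )
    bundle.findings = apply_consequence_rules(bundle, dictionary, plan)
    return bundle
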