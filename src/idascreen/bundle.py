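"""The ScreeningBundle: every computed IDA result, keyed by checklist item.

The bundle is the single handoff object between the screening pipeline, the
consequence rule engine, and the report renderer. Items that the plan cannot
evaluate (e.g. participant missingness without enrollment counts) appear as
explicit "not evaluable" entries rather than being silently absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from .blinding import BlindingRecord
from .data_model import IDAPlan, ValidationReport
from .missingness import CascadeRow, Dendrogram, DiscordanceMatrix, MissingSummary
from .multivariate import CorrelationMatrix, RedundancyResult, VifResult
from .transforms import TransformDecision
from .univariate import CategoricalSummary, ContinuousSummary, SpikeFlag

__all__ = ["ScreeningBundle", "CHECKLIST_ITEMS"]

#: Checklist item ids in report order.
CHECKLIST_ITEMS = (
    "PRE2", "PRE3",
    "M1", "M2", "M3", "M4", "ME1",
    "U1", "U2", "UE1",
    "V1", "V2", "V3", "VE1", "VE2", "VE3",
)


@dataclass
class ScreeningBundle:
    plan: IDAPlan
    validation: ValidationReport
    blinding: BlindingRecord | None

    # missing values domain
    unit_missingness: pd.DataFrame | str                       # M1
    item_missing: list[MissingSummary]                         # M2
    cascade: list[CascadeRow]                                  # M3
    stratified_cascade: pd.DataFrame                           # M4
    discordance: DiscordanceMatrix | None                      # M4
    missingness_dendrogram: Dendrogram | None                  # M4
    missingness_groups: dict[str, pd.DataFrame | str]          # ME1, per model set

    # univariate domain
    categorical: list[CategoricalSummary]                      # U1
    continuous: list[ContinuousSummary]                        # U2
    spikes: list[SpikeFlag]                                    # U2 / UE1
    transform_decisions: list[TransformDecision]               # U2

    # multivariate domain
    structural_associations: pd.DataFrame                      # V1
    spearman: CorrelationMatrix | None                         # V2
    pearson: CorrelationMatrix | None                          # VE1
    discrepant_pairs: pd.DataFrame                             # VE1
    interactions: list[dict]                                   # V3
    variable_dendrogram: Dendrogram | None                     # VE2
    high_corr_pairs: pd.DataFrame                              # VE2
    cluster_notices: list[str]                                 # VE2
    vifs: list[VifResult]                                      # VE3
    redundancy: list[RedundancyResult]                         # VE3

    findings: list[Any] = field(default_factory=list)          # consequences
    provenance: dict = field(default_factory=dict)

    def item_missing_by_variable(self) -> dict[str, MissingSummary]:
        return {m.variable: m for m in self.item_missing}

    def continuous_by_variable(self) -> dict[str, ContinuousSummary]:
        return {s.variable: s for s in self.continuous}
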