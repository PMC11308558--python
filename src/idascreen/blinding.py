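"""Outcome blinding: detach the outcome from the predictors by permutation.

Screening must never evaluate predictor–outcome associations. The blinded
IDA dataset enforces this mechanically: the outcome column is permuted by a
seeded uniform random permutation while every predictor column is left
byte-identical. The outcome's marginal distribution — including which cells
are missing — is preserved exactly, because a missing cell travels with its
permutation slot. All univariate outcome summaries are therefore identical
before and after blinding, while any outcome–predictor association is
destroyed in expectation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from datetime import datetime, timezone

import numpy as np

from .data_model import AnalysisDataset, DataDictionary

__all__ = ["BlindingRecord", "blind_outcome"]


@dataclass(frozen=True)
class BlindingRecord:
    """Provenance of an applied outcome permutation.

    The checksum digests the permutation indices, so the same seed applied to
    the same dataset always yields the same checksum.
    """

    seed: int
    outcome: str
    n_rows: int
    permutation_checksum: str
    timestamp: str

    def to_provenance(self) -> dict:
        # timestamp intentionally excluded: machine-readable outputs must be
        # byte-identical across runs with identical inputs and seed
        return {
            "seed": self.seed,
            "outcome": self.outcome,
            "n_rows": self.n_rows,
            "permutation_checksum": self.permutation_checksum,
        }


def blind_outcome(
    ds: AnalysisDataset, dictionary: DataDictionary, seed: int
) -> tuple[AnalysisDataset, BlindingRecord]:
    """Return a copy of ``ds`` with the outcome column randomly permuted.

    The permutation is uniform over row orders, drawn from
    ``numpy.random.default_rng(seed)``; missing outcome cells are permuted
    along with observed ones, so the outcome multiset (values and missing
    count) is invariant.
    """
    outcome = dictionary.outcome.name
    if outcome not in ds.df.columns:
        raise ValueError(f"outcome column {outcome!r} not present in dataset")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(ds.n_rows)
    checksum = hashlib.sha256(perm.astype(np.int64).tobytes()).hexdigest()

    df = ds.df.copy()
    df[outcome] = ds.df[outcome].to_numpy()[perm]

    record = BlindingRecord(
        seed=seed,
        outcome=outcome,
        n_rows=ds.n_rows,
        permutation_checksum=checksum,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    return AnalysisDataset(df=df, limit_violations=dict(ds.limit_violations)), record
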