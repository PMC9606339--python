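"""Threshold rules that turn index values into RVOT/LVOT calls.

Each published criterion is a single comparison of an index value against a
cutoff. ``direction`` states which side of the cutoff predicts RVOT and
``strict`` whether the comparator is ">" (boundary goes to the non-GE class)
or ">=" (boundary goes to the GE class), matching the comparator each rule
was published with.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .core_types import Call, Direction, PatientRecord


@dataclass(frozen=True)
class CriterionRule:
    name: str
    cutoff: float
    direction: Direction
    strict: bool = False  # True -> ">" comparator; False -> ">="
    enabled: bool = True

    def comparator(self) -> str:
        return ">" if self.strict else ">="


def classify(value: Optional[float], rule: CriterionRule) -> Call:
    """Apply one threshold rule. Missing (None/NaN) values -> INDETERMINATE.

    Signed-infinite values are legitimate ratio sentinels and classify like
    any other value under the comparator.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return Call.INDETERMINATE
    ge_side = value > rule.cutoff if rule.strict else value >= rule.cutoff
    if rule.direction is Direction.GE_PREDICTS_RVOT:
        return Call.RVOT if ge_side else Call.LVOT
    return Call.LVOT if ge_side else Call.RVOT


def classify_cohort(cohort: Iterable[PatientRecord], config) -> pd.DataFrame:
    """Per-patient, per-criterion calls and raw index values.

    Returns a DataFrame indexed by patient_id (input order preserved) with a
    ``<criterion>`` call column and a ``<criterion>_value`` column per enabled
    criterion in ``config`` (a :class:`otva.ecg_indices.CriteriaConfig`).
    """
    from .ecg_indices import compute_all  # local import: avoids module cycle

    cohort = list(cohort)
    if not cohort:
        raise ValueError("cohort must be non-empty")
    rows = []
    for rec in cohort:
        results = compute_all(rec, config)
        row: dict = {"patient_id": rec.patient_id, "origin": rec.origin.value}
        for res in results:
            row[res.criterion_name] = res.predicted_origin.value
            row[f"{res.criterion_name}_value"] = (
                float("nan") if res.value is None else res.value
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")
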