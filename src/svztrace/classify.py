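"""Patient-level recurrence-pattern classification and cohort summarization.

A patient with a recurrent sample is labeled by rule cascade:

1. no trunk variant (SVZ-tumor-shared, PRESENT in SVZ, primary and recurrent)
   -> UNKNOWN: without a lineage link through the SVZ nothing can be said;
2. any inter-tumor-shared variant (both tumors, not SVZ) -> PRIMARY_ASSOCIATED:
   the recurrence carries a direct genetic link to the dominant primary clone;
3. any primary-private variant confidently ABSENT from the recurrent tumor
   -> SVZ_ASSOCIATED: the primary's private clone went extinct while the
   trunk persisted, i.e. the recurrence branched from the early progenitor;
4. otherwise UNKNOWN (insufficient informative variants).

Rule 2 deliberately precedes rule 3: an inter-tumor-shared mutation directly
links the two tumors, which the SVZ-associated pattern explicitly excludes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .categorize import MutationCategory, categorize_patient
from .io import Role
from .presence import PatientPresence, Presence


class RecurrencePattern(str, Enum):
    SVZ_ASSOCIATED = "SVZ_ASSOCIATED"
    PRIMARY_ASSOCIATED = "PRIMARY_ASSOCIATED"
    UNKNOWN = "UNKNOWN"


class MissingRecurrentSampleError(ValueError):
    """Raised when a patient without a recurrent sample is classified."""


@dataclass
class PatientClassification:
    """A recurrence-pattern label plus the machine-readable rule firings."""

    patient_id: str
    pattern: RecurrencePattern
    rationale: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "pattern": self.pattern.value,
            "rationale": self.rationale,
        }


def classify_recurrence_pattern(
    presence: PatientPresence,
    categories: pd.DataFrame | None = None,
    *,
    strict_tert: bool = False,
    trunk_gene: str = "TERT",
) -> PatientClassification:
    """Classify one patient's recurrence as SVZ/primary-associated or unknown.

    ``strict_tert`` restricts trunk-link evidence to variants in ``trunk_gene``
    (the promoter mutation the study relies on empirically); by default any
    SVZ-tumor-shared variant present in all three tissues counts.
    """
    if not presence.has_recurrent:
        raise MissingRecurrentSampleError(
            f"{presence.patient_id}: no recurrent sample; recurrence pattern undefined"
        )
    if categories is None:
        categories = categorize_patient(presence)

    trunk, inter_tumor, extinct_primary, recurrent_private = [], [], [], []
    for key, row in categories.iterrows():
        category = MutationCategory(row["category"])
        if category is MutationCategory.SVZ_TUMOR_SHARED:
            in_all_three = all(
                presence.state(key, role) is Presence.PRESENT
                for role in (Role.SVZ, Role.PRIMARY, Role.RECURRENT)
            )
            gene_ok = (not strict_tert) or row["gene"] == trunk_gene
            if in_all_three and gene_ok:
                trunk.append(key)
        elif category is MutationCategory.INTER_TUMOR_SHARED:
            inter_tumor.append(key)
        elif category is MutationCategory.PRIMARY_PRIVATE:
            # PRIMARY_PRIVATE already implies a confident ABSENT in the
            # recurrent tumor (an INDETERMINATE would have made it UNRESOLVED);
            # the check is kept explicit as the extinction clause.
            if presence.state(key, Role.RECURRENT) is Presence.ABSENT:
                extinct_primary.append(key)
        elif category is MutationCategory.RECURRENT_PRIVATE:
            recurrent_private.append(key)

    rationale = {
        "trunk_variants": sorted(trunk),
        "inter_tumor_variants": sorted(inter_tumor),
        "extinct_primary_private_variants": sorted(extinct_primary),
        "recurrent_private_variants": sorted(recurrent_private),
        "strict_tert": strict_tert,
    }
    if not trunk:
        pattern, rule = RecurrencePattern.UNKNOWN, "no_trunk_link"
    elif inter_tumor:
        pattern, rule = RecurrencePattern.PRIMARY_ASSOCIATED, "inter_tumor_shared"
    elif extinct_primary:
        pattern, rule = RecurrencePattern.SVZ_ASSOCIATED, "primary_private_extinct"
    else:
        pattern, rule = RecurrencePattern.UNKNOWN, "insufficient_informative_variants"
    rationale["rule"] = rule
    return PatientClassification(
        patient_id=presence.patient_id, pattern=pattern, rationale=rationale
    )


def _round1(x: Decimal) -> float:
    return float(x.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    """Counts and one-decimal percentages per recurrence pattern."""

    counts: dict[str, int]
    percentages: dict[str, float]
    table: pd.DataFrame

    @property
    def n(self) -> int:
        return sum(self.counts.values())


def summarize_cohort(
    results: Sequence[PatientClassification | RecurrencePattern | str],
) -> CohortSummary:
    """Summarize per-patient labels into counts and percentages.

    Accepts PatientClassification objects or bare labels. Percentages are
    rounded half-up to one decimal; ordering is fixed (SVZ-associated,
    primary-associated, unknown) for determinism.
    """
    if len(results) == 0:
        raise ValueError("summarize_cohort requires at least one patient")
    labels = [
        r.pattern if isinstance(r, PatientClassification) else RecurrencePattern(r)
        for r in results
    ]
    order = [
        RecurrencePattern.SVZ_ASSOCIATED,
        RecurrencePattern.PRIMARY_ASSOCIATED,
        RecurrencePattern.UNKNOWN,
    ]
    total = len(labels)
    counts = {p.value: sum(1 for x in labels if x is p) for p in order}
    percentages = {
        p.value: _round1(Decimal(100) * Decimal(counts[p.value]) / Decimal(total))
        for p in order
    }
    table = pd.DataFrame(
        {
            "pattern": [p.value for p in order],
            "count": [counts[p.value] for p in order],
            "percent": [percentages[p.value] for p in order],
        }
    )
    return CohortSummary(counts=counts, percentages=percentages, table=table)
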