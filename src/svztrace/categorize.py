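"""Mutation-sharing categories across SVZ, primary and recurrent tissue.

Categories follow the sharing pattern of a somatic variant across the three
tissues: SVZ_TUMOR_SHARED (in SVZ and at least one tumor — the trunk class),
INTER_TUMOR_SHARED (in both tumors, not SVZ), PRIMARY_PRIVATE,
RECURRENT_PRIVATE, SVZ_PRIVATE, and UNRESOLVED when an INDETERMINATE presence
call blocks the deciding comparison.

The INDETERMINATE rule is implemented by completion enumeration: every
INDETERMINATE slot is expanded to both PRESENT and ABSENT; if all completions
imply the same category the triple resolves to it, otherwise it is UNRESOLVED.
A completion in which the variant is present nowhere counts as a distinct
"variant does not exist" outcome, so e.g. (INDETERMINATE, ABSENT, ABSENT) is
UNRESOLVED rather than SVZ_PRIVATE.
"""

from __future__ import annotations

from enum import Enum
from itertools import product

import pandas as pd

from .io import Role
from .presence import PatientPresence, Presence, PresenceCall


class MutationCategory(str, Enum):
    SVZ_TUMOR_SHARED = "SVZ_TUMOR_SHARED"
    INTER_TUMOR_SHARED = "INTER_TUMOR_SHARED"
    PRIMARY_PRIVATE = "PRIMARY_PRIVATE"
    RECURRENT_PRIVATE = "RECURRENT_PRIVATE"
    SVZ_PRIVATE = "SVZ_PRIVATE"
    UNRESOLVED = "UNRESOLVED"


_NONEXISTENT = "NONEXISTENT"  # all-absent completion: the variant is not there at all


def _resolved_category(svz: bool, primary: bool, recurrent: bool | None):
    """Category for a fully determined presence profile (True/False per tissue).

    ``recurrent is None`` means the patient has no recurrent sample yet.
    Returns _NONEXISTENT for the all-absent profile.
    """
    if recurrent is None:
        if svz and primary:
            return MutationCategory.SVZ_TUMOR_SHARED
        if primary:
            return MutationCategory.PRIMARY_PRIVATE
        if svz:
            return MutationCategory.SVZ_PRIVATE
        return _NONEXISTENT
    if svz and (primary or recurrent):
        return MutationCategory.SVZ_TUMOR_SHARED
    if primary and recurrent:
        return MutationCategory.INTER_TUMOR_SHARED
    if primary:
        return MutationCategory.PRIMARY_PRIVATE
    if recurrent:
        return MutationCategory.RECURRENT_PRIVATE
    if svz:
        return MutationCategory.SVZ_PRIVATE
    return _NONEXISTENT


def _as_state(call: Presence | PresenceCall) -> Presence:
    return call.state if isinstance(call, PresenceCall) else Presence(call)


def categorize_variant(
    svz: Presence | PresenceCall,
    primary: Presence | PresenceCall,
    recurrent: Presence | PresenceCall | None = None,
) -> MutationCategory:
    """Assign the sharing category for one somatic variant.

    Raises ValueError on an all-ABSENT triple (such a variant should not have
    been called anywhere and cannot be categorized).
    """
    states = [_as_state(svz), _as_state(primary)]
    has_recurrent = recurrent is not None
    if has_recurrent:
        states.append(_as_state(recurrent))

    if all(s is Presence.ABSENT for s in states):
        raise ValueError("variant ABSENT in every tissue: nothing to categorize")

    options = [
        (True, False) if s is Presence.INDETERMINATE else ((s is Presence.PRESENT),)
        for s in states
    ]
    outcomes = set()
    for completion in product(*options):
        if has_recurrent:
            outcomes.add(_resolved_category(*completion))
        else:
            outcomes.add(_resolved_category(completion[0], completion[1], None))
    if len(outcomes) == 1:
        (only,) = outcomes
        if only is _NONEXISTENT:  # unreachable given the all-ABSENT guard
            raise ValueError("variant cannot exist in any completion")
        return only
    return MutationCategory.UNRESOLVED


def _shared_tumors(primary: Presence, recurrent: Presence | None) -> str:
    tumors = []
    if primary is Presence.PRESENT:
        tumors.append("PRIMARY")
    if recurrent is Presence.PRESENT:
        tumors.append("RECURRENT")
    return "+".join(tumors)


def categorize_patient(presence: PatientPresence) -> pd.DataFrame:
    """Categorize every somatic (germline-excluded) variant of a patient.

    Returns a frame indexed by variant key with columns chrom, pos, ref, alt,
    gene, category, and shared_tumors (which tumors a SVZ_TUMOR_SHARED variant
    is shared with — the trunk class spans SVZ+either/both tumors).
    """
    rows = []
    for key in presence.somatic_keys:
        rec = presence.variants[key]
        svz = presence.state(key, Role.SVZ)
        primary = presence.state(key, Role.PRIMARY)
        recurrent = presence.state(key, Role.RECURRENT) if presence.has_recurrent else None
        category = categorize_variant(svz, primary, recurrent)
        rows.append(
            {
                "variant": key,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alt,
                "gene": rec.gene or "",
                "category": category.value,
                "shared_tumors": (
                    _shared_tumors(primary, recurrent)
                    if category is MutationCategory.SVZ_TUMOR_SHARED
                    else ""
                ),
            }
        )
    columns = ["variant", "chrom", "pos", "ref", "alt", "gene", "category", "shared_tumors"]
    frame = pd.DataFrame(rows, columns=columns)
    return frame.set_index("variant")


def oncoplot_matrix(category_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Cohort-wide oncoplot matrix: rows gene/variant labels, columns patients.

    Cell values are category tokens; distinct alleles of one gene stay distinct
    rows (allele-level identity).
    """
    cells: dict[str, dict[str, str]] = {}
    for patient_id, table in category_tables.items():
        for key, row in table.iterrows():
            label = f"{row['gene']} {key}".strip()
            cells.setdefault(label, {})[patient_id] = row["category"]
    frame = pd.DataFrame.from_dict(cells, orient="index").fillna("")
    frame = frame.reindex(sorted(frame.index), columns=sorted(frame.columns))
    frame.index.name = "variant"
    return frame
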