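"""Depth-aware presence calling: PRESENT / ABSENT / INDETERMINATE per tissue.

A variant is PRESENT in a sample when its alt-read support both clears a
minimum read count and is inconsistent with sequencing noise (one-sided
binomial tail test at the assumed per-base miscall rate). Claiming ABSENT is
only allowed when the experiment had the power to detect a variant at the
study's minimum VAF of interest: absence of evidence is evidence of absence
only at sufficient depth. Everything else is INDETERMINATE — an explicit
insufficient-evidence state that propagates into UNRESOLVED categories and
UNKNOWN patient labels downstream rather than fabricating clonal extinction
from thin coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import binom

from .io import ManifestError, PatientManifest, Role, VariantCall


@dataclass(frozen=True)
class PresenceParams:
    """Thresholds governing presence calls.

    min_alt_reads: minimum alt reads for PRESENT.
    alpha: significance level of the one-sided noise test.
    error_rate: assumed per-base miscall fraction.
    vaf_detect: minimum VAF an ABSENT call must have been able to detect.
    power_floor: required detection power (at vaf_detect) for ABSENT.
    """

    min_alt_reads: int = 3
    alpha: float = 1e-3
    error_rate: float = 1e-3
    vaf_detect: float = 0.02
    power_floor: float = 0.9

    def __post_init__(self) -> None:
        if self.min_alt_reads < 1:
            raise ValueError("min_alt_reads must be >= 1")
        for name in ("alpha", "error_rate", "vaf_detect", "power_floor"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.vaf_detect <= self.error_rate:
            raise ValueError("vaf_detect must exceed error_rate")


DEFAULT_PARAMS = PresenceParams()


class Presence(str, Enum):
    PRESENT = "PRESENT"
    ABSENT = "ABSENT"
    INDETERMINATE = "INDETERMINATE"


@dataclass(frozen=True)
class PresenceCall:
    """A presence state with its supporting VAF estimate and noise p-value."""

    state: Presence
    vaf: float
    p_value: float


@lru_cache(maxsize=65536)
def min_present_alt(total_depth: int, params: PresenceParams = DEFAULT_PARAMS) -> int:
    """Smallest alt count k* satisfying the PRESENT criteria at this depth.

    k* = min k such that k >= min_alt_reads and P(X >= k | Binom(depth, error)) <= alpha.
    May exceed total_depth at very low depth, in which case PRESENT is unreachable.
    """
    n, e, alpha = total_depth, params.error_rate, params.alpha
    k = max(params.min_alt_reads, 1)
    while k <= n and binom.sf(k - 1, n, e) > alpha:
        k += 1
    return k


def call_presence(
    alt_count: int,
    total_depth: int,
    params: PresenceParams = DEFAULT_PARAMS,
) -> PresenceCall:
    """Classify one (alt, depth) observation as PRESENT/ABSENT/INDETERMINATE."""
    if total_depth < 1:
        raise ValueError(f"total_depth must be >= 1, got {total_depth}")
    if not 0 <= alt_count <= total_depth:
        raise ValueError(f"alt_count {alt_count} outside [0, {total_depth}]")
    p_value = float(binom.sf(alt_count - 1, total_depth, params.error_rate))
    vaf = alt_count / total_depth
    if alt_count >= min_present_alt(total_depth, params) and p_value <= params.alpha:
        state = Presence.PRESENT
    elif detection_power(total_depth, params.vaf_detect, params) >= params.power_floor:
        state = Presence.ABSENT
    else:
        state = Presence.INDETERMINATE
    return PresenceCall(state=state, vaf=vaf, p_value=p_value)


@lru_cache(maxsize=65536)
def detection_power(
    total_depth: int,
    vaf: float,
    params: PresenceParams = DEFAULT_PARAMS,
) -> float:
    """Probability that a true variant at ``vaf`` yields a PRESENT call.

    P(X >= k*) under Binomial(total_depth, vaf), with k* the smallest alt count
    meeting the PRESENT criteria. Zero when k* exceeds the depth. Note that the
    discreteness of k* makes power only piecewise-monotone in depth: it dips
    slightly wherever k* steps up.
    """
    if not 0 < vaf <= 0.5:
        raise ValueError(f"vaf must be in (0, 0.5], got {vaf}")
    k_star = min_present_alt(total_depth, params)
    if k_star > total_depth:
        return 0.0
    return float(binom.sf(k_star - 1, total_depth, vaf))


class PatientPresence:
    """Per-variant, per-tissue presence calls for one patient.

    Variants PRESENT in blood are flagged germline and excluded from the
    somatic analysis; ``calls`` covers the non-blood tissues only.
    """

    def __init__(
        self,
        patient_id: str,
        variants: Mapping[str, VariantCall],
        calls: Mapping[str, Mapping[Role, PresenceCall]],
        germline: set[str],
        roles: Sequence[Role],
    ) -> None:
        self.patient_id = patient_id
        self.variants = dict(variants)
        self.calls = {k: dict(v) for k, v in calls.items()}
        self.germline = set(germline)
        self.roles = list(roles)

    @property
    def has_recurrent(self) -> bool:
        return Role.RECURRENT in self.roles

    @property
    def somatic_keys(self) -> list[str]:
        keys = [k for k in self.calls if k not in self.germline]
        return sorted(keys, key=lambda k: self.variants[k].sort_key)

    def state(self, key: str, role: Role) -> Presence:
        return self.calls[key][role].state

    def call(self, key: str, role: Role) -> PresenceCall:
        return self.calls[key][role]

    def states_frame(self) -> pd.DataFrame:
        """Somatic presence matrix: rows variant keys, columns tissue roles."""
        rows = {
            k: {role.value: self.calls[k][role].state.value for role in self.roles}
            for k in self.somatic_keys
        }
        frame = pd.DataFrame.from_dict(rows, orient="index")
        frame = frame.reindex(columns=[r.value for r in self.roles])
        frame.index.name = "variant"
        return frame

    def vaf_frame(self) -> pd.DataFrame:
        """Somatic observed-VAF matrix matching states_frame's layout."""
        rows = {
            k: {role.value: self.calls[k][role].vaf for role in self.roles}
            for k in self.somatic_keys
        }
        frame = pd.DataFrame.from_dict(rows, orient="index")
        frame = frame.reindex(columns=[r.value for r in self.roles])
        frame.index.name = "variant"
        return frame

    def to_tsv(self, path: str | Path) -> None:
        self.states_frame().to_csv(path, sep="\t")


def call_patient(
    records: Iterable[VariantCall],
    manifest: PatientManifest,
    params: PresenceParams = DEFAULT_PARAMS,
) -> PatientPresence:
    """Call presence for every variant in every non-blood tissue of a patient."""
    blood = manifest.sample_for(Role.BLOOD)
    tissue_roles = [Role.SVZ, Role.PRIMARY] + (
        [Role.RECURRENT] if manifest.has_recurrent else []
    )
    role_sample = {role: manifest.sample_for(role) for role in tissue_roles}

    variants: dict[str, VariantCall] = {}
    calls: dict[str, dict[Role, PresenceCall]] = {}
    germline: set[str] = set()
    for rec in records:
        for name in [blood] + list(role_sample.values()):
            if name not in rec.counts:
                raise ManifestError(
                    f"{manifest.patient_id}: variant {rec.key} lacks counts for sample {name!r}"
                )
        if rec.key in variants:
            raise ValueError(f"duplicate variant {rec.key}")
        variants[rec.key] = rec
        blood_call = call_presence(rec.alt_count(blood), rec.depth(blood), params)
        if blood_call.state is Presence.PRESENT:
            germline.add(rec.key)
        calls[rec.key] = {
            role: call_presence(rec.alt_count(name), rec.depth(name), params)
            for role, name in role_sample.items()
        }
    return PatientPresence(
        patient_id=manifest.patient_id,
        variants=variants,
        calls=calls,
        germline=germline,
        roles=tissue_roles,
    )
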