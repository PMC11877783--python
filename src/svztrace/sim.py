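"""Branched clonal-evolution simulator for longitudinal GBM sampling designs.

Generates patients with a blood control, a tumor-free SVZ sample carrying an
early-progenitor trunk clone at low cell fraction, and primary/recurrent
tumors dominated by branch clones. Each mutation's cancer-cell fraction (CCF)
in a sample is the summed fraction of the carrying clone's subtree; VAF is the
copy-number-neutral heterozygous conversion 0.5 * purity * CCF; read counts
are binomial at the requested depth with a uniform miscall floor. Ground-truth
sharing categories, the patient-level recurrence pattern, and the generating
clone tree ride along with every dataset, so every downstream stage can be
scored against the generative truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .categorize import MutationCategory, categorize_patient
from .classify import PatientClassification, classify_recurrence_pattern
from .io import (
    PatientManifest,
    Role,
    VariantCall,
    write_manifest,
    write_variant_table,
)
from .presence import PatientPresence, Presence, PresenceCall

_ROLE_ORDER = (Role.BLOOD, Role.SVZ, Role.PRIMARY, Role.RECURRENT)


@dataclass(frozen=True)
class Mutation:
    """Catalog entry: one somatic variant and the branch it arose on."""

    mutation_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None
    driver: bool = False

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class Clone:
    """A clone in the rooted tree; parent_id None means child of germline root."""

    clone_id: str
    parent_id: str | None
    mutation_ids: tuple[str, ...]


@dataclass(frozen=True)
class SampleDef:
    """One sequenced specimen.

    purity: fraction of cells belonging to the mutant lineage (0 for blood).
    clone_fractions: clone_id -> fraction of the mutant lineage assigned to
    that clone (must sum to 1 when purity > 0).
    fixed_depth: draw exactly mean_depth reads instead of Poisson dispersion.
    """

    name: str
    role: Role
    purity: float
    mean_depth: int
    clone_fractions: Mapping[str, float] = field(default_factory=dict)
    fixed_depth: bool = False


@dataclass
class SimulationSpec:
    """Full description of one simulated patient."""

    patient_id: str
    clones: Sequence[Clone]
    mutations: Sequence[Mutation]
    samples: Sequence[SampleDef]
    error_rate: float = 1e-3
    noiseless: bool = False
    seed: int = 0

    def validate(self) -> None:
        clone_ids = [c.clone_id for c in self.clones]
        if len(set(clone_ids)) != len(clone_ids):
            raise ValueError("duplicate clone ids")
        known = set(clone_ids)
        for c in self.clones:
            if c.parent_id is not None and c.parent_id not in known:
                raise ValueError(f"clone {c.clone_id}: unknown parent {c.parent_id}")
        # rooted tree: walking up from every clone must terminate at germline
        parents = {c.clone_id: c.parent_id for c in self.clones}
        for cid in clone_ids:
            seen, cur = set(), cid
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"clone graph cycle through {cur}")
                seen.add(cur)
                cur = parents[cur]
        mut_ids = [m for c in self.clones for m in c.mutation_ids]
        if len(set(mut_ids)) != len(mut_ids):
            raise ValueError("mutation assigned to more than one clone")
        catalog = {m.mutation_id for m in self.mutations}
        keys = [m.key for m in self.mutations]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate variant keys in catalog")
        missing = set(mut_ids) - catalog
        if missing:
            raise ValueError(f"clone mutations missing from catalog: {sorted(missing)}")
        if not 0 <= self.error_rate <= 0.01:
            raise ValueError(f"error_rate must be in [0, 0.01], got {self.error_rate}")
        roles = [s.role for s in self.samples]
        if len(set(roles)) != len(roles):
            raise ValueError("duplicate sample roles")
        for s in self.samples:
            if not 0 <= s.purity <= 1:
                raise ValueError(f"sample {s.name}: purity {s.purity} outside [0,1]")
            if s.role is Role.BLOOD and s.purity != 0:
                raise ValueError("blood sample must have purity 0")
            if s.mean_depth < 1:
                raise ValueError(f"sample {s.name}: mean_depth must be >= 1")
            if s.purity > 0:
                total = sum(s.clone_fractions.values())
                if any(f < 0 for f in s.clone_fractions.values()):
                    raise ValueError(f"sample {s.name}: negative clone fraction")
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"sample {s.name}: clone fractions sum to {total}, expected 1"
                    )
                unknown = set(s.clone_fractions) - known
                if unknown:
                    raise ValueError(f"sample {s.name}: unknown clones {sorted(unknown)}")

    def sample(self, role: Role) -> SampleDef:
        for s in self.samples:
            if s.role is role:
                return s
        raise KeyError(role)

    @property
    def manifest(self) -> PatientManifest:
        entries = {
            s.name: (f"{self.patient_id}.variants.tsv", s.role) for s in self.samples
        }
        return PatientManifest(patient_id=self.patient_id, entries=entries)


class ClonalTree:
    """The generating clone tree, exposed in mutation-relation form.

    mutation_nodes maps variant keys to clone ids; is_ancestor follows
    parent->child edges. Compatible with lineage.tree_concordance.
    """

    def __init__(self, clones: Sequence[Clone], mutations: Sequence[Mutation]) -> None:
        self._parent = {c.clone_id: c.parent_id for c in clones}
        by_id = {m.mutation_id: m for m in mutations}
        self._mutation_nodes = {
            by_id[mid].key: c.clone_id for c in clones for mid in c.mutation_ids
        }

    @property
    def mutation_nodes(self) -> Mapping[str, str]:
        return self._mutation_nodes

    def is_ancestor(self, node_a: str, node_b: str) -> bool:
        if node_a == node_b:
            return False
        cur = self._parent.get(node_b)
        while cur is not None:
            if cur == node_a:
                return True
            cur = self._parent.get(cur)
        return False

    def restricted(self, keys: Iterable[str]) -> "ClonalTree":
        keys = set(keys)
        view = object.__new__(ClonalTree)
        view._parent = dict(self._parent)
        view._mutation_nodes = {
            k: v for k, v in self._mutation_nodes.items() if k in keys
        }
        return view


@dataclass
class PatientDataset:
    """Simulated variant table plus generative ground truth."""

    patient_id: str
    variants: list[VariantCall]
    truth_categories: dict[str, MutationCategory]
    truth_pattern: PatientClassification | None
    tree: ClonalTree
    spec: SimulationSpec


def ccf_to_vaf(ccf: float, purity: float) -> float:
    """Heterozygous, copy-number-neutral CCF -> VAF conversion: 0.5*purity*ccf."""
    if not 0 <= ccf <= 1:
        raise ValueError(f"ccf must be in [0,1], got {ccf}")
    if not 0 <= purity <= 1:
        raise ValueError(f"purity must be in [0,1], got {purity}")
    return 0.5 * purity * ccf


def sample_reads(
    vaf: float,
    depth: int,
    error_rate: float,
    rng: np.random.Generator,
    *,
    noiseless: bool = False,
    fixed_depth: bool = False,
) -> tuple[int, int]:
    """Draw (alt_count, total_depth) for one site in one sample.

    Total depth is Poisson-dispersed around ``depth`` (fixed when requested);
    alt reads are Binomial(total, vaf*(1-e) + (1-vaf)*e/3), i.e. true variant
    reads minus miscalled-away ones plus 1/3 of miscalls from reference bases.
    Noiseless mode returns (round(depth*vaf), depth) exactly.
    """
    if not 0 <= vaf <= 0.5:
        raise ValueError(f"vaf must be in [0, 0.5], got {vaf}")
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    if noiseless:
        return int(round(depth * vaf)), depth
    total = depth if fixed_depth else max(1, int(rng.poisson(depth)))
    p = vaf * (1.0 - error_rate) + (1.0 - vaf) * error_rate / 3.0
    alt = int(rng.binomial(total, p))
    return alt, total


def _subtree_fractions(spec: SimulationSpec) -> dict[str, set[str]]:
    children: dict[str | None, list[str]] = {}
    for c in spec.clones:
        children.setdefault(c.parent_id, []).append(c.clone_id)

    def collect(cid: str) -> set[str]:
        out = {cid}
        for kid in children.get(cid, []):
            out |= collect(kid)
        return out

    return {c.clone_id: collect(c.clone_id) for c in spec.clones}


def mutation_ccf(spec: SimulationSpec, sample: SampleDef, mutation_id: str) -> float:
    """CCF of a mutation: summed fractions of the carrying clone's subtree."""
    carrier = None
    for c in spec.clones:
        if mutation_id in c.mutation_ids:
            carrier = c.clone_id
            break
    if carrier is None:
        raise ValueError(f"mutation {mutation_id} not assigned to any clone")
    subtree = _subtree_fractions(spec)[carrier]
    ccf = sum(sample.clone_fractions.get(cid, 0.0) for cid in subtree)
    return min(max(ccf, 0.0), 1.0)  # guard float round-off in fraction sums


def _truth_presence(spec: SimulationSpec) -> PatientPresence:
    """Noise-free presence object straight from clone membership."""
    roles = [s.role for s in spec.samples if s.role is not Role.BLOOD]
    roles = [r for r in _ROLE_ORDER if r in roles]
    variants: dict[str, VariantCall] = {}
    calls: dict[str, dict[Role, PresenceCall]] = {}
    for m in spec.mutations:
        counts = {s.name: (s.mean_depth, 0) for s in spec.samples}
        variants[m.key] = VariantCall(
            chrom=m.chrom, pos=m.pos, ref=m.ref, alt=m.alt, gene=m.gene, counts=counts
        )
        per_role: dict[Role, PresenceCall] = {}
        for s in spec.samples:
            if s.role is Role.BLOOD:
                continue
            vaf = ccf_to_vaf(mutation_ccf(spec, s, m.mutation_id), s.purity)
            state = Presence.PRESENT if vaf > 0 else Presence.ABSENT
            per_role[s.role] = PresenceCall(state=state, vaf=vaf, p_value=0.0 if vaf > 0 else 1.0)
        calls[m.key] = per_role
    return PatientPresence(
        patient_id=spec.patient_id,
        variants=variants,
        calls=calls,
        germline=set(),
        roles=roles,
    )


def simulate_patient(spec: SimulationSpec) -> PatientDataset:
    """Simulate one patient's variant table with truth labels.

    Deterministic given spec.seed; in noiseless mode the read counts are exact
    expectations (rounded) at exactly mean_depth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    variants: list[VariantCall] = []
    for m in spec.mutations:
        counts: dict[str, tuple[int, int]] = {}
        for s in spec.samples:
            vaf = ccf_to_vaf(mutation_ccf(spec, s, m.mutation_id), s.purity)
            alt, total = sample_reads(
                vaf,
                s.mean_depth,
                spec.error_rate,
                rng,
                noiseless=spec.noiseless,
                fixed_depth=s.fixed_depth,
            )
            counts[s.name] = (total, alt)
        variants.append(
            VariantCall(chrom=m.chrom, pos=m.pos, ref=m.ref, alt=m.alt, gene=m.gene, counts=counts)
        )

    truth_presence = _truth_presence(spec)
    truth_table = categorize_patient(truth_presence)
    truth_categories = {
        key: MutationCategory(row["category"]) for key, row in truth_table.iterrows()
    }
    truth_pattern = (
        classify_recurrence_pattern(truth_presence, truth_table)
        if truth_presence.has_recurrent
        else None
    )
    return PatientDataset(
        patient_id=spec.patient_id,
        variants=variants,
        truth_categories=truth_categories,
        truth_pattern=truth_pattern,
        tree=ClonalTree(spec.clones, spec.mutations),
        spec=spec,
    )


def write_patient_dataset(dataset: PatientDataset, outdir: str | Path) -> Path:
    """Write variants TSV, truth sidecar TSV and manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pid = dataset.patient_id
    write_variant_table(dataset.variants, outdir / f"{pid}.variants.tsv")
    truth_lines = ["# truth labels", "record\tkey\tvalue"]
    for key in sorted(dataset.truth_categories):
        truth_lines.append(f"category\t{key}\t{dataset.truth_categories[key].value}")
    if dataset.truth_pattern is not None:
        truth_lines.append(f"pattern\t{pid}\t{dataset.truth_pattern.pattern.value}")
    (outdir / f"{pid}.truth.tsv").write_text("\n".join(truth_lines) + "\n")
    manifest_path = outdir / f"{pid}.manifest.txt"
    write_manifest(dataset.spec.manifest, manifest_path)
    return manifest_path


# ---------------------------------------------------------------------------
# presets and random scenarios


def gbm244_preset(seed: int = 0, noiseless: bool = False) -> SimulationSpec:
    """Three-clone patient emulating the cohort's WGS worked example.

    Trunk clone with a TERT-promoter-like and an EGFR-like driver shared by
    SVZ (low cell fraction) and both tumors; a primary-restricted branch and a
    recurrent-restricted sibling branch carrying five private passengers each.
    Depths emulate the panel's median 1063x; purities are documented defaults.
    """
    mutations = [
        Mutation("TERT_promoter", "chr5", 1295228, "G", "A", gene="TERT", driver=True),
        Mutation("EGFR_driver", "chr7", 55191822, "T", "G", gene="EGFR", driver=True),
        Mutation("PP1", "chr1", 41976870, "C", "T"),
        Mutation("PP2", "chr2", 178531000, "G", "A"),
        Mutation("PP3", "chr3", 121487200, "A", "G"),
        Mutation("PP4", "chr9", 95849100, "C", "A"),
        Mutation("PP5", "chr12", 49018500, "T", "C"),
        Mutation("RP1", "chr4", 106155200, "G", "T"),
        Mutation("RP2", "chr6", 152129300, "C", "T"),
        Mutation("RP3", "chr11", 65861400, "A", "C"),
        Mutation("RP4", "chr15", 66702500, "G", "A"),
        Mutation("RP5", "chr19", 11096800, "T", "A"),
    ]
    clones = [
        Clone("trunk", None, ("TERT_promoter", "EGFR_driver")),
        Clone("primary_branch", "trunk", ("PP1", "PP2", "PP3", "PP4", "PP5")),
        Clone("recurrent_branch", "trunk", ("RP1", "RP2", "RP3", "RP4", "RP5")),
    ]
    samples = [
        SampleDef("blood", Role.BLOOD, 0.0, 1063),
        SampleDef("svz", Role.SVZ, 0.05, 1063, {"trunk": 1.0}),
        SampleDef("primary", Role.PRIMARY, 0.8, 1063, {"trunk": 0.1, "primary_branch": 0.9}),
        SampleDef("recurrent", Role.RECURRENT, 0.8, 1063, {"trunk": 0.1, "recurrent_branch": 0.9}),
    ]
    return SimulationSpec(
        patient_id="GBM-244-SIM",
        clones=clones,
        mutations=mutations,
        samples=samples,
        error_rate=1e-3,
        noiseless=noiseless,
        seed=seed,
    )


_BASES = np.array(list("ACGT"))


def _random_catalog(rng: np.random.Generator, n: int, start_index: int = 0) -> list[Mutation]:
    chroms = rng.integers(1, 23, size=n)
    positions = rng.choice(180_000_000, size=n, replace=False) + 10_000
    muts = []
    for i in range(n):
        ref, alt = rng.choice(4, size=2, replace=False)
        muts.append(
            Mutation(
                mutation_id=f"M{start_index + i}",
                chrom=f"chr{chroms[i]}",
                pos=int(positions[i]),
                ref=str(_BASES[ref]),
                alt=str(_BASES[alt]),
            )
        )
    return muts


def random_patient_spec(
    seed: int,
    pattern: str = "svz_associated",
    *,
    depth: int = 1063,
    noiseless: bool = False,
    error_rate: float = 1e-3,
    muts_per_clone: tuple[int, int] = (3, 6),
    patient_id: str | None = None,
) -> SimulationSpec:
    """Random branched scenario with a known generative recurrence pattern.

    ``pattern`` is "svz_associated" (trunk + two sibling branches; the
    recurrence descends from the early progenitor, primary-private mutations
    extinct) or "primary_associated" (an extra inter-tumor clone between trunk
    and both branches, genetically linking the tumors). Defaults encode the
    study conditions: SVZ mutant fraction U(0.02, 0.10), tumor purity
    U(0.6, 0.9), trunk residual fraction in tumors U(0.05, 0.25), panel depth
    1063x, miscall floor 1e-3.
    """
    if pattern not in ("svz_associated", "primary_associated"):
        raise ValueError(f"unknown pattern {pattern!r}")
    rng = np.random.default_rng(seed)
    lo, hi = muts_per_clone
    inter = pattern == "primary_associated"
    n_clones = 4 if inter else 3
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(n_clones)]
    catalog = _random_catalog(rng, sum(sizes))
    # first trunk mutation doubles as the TERT-promoter-like trunk driver
    catalog[0] = replace(catalog[0], gene="TERT", driver=True)

    ids = [m.mutation_id for m in catalog]
    bounds = np.cumsum([0] + sizes)
    groups = [tuple(ids[bounds[i] : bounds[i + 1]]) for i in range(n_clones)]

    clones = [Clone("trunk", None, groups[0])]
    branch_parent = "trunk"
    if inter:
        clones.append(Clone("inter", "trunk", groups[1]))
        branch_parent = "inter"
    clones.append(Clone("primary_branch", branch_parent, groups[-2]))
    clones.append(Clone("recurrent_branch", branch_parent, groups[-1]))

    svz_fraction = float(rng.uniform(0.02, 0.10))
    purity_p = float(rng.uniform(0.6, 0.9))
    purity_r = float(rng.uniform(0.6, 0.9))
    trunk_p = float(rng.uniform(0.05, 0.25))
    trunk_r = float(rng.uniform(0.05, 0.25))
    if inter:
        inter_p = float(rng.uniform(0.1, 0.3))
        inter_r = float(rng.uniform(0.1, 0.3))
        fr_p = {"trunk": trunk_p, "inter": inter_p, "primary_branch": 1 - trunk_p - inter_p}
        fr_r = {"trunk": trunk_r, "inter": inter_r, "recurrent_branch": 1 - trunk_r - inter_r}
    else:
        fr_p = {"trunk": trunk_p, "primary_branch": 1 - trunk_p}
        fr_r = {"trunk": trunk_r, "recurrent_branch": 1 - trunk_r}

    samples = [
        SampleDef("blood", Role.BLOOD, 0.0, depth),
        SampleDef("svz", Role.SVZ, svz_fraction, depth, {"trunk": 1.0}),
        SampleDef("primary", Role.PRIMARY, purity_p, depth, fr_p),
        SampleDef("recurrent", Role.RECURRENT, purity_r, depth, fr_r),
    ]
    return SimulationSpec(
        patient_id=patient_id or f"SIM-{pattern}-{seed}",
        clones=clones,
        mutations=catalog,
        samples=samples,
        error_rate=error_rate,
        noiseless=noiseless,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# packaged cohort fixture


@dataclass
class CohortPatient:
    """One fixture patient: variant table plus an in-memory manifest."""

    patient_id: str
    variants: list[VariantCall]
    manifest: PatientManifest


_FIXTURE_PATIENTS = (
    "GBM-1932",
    "GBM-1492",
    "GBM-1250",
    "GBM-1938",
    "GBM-2488",
    "GBM-2441",
    "GBM-260",
    "GBM-244",
    "GBM-2455",
    "GBM-2437",
)


def cohort_fixture() -> list[CohortPatient]:
    """The packaged 10-patient cohort of presence-profile variant tables.

    A version-controlled transcription of the cohort's per-patient sharing
    relations: every patient shares a TERT-promoter variant across
    SVZ/primary/recurrent; two patients additionally carry inter-tumor-shared
    variants absent from the SVZ; six carry primary-private variants extinct
    in the recurrence plus recurrent-private variants; two carry too little
    informative coverage for lineage determination (non-trunk calls
    indeterminate in a deciding tissue). Depths and alt counts are synthetic
    round numbers chosen to make those relations unambiguous at default
    presence thresholds; the source study reports the relations only
    qualitatively.
    """
    from .io import read_variant_table

    base = resources.files("svztrace") / "fixtures" / "cohort"
    patients = []
    for pid in _FIXTURE_PATIENTS:
        path = base / f"{pid}.tsv"
        with resources.as_file(path) as fp:
            variants = read_variant_table(fp)
            entries = {
                "blood": (str(fp), Role.BLOOD),
                "svz": (str(fp), Role.SVZ),
                "primary": (str(fp), Role.PRIMARY),
                "recurrent": (str(fp), Role.RECURRENT),
            }
        patients.append(
            CohortPatient(
                patient_id=pid,
                variants=variants,
                manifest=PatientManifest(patient_id=pid, entries=entries),
            )
        )
    return patients
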