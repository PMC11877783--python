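"""Readers and writers for variant tables, a minimal VCF dialect, and patient manifests.

The native exchange format is a tab-separated variant table: columns
``chrom  pos  ref  alt  gene`` followed by one ``<sample>_depth`` /
``<sample>_alt`` column pair per sequenced sample. ``#``-prefixed lines are
comments. Coordinates are 1-based VCF convention; indels are left-anchored.

Variant identity is allele-level: two different alt alleles at one locus are
two distinct variants (a gene can carry a primary-private and a distinct
recurrent-private mutation simultaneously).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd


class Role(str, Enum):
    """Tissue role of a sequenced sample within one patient."""

    BLOOD = "BLOOD"
    SVZ = "SVZ"
    PRIMARY = "PRIMARY"
    RECURRENT = "RECURRENT"


class VariantTableError(ValueError):
    """Malformed variant table or VCF content."""


class ManifestError(ValueError):
    """Malformed or inconsistent patient manifest."""


_BASE_COLUMNS = ("chrom", "pos", "ref", "alt", "gene")
_ALLELE_RE = re.compile(r"^[ACGTNacgtn]+$")


def chrom_sort_key(chrom: str) -> tuple:
    """Natural chromosome ordering: numeric first, then named (X, Y, MT...)."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    try:
        return (0, int(c), "")
    except ValueError:
        return (1, 0, c)


@dataclass
class VariantCall:
    """One somatic variant with per-sample read support.

    ``counts`` maps sample name -> (total_depth, alt_count).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantTableError(f"pos must be >= 1, got {self.pos}")
        for allele, label in ((self.ref, "ref"), (self.alt, "alt")):
            if not allele or not _ALLELE_RE.match(allele):
                raise VariantTableError(f"invalid {label} allele {allele!r}")
        for sample, (depth, alt) in self.counts.items():
            if not (isinstance(depth, int) and isinstance(alt, int)):
                raise VariantTableError(
                    f"{self.key} sample {sample}: counts must be integers"
                )
            if not 0 <= alt <= depth:
                raise VariantTableError(
                    f"{self.key} sample {sample}: alt_count {alt} outside [0, depth={depth}]"
                )

    @property
    def key(self) -> str:
        """Allele-level identity key."""
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def sort_key(self) -> tuple:
        return (chrom_sort_key(self.chrom), self.pos, self.ref, self.alt)

    def depth(self, sample: str) -> int:
        return self.counts[sample][0]

    def alt_count(self, sample: str) -> int:
        return self.counts[sample][1]

    def vaf(self, sample: str) -> float:
        depth, alt = self.counts[sample]
        return alt / depth if depth else 0.0


@dataclass(frozen=True)
class PatientManifest:
    """Maps sample names to (file path, tissue role) for one patient.

    Exactly one BLOOD, SVZ and PRIMARY entry; zero or one RECURRENT.
    """

    patient_id: str
    entries: Mapping[str, tuple[str, Role]]

    def __post_init__(self) -> None:
        roles = [role for _, role in self.entries.values()]
        if len(set(roles)) != len(roles):
            raise ManifestError(f"{self.patient_id}: duplicate tissue roles")
        for required in (Role.BLOOD, Role.SVZ, Role.PRIMARY):
            if required not in roles:
                raise ManifestError(f"{self.patient_id}: missing {required.value} sample")

    def role_of(self, sample: str) -> Role:
        try:
            return self.entries[sample][1]
        except KeyError:
            raise ManifestError(
                f"{self.patient_id}: sample {sample!r} not in manifest"
            ) from None

    def sample_for(self, role: Role) -> str | None:
        for name, (_, r) in self.entries.items():
            if r == role:
                return name
        return None

    def path_for(self, role: Role) -> str | None:
        for name, (path, r) in self.entries.items():
            if r == role:
                return path
        return None

    @property
    def has_recurrent(self) -> bool:
        return self.sample_for(Role.RECURRENT) is not None

    @property
    def sample_names(self) -> list[str]:
        return list(self.entries)


def read_manifest(path: str | Path) -> PatientManifest:
    """Parse the flat key-value manifest format.

    Lines: ``patient<TAB><id>`` once, then ``sample<TAB><name><TAB><role><TAB><path>``
    per sample; ``#`` comments and blank lines ignored. Relative paths are
    resolved against the manifest's directory.
    """
    path = Path(path)
    patient_id: str | None = None
    entries: dict[str, tuple[str, Role]] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "patient" and len(fields) == 2:
            patient_id = fields[1]
        elif fields[0] == "sample" and len(fields) == 4:
            name, role_str, sample_path = fields[1], fields[2], fields[3]
            try:
                role = Role(role_str)
            except ValueError:
                raise ManifestError(f"{path}:{lineno}: unknown role {role_str!r}") from None
            if name in entries:
                raise ManifestError(f"{path}:{lineno}: duplicate sample {name!r}")
            resolved = sample_path if Path(sample_path).is_absolute() else str(path.parent / sample_path)
            entries[name] = (resolved, role)
        else:
            raise ManifestError(f"{path}:{lineno}: unparseable line {raw!r}")
    if patient_id is None:
        raise ManifestError(f"{path}: missing 'patient' line")
    return PatientManifest(patient_id=patient_id, entries=entries)


def write_manifest(manifest: PatientManifest, path: str | Path) -> None:
    lines = [f"patient\t{manifest.patient_id}"]
    for name, (sample_path, role) in manifest.entries.items():
        lines.append(f"sample\t{name}\t{role.value}\t{sample_path}")
    Path(path).write_text("\n".join(lines) + "\n")


def _sample_names_from_columns(columns: Sequence[str]) -> list[str]:
    missing = [c for c in _BASE_COLUMNS if c not in columns]
    if missing:
        raise VariantTableError(f"missing required columns: {missing}")
    names: list[str] = []
    for col in columns:
        if col.endswith("_depth"):
            name = col[: -len("_depth")]
            if f"{name}_alt" not in columns:
                raise VariantTableError(f"column {col} has no matching {name}_alt")
            names.append(name)
        elif col.endswith("_alt"):
            name = col[: -len("_alt")]
            if f"{name}_depth" not in columns:
                raise VariantTableError(f"column {col} has no matching {name}_depth")
    if not names:
        raise VariantTableError("no <sample>_depth/<sample>_alt column pairs found")
    return names


def read_variant_table(path: str | Path) -> list[VariantCall]:
    """Read a TSV variant table; malformed rows are rejected with row numbers."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if frame.empty and not any(c.endswith("_depth") for c in frame.columns):
        # a header-only table written from an empty record set has no samples
        missing = [c for c in _BASE_COLUMNS if c not in frame.columns]
        if missing:
            raise VariantTableError(f"missing required columns: {missing}")
        return []
    samples = _sample_names_from_columns(list(frame.columns))
    records: list[VariantCall] = []
    errors: list[str] = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        row_d = dict(zip(frame.columns, row))
        try:
            counts: dict[str, tuple[int, int]] = {}
            for s in samples:
                counts[s] = (int(row_d[f"{s}_depth"]), int(row_d[f"{s}_alt"]))
            records.append(
                VariantCall(
                    chrom=row_d["chrom"],
                    pos=int(row_d["pos"]),
                    ref=row_d["ref"],
                    alt=row_d["alt"],
                    gene=row_d["gene"] or None,
                    counts=counts,
                )
            )
        except (ValueError, VariantTableError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise VariantTableError(f"{path}: " + "; ".join(errors))
    return records


def write_variant_table(records: Iterable[VariantCall], path: str | Path) -> None:
    """Write records as TSV in canonical order (chrom, pos, ref, alt)."""
    records = sorted(records, key=lambda r: r.sort_key)
    samples: list[str] = []
    for rec in records:
        for s in rec.counts:
            if s not in samples:
                samples.append(s)
    columns = list(_BASE_COLUMNS) + [f"{s}_{k}" for s in samples for k in ("depth", "alt")]
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "chrom": rec.chrom,
            "pos": rec.pos,
            "ref": rec.ref,
            "alt": rec.alt,
            "gene": rec.gene or "",
        }
        for s in samples:
            depth, alt = rec.counts.get(s, (0, 0))
            row[f"{s}_depth"] = depth
            row[f"{s}_alt"] = alt
        rows.append(row)
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, sep="\t", index=False)


def read_vcf_subset(
    path: str | Path,
    manifest: PatientManifest,
    keep_nonpass: bool = False,
) -> list[VariantCall]:
    """Read a VCF 4.x subset into VariantCall records.

    Only FILTER=PASS records are retained unless ``keep_nonpass``; multi-allelic
    records are split one VariantCall per alt allele; per-sample depth is the
    sum of that record's AD entries. Gene labels are taken from INFO/GENE when
    present.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    for name in manifest.sample_names:
        if name not in vcf_samples:
            raise ManifestError(
                f"{manifest.patient_id}: manifest sample {name!r} not in VCF samples {vcf_samples}"
            )
    sample_idx = {name: vcf_samples.index(name) for name in manifest.sample_names}
    records: list[VariantCall] = []
    for variant in vcf:
        if variant.FILTER is not None and not keep_nonpass:
            continue  # cyvcf2 reports PASS as None
        ad = variant.format("AD")
        if ad is None:
            raise VariantTableError(
                f"{path}: record {variant.CHROM}:{variant.POS} lacks FORMAT/AD"
            )
        gene = variant.INFO.get("GENE")
        for j, alt in enumerate(variant.ALT):
            counts: dict[str, tuple[int, int]] = {}
            for name, idx in sample_idx.items():
                row = [int(x) for x in ad[idx] if int(x) >= 0]
                total = sum(row)
                alt_count = int(ad[idx][j + 1]) if ad[idx][j + 1] >= 0 else 0
                counts[name] = (total, alt_count)
            records.append(
                VariantCall(
                    chrom=variant.CHROM,
                    pos=variant.POS,
                    ref=variant.REF,
                    alt=alt,
                    gene=gene,
                    counts=counts,
                )
            )
    return records


def write_vcf(records: Iterable[VariantCall], path: str | Path) -> None:
    """Emit records as a minimal single- or multi-sample VCF 4.2 with AD counts."""
    records = sorted(records, key=lambda r: r.sort_key)
    samples: list[str] = []
    for rec in records:
        for s in rec.counts:
            if s not in samples:
                samples.append(s)
    contigs: list[str] = []
    for rec in records:
        if rec.chrom not in contigs:
            contigs.append(rec.chrom)
    lines = [
        "##fileformat=VCFv4.2",
        *[f"##contig=<ID={c}>" for c in sorted(contigs, key=chrom_sort_key)],
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol annotation">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for rec in records:
        info = f"GENE={rec.gene}" if rec.gene else "."
        fields = [
            rec.chrom,
            str(rec.pos),
            ".",
            rec.ref,
            rec.alt,
            ".",
            "PASS",
            info,
            "GT:AD",
        ]
        for s in samples:
            depth, alt = rec.counts.get(s, (0, 0))
            fields.append(f"./.:{depth - alt},{alt}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")
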