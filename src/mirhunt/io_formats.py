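"""Sequence, structure, config and report I/O.

Reads FASTA in the miRBase mature dialect (``>spe-miR156a-5p ...``) and the
dbEST dialect; writes dot-bracket structure files, Newick trees and TSV
screening reports.  All public coordinates are 1-based inclusive; internal
coordinates everywhere else in the package are 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO


class MirhuntError(Exception):
    """Base class for package errors."""


class ValidationError(MirhuntError):
    """Invalid input data or configuration."""


RNA_ALPHABET = set("ACGUN")
DNA_ALPHABET = set("ACGTN")

_COMPLEMENT_RNA = str.maketrans("ACGUN", "UGCAN")
_COMPLEMENT_DNA = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(residues: str) -> str:
    """Reverse complement for RNA or DNA residue strings (N maps to N)."""
    table = _COMPLEMENT_DNA if "T" in residues else _COMPLEMENT_RNA
    return residues.translate(table)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence in canonical uppercase form."""

    id: str
    description: str
    residues: str
    moltype: str = "RNA"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        alphabet = RNA_ALPHABET if self.moltype == "RNA" else DNA_ALPHABET
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in alphabet:
                raise ValidationError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


def normalize_residues(raw: str, moltype: str) -> str:
    """Uppercase and convert the T/U alphabet to the requested molecule type.

    Idempotent: normalizing an already-normalized string is a no-op.
    """
    s = raw.upper()
    if moltype == "RNA":
        return s.replace("T", "U")
    if moltype == "DNA":
        return s.replace("U", "T")
    raise ValidationError(f"unknown moltype {moltype!r}")


def read_fasta(path: str | Path, moltype: str = "RNA") -> list[SequenceRecord]:
    """Read a FASTA file into validated, normalized records.

    Raises :class:`ValidationError` on an empty file, a duplicated id
    (named in the message) or an illegal residue (with its position).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = normalize_residues(str(rec.seq), moltype)
        records.append(
            SequenceRecord(
                id=rec.id,
                description=rec.description[len(rec.id):].strip(),
                residues=residues,
                moltype=moltype,
            )
        )
    if not records:
        raise ValidationError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


_FAMILY_RE = re.compile(
    r"^(?:[A-Za-z]{2,5}-)?(?P<stem>miR|MIR|let|lin)-?(?P<num>\d+)",
)


def family_of(mirna_id: str) -> str:
    """miRNA family from a miRBase-style id.

    Strips the species prefix and any paralog letter / arm suffix:
    ``bra-miR156h-5p`` -> ``miR156``; ``ath-MIR5021a`` -> ``miR5021``.
    Ids that do not look like miRBase names are returned unchanged.
    """
    m = _FAMILY_RE.match(mirna_id)
    if not m:
        return mirna_id
    stem = m.group("stem")
    if stem.lower() in ("mir",):
        stem = "miR"
    return f"{stem}{m.group('num')}"


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline.

    Defaults encode the screening regime for conserved plant pre-miRNAs:
    homology within 4 substitutions, MFE at or below -15 kcal/mol, MFEI at
    or below -0.7, GC between 20 and 70 %, precursors 50-350 nt, folding at
    37 degC with interior/bulge loops capped at 30 nt.
    """

    max_mismatches: int = 4
    mfe_cutoff: float = -15.0
    mfei_cutoff: float = -0.7
    mfei_high_confidence: float = -0.85
    gc_min: float = 20.0
    gc_max: float = 70.0
    precursor_min: int = 50
    precursor_max: int = 350
    fold_temperature: float = 37.0  # informational; the energy tables are 37C
    max_loop_size: int = 30
    duplex_max_mismatches: int = 6
    max_mature_break: int = 3
    min_orf_aa: int = 80
    identity_threshold: float = 0.95
    target_max_expectation: float = 3.0
    target_max_gaps: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.mfe_cutoff < 0:
            raise ValidationError("mfe_cutoff must be negative")
        if not self.gc_min < self.gc_max:
            raise ValidationError("gc_min must be below gc_max")
        if self.precursor_min < 40:
            raise ValidationError("precursor_min must be at least 40 nt")
        if self.precursor_max < self.precursor_min:
            raise ValidationError("precursor_max below precursor_min")
        if self.max_mismatches < 0 or self.duplex_max_mismatches < 0:
            raise ValidationError("mismatch budgets must be non-negative")
        for name in ("mfe_cutoff", "mfei_cutoff", "gc_min", "gc_max"):
            value = getattr(self, name)
            if value != value or value in (float("inf"), float("-inf")):
                raise ValidationError(f"{name} must be finite")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config {path}: expected a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"config {path}: unknown keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# --- dot-bracket structure files -------------------------------------------

def write_dotbracket(entries: Sequence[tuple[str, str, str, float]], path: str | Path) -> None:
    """Write ``(id, sequence, dotbracket, mfe)`` entries, MFOLD-like:
    id line, sequence line, structure line with a trailing ``(energy)``."""
    with open(path, "w") as fh:
        for name, seq, db, mfe in entries:
            fh.write(f">{name}\n{seq}\n{db} ({mfe:.1f})\n")


def read_dotbracket(path: str | Path) -> list[tuple[str, str, str, float]]:
    entries = []
    lines = [ln.rstrip("\n") for ln in open(path) if ln.strip()]
    for i in range(0, len(lines), 3):
        name = lines[i].lstrip(">")
        seq = lines[i + 1]
        struct_line = lines[i + 2]
        db, _, energy = struct_line.rpartition(" (")
        entries.append((name, seq, db, float(energy.rstrip(")"))))
    return entries


# --- screening report -------------------------------------------------------

REPORT_COLUMNS = [
    "candidate_id", "est_id", "family", "strand", "mature_start", "mature_end",
    "arm", "precursor_length", "mfe", "amfe", "mfei", "gc_percent",
    "starts_with_u", "c_arm", "c_mature_contiguity", "c_duplex_mismatches",
    "c_mfe", "c_mfei", "c_gc", "c_length", "high_confidence", "verdict",
    "repeats",
]

CRITERIA_ORDER = [
    "arm", "mature_contiguity", "duplex_mismatches", "mfe", "mfei", "gc", "length",
]


def _fmt(value) -> str:
    if isinstance(value, bool):
        return "PASS" if value else "FAIL"
    if isinstance(value, float):
        return f"{value:.3f}"
    return str(value)


def write_report(reports: Iterable, path: str | Path) -> None:
    """Write ScreenReports as a deterministic TSV (header always present)."""
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for r in reports:
            repeats = ";".join(
                f"({run.unit})n@{run.begin}-{run.end}x{run.copies:.1f}"
                for run in r.repeat_annotations
            )
            row = [
                r.candidate_id, r.est_id, r.family, r.strand,
                str(r.mature_start), str(r.mature_end), r.arm,
                str(r.length), f"{r.mfe:.1f}", f"{r.amfe:.2f}", f"{r.mfei:.3f}",
                f"{r.gc_percent:.2f}",
                "yes" if r.starts_with_u else "no",
            ]
            row += [_fmt(r.criteria[c]) for c in CRITERIA_ORDER]
            row += [
                "yes" if r.high_confidence else "no",
                "PASS" if r.verdict else "FAIL",
                repeats,
            ]
            fh.write("\t".join(row) + "\n")
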