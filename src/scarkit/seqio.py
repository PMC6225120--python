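"""Reading and writing of all external formats.

FASTA (aligned or unaligned), the two-column sample sheet mapping sequence
IDs to taxon labels, the primer-panel TSV (taxon, primer name, sequence,
product size), and TSV/JSON result reports.

Normalization rules applied on read:

* sequences are upper-cased,
* ``U`` (RNA) becomes ``T``,
* ``.`` is accepted as a gap synonym and becomes ``-``.

Characters outside IUPAC nucleotide codes plus ``-`` are a format error.
Duplicate record IDs are an error, not silently suffixed: voucher samples
must stay traceable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import (
    AlignmentShapeError,
    DuplicateIdError,
    EmptyPanelError,
    FormatError,
    PairingError,
    PartitionError,
)

IUPAC_BASES = frozenset("ACGT")
IUPAC_AMBIGUITY = frozenset("RYSWKMBDHVN")
GAP = "-"
ALPHABET = IUPAC_BASES | IUPAC_AMBIGUITY | {GAP}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly ambiguous) DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_seq(raw: str, *, context: str = "sequence") -> str:
    """Uppercase, map U->T and .->-, and validate the alphabet.

    Raises FormatError naming the first offending position (1-based).
    """
    seq = raw.upper().replace("U", "T").replace(".", GAP)
    for pos, ch in enumerate(seq, start=1):
        if ch not in ALPHABET:
            raise FormatError(
                f"illegal character {ch!r} at position {pos} in {context}"
            )
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """One labeled DNA sequence (aligned rows may contain '-')."""

    id: str
    seq: str
    species: str | None = None

    def __post_init__(self):
        if not self.id:
            raise FormatError("record id must be nonempty")
        if not self.seq:
            raise FormatError(f"record {self.id!r}: sequence must be nonempty")

    @property
    def ungapped(self) -> str:
        return self.seq.replace(GAP, "")


@dataclass(frozen=True)
class SpeciesPartition:
    """Mapping of sample IDs to taxon labels, taxa kept in declaration order."""

    assignment: Mapping[str, str]
    taxa: tuple[str, ...]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "SpeciesPartition":
        assignment: dict[str, str] = {}
        taxa: list[str] = []
        for sample_id, taxon in pairs:
            if sample_id in assignment:
                raise DuplicateIdError(f"duplicate sample id {sample_id!r} in sheet")
            assignment[sample_id] = taxon
            if taxon not in taxa:
                taxa.append(taxon)
        return cls(assignment=assignment, taxa=tuple(taxa))

    def samples_of(self, taxon: str) -> tuple[str, ...]:
        return tuple(s for s, t in self.assignment.items() if t == taxon)

    def validate_against(self, records: Sequence[SequenceRecord]) -> None:
        ids = {r.id for r in records}
        missing = [s for s in self.assignment if s not in ids]
        if missing:
            raise PartitionError(
                f"sample sheet ids absent from sequences: {sorted(missing)}"
            )
        for taxon in self.taxa:
            if not self.samples_of(taxon):
                raise PartitionError(f"taxon {taxon!r} has no samples")

    def restrict(self, exclude_taxa: Iterable[str]) -> "SpeciesPartition":
        drop = set(exclude_taxa)
        keep = {s: t for s, t in self.assignment.items() if t not in drop}
        return SpeciesPartition(
            assignment=keep, taxa=tuple(t for t in self.taxa if t not in drop)
        )


@dataclass(frozen=True)
class ScarPrimerPair:
    """A species-specific forward/reverse primer pair.

    Both primers are stored 5'->3' as synthesized; the reverse primer binds
    the plus strand as its reverse complement.
    """

    taxon: str
    forward: str
    reverse: str
    expected_size: int | None = None

    def __post_init__(self):
        for name, primer in (("forward", self.forward), ("reverse", self.reverse)):
            if len(primer) < 10:
                raise FormatError(
                    f"{self.taxon} {name} primer shorter than 10 nt: {primer!r}"
                )
            bad = set(primer) - IUPAC_BASES
            if bad:
                raise FormatError(
                    f"{self.taxon} {name} primer contains non-ACGT base(s) "
                    f"{sorted(bad)}: {primer!r}"
                )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, aligned: bool = False) -> list[SequenceRecord]:
    """Read a multi-FASTA into SequenceRecords, in file order.

    With ``aligned=True`` all sequences must have equal length (gap columns
    included); unequal lengths raise AlignmentShapeError.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = normalize_seq(str(rec.seq), context=f"record {rec.id!r}")
        records.append(SequenceRecord(id=rec.id, seq=seq))
    if aligned and records:
        lengths = {len(r.seq) for r in records}
        if len(lengths) > 1:
            raise AlignmentShapeError(
                f"aligned FASTA rows differ in length: {sorted(lengths)}"
            )
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# Sample sheet


def read_sample_sheet(path: str | Path) -> SpeciesPartition:
    """Two-column TSV (sample id, taxon label); '#' lines are comments."""
    pairs: list[tuple[str, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(
                f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
            )
        pairs.append((parts[0].strip(), parts[1].strip()))
    return SpeciesPartition.from_pairs(pairs)


def write_sample_sheet(partition: SpeciesPartition, path: str | Path) -> None:
    lines = [f"{s}\t{t}" for s, t in partition.assignment.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Primer panel TSV


def read_primer_table(path: str | Path) -> list[ScarPrimerPair]:
    """Parse a primer panel TSV into ScarPrimerPairs.

    Columns: taxon, primer name, sequence, product size (blank allowed on
    continuation rows). Primer names carry an F/R suffix marking forward and
    reverse. Rows are paired per taxon; a taxon with only one primer is a
    pairing error.
    """
    rows: list[tuple[str, str, str, int | None]] = []
    header_skipped = False
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) < 3:
            raise FormatError(
                f"{path}:{lineno}: expected >=3 tab-separated columns"
            )
        taxon, name, seq = parts[0], parts[1], parts[2]
        size_txt = parts[3] if len(parts) > 3 else ""
        if not header_skipped and not _looks_like_dna(seq):
            header_skipped = True  # tolerate a single header row
            continue
        size: int | None = None
        if size_txt:
            try:
                size = int(size_txt)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: product size {size_txt!r} is not an integer"
                ) from None
        rows.append((taxon, name, normalize_seq(seq, context=f"primer {name!r}"), size))

    if not rows:
        raise EmptyPanelError(f"primer table {path} contains no primer rows")

    # Continuation rows (Table-3 style) leave taxon blank: inherit previous.
    filled: list[tuple[str, str, str, int | None]] = []
    last_taxon = None
    for taxon, name, seq, size in rows:
        if not taxon:
            if last_taxon is None:
                raise FormatError(f"{path}: first primer row lacks a taxon")
            taxon = last_taxon
        last_taxon = taxon
        filled.append((taxon, name, seq, size))

    pairs: list[ScarPrimerPair] = []
    by_taxon: dict[str, list[tuple[str, str, int | None]]] = {}
    order: list[str] = []
    for taxon, name, seq, size in filled:
        by_taxon.setdefault(taxon, []).append((name, seq, size))
        if taxon not in order:
            order.append(taxon)
    for taxon in order:
        entries = by_taxon[taxon]
        fwd = [e for e in entries if e[0].upper().endswith("F")]
        rev = [e for e in entries if e[0].upper().endswith("R")]
        if len(fwd) != 1 or len(rev) != 1:
            raise PairingError(
                f"taxon {taxon!r}: need exactly one forward (…F) and one "
                f"reverse (…R) primer, got {len(fwd)} forward / {len(rev)} reverse"
            )
        size = next((e[2] for e in entries if e[2] is not None), None)
        pairs.append(
            ScarPrimerPair(
                taxon=taxon, forward=fwd[0][1], reverse=rev[0][1], expected_size=size
            )
        )
    return pairs


def _looks_like_dna(text: str) -> bool:
    return bool(text) and set(text.upper()) <= (ALPHABET | {"U", "."})


def write_primer_table(pairs: Sequence[ScarPrimerPair], path: str | Path) -> None:
    """Write a panel TSV in the (taxon, name, sequence, size) layout."""
    lines = ["taxon\tprimer_name\tsequence\tproduct_size"]
    for p in pairs:
        size = "" if p.expected_size is None else str(p.expected_size)
        lines.append(f"{p.taxon}\t{p.taxon}-F\t{p.forward}\t{size}")
        lines.append(f"{p.taxon}\t{p.taxon}-R\t{p.reverse}\t{size}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Reports


def _as_row(obj) -> dict:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, dict):
        return dict(obj)
    raise TypeError(f"cannot serialize {type(obj).__name__} as a report row")


def _render_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return f"{value:.4f}"
    if isinstance(value, (list, tuple, set, frozenset)):
        return ",".join(str(v) for v in sorted(value) if True)
    return str(value)


def write_report(rows: Sequence, path: str | Path, format: str = "tsv",
                 columns: Sequence[str] | None = None) -> None:
    """Write dataclass/dict rows as TSV or JSON with deterministic columns.

    Floats are printed to 4 decimal places in TSV, matching the precision
    used for distance summaries.
    """
    if format not in {"tsv", "json"}:
        raise FormatError(f"unknown report format {format!r}")
    dicts = [_as_row(r) for r in rows]
    if columns is None:
        columns = list(dicts[0].keys()) if dicts else []
    path = Path(path)
    if format == "json":
        payload = [{c: d.get(c) for c in (columns or d.keys())} for d in dicts]

        def _default(o):
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(type(o).__name__)

        path.write_text(json.dumps(payload, indent=2, default=_default) + "\n")
    else:
        lines = ["\t".join(columns)]
        for d in dicts:
            lines.append("\t".join(_render_cell(d.get(c)) for c in columns))
        path.write_text("\n".join(lines) + "\n")
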