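"""Detection of species-specific (diagnostic) polymorphisms in an alignment.

A substitution site for a taxon is an alignment column where

  (i)   every sample of the taxon carries the same unambiguous base,
  (ii)  that base occurs in no sample outside the taxon, and
  (iii) no sample of the taxon is gapped there.

Non-target samples need not agree among themselves, so one column may be
diagnostic for more than one taxon (with three taxa, a three-way-different
column serves all three). A column containing an IUPAC ambiguity code in any
included sample is disqualified for every taxon — conservative, since a
marker anchored on an uncertain base is not trustworthy.

An indel event for a taxon is a maximal run of consecutive columns that is
gapped in every sample of the taxon and ungapped in every other sample, or
the inverse (taxon has bases where everyone else is gapped). A multi-column
run counts as one event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import PartitionError
from .seqio import GAP, IUPAC_BASES, SpeciesPartition

__all__ = [
    "DiagnosticSite",
    "IndelEvent",
    "TaxonDiagnostics",
    "DiagnosticSummary",
    "scan_diagnostic_sites",
    "diagnostic_windows",
]


@dataclass(frozen=True)
class DiagnosticSite:
    """One alignment column diagnostic for one taxon (substitution)."""

    column: int
    taxon: str
    kind: str  # "substitution"
    target_state: str
    other_states: frozenset[str]


@dataclass(frozen=True)
class IndelEvent:
    """Maximal taxon-exclusive gap run, 0-based half-open columns."""

    start: int
    end: int
    taxon: str
    kind: str  # "deletion" (taxon gapped) | "insertion" (others gapped)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TaxonDiagnostics:
    substitution_sites: tuple[DiagnosticSite, ...]
    indel_events: tuple[IndelEvent, ...]


@dataclass(frozen=True)
class DiagnosticSummary:
    per_taxon: Mapping[str, TaxonDiagnostics]

    def counts(self) -> dict[str, tuple[int, int]]:
        """taxon -> (n substitution sites, n indel events)."""
        return {
            t: (len(d.substitution_sites), len(d.indel_events))
            for t, d in self.per_taxon.items()
        }

    def columns_of(self, taxon: str) -> tuple[int, ...]:
        return tuple(s.column for s in self.per_taxon[taxon].substitution_sites)


def scan_diagnostic_sites(
    alignment,
    partition: SpeciesPartition,
    exclude_taxa: Iterable[str] = (),
) -> DiagnosticSummary:
    """Scan every column for taxon-diagnostic substitutions and indel runs."""
    part = partition.restrict(exclude_taxa)
    for taxon in part.taxa:
        if not part.samples_of(taxon):
            raise PartitionError(f"taxon {taxon!r} has no samples in the alignment")
    included = [r for r in alignment.records if r.id in part.assignment]
    present = {r.id for r in included}
    missing = set(part.assignment) - present
    if missing:
        raise PartitionError(f"sheet ids missing from alignment: {sorted(missing)}")

    rows = {r.id: r.seq for r in included}
    ncol = alignment.n_columns
    members = {t: part.samples_of(t) for t in part.taxa}

    subs: dict[str, list[DiagnosticSite]] = {t: [] for t in part.taxa}
    for j in range(ncol):
        column = {s: rows[s][j] for s in rows}
        states = set(column.values())
        if states & (set("RYSWKMBDHVN")):
            continue  # ambiguity disqualifies the column for every taxon
        for taxon in part.taxa:
            mine = {column[s] for s in members[taxon]}
            if len(mine) != 1:
                continue
            state = next(iter(mine))
            if state == GAP or state not in IUPAC_BASES:
                continue
            others = {column[s] for s in rows if s not in set(members[taxon])}
            if state in others:
                continue
            if others <= {GAP}:
                continue  # taxon-exclusive insertion column: indel, not substitution
            subs[taxon].append(
                DiagnosticSite(
                    column=j,
                    taxon=taxon,
                    kind="substitution",
                    target_state=state,
                    other_states=frozenset(others),
                )
            )

    indels: dict[str, list[IndelEvent]] = {t: [] for t in part.taxa}
    for taxon in part.taxa:
        mine = set(members[taxon])
        run_kind: str | None = None
        run_start = 0
        for j in range(ncol + 1):
            kind = None
            if j < ncol:
                my_gapped = all(rows[s][j] == GAP for s in mine)
                my_bases = all(rows[s][j] != GAP for s in mine)
                others_gapped = all(rows[s][j] == GAP for s in rows if s not in mine)
                others_bases = all(rows[s][j] != GAP for s in rows if s not in mine)
                if my_gapped and others_bases:
                    kind = "deletion"
                elif my_bases and others_gapped:
                    kind = "insertion"
            if kind != run_kind:
                if run_kind is not None:
                    indels[taxon].append(
                        IndelEvent(start=run_start, end=j, taxon=taxon, kind=run_kind)
                    )
                run_kind = kind
                run_start = j

    return DiagnosticSummary(
        per_taxon={
            t: TaxonDiagnostics(
                substitution_sites=tuple(subs[t]), indel_events=tuple(indels[t])
            )
            for t in part.taxa
        }
    )


def diagnostic_windows(
    summary: DiagnosticSummary,
    min_sites: int = 1,
    window_len: int = 25,
    n_columns: int | None = None,
) -> list[tuple[str, tuple[int, int]]]:
    """Candidate primer-anchoring windows, one centered on each site.

    For each diagnostic substitution site a half-open column interval of
    length ``window_len`` centered on the site is formed (clipped to the
    alignment when ``n_columns`` is given); windows holding at least
    ``min_sites`` of the taxon's sites are returned sorted by site count
    descending, then leftmost first.
    """
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    out: list[tuple[str, tuple[int, int], int]] = []
    for taxon, diag in summary.per_taxon.items():
        cols = sorted(s.column for s in diag.substitution_sites)
        seen: set[tuple[int, int]] = set()
        for c in cols:
            start = max(c - window_len // 2, 0)
            if n_columns is not None:
                start = min(start, max(0, n_columns - window_len))
            end = start + window_len
            if (start, end) in seen:
                continue
            seen.add((start, end))
            count = sum(1 for x in cols if start <= x < end)
            if count >= min_sites:
                out.append((taxon, (start, end), count))
    out.sort(key=lambda item: (-item[2], item[1][0], item[0]))
    return [(taxon, interval) for taxon, interval, _ in out]
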