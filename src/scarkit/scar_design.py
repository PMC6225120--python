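"""Species-specific primer design and multiplex panel assembly.

Primer candidates are taken from the target taxon's consensus sequence and
anchored on diagnostic substitution sites: the 3' end of every candidate
places at least one diagnostic base within its terminal 3 nt against every
non-target taxon, the classic specificity lever of allele/species-specific
PCR (a 3' mismatch blocks extension). A multiplex panel then picks one
forward/reverse pair per taxon so that the predicted amplicons form a size
ladder resolvable on an agarose gel: all products distinct, every pairwise
size gap at least a configured minimum.

Melting temperatures use the Wallace rule 2(A+T)+4(G+C) for primers of at
most 14 nt and the nearest-neighbor thermodynamic model (SantaLucia
parameters, as implemented in Biopython) for longer ones.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio.SeqUtils import MeltingTemp

from .errors import (
    ConfigError,
    InfeasiblePanelError,
    ScarKitError,
)
from .seqio import GAP, IUPAC_BASES, ScarPrimerPair, SpeciesPartition, reverse_complement
from .aligndist import Alignment
from .diagnostics import DiagnosticSummary

__all__ = [
    "DesignConstraints",
    "PrimerCandidate",
    "ScarPanel",
    "melting_temperature",
    "taxon_consensus",
    "enumerate_candidates",
    "select_multiplex_panel",
]


@dataclass(frozen=True)
class DesignConstraints:
    """Tunable primer/panel design constraints.

    Lengths in nt, amplicons in bp, Tm in Celsius, GC as a fraction. The
    amplicon ceiling of 400 bp reflects that short SCAR targets still
    amplify from the degraded DNA of processed herbal material; the 40 bp
    minimum size gap keeps neighboring multiplex bands resolvable on a
    1.5-2% agarose gel.
    """

    primer_len_min: int = 18
    primer_len_max: int = 25
    amplicon_min: int = 100
    amplicon_max: int = 400
    tm_min: float = 58.0
    tm_max: float = 72.0
    gc_min: float = 0.40
    gc_max: float = 0.70
    three_prime_window: int = 3
    min_three_prime_diag: int = 1
    min_nontarget_mismatches: int = 2
    min_size_gap: int = 40
    min_spacer: int = 20
    forward_region: tuple[int, int] | None = None  # alignment columns, half-open
    reverse_region: tuple[int, int] | None = None

    def __post_init__(self):
        if self.primer_len_min > self.primer_len_max:
            raise ConfigError("empty primer length range")
        if self.amplicon_min > self.amplicon_max:
            raise ConfigError("empty amplicon range")
        if self.amplicon_max < self.amplicon_min + self.min_size_gap:
            raise ConfigError("amplicon range cannot hold the required size gap")
        if self.tm_min > self.tm_max or self.gc_min > self.gc_max:
            raise ConfigError("empty Tm or GC range")


@dataclass(frozen=True)
class PrimerCandidate:
    """One primer candidate on the taxon consensus.

    ``start_col``/``end_col`` delimit the alignment-column footprint
    (half-open); ``start_base``/``end_base`` the same footprint in ungapped
    consensus base coordinates. The stored sequence is always 5'->3' as
    synthesized: reverse-strand candidates hold the reverse complement of
    the plus-strand consensus slice.
    """

    taxon: str
    sequence: str
    strand: str  # "+" or "-"
    start_col: int
    end_col: int
    start_base: int
    end_base: int
    tm_celsius: float
    gc_fraction: float
    diagnostic_columns: tuple[int, ...]
    three_prime_anchor: bool

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ScarPanel:
    """One primer pair per taxon with predicted sizes forming a size ladder."""

    pairs: tuple[ScarPrimerPair, ...]
    min_size_gap: int

    def __post_init__(self):
        sizes = [p.expected_size for p in self.pairs]
        if any(s is None for s in sizes):
            raise ConfigError("panel pairs must carry expected sizes")
        if len(set(sizes)) != len(sizes):
            raise ConfigError(f"panel product sizes not distinct: {sizes}")

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(p.taxon for p in self.pairs)

    def pair_of(self, taxon: str) -> ScarPrimerPair:
        for p in self.pairs:
            if p.taxon == taxon:
                return p
        raise KeyError(taxon)

    @classmethod
    def from_pairs(cls, pairs: Sequence[ScarPrimerPair]) -> "ScarPanel":
        sizes = sorted(p.expected_size for p in pairs)
        gap = min((b - a for a, b in zip(sizes, sizes[1:])), default=0)
        return cls(pairs=tuple(pairs), min_size_gap=gap)


# ---------------------------------------------------------------------------
# Melting temperature


# Nearest-neighbor Tm is evaluated under typical PCR-buffer conditions
# (50 mM monovalent salt, 2.5 mM Mg2+, 0.8 mM total dNTPs, 0.5 uM primer,
# template in excess ignored), where standard taxon-diagnostic primers land
# in the high-50s to low-70s Celsius.
_TM_NN_CONDITIONS = dict(Na=50, Mg=2.5, dNTPs=0.8, dnac1=500, dnac2=0)


def melting_temperature(sequence: str) -> float:
    """Primer melting temperature in Celsius.

    Wallace rule 2(A+T)+4(G+C) for <=14 nt; nearest-neighbor thermodynamics
    (SantaLucia unified parameters, PCR-buffer salt/Mg corrections) for
    longer primers. Only unambiguous A/C/G/T input of length >=4 is
    supported.
    """
    seq = sequence.upper()
    if len(seq) < 4:
        raise ScarKitError(f"primer too short for a Tm estimate: {sequence!r}")
    if set(seq) - IUPAC_BASES:
        raise ScarKitError(
            f"ambiguous or non-DNA characters in primer: {sequence!r}"
        )
    if len(seq) <= 14:
        return float(MeltingTemp.Tm_Wallace(seq))
    return float(MeltingTemp.Tm_NN(seq, **_TM_NN_CONDITIONS))


def gc_fraction(sequence: str) -> float:
    seq = sequence.upper()
    return (seq.count("G") + seq.count("C")) / len(seq)


# ---------------------------------------------------------------------------
# Consensus


@dataclass(frozen=True)
class TaxonConsensus:
    """Majority-rule consensus of one taxon's aligned rows.

    ``aligned``: consensus with gap columns kept; ``bases``: ungapped
    consensus; ``base_cols[i]``: alignment column of base i;
    ``polymorphic_cols``: columns where the taxon's samples disagree.
    """

    taxon: str
    aligned: str
    bases: str
    base_cols: tuple[int, ...]
    polymorphic_cols: frozenset[int]

    def col_of_base(self, base_index: int) -> int:
        return self.base_cols[base_index]


def taxon_consensus(alignment: Alignment, partition: SpeciesPartition, taxon: str) -> TaxonConsensus:
    samples = partition.samples_of(taxon)
    if not samples:
        raise ConfigError(f"taxon {taxon!r} has no samples")
    rows = [alignment.row(s) for s in samples]
    aligned_chars: list[str] = []
    poly: set[int] = set()
    for j in range(alignment.n_columns):
        states = {r[j] for r in rows}
        if len(states) > 1:
            poly.add(j)
        counts: dict[str, int] = {}
        for r in rows:
            counts[r[j]] = counts.get(r[j], 0) + 1
        base_counts = {b: c for b, c in counts.items() if b != GAP}
        aligned_chars.append(
            max(sorted(base_counts), key=lambda b: base_counts[b]) if base_counts else GAP
        )
    aligned = "".join(aligned_chars)
    base_cols = tuple(j for j, ch in enumerate(aligned) if ch != GAP)
    bases = "".join(aligned[j] for j in base_cols)
    return TaxonConsensus(
        taxon=taxon,
        aligned=aligned,
        bases=bases,
        base_cols=base_cols,
        polymorphic_cols=frozenset(poly),
    )


# ---------------------------------------------------------------------------
# Candidate enumeration


def enumerate_candidates(
    alignment: Alignment,
    partition: SpeciesPartition,
    summary: DiagnosticSummary,
    taxon: str,
    constraints: DesignConstraints = DesignConstraints(),
) -> list[PrimerCandidate]:
    """Enumerate primer candidates for one taxon, both strands.

    Every candidate covers at least one of the taxon's diagnostic
    substitution columns within its 3'-terminal window, satisfies the
    length/Tm/GC constraints, carries at least ``min_nontarget_mismatches``
    differences against every non-target consensus over its footprint, spans
    no intra-taxon polymorphic column, and occurs exactly once on its strand
    in the taxon consensus. Sorted by (diagnostic sites covered desc,
    |Tm - Tm midrange| asc, start column asc).
    """
    if taxon not in summary.per_taxon:
        raise ConfigError(f"taxon {taxon!r} absent from diagnostic summary")
    cons = taxon_consensus(alignment, partition, taxon)
    other_cons = {
        t: taxon_consensus(alignment, partition, t)
        for t in summary.per_taxon
        if t != taxon
    }
    diag_cols = sorted(summary.columns_of(taxon))
    if not diag_cols:
        return []
    diag_set = set(diag_cols)
    pos_of_col = {c: i for i, c in enumerate(cons.base_cols)}
    n_bases = len(cons.bases)
    tm_mid = 0.5 * (constraints.tm_min + constraints.tm_max)

    seen: set[tuple[str, int, str]] = set()
    out: list[PrimerCandidate] = []

    def footprint_ok(col_start: int, col_end: int) -> bool:
        return not any(
            j in cons.polymorphic_cols for j in range(col_start, col_end)
        )

    def in_region(col_start: int, col_end: int, region) -> bool:
        return region is None or (region[0] <= col_start and col_end <= region[1])

    def try_candidate(p_lo: int, p_hi: int, strand: str):
        """Base-index footprint [p_lo, p_hi] inclusive on the consensus."""
        col_start = cons.base_cols[p_lo]
        col_end = cons.base_cols[p_hi] + 1
        plus_seq = cons.bases[p_lo : p_hi + 1]
        seq = plus_seq if strand == "+" else reverse_complement(plus_seq)
        key = (seq, col_start, strand)
        if key in seen:
            return
        seen.add(key)
        if set(plus_seq) - IUPAC_BASES:
            return
        if not footprint_ok(col_start, col_end):
            return
        region = (
            constraints.forward_region if strand == "+" else constraints.reverse_region
        )
        if not in_region(col_start, col_end, region):
            return
        tm = melting_temperature(seq)
        if not (constraints.tm_min <= tm <= constraints.tm_max):
            return
        gc = gc_fraction(seq)
        if not (constraints.gc_min <= gc <= constraints.gc_max):
            return
        covered = tuple(c for c in diag_cols if col_start <= c < col_end)
        # 3'-terminal window in base coordinates
        if strand == "+":
            tail = cons.base_cols[max(p_lo, p_hi - constraints.three_prime_window + 1) : p_hi + 1]
        else:
            tail = cons.base_cols[p_lo : min(p_hi + 1, p_lo + constraints.three_prime_window)]
        n_tail_diag = sum(1 for c in tail if c in diag_set)
        if n_tail_diag < constraints.min_three_prime_diag:
            return
        # mismatches against every non-target consensus over the footprint
        for oc in other_cons.values():
            mm = sum(
                1
                for j in range(col_start, col_end)
                if cons.aligned[j] != oc.aligned[j]
            )
            if mm < constraints.min_nontarget_mismatches:
                return
        # exactly one exact occurrence on the designed strand
        probe = plus_seq  # plus-strand binding footprint for either strand
        if cons.bases.count(probe) != 1:
            return
        out.append(
            PrimerCandidate(
                taxon=taxon,
                sequence=seq,
                strand=strand,
                start_col=col_start,
                end_col=col_end,
                start_base=p_lo,
                end_base=p_hi + 1,
                tm_celsius=tm,
                gc_fraction=gc,
                diagnostic_columns=covered,
                three_prime_anchor=True,
            )
        )

    for d in diag_cols:
        if d not in pos_of_col:
            continue  # consensus gapped at a diagnostic column: cannot happen for subs
        p_d = pos_of_col[d]
        for L in range(constraints.primer_len_min, constraints.primer_len_max + 1):
            for offset in range(constraints.three_prime_window):
                # forward: 3' end base index p_e with d among the last bases
                p_e = p_d + offset
                p_s = p_e - L + 1
                if p_s >= 0 and p_e < n_bases:
                    try_candidate(p_s, p_e, "+")
                # reverse: 3' end maps to the left edge of the footprint
                p_l = p_d - offset
                p_r = p_l + L - 1
                if p_l >= 0 and p_r < n_bases:
                    try_candidate(p_l, p_r, "-")

    out.sort(
        key=lambda c: (
            -len(c.diagnostic_columns),
            abs(c.tm_celsius - tm_mid),
            c.start_col,
            c.strand,
        )
    )
    return out


# ---------------------------------------------------------------------------
# Panel selection


def _pair_options(
    forwards: Sequence[PrimerCandidate],
    reverses: Sequence[PrimerCandidate],
    constraints: DesignConstraints,
    max_per_strand: int = 500,
) -> dict[int, tuple[PrimerCandidate, PrimerCandidate]]:
    """Feasible (size -> best-ranked pair) options for one taxon."""
    regions_annotated = (
        constraints.forward_region is not None
        and constraints.reverse_region is not None
    )
    options: dict[int, tuple[int, PrimerCandidate, PrimerCandidate]] = {}
    for fi, f in enumerate(forwards[:max_per_strand]):
        for ri, r in enumerate(reverses[:max_per_strand]):
            spacer = r.start_base - f.end_base
            if spacer < (0 if regions_annotated else constraints.min_spacer):
                continue
            size = r.end_base - f.start_base
            if not (constraints.amplicon_min <= size <= constraints.amplicon_max):
                continue
            rank = fi + ri
            if size not in options or rank < options[size][0]:
                options[size] = (rank, f, r)
    return {size: (f, r) for size, (rank, f, r) in options.items()}


def select_multiplex_panel(
    candidates: Mapping[str, Sequence[PrimerCandidate]],
    constraints: DesignConstraints = DesignConstraints(),
    alignment: Alignment | None = None,
    partition: SpeciesPartition | None = None,
) -> ScarPanel:
    """Assemble one primer pair per taxon into a size-ladder multiplex panel.

    Chooses the size combination maximizing the minimum pairwise product-size
    gap (which must reach ``constraints.min_size_gap``); ties prefer smaller
    total product size, then the lexicographically smallest size tuple in
    sorted taxon order. When an alignment and partition are supplied, each
    candidate panel is verified by in-silico multiplex PCR before acceptance:
    every sample of a taxon must yield exactly one product of the predicted
    size and samples of other taxa none.
    """
    from . import vpcr  # deferred: vpcr imports ScarPanel from here

    taxa = sorted(candidates)
    per_taxon_options: dict[str, dict[int, tuple[PrimerCandidate, PrimerCandidate]]] = {}
    for taxon in taxa:
        cands = candidates[taxon]
        fwd = [c for c in cands if c.strand == "+"]
        rev = [c for c in cands if c.strand == "-"]
        if not fwd or not rev:
            raise InfeasiblePanelError(
                f"taxon {taxon!r}: need >=1 forward and >=1 reverse candidate"
            )
        options = _pair_options(fwd, rev, constraints)
        if not options:
            raise InfeasiblePanelError(
                f"taxon {taxon!r}: no forward/reverse combination yields an "
                f"amplicon in [{constraints.amplicon_min}, {constraints.amplicon_max}]"
            )
        per_taxon_options[taxon] = options

    # Cap the size search: with hundreds of distinct sizes per taxon the full
    # cartesian product is wasteful; an even-spread subsample (endpoints kept)
    # loses at most a few bp of ladder resolution against a >=40 bp gap.
    max_combos = 200_000
    per_taxon_sizes: dict[str, list[int]] = {}
    cap = max(2, int(max_combos ** (1.0 / len(taxa))))
    for t in taxa:
        sizes = sorted(per_taxon_options[t])
        if len(sizes) > cap:
            idx = np.linspace(0, len(sizes) - 1, cap).round().astype(int)
            sizes = sorted({sizes[i] for i in idx})
        per_taxon_sizes[t] = sizes

    combos = []
    for sizes in itertools.product(*(per_taxon_sizes[t] for t in taxa)):
        gaps = [abs(a - b) for a, b in itertools.combinations(sizes, 2)]
        min_gap = min(gaps) if gaps else 0
        combos.append((-min_gap, sum(sizes), sizes))
    combos.sort()

    best_gap = -combos[0][0] if combos else 0
    feasible = [c for c in combos if -c[0] >= constraints.min_size_gap]
    if not feasible:
        raise InfeasiblePanelError(
            f"no combination reaches the minimum size gap "
            f"{constraints.min_size_gap} bp (best achievable: {best_gap} bp)",
            best_gap=best_gap,
        )

    verify = alignment is not None and partition is not None
    last_error = None
    for neg_gap, _total, sizes in feasible:
        pairs = []
        for taxon, size in zip(taxa, sizes):
            f, r = per_taxon_options[taxon][size]
            pairs.append(
                ScarPrimerPair(
                    taxon=taxon,
                    forward=f.sequence,
                    reverse=r.sequence,
                    expected_size=size,
                )
            )
        panel = ScarPanel(pairs=tuple(pairs), min_size_gap=-neg_gap)
        if not verify:
            return panel
        ok, last_error = _verified_by_vpcr(panel, alignment, partition, vpcr)
        if ok:
            return panel
    raise InfeasiblePanelError(
        f"no size-feasible panel survived in-silico PCR verification "
        f"(last failure: {last_error})",
        best_gap=best_gap,
    )


def _verified_by_vpcr(panel, alignment, partition, vpcr) -> tuple[bool, str | None]:
    params = vpcr.PcrParams(max_total_mismatches=0)
    expected = {p.taxon: p.expected_size for p in panel.pairs}
    for rec in alignment.records:
        taxon = partition.assignment.get(rec.id)
        if taxon is None:
            continue
        lane = vpcr.simulate_multiplex(
            {rec.id: [rec]}, panel, params
        )[rec.id]
        sizes = [size for size, _count in lane.bands]
        if taxon in expected:
            if sizes != [expected[taxon]]:
                return False, f"{rec.id}: expected [{expected[taxon]}], got {sizes}"
        elif sizes:
            return False, f"{rec.id}: off-target products {sizes}"
    return True, None
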