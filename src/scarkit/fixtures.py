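"""Synthetic barcode panels with planted, recoverable ground truth.

The generator emulates the data regime of a nuclear-spacer (ITS-like)
barcode panel for a few closely related species: near-identical sequences of
~690 bp, a handful of fixed species-specific substitutions per taxon (tens
at most), at most one or two short taxon-exclusive indel events, low
intra-taxon polymorphism, and two conserved flanking zones (mimicking the
ITS1/ITS2 spacers around 5.8S) where primers can land.

Everything is drawn from one seeded generator, so a fixed seed reproduces
the panel byte for byte. Planted features never overlap each other, and
random intra-taxon polymorphisms never land on planted columns or inside
the conserved zones, so the diagnostic-site scanner's output can be compared
against the planted truth exactly.

It does NOT simulate sequencing error, chimeras, alignment uncertainty, or
intra-genomic ITS paralogs; real data can violate the clean separation of
fixed versus polymorphic sites that these panels guarantee.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .seqio import GAP, SequenceRecord, SpeciesPartition
from .aligndist import Alignment

__all__ = ["PanelConfig", "PanelTruth", "generate_panel", "unaligned_records",
           "synthetic_template", "write_panel"]

BASES = "ACGT"
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {
    "A": "CT", "G": "CT", "C": "AG", "T": "AG",
}


@dataclass(frozen=True)
class PanelConfig:
    """Study conditions for one synthetic panel.

    Defaults mirror a small herbal-barcode survey: three taxa, four samples
    each, 690 bp, 18/10/16 planted species-specific substitutions, one 1-bp
    insertion in the third taxon, and a low intra-taxon polymorphism rate
    (one or two variable sites per sample, as seen in near-clonal ITS data).
    """

    taxa: tuple[str, ...] = ("taxonA", "taxonB", "taxonC")
    samples_per_taxon: int = 4
    base_length: int = 690
    n_substitutions: tuple[int, ...] = (18, 10, 16)
    # (taxon index, length, kind) — kind "insertion": taxon has bases, others gaps
    indels: tuple[tuple[int, int, str], ...] = ((2, 1, "insertion"),)
    polymorphism_rate: float = 0.002
    # conserved flanks mimicking ITS1 and early ITS2: any forward anchored in
    # the first zone and reverse in the second yields a product under 400 bp
    forward_zone: tuple[int, int] = (70, 200)
    reverse_zone: tuple[int, int] = (340, 460)
    min_zone_sites: int = 3
    seed: int = 0

    def __post_init__(self):
        if len(self.n_substitutions) != len(self.taxa):
            raise ConfigError("need one substitution count per taxon")
        if not (0 <= self.polymorphism_rate < 1):
            raise ConfigError("polymorphism rate must lie in [0, 1)")
        if self.samples_per_taxon < 1:
            raise ConfigError("need >=1 sample per taxon")
        budget = sum(self.n_substitutions) + sum(l for _, l, _ in self.indels)
        if budget > self.base_length // 2:
            raise ConfigError(
                f"requested features ({budget} columns) exceed half the "
                f"sequence length {self.base_length}"
            )
        for zone in (self.forward_zone, self.reverse_zone):
            if not (0 <= zone[0] < zone[1] <= self.base_length):
                raise ConfigError(f"zone {zone} outside sequence bounds")
        for t_idx, length, kind in self.indels:
            if not (0 <= t_idx < len(self.taxa)) or length < 1:
                raise ConfigError(f"bad indel spec {(t_idx, length, kind)}")
            if kind not in ("insertion", "deletion"):
                raise ConfigError(f"indel kind must be insertion/deletion: {kind!r}")
        for n in self.n_substitutions:
            needed = 2 * self.min_zone_sites
            if 0 < n < needed:
                raise ConfigError(
                    f"each taxon with planted substitutions needs >= {needed} "
                    f"(min_zone_sites per zone); got {n}"
                )


@dataclass(frozen=True)
class PanelTruth:
    """Planted ground truth, re-derivable from the emitted alignment."""

    ancestral: str
    # taxon -> {column: (ancestral_base, planted_base)}
    substitutions: Mapping[str, Mapping[int, tuple[str, str]]]
    # (taxon, start, end, kind), 0-based half-open alignment columns
    indel_events: tuple[tuple[str, int, int, str], ...]
    # sample -> {column: base}
    polymorphisms: Mapping[str, Mapping[int, str]]

    def substitution_columns(self, taxon: str) -> tuple[int, ...]:
        return tuple(sorted(self.substitutions[taxon]))

    def to_json(self) -> str:
        payload = {
            "ancestral": self.ancestral,
            "substitutions": {
                t: {str(c): list(v) for c, v in cols.items()}
                for t, cols in self.substitutions.items()
            },
            "indel_events": [list(e) for e in self.indel_events],
            "polymorphisms": {
                s: {str(c): b for c, b in cols.items()}
                for s, cols in self.polymorphisms.items()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _mutant_base(anc: str, rng: np.random.Generator) -> str:
    """Transition with probability 0.5, otherwise a random transversion."""
    if rng.random() < 0.5:
        return TRANSITION[anc]
    return TRANSVERSIONS[anc][rng.integers(0, 2)]


def generate_panel(
    config: PanelConfig = PanelConfig(),
) -> tuple[Alignment, SpeciesPartition, PanelTruth]:
    """Generate an aligned panel, its partition, and the planted truth."""
    rng = np.random.default_rng(config.seed)
    L = config.base_length
    ancestral = "".join(BASES[i] for i in rng.integers(0, 4, size=L))

    available = set(range(L))
    zone_cols = {
        "fwd": set(range(*config.forward_zone)),
        "rev": set(range(*config.reverse_zone)),
    }

    def draw_from(pool: set[int], k: int) -> list[int]:
        pool_sorted = sorted(pool & available)
        if len(pool_sorted) < k:
            raise ConfigError("not enough free columns to place features")
        picked = rng.choice(len(pool_sorted), size=k, replace=False)
        cols = [pool_sorted[i] for i in picked]
        available.difference_update(cols)
        return cols

    # indel runs first (need contiguous free stretches)
    indel_events: list[tuple[str, int, int, str]] = []
    for t_idx, length, kind in config.indels:
        taxon = config.taxa[t_idx]
        middle = [
            c
            for c in sorted(available - zone_cols["fwd"] - zone_cols["rev"])
            if all(c + o in available for o in range(length))
        ]
        if not middle:
            raise ConfigError("no room for the requested indel run")
        start = middle[rng.integers(0, len(middle))]
        available.difference_update(range(start, start + length))
        indel_events.append((taxon, start, start + length, kind))

    substitutions: dict[str, dict[int, tuple[str, str]]] = {}
    for t_idx, taxon in enumerate(config.taxa):
        n = config.n_substitutions[t_idx]
        cols: list[int] = []
        if n > 0:
            cols += draw_from(zone_cols["fwd"], config.min_zone_sites)
            cols += draw_from(zone_cols["rev"], config.min_zone_sites)
            cols += draw_from(available, n - 2 * config.min_zone_sites)
        substitutions[taxon] = {
            c: (ancestral[c], _mutant_base(ancestral[c], rng)) for c in sorted(cols)
        }

    # eligible columns for random intra-taxon polymorphism
    protected = set()
    for cols in substitutions.values():
        protected.update(cols)
    for _taxon, start, end, _kind in indel_events:
        protected.update(range(start, end))
    protected.update(zone_cols["fwd"])
    protected.update(zone_cols["rev"])
    eligible = np.array(sorted(set(range(L)) - protected))

    records: list[SequenceRecord] = []
    sheet: list[tuple[str, str]] = []
    polymorphisms: dict[str, dict[int, str]] = {}
    for taxon in config.taxa:
        base_row = list(ancestral)
        for c, (_anc, planted) in substitutions[taxon].items():
            base_row[c] = planted
        for ev_taxon, start, end, kind in indel_events:
            gapped = (kind == "deletion") == (ev_taxon == taxon)
            if gapped:
                for c in range(start, end):
                    base_row[c] = GAP
        for k in range(config.samples_per_taxon):
            sample_id = f"{taxon}-{k + 1}"
            row = list(base_row)
            poly: dict[int, str] = {}
            if config.polymorphism_rate > 0 and eligible.size:
                hits = eligible[
                    rng.random(eligible.size) < config.polymorphism_rate
                ]
                for c in hits.tolist():
                    row[c] = _mutant_base(row[c], rng)
                    poly[c] = row[c]
            records.append(SequenceRecord(id=sample_id, seq="".join(row), species=taxon))
            sheet.append((sample_id, taxon))
            polymorphisms[sample_id] = poly

    alignment = Alignment(tuple(records))
    partition = SpeciesPartition.from_pairs(sheet)
    truth = PanelTruth(
        ancestral=ancestral,
        substitutions=substitutions,
        indel_events=tuple(indel_events),
        polymorphisms=polymorphisms,
    )
    return alignment, partition, truth


def unaligned_records(alignment: Alignment) -> list[SequenceRecord]:
    """Gap-stripped copies of every row (for exercising the aligner)."""
    return [
        SequenceRecord(id=r.id, seq=r.ungapped, species=r.species)
        for r in alignment.records
    ]


def synthetic_template(
    forward: str,
    reverse: str,
    spacer_len: int,
    seed: int = 0,
    avoid_primers: Sequence[str] = (),
    max_redraws: int = 100,
) -> SequenceRecord:
    """Template = forward primer + random spacer + revcomp(reverse primer).

    The product of (forward, reverse) on this template is exactly
    ``len(forward) + spacer_len + len(reverse)`` bp. The spacer is redrawn
    if it spuriously contains a binding footprint (forward or reverse
    orientation) of any primer in ``avoid_primers`` — or of the two flanking
    primers themselves — so the construction yields a single clean product.
    """
    from .seqio import reverse_complement

    rng = np.random.default_rng(seed)
    probes = set()
    for p in list(avoid_primers) + [forward, reverse]:
        probes.add(p)
        probes.add(reverse_complement(p))
    for _ in range(max_redraws):
        spacer = "".join(BASES[i] for i in rng.integers(0, 4, size=spacer_len))
        template = forward + spacer + reverse_complement(reverse)
        interior = template[1 : len(template) - 1]
        clean = True
        for probe in probes:
            hits = _count_occurrences(template, probe)
            expected = 1 if probe in (forward, reverse_complement(reverse)) else 0
            if probe == forward and probe == reverse_complement(reverse):
                expected = 2
            if hits != expected:
                clean = False
                break
        if clean:
            return SequenceRecord(id="synthetic-template", seq=template)
    raise ConfigError("could not draw a spacer free of spurious primer sites")


def _count_occurrences(text: str, pattern: str) -> int:
    count = start = 0
    while True:
        idx = text.find(pattern, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def write_panel(
    alignment: Alignment,
    partition: SpeciesPartition,
    truth: PanelTruth,
    outdir: str | Path,
    stem: str = "panel",
) -> dict[str, Path]:
    """Write aligned FASTA, unaligned FASTA, sample sheet, and truth JSON."""
    from . import seqio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "aligned": outdir / f"{stem}.aligned.fasta",
        "unaligned": outdir / f"{stem}.fasta",
        "sheet": outdir / f"{stem}.samples.tsv",
        "truth": outdir / f"{stem}.truth.json",
    }
    seqio.write_fasta(alignment.records, paths["aligned"])
    seqio.write_fasta(unaligned_records(alignment), paths["unaligned"])
    seqio.write_sample_sheet(partition, paths["sheet"])
    paths["truth"].write_text(truth.to_json() + "\n")
    return paths
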