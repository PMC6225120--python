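"""In-silico multiplex PCR, virtual gel, and sample classification.

A primer binds a template wherever the total mismatch count stays within
budget AND the 3'-terminal clamp bases match exactly — Taq extends from the
3' end, so a terminal mismatch blocks amplification even when the rest of
the primer anneals. Amplicons are enumerated between forward sites on the
plus strand and reverse sites on the minus strand (forward 3' end left of
the reverse 3' end), primers included in the product, 0-based half-open
plus-strand coordinates. Cross-pair products (forward of one pair with
reverse of another) are real multiplex artifacts and are emitted flagged.

A gel lane is the sorted multiset of product sizes for one sample (which may
pool several templates, modeling mixed or adulterated material). The
classifier assigns each band to the panel taxon whose expected size lies
within tolerance and calls the sample authentic, adulterant_detected, mixed,
no_amplification, or unexplained_bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import AmbiguousPanelError, ConfigError
from .seqio import GAP, SequenceRecord, reverse_complement
from .scar_design import ScarPanel

__all__ = [
    "PcrParams",
    "BindingSite",
    "Amplicon",
    "GelLane",
    "IdentificationResult",
    "find_binding_sites",
    "simulate_multiplex",
    "classify_lane",
]


@dataclass(frozen=True)
class PcrParams:
    """Binding and band-matching tolerances.

    Zero mismatches is the default for design verification; a small mismatch
    budget (survey mode) is appropriate when classifying query sequences
    that may diverge slightly from the panel's source alignment. The wet
    assay's true tolerance is unknowable in silico; both regimes are exposed.
    """

    max_total_mismatches: int = 0
    three_prime_clamp_len: int = 3
    max_product_len: int = 2000
    size_tolerance: int = 3

    def __post_init__(self):
        if self.size_tolerance < 0 or self.max_total_mismatches < 0:
            raise ConfigError("tolerances must be >= 0")


@dataclass(frozen=True)
class BindingSite:
    """One qualifying primer binding site on a template."""

    template_id: str
    three_prime_pos: int  # plus-strand coordinate of the primer's 3' end
    strand: str  # "+" or "-"
    mismatches: int
    clamp_ok: bool
    start: int  # leftmost plus-strand coordinate of the footprint
    end: int  # half-open right edge


@dataclass(frozen=True)
class Amplicon:
    """One predicted product, primers inclusive."""

    template_id: str
    start: int
    end: int
    taxon: str  # primer-pair label; "fwdtaxon x revtaxon" for cross-pair artifacts
    cross_pair: bool = False

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GelLane:
    """Virtual-gel observable for one sample: sorted (size, count) bands."""

    sample_id: str
    bands: tuple[tuple[int, int], ...]
    amplicons: tuple[Amplicon, ...] = ()

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(size for size, _ in self.bands)


@dataclass(frozen=True)
class IdentificationResult:
    sample_id: str
    detected_taxa: frozenset[str]
    status: str  # authentic | adulterant_detected | mixed | no_amplification | unexplained_bands
    band_sizes: tuple[int, ...] = ()
    unexplained_sizes: tuple[int, ...] = ()


def _clean_template(record: SequenceRecord) -> str:
    return record.seq.replace(GAP, "")


def find_binding_sites(
    template: SequenceRecord | str,
    primer: str,
    strand_mode: str = "both",
    params: PcrParams = PcrParams(),
) -> list[BindingSite]:
    """All qualifying binding sites of one primer on one template.

    Plus-strand sites have the primer reading left-to-right (3' end at the
    right edge); minus-strand sites are where the primer's reverse
    complement appears on the plus strand (3' end at the left edge).
    Overlapping sites are all reported. A primer longer than the template
    yields an empty list.
    """
    if isinstance(template, str):
        template = SequenceRecord(id="template", seq=template)
    seq = _clean_template(template)
    n, m = len(seq), len(primer)
    if m > n:
        return []
    clamp = min(params.three_prime_clamp_len, m)
    sites: list[BindingSite] = []

    if strand_mode in ("both", "+"):
        for pos in range(n - m + 1):
            window = seq[pos : pos + m]
            if clamp and window[m - clamp :] != primer[m - clamp :]:
                continue
            mm = sum(1 for a, b in zip(window, primer) if a != b)
            if mm <= params.max_total_mismatches:
                sites.append(
                    BindingSite(
                        template_id=template.id,
                        three_prime_pos=pos + m - 1,
                        strand="+",
                        mismatches=mm,
                        clamp_ok=True,
                        start=pos,
                        end=pos + m,
                    )
                )
    if strand_mode in ("both", "-"):
        rc = reverse_complement(primer)
        for pos in range(n - m + 1):
            window = seq[pos : pos + m]
            # primer 3' end maps to plus-strand position `pos`
            if clamp and window[:clamp] != rc[:clamp]:
                continue
            mm = sum(1 for a, b in zip(window, rc) if a != b)
            if mm <= params.max_total_mismatches:
                sites.append(
                    BindingSite(
                        template_id=template.id,
                        three_prime_pos=pos,
                        strand="-",
                        mismatches=mm,
                        clamp_ok=True,
                        start=pos,
                        end=pos + m,
                    )
                )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def simulate_multiplex(
    samples: Mapping[str, Sequence[SequenceRecord]],
    panel: ScarPanel,
    params: PcrParams = PcrParams(),
    include_cross_pair: bool = False,
) -> dict[str, GelLane]:
    """Run the multiplex panel over every sample; one gel lane per sample.

    A sample may contain several templates (mixed material); its lane is the
    union of the products of every template. Products pair a forward site on
    the plus strand with a reverse site on the minus strand whose 3' ends
    face each other; ``include_cross_pair`` additionally emits (flagged)
    products formed by the forward primer of one pair and the reverse of
    another.
    """
    if not panel.pairs:
        raise ConfigError("empty panel")
    lanes: dict[str, GelLane] = {}
    for sample_id, templates in samples.items():
        amplicons: list[Amplicon] = []
        for template in templates:
            # each primer can prime off either strand; a product needs one
            # plus-strand site (3' end at its right edge) and one minus-strand
            # site (3' end at its left edge) facing each other
            plus_sites: dict[str, list[BindingSite]] = {}
            minus_sites: dict[str, list[BindingSite]] = {}
            for pair in panel.pairs:
                for role, primer in (("F", pair.forward), ("R", pair.reverse)):
                    key = f"{pair.taxon}/{role}"
                    plus_sites[key] = find_binding_sites(template, primer, "+", params)
                    minus_sites[key] = find_binding_sites(template, primer, "-", params)
            for left_key, lsites in plus_sites.items():
                ltx, lrole = left_key.split("/")
                for right_key, rsites in minus_sites.items():
                    rtx, rrole = right_key.split("/")
                    if lrole == rrole:
                        continue  # two forwards (or two reverses) never pair
                    cross = ltx != rtx
                    if cross and not include_cross_pair:
                        continue
                    ftx = ltx if lrole == "F" else rtx
                    other = rtx if lrole == "F" else ltx
                    for ls in lsites:
                        for rs in rsites:
                            if ls.three_prime_pos >= rs.three_prime_pos:
                                continue
                            size = rs.end - ls.start
                            if size > params.max_product_len:
                                continue
                            amplicons.append(
                                Amplicon(
                                    template_id=template.id,
                                    start=ls.start,
                                    end=rs.end,
                                    taxon=ftx if not cross else f"{ftx} x {other}",
                                    cross_pair=cross,
                                )
                            )
        counts: dict[int, int] = {}
        for a in amplicons:
            counts[a.size] = counts.get(a.size, 0) + 1
        bands = tuple(sorted(counts.items()))
        lanes[sample_id] = GelLane(
            sample_id=sample_id, bands=bands, amplicons=tuple(amplicons)
        )
    return lanes


def check_panel_resolvable(panel: ScarPanel, params: PcrParams) -> None:
    """Raise if two expected product sizes cannot be told apart on the gel."""
    sizes = sorted(p.expected_size for p in panel.pairs)
    for a, b in zip(sizes, sizes[1:]):
        if b - a <= 2 * params.size_tolerance:
            raise AmbiguousPanelError(
                f"panel sizes {a} and {b} are within 2 x size tolerance "
                f"({params.size_tolerance} bp); bands would be ambiguous"
            )


def classify_lane(
    lane: GelLane,
    panel: ScarPanel,
    params: PcrParams = PcrParams(),
    authentic_taxa: Iterable[str] = (),
) -> IdentificationResult:
    """Assign each band to a panel taxon and call the sample's status.

    * no band at all -> ``no_amplification``
    * any band matching no taxon -> ``unexplained_bands``
    * only authentic taxa detected -> ``authentic``
    * only non-authentic taxa -> ``adulterant_detected``
    * both -> ``mixed``
    """
    check_panel_resolvable(panel, params)
    authentic = set(authentic_taxa)
    unknown = authentic - set(panel.taxa)
    if unknown:
        raise ConfigError(f"authentic taxa not in panel: {sorted(unknown)}")

    detected: set[str] = set()
    unexplained: list[int] = []
    for size, _count in lane.bands:
        match = [
            p.taxon
            for p in panel.pairs
            if abs(size - p.expected_size) <= params.size_tolerance
        ]
        if match:
            detected.update(match)
        else:
            unexplained.append(size)

    if not lane.bands:
        status = "no_amplification"
    elif unexplained:
        status = "unexplained_bands"
    elif detected <= authentic:
        status = "authentic"
    elif detected & authentic:
        status = "mixed"
    else:
        status = "adulterant_detected"
    return IdentificationResult(
        sample_id=lane.sample_id,
        detected_taxa=frozenset(detected),
        status=status,
        band_sizes=lane.sizes,
        unexplained_sizes=tuple(unexplained),
    )
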