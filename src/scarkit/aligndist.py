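"""Alignment and distance layer.

* progressive multiple alignment (closest-pair-first guide order, consensus
  merge, "once a gap always a gap"),
* Kimura 2-parameter (K2P) distances under pairwise deletion,
* per-taxon variability summaries in the style of a barcode characterization
  table (intra-/inter-taxon mean +/- SD, diagnostic mutation counts),
* neighbor-joining trees with column-bootstrap monophyly support.

The K2P distance separates transitions (A<->G, C<->T; proportion P) from
transversions (proportion Q):

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Sites with a gap or IUPAC ambiguity code in either row are excluded from the
comparison (pairwise deletion), which preserves signal around isolated indel
columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

from .errors import (
    AlignmentShapeError,
    DegenerateInputError,
    SaturationError,
    UndefinedDistanceError,
)
from .seqio import GAP, IUPAC_BASES, SequenceRecord, SpeciesPartition

TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}


# ---------------------------------------------------------------------------
# Alignment container


@dataclass(frozen=True)
class Alignment:
    """Equal-length rows over {A,C,G,T, ambiguity codes, '-'}; 0-based columns."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self):
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) > 1:
            raise AlignmentShapeError(f"row lengths differ: {sorted(lengths)}")
        if not self.records or next(iter(lengths)) < 1:
            raise AlignmentShapeError("alignment needs >=1 row and >=1 column")

    @property
    def n_columns(self) -> int:
        return len(self.records[0].seq)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def row(self, sample_id: str) -> str:
        for r in self.records:
            if r.id == sample_id:
                return r.seq
        raise KeyError(sample_id)

    def column(self, j: int) -> tuple[str, ...]:
        return tuple(r.seq[j] for r in self.records)

    def subset(self, ids: Iterable[str]) -> "Alignment":
        keep = set(ids)
        return Alignment(tuple(r for r in self.records if r.id in keep))


# ---------------------------------------------------------------------------
# Progressive alignment

_aligner_cache: dict[tuple, Align.PairwiseAligner] = {}


def _aligner(match: float, mismatch: float, gap_open: float, gap_extend: float):
    key = (match, mismatch, gap_open, gap_extend)
    if key not in _aligner_cache:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = match
        a.mismatch_score = mismatch
        a.open_gap_score = gap_open
        a.extend_gap_score = gap_extend
        _aligner_cache[key] = a
    return _aligner_cache[key]


def _consensus_of_rows(rows: Sequence[str]) -> str:
    """Majority base per column; gaps lose to any base; ties break by ACGT order."""
    n = len(rows[0])
    out = []
    for j in range(n):
        counts: dict[str, int] = {}
        for r in rows:
            ch = r[j]
            counts[ch] = counts.get(ch, 0) + 1
        base_counts = {b: c for b, c in counts.items() if b != GAP}
        if base_counts:
            best = max(sorted(base_counts), key=lambda b: base_counts[b])
        else:
            best = GAP
        out.append(best)
    return "".join(out)


def _merge_groups(rows_a: list[str], rows_b: list[str], aligner) -> tuple[list[str], list[str]]:
    """Align two alignments via their consensus sequences; existing gaps kept."""
    cons_a = _consensus_of_rows(rows_a).replace(GAP, "N")
    cons_b = _consensus_of_rows(rows_b).replace(GAP, "N")
    aln = aligner.align(cons_a, cons_b)[0]
    new_a, new_b = str(aln[0]), str(aln[1])
    out_a = _expand_rows(rows_a, new_a)
    out_b = _expand_rows(rows_b, new_b)
    return out_a, out_b


def _expand_rows(rows: list[str], gapped_consensus: str) -> list[str]:
    """Insert into every row the gap columns the merge added to the consensus."""
    out = ["" for _ in rows]
    src = 0
    for ch in gapped_consensus:
        if ch == GAP:
            for i in range(len(rows)):
                out[i] += GAP
        else:
            for i, r in enumerate(rows):
                out[i] += r[src]
            src += 1
    assert src == len(rows[0])
    return [*out]


def progressive_align(
    records: Sequence[SequenceRecord],
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
    match: float = 1.0,
    mismatch: float = -1.0,
) -> Alignment:
    """Progressive multiple alignment, deterministic for fixed input order.

    Guide order: pairwise global-alignment scores are computed for all input
    pairs; groups are merged closest (highest-scoring) pair first, with ties
    broken by input order. Group-to-group merges align the two group
    consensus sequences and propagate the new gap columns to every member
    row, so gaps already placed are never removed and ungapping any output
    row returns the corresponding input sequence.
    """
    if len(records) < 2:
        raise DegenerateInputError("progressive alignment needs >=2 sequences")
    aligner = _aligner(match, mismatch, gap_open, gap_extend)
    seqs = [r.ungapped for r in records]
    n = len(seqs)

    score = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            # normalize by length so short identical pairs do not lose to
            # long slightly-divergent pairs
            s = aligner.score(seqs[i], seqs[j]) / max(len(seqs[i]), len(seqs[j]))
            score[i, j] = score[j, i] = s

    groups: list[list[int]] = [[i] for i in range(n)]
    rows: list[list[str]] = [[s] for s in seqs]

    def group_score(a: list[int], b: list[int]) -> float:
        return float(np.mean([score[i, j] for i in a for j in b]))

    while len(groups) > 1:
        best = None
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                s = group_score(groups[gi], groups[gj])
                if best is None or s > best[0] + 1e-12:
                    best = (s, gi, gj)
        _, gi, gj = best
        merged_a, merged_b = _merge_groups(rows[gi], rows[gj], aligner)
        groups[gi] = groups[gi] + groups[gj]
        rows[gi] = merged_a + merged_b
        del groups[gj], rows[gj]

    order = groups[0]
    by_input: dict[int, str] = {idx: rows[0][k] for k, idx in enumerate(order)}
    aligned = tuple(
        SequenceRecord(id=records[i].id, seq=by_input[i], species=records[i].species)
        for i in range(n)
    )
    return Alignment(aligned)


# ---------------------------------------------------------------------------
# K2P distances


@dataclass(frozen=True)
class PairwiseCounts:
    """Transition/transversion proportions over gap- and ambiguity-free sites."""

    P: float
    Q: float
    L: int


def pairwise_counts(row_a: str, row_b: str) -> PairwiseCounts:
    """Count transition/transversion proportions under pairwise deletion."""
    if len(row_a) != len(row_b):
        raise AlignmentShapeError("rows must have equal aligned length")
    L = ts = tv = 0
    for a, b in zip(row_a, row_b):
        if a not in IUPAC_BASES or b not in IUPAC_BASES:
            continue
        L += 1
        if a != b:
            if frozenset((a, b)) in TRANSITION_PAIRS:
                ts += 1
            else:
                tv += 1
    if L == 0:
        raise UndefinedDistanceError("no comparable (gap/ambiguity-free) sites")
    return PairwiseCounts(P=ts / L, Q=tv / L, L=L)


def k2p_distance(counts: PairwiseCounts) -> float:
    """Kimura 2-parameter distance in substitutions/site."""
    w1 = 1.0 - 2.0 * counts.P - counts.Q
    w2 = 1.0 - 2.0 * counts.Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"substitution proportions saturated (P={counts.P:.4f}, Q={counts.Q:.4f})"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_matrix(alignment: Alignment) -> tuple[tuple[str, ...], np.ndarray]:
    """Square symmetric K2P matrix over all rows, zero diagonal."""
    ids = alignment.ids
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dij = k2p_distance(
                pairwise_counts(alignment.records[i].seq, alignment.records[j].seq)
            )
            d[i, j] = d[j, i] = dij
    return ids, d


# ---------------------------------------------------------------------------
# Variability summary


@dataclass(frozen=True)
class VariabilityRow:
    """One taxon's barcode characterization (lengths, K2P variability, mutations)."""

    taxon: str
    its_length_bp: int
    aligned_length_bp: int
    intra_mean: float | None
    intra_sd: float | None
    inter_mean: float
    inter_sd: float
    n_indel_events: int
    n_specific_substitutions: int


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return mean, sd


def summarize_variability(
    alignment: Alignment,
    partition: SpeciesPartition,
    exclude_taxa: Iterable[str] = (),
) -> list[VariabilityRow]:
    """Per-taxon intra/inter K2P variability plus diagnostic mutation counts.

    ``exclude_taxa`` (typically the outgroup) is removed before any
    comparison. Taxa with a single sample get undefined intra fields.
    Distances use pairwise deletion; SD is the sample standard deviation over
    the pairwise distances.
    """
    from .diagnostics import scan_diagnostic_sites  # local import: cycle avoidance

    part = partition.restrict(exclude_taxa)
    part.validate_against(alignment.records)
    aln = alignment.subset(part.assignment.keys())
    ids, dmat = k2p_matrix(aln)
    index = {s: k for k, s in enumerate(ids)}
    summary = scan_diagnostic_sites(alignment, partition, exclude_taxa=exclude_taxa)

    rows: list[VariabilityRow] = []
    for taxon in part.taxa:
        members = [index[s] for s in part.samples_of(taxon)]
        others = [k for k in range(len(ids)) if k not in members]
        intra = [dmat[i, j] for a, i in enumerate(members) for j in members[a + 1:]]
        inter = [dmat[i, j] for i in members for j in others]
        intra_mean, intra_sd = _mean_sd(intra) if intra else (None, None)
        inter_mean, inter_sd = _mean_sd(inter)
        lengths = [len(aln.row(s).replace(GAP, "")) for s in part.samples_of(taxon)]
        modal_len = max(sorted(set(lengths)), key=lengths.count)
        tx = summary.per_taxon[taxon]
        rows.append(
            VariabilityRow(
                taxon=taxon,
                its_length_bp=modal_len,
                aligned_length_bp=alignment.n_columns,
                intra_mean=intra_mean,
                intra_sd=intra_sd,
                inter_mean=inter_mean,
                inter_sd=inter_sd,
                n_indel_events=len(tx.indel_events),
                n_specific_substitutions=len(tx.substitution_sites),
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Neighbor-joining


@dataclass
class PhyloTree:
    """Unrooted tree as an adjacency map; leaves are sample IDs.

    Internal nodes are integers; edges carry (length, support) where support
    is a bootstrap percentage or None (always None on leaf edges).
    """

    adjacency: dict[object, list[tuple[object, float]]]
    leaves: frozenset[str]
    supports: dict[frozenset, float] = field(default_factory=dict)

    def bipartitions(self) -> set[frozenset]:
        """Nontrivial splits, each as a frozenset of its two leaf-set sides."""
        out: set[frozenset] = set()
        seen = set()
        for u, nbrs in self.adjacency.items():
            for v, _ in nbrs:
                key = frozenset((u, v))
                if key in seen:
                    continue
                seen.add(key)
                side = frozenset(self._leaves_beyond(u, v))
                comp = frozenset(self.leaves - side)
                if len(side) >= 2 and len(comp) >= 2:
                    out.add(frozenset((side, comp)))
        return out

    def _leaves_beyond(self, u, v) -> set[str]:
        """Leaves reachable from v when the edge (u, v) is removed."""
        stack, seen, found = [v], {u, v}, set()
        while stack:
            node = stack.pop()
            if node in self.leaves:
                found.add(node)
            for nxt, _ in self.adjacency.get(node, []):
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return found

    def has_clade(self, leafset: Iterable[str]) -> bool:
        """True if the leaf set (or its complement) is an edge bipartition."""
        s = frozenset(leafset)
        if len(s) == 1 or s == self.leaves:
            return True
        if not s <= self.leaves:
            raise KeyError(f"unknown leaves: {sorted(s - self.leaves)}")
        comp = frozenset(self.leaves - s)
        if len(comp) == 1:
            return True  # complement of a single leaf: always a split
        return frozenset((s, comp)) in self.bipartitions()

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        dist = {a: 0.0}
        stack = [a]
        while stack:
            node = stack.pop()
            if node == b:
                break
            for nxt, ln in self.adjacency[node]:
                if nxt not in dist:
                    dist[nxt] = dist[node] + ln
                    stack.append(nxt)
        return dist[b]

    def newick(self) -> str:
        """Newick string rooted at an arbitrary internal node (or leaf for n<3)."""
        root = next(
            (n for n in self.adjacency if n not in self.leaves),
            next(iter(self.adjacency)),
        )

        def render(node, parent) -> str:
            children = [(v, ln) for v, ln in self.adjacency[node] if v != parent]
            if node in self.leaves:
                return node
            inner = ",".join(
                f"{render(v, node)}:{ln:.6f}" for v, ln in children
            )
            label = ""
            if parent is not None:
                side = frozenset(self._leaves_beyond(parent, node))
                sup = self.supports.get(
                    side, self.supports.get(frozenset(self.leaves - side))
                )
                if sup is not None:
                    label = f"{sup:g}"
            return f"({inner}){label}"

        return render(root, None) + ";"


def nj_tree(ids: Sequence[str], dist: np.ndarray) -> PhyloTree:
    """Classic neighbor-joining on a symmetric matrix with zero diagonal.

    Negative branch-length estimates are clamped to 0. On an additive matrix
    leaf-to-leaf path lengths reproduce the input distances.
    """
    n = len(ids)
    if n < 3:
        raise DegenerateInputError("neighbor-joining needs >=3 taxa")
    d = np.array(dist, dtype=float)
    if d.shape != (n, n) or not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be square symmetric with zero diagonal")

    nodes: list[object] = list(ids)
    adjacency: dict[object, list[tuple[object, float]]] = {x: [] for x in ids}
    next_internal = 0
    active = list(range(n))
    D = d.copy()

    def link(a, b, ln):
        ln = max(0.0, float(ln))
        adjacency.setdefault(a, []).append((b, ln))
        adjacency.setdefault(b, []).append((a, ln))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(q), q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = D[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2 * (m - 2))
        lj = dij - li
        new = f"@{next_internal}"
        next_internal += 1
        nodes.append(new)
        link(nodes[i], new, li)
        link(nodes[j], new, lj)
        # distances from the new node
        newdist = 0.5 * (D[i, active] + D[j, active] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        k = D.shape[0] - 1
        D[k, active] = newdist
        D[active, k] = newdist
        active = [x for x in active if x not in (i, j)] + [k]
        assert len(nodes) == D.shape[0]

    i, j, k = active
    center = f"@{next_internal}"
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        link(nodes[idx], center, ln)

    # internal node names -> opaque objects (keep strings only for leaves)
    leafset = frozenset(ids)
    return PhyloTree(adjacency=adjacency, leaves=leafset)


# ---------------------------------------------------------------------------
# Bootstrap monophyly


@dataclass(frozen=True)
class MonophylyResult:
    taxon: str
    is_monophyletic: bool | None
    support: float | None


def monophyly_support(
    alignment: Alignment,
    partition: SpeciesPartition,
    n_replicates: int = 100,
    seed: int = 0,
    exclude_taxa: Iterable[str] = (),
) -> list[MonophylyResult]:
    """Column-bootstrap NJ monophyly support per taxon.

    Support is the percentage of replicate NJ trees (alignment columns
    resampled with replacement) in which the taxon's samples form one side
    of an edge bipartition. Single-sample taxa are trivially monophyletic
    with support 100. A panel of identical sequences has no resolving signal
    and yields an undefined (None) call.
    """
    part = partition.restrict(exclude_taxa)
    part.validate_against(alignment.records)
    aln = alignment.subset(part.assignment.keys())
    ids, d = k2p_matrix(aln)
    rng = np.random.default_rng(seed)

    results: list[MonophylyResult] = []
    if not np.any(d > 0):
        for taxon in part.taxa:
            if len(part.samples_of(taxon)) == 1:
                results.append(MonophylyResult(taxon, True, 100.0))
            else:
                results.append(MonophylyResult(taxon, None, None))
        return results

    full_tree = nj_tree(ids, d)
    rows = {r.id: r.seq for r in aln.records}
    ncol = aln.n_columns
    clade_hits = {taxon: 0 for taxon in part.taxa}
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep_rows = {
            s: "".join(rows[s][c] for c in cols) for s in ids
        }
        rep_aln = Alignment(
            tuple(SequenceRecord(id=s, seq=rep_rows[s]) for s in ids)
        )
        try:
            rep_ids, rep_d = k2p_matrix(rep_aln)
            rep_tree = nj_tree(rep_ids, rep_d)
        except (UndefinedDistanceError, SaturationError):
            continue
        for taxon in part.taxa:
            members = set(part.samples_of(taxon))
            if len(members) == 1 or rep_tree.has_clade(members):
                clade_hits[taxon] += 1

    for taxon in part.taxa:
        members = set(part.samples_of(taxon))
        if len(members) == 1:
            results.append(MonophylyResult(taxon, True, 100.0))
        else:
            results.append(
                MonophylyResult(
                    taxon,
                    full_tree.has_clade(members),
                    100.0 * clade_hits[taxon] / n_replicates,
                )
            )
    return results
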