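import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import scarkit as sk
from scarkit.aligndist import (
    Alignment,
    k2p_distance,
    k2p_matrix,
    monophyly_support,
    nj_tree,
    pairwise_counts,
    progressive_align,
    summarize_variability,
)
from scarkit.errors import (
    DegenerateInputError,
    SaturationError,
    UndefinedDistanceError,
)


def _rec(i, s):
    return sk.SequenceRecord(id=f"s{i}", seq=s)


# ---------------------------------------------------------------------------
# Pairwise counts / K2P


@pytest.mark.parametrize(
    "a, b, P, Q, L",
    [
        ("ACGT", "ACGT", 0.0, 0.0, 4),
        ("ACGT", "GCGT", 0.25, 0.0, 4),  # A->G transition
        ("AC-T", "ACGT", 0.0, 0.0, 3),  # gap column excluded
        ("ACNT", "ACGT", 0.0, 0.0, 3),  # ambiguity excluded
        ("ACGT", "AGGT", 0.0, 0.25, 4),  # C->G transversion
    ],
)
def test_pairwise_counts(a, b, P, Q, L):
    c = pairwise_counts(a, b)
    assert (c.P, c.Q, c.L) == (pytest.approx(P), pytest.approx(Q), L)


def test_pairwise_counts_all_gaps_is_undefined():
    with pytest.raises(UndefinedDistanceError):
        pairwise_counts("--N-", "AC-T")


@pytest.mark.parametrize(
    "P, Q, expected",
    [
        (0.0, 0.0, 0.0),
        (0.1, 0.05, -0.5 * math.log(0.75) - 0.25 * math.log(0.9)),  # 0.17018
        (0.01, 0.0, -0.5 * math.log(0.98)),  # 0.010101
    ],
)
def test_k2p_distance_closed_form(P, Q, expected):
    d = k2p_distance(sk.PairwiseCounts(P=P, Q=Q, L=100))
    assert d == pytest.approx(expected, abs=1e-9)
    assert round(d, 5) == round(expected, 5)


def test_k2p_saturation_raises_not_nan():
    with pytest.raises(SaturationError):
        k2p_distance(sk.PairwiseCounts(P=0.5, Q=0.0, L=10))
    with pytest.raises(SaturationError):
        k2p_distance(sk.PairwiseCounts(P=0.0, Q=0.5, L=10))


aligned_pair = st.integers(1, 40).flatmap(
    lambda n: st.tuples(
        st.text(alphabet="ACGT", min_size=n, max_size=n),
        st.text(alphabet="ACGT-", min_size=n, max_size=n),
    )
)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(aligned_pair)
def test_k2p_symmetry_and_p_distance_bound(pair):
    a, b = pair
    try:
        cab, cba = pairwise_counts(a, b), pairwise_counts(b, a)
    except UndefinedDistanceError:
        return
    assert (cab.P, cab.Q, cab.L) == (cba.P, cba.Q, cba.L)
    try:
        d = k2p_distance(cab)
    except SaturationError:
        return
    assert d == pytest.approx(k2p_distance(cba))
    # rate-corrected distance never undershoots the raw p-distance
    assert d >= cab.P + cab.Q - 1e-12


# ---------------------------------------------------------------------------
# Progressive alignment


def _needleman_wunsch(a, b, match=1, mismatch=-1, gap=-2):
    """Tiny independent global aligner (linear gaps) used as an oracle."""
    n, m = len(a), len(b)
    score = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = i * gap
    for j in range(1, m + 1):
        score[0][j] = j * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            score[i][j] = max(
                score[i - 1][j - 1] + s, score[i - 1][j] + gap, score[i][j - 1] + gap
            )
    # traceback
    out_a, out_b = [], []
    i, j = n, m
    while i or j:
        if i and j and score[i][j] == score[i - 1][j - 1] + (
            match if a[i - 1] == b[j - 1] else mismatch
        ):
            out_a.append(a[i - 1]); out_b.append(b[j - 1]); i -= 1; j -= 1
        elif i and score[i][j] == score[i - 1][j] + gap:
            out_a.append(a[i - 1]); out_b.append("-"); i -= 1
        else:
            out_a.append("-"); out_b.append(b[j - 1]); j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def test_identical_sequences_align_without_gaps():
    aln = progressive_align([_rec(1, "ACGTACGT"), _rec(2, "ACGTACGT")])
    assert [r.seq for r in aln.records] == ["ACGTACGT", "ACGTACGT"]


def test_single_deletion_yields_one_gap_column():
    a, b = "ACGTACGT", "ACGACGT"
    aln = progressive_align([_rec(1, a), _rec(2, b)])
    assert aln.n_columns == 8
    gap_cols = [
        j for j in range(aln.n_columns) if "-" in {r.seq[j] for r in aln.records}
    ]
    assert len(gap_cols) == 1
    # independent oracle agrees on the gap count
    oa, ob = _needleman_wunsch(a, b)
    assert (oa + ob).count("-") == 1


def test_single_record_is_degenerate():
    with pytest.raises(DegenerateInputError):
        progressive_align([_rec(1, "ACGT")])


def test_ungap_identity_and_determinism_on_fixture_panel(panel_fixture):
    aln_true, _part, _truth = panel_fixture
    unaligned = sk.unaligned_records(aln_true)
    aln1 = progressive_align(unaligned)
    aln2 = progressive_align(unaligned)
    assert [r.seq for r in aln1.records] == [r.seq for r in aln2.records]
    for out, inp in zip(aln1.records, unaligned):
        assert out.id == inp.id
        assert out.ungapped == inp.seq
    # near-identical ITS-like panel with one 1-bp insertion realigns to 690
    assert aln1.n_columns == aln_true.n_columns == 690


# ---------------------------------------------------------------------------
# Variability summary


def _panel_alignment():
    # two taxa, two identical samples each, cross pairs all at one distance
    rows = [
        ("a1", "AAAAAAAAAA", "X"),
        ("a2", "AAAAAAAAAA", "X"),
        ("b1", "GAAAAAAAAA", "Y"),
        ("b2", "GAAAAAAAAA", "Y"),
    ]
    aln = Alignment(tuple(sk.SequenceRecord(id=i, seq=s, species=t) for i, s, t in rows))
    part = sk.SpeciesPartition.from_pairs([(i, t) for i, s, t in rows])
    return aln, part


def test_identical_within_taxon_gives_zero_intra():
    aln = Alignment(tuple(_rec(i, "ACGTACGT") for i in range(3)))
    part = sk.SpeciesPartition.from_pairs([(f"s{i}", "A") for i in range(3)])
    # add a distinct second taxon so inter distances exist
    aln = Alignment(aln.records + (sk.SequenceRecord(id="t0", seq="ACGTACGA"),))
    part = sk.SpeciesPartition.from_pairs(
        [(f"s{i}", "A") for i in range(3)] + [("t0", "B")]
    )
    rows = summarize_variability(aln, part)
    row_a = next(r for r in rows if r.taxon == "A")
    assert row_a.intra_mean == 0.0 and row_a.intra_sd == 0.0


def test_constant_cross_distance_gives_inter_sd_zero():
    aln, part = _panel_alignment()
    rows = summarize_variability(aln, part)
    d0 = k2p_distance(pairwise_counts("AAAAAAAAAA", "GAAAAAAAAA"))
    for row in rows:
        assert row.inter_mean == pytest.approx(d0)
        assert row.inter_sd == pytest.approx(0.0)
        assert row.intra_mean == pytest.approx(0.0)


def test_variability_single_sample_taxon_has_undefined_intra():
    aln, part = _panel_alignment()
    part2 = sk.SpeciesPartition.from_pairs(
        [("a1", "X"), ("a2", "X"), ("b1", "Y"), ("b2", "Z")]
    )
    rows = summarize_variability(aln, part2)
    row_z = next(r for r in rows if r.taxon == "Z")
    assert row_z.intra_mean is None and row_z.intra_sd is None


def test_variability_is_invariant_to_record_order(panel_fixture):
    aln, part, _truth = panel_fixture
    rows = summarize_variability(aln, part)
    flipped = Alignment(tuple(reversed(aln.records)))
    rows_flipped = summarize_variability(flipped, part)
    assert rows == rows_flipped


def test_variability_counts_match_diagnostics(panel_fixture):
    aln, part, truth = panel_fixture
    rows = {r.taxon: r for r in summarize_variability(aln, part)}
    for taxon in part.taxa:
        assert rows[taxon].n_specific_substitutions == len(truth.substitutions[taxon])
    assert rows["taxonC"].n_indel_events == 1
    assert rows["taxonC"].its_length_bp == 690  # carries the 1-bp insertion
    assert rows["taxonA"].its_length_bp == 689


# ---------------------------------------------------------------------------
# Neighbor-joining


def test_nj_three_taxon_closed_form():
    ids = ("a", "b", "c")
    d = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
    tree = nj_tree(ids, d)
    # unique 3-leaf star: leaf branches (1, 1, 2)
    lengths = {
        leaf: tree.adjacency[leaf][0][1] for leaf in ids
    }
    assert lengths == {"a": 1.0, "b": 1.0, "c": 2.0}
    for x, y in itertools.combinations(ids, 2):
        assert tree.path_length(x, y) == pytest.approx(d[ids.index(x), ids.index(y)])


def test_nj_all_zero_matrix_gives_zero_branches():
    ids = ("a", "b", "c", "d")
    tree = nj_tree(ids, np.zeros((4, 4)))
    for node, nbrs in tree.adjacency.items():
        for _other, length in nbrs:
            assert length == 0.0


def test_nj_fewer_than_three_taxa_is_degenerate():
    with pytest.raises(DegenerateInputError):
        nj_tree(("a", "b"), np.zeros((2, 2)))


def _additive_matrix(ids, edges, topology_paths):
    """Path-length matrix of a leaf-labeled tree given leaf->leaf edge paths."""
    n = len(ids)
    d = np.zeros((n, n))
    for (i, j), path in topology_paths.items():
        d[i, j] = d[j, i] = sum(edges[e] for e in path)
    return d


def test_nj_recovers_four_taxon_topology_against_brute_force():
    # true tree: ((a,b),(c,d)) with internal edge e
    ids = ("a", "b", "c", "d")
    ea, eb, ec, ed, e = 1.0, 2.0, 1.5, 0.5, 3.0
    d = np.array(
        [
            [0, ea + eb, ea + e + ec, ea + e + ed],
            [ea + eb, 0, eb + e + ec, eb + e + ed],
            [ea + e + ec, eb + e + ec, 0, ec + ed],
            [ea + e + ed, eb + e + ed, ec + ed, 0],
        ]
    )
    tree = nj_tree(ids, d)
    # brute force: of the three unrooted quartet topologies, only ab|cd fits
    assert tree.has_clade({"a", "b"})
    assert tree.has_clade({"c", "d"})
    assert not tree.has_clade({"a", "c"})
    assert not tree.has_clade({"a", "d"})
    # additive recovery: path lengths reproduce the input
    for i, x in enumerate(ids):
        for j, y in enumerate(ids):
            if i < j:
                assert tree.path_length(x, y) == pytest.approx(d[i, j])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.integers(4, 6))
def test_nj_additive_recovery_on_random_trees(seed, n_leaves):
    """NJ on the path-length matrix of a random binary tree recovers it."""
    rng = np.random.default_rng(seed)
    ids = tuple(f"L{i}" for i in range(n_leaves))
    # build a random unrooted binary tree by sequential leaf attachment
    adjacency = {ids[0]: [], ids[1]: [], ids[2]: []}
    center = "I0"
    adjacency[center] = []

    def link(u, v, ln):
        adjacency.setdefault(u, []).append((v, ln))
        adjacency.setdefault(v, []).append((u, ln))

    def blen():
        return float(rng.uniform(0.5, 3.0))

    edges = []
    for leaf in ids[:3]:
        link(leaf, center, blen())
        edges.append((leaf, center))
    for k, leaf in enumerate(ids[3:], start=1):
        u, v = edges[rng.integers(0, len(edges))]
        # split edge (u,v) with a new internal node, attach the new leaf
        new = f"I{k}"
        old_len = next(ln for x, ln in adjacency[u] if x == v)
        adjacency[u] = [(x, ln) for x, ln in adjacency[u] if x != v]
        adjacency[v] = [(x, ln) for x, ln in adjacency[v] if x != u]
        half = old_len / 2
        link(u, new, half)
        link(v, new, half)
        link(leaf, new, blen())
        edges.remove((u, v))
        edges += [(u, new), (v, new), (leaf, new)]

    true_tree = sk.PhyloTree(adjacency=adjacency, leaves=frozenset(ids))
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = true_tree.path_length(ids[i], ids[j])
    recovered = nj_tree(ids, d)
    assert recovered.bipartitions() == true_tree.bipartitions()
    for i in range(n):
        for j in range(i + 1, n):
            assert recovered.path_length(ids[i], ids[j]) == pytest.approx(d[i, j])


# ---------------------------------------------------------------------------
# Monophyly support


def test_single_sample_taxon_is_trivially_monophyletic(panel_fixture):
    aln, part, _ = panel_fixture
    # relabel one sample as its own taxon
    pairs = [(s, t) for s, t in part.assignment.items()]
    pairs[0] = (pairs[0][0], "loner")
    part2 = sk.SpeciesPartition.from_pairs(pairs)
    res = {m.taxon: m for m in monophyly_support(aln, part2, 10, seed=0)}
    assert res["loner"].is_monophyletic is True
    assert res["loner"].support == 100.0


def test_planted_panel_taxa_are_monophyletic_with_high_support(panel_fixture):
    aln, part, _ = panel_fixture
    res = monophyly_support(aln, part, n_replicates=100, seed=42)
    for m in res:
        assert m.is_monophyletic is True
        assert m.support >= 95.0


def test_identical_sequences_give_undefined_monophyly():
    records = tuple(_rec(i, "ACGTACGTAC") for i in range(6))
    aln = Alignment(records)
    part = sk.SpeciesPartition.from_pairs(
        [(f"s{i}", "A" if i < 3 else "B") for i in range(6)]
    )
    res = {m.taxon: m for m in monophyly_support(aln, part, 10, seed=0)}
    assert res["A"].is_monophyletic is None
    assert res["B"].is_monophyletic is None


def test_monophyly_is_deterministic_for_fixed_seed(panel_fixture):
    aln, part, _ = panel_fixture
    r1 = monophyly_support(aln, part, n_replicates=30, seed=7)
    r2 = monophyly_support(aln, part, n_replicates=30, seed=7)
    assert r1 == r2
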