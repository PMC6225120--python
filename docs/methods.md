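# Methods

This note records the models, rules, parameter defaults, and numerical
choices behind `scarkit`, and what its synthetic panels do and do not show
about real data.

## Sequence model and normalization

Sequences are DNA strings over A/C/G/T plus IUPAC ambiguity codes and `-`
for gaps. On input everything is upper-cased, `U` is mapped to `T` (RNA
dialects) and `.` to `-` (alternative gap spelling). Duplicate record IDs
are an error rather than silently suffixed: in authentication work each
record traces to a voucher sample and must stay unique.

## Progressive alignment

`progressive_align` is a guide-order progressive aligner for near-identical
barcode panels. All pairwise global-alignment scores are computed first
(affine gaps; defaults match +1, mismatch −1, gap open −5, gap extend −1);
groups are then merged closest pair first, ties broken by input order.
A group-to-group merge aligns the two group consensus sequences (majority
base per column; the pairwise DP kernel is Biopython's `PairwiseAligner`)
and propagates the new gap columns to every member row — the classic "once a
gap, always a gap" rule — so ungapping any output row always returns the
corresponding input sequence exactly. For the intended regime (sequences
diverging by a few percent with at most short indels) consensus merging is
effectively exact; it is *not* a general-purpose MSA method and will degrade
on deeply diverged inputs.

Pairwise scores are normalized by the longer sequence length before guide
clustering so that short identical pairs are not outranked by long,
slightly divergent ones.

## Distances and trees

**K2P.** `pairwise_counts` compares two aligned rows under *pairwise
deletion*: any site with a gap or ambiguity code in either row is excluded
from the compared length L. Transitions are A↔G and C↔T; everything else
differing is a transversion. The Kimura 2-parameter distance is
`d = −½ ln(1−2P−Q) − ¼ ln(1−2Q)` (substitutions/site). Saturated inputs
(either log argument ≤ 0) raise a typed error instead of returning NaN;
L = 0 raises an undefined-distance error. Pairwise deletion was chosen over
complete deletion because a single taxon-exclusive indel column would
otherwise discard signal for every pair; distances are reported to 4
decimals.

**Variability summary.** Per taxon: modal ungapped length, aligned length,
intra-taxon mean ± SD over all within-taxon pairwise K2P distances
(undefined for single-sample taxa), inter-taxon mean ± SD over all pairs
with exactly one member in the taxon (any designated outgroup excluded
first). The ± value is the sample standard deviation (ddof = 1) over the
pairwise distances. Diagnostic mutation counts are delegated to the scanner
below.

**Neighbor-joining.** Classic NJ on the K2P matrix; negative branch-length
estimates are clamped to 0. On an additive matrix the leaf-to-leaf path
lengths reproduce the input distances and the topology is recovered (tested
against brute-force quartet enumeration and random 4–6-leaf trees). NJ was
chosen over likelihood methods deliberately: it is deterministic, runs in
milliseconds at panel scale, and the monophyly conclusions drawn from these
barcode panels are distance-driven. Monophyly of a taxon is evaluated on the
unrooted tree as an edge bipartition separating exactly the taxon's samples
— no rooting is needed. Bootstrap support is the percentage of
column-resampled (with replacement) NJ replicates in which that bipartition
reappears; single-sample taxa are reported trivially monophyletic at 100.
A panel of identical sequences has no resolving signal: the call is reported
as undefined (`None`) rather than pretending a star tree supports anything.

## Diagnostic sites

A **substitution site** for taxon T is an alignment column where (i) every
T sample carries the same unambiguous base, (ii) that base occurs in no
sample outside T, and (iii) no T sample is gapped there. Non-target samples
need not agree among themselves, so with three taxa a three-way-different
column is diagnostic for all three — each taxon's count lists it
independently. Two deliberately conservative rules: any IUPAC ambiguity code
in the column disqualifies it for every taxon (a marker anchored on an
uncertain base is not trustworthy), and a column where *all* non-target
samples are gapped is treated as pure indel signal, not additionally as a
substitution site.

An **indel event** is a maximal run of consecutive columns gapped in every
T sample and ungapped in every other sample, or the inverse; a multi-column
run counts once. Events are reported from each taxon's perspective, so a
run that is an insertion for one taxon appears as the mirrored deletion for
the taxa on the other side when (and only when) those taxa are each
uniform against all remaining samples.

`diagnostic_windows` enumerates one candidate anchoring window per site,
centered on it (start = site − window/2, clipped to the alignment), and
returns windows holding at least `min_sites` sites sorted by site count then
position. Centering on sites rather than sliding a stride-1 window gives one
natural window per site cluster instead of dozens of near-duplicates.

## Primer design

Primer sequences are read off the **taxon consensus** (majority base per
column, gaps dropped); any intra-taxon polymorphic column inside a
candidate's footprint disqualifies it — a species-specific primer must
amplify *all* authentic samples, so it may only sit on sequence fixed within
the taxon.

A candidate must:

* have length 18–25 nt (default), melting temperature 58–72 °C, GC 40–70%;
* cover ≥ 1 diagnostic substitution site within its 3′-terminal 3 nt
  (forward primers anchor near their right edge, reverse primers — written
  5′→3′ as synthesized, binding the plus strand as their reverse
  complement — near the left edge of their plus-strand footprint); the
  3′-terminal mismatch against every non-target is what blocks extension on
  the wrong species;
* differ from every non-target taxon consensus at ≥ 2 positions over its
  footprint (default), so specificity never hangs on a single base;
* occur exactly once on its strand in its own taxon consensus.

**Melting temperature** uses the Wallace rule 2(A+T)+4(G+C) for ≤ 14 nt and
the nearest-neighbor model (SantaLucia unified parameters, via Biopython)
for longer primers, evaluated under PCR-buffer conditions — 50 mM monovalent
salt, 2.5 mM Mg²⁺, 0.8 mM total dNTPs, 0.5 µM primer — i.e., the chemistry
of a standard hot-start multiplex reaction; under these conditions typical
species-diagnostic primers of this length land in the high-50s to low-70s
°C, matching the default design window.

**Panel selection** considers, per taxon, every forward/reverse combination
with a ≥ 20 bp spacer (or any non-overlapping placement when explicit
forward/reverse regions are annotated) and an amplicon of 100–400 bp
(primers inclusive; short targets still amplify from degraded DNA). Among
all cross-taxon size combinations it picks the one **maximizing the minimum
pairwise size gap**, requiring at least 40 bp (two bands closer than that
are hard to call on agarose); ties prefer the smaller total product size,
then the lexicographically smallest size tuple. When there are hundreds of
distinct candidate sizes per taxon, the search subsamples each taxon's
sorted size list evenly (endpoints kept, ≥ ~58 sizes/taxon for three taxa)
— a resolution loss of a few bp at most against a 40 bp constraint. Each
chosen panel is verified by the in-silico PCR engine against every input
sample (exactly one product of the predicted size on targets, zero on
non-targets) before being returned; if no combination reaches the gap, an
infeasibility error reports the best achievable gap. Infeasibility is a
real outcome, not a bug: a taxon whose diagnostic sites are isolated (one
site cannot satisfy the 2-mismatch floor) or sit in GC-extreme sequence
(Tm out of window) may admit no valid candidate on one strand.

## In-silico PCR

A primer binds wherever its total mismatch count is within budget **and**
its 3′-terminal clamp (default 3 nt) matches exactly. Both strands of every
template are scanned; overlapping sites are all reported. Products are
enumerated between any plus-strand site and any minus-strand site of the
two primers of a pair with 3′ ends facing each other — in either role
order, so the engine is strand-symmetric: reverse-complementing a template
leaves its band multiset unchanged. Coordinates are 0-based half-open;
primers are included in the product size (a template built as
forward + 215-nt spacer + revcomp(reverse) with 22-nt primers yields exactly
22+215+22 = 259 bp). Cross-pair products (forward of one taxon with reverse
of another) are emitted flagged when requested — a real multiplex risk the
designer should screen.

Defaults: 0 mismatches for design verification; a survey mode (2 mismatches,
clamp 3) for classifying query material that may diverge slightly from the
panel's source alignment. The wet assay's true mismatch tolerance is a
property of the chemistry that cannot be derived in silico; both regimes are
exposed as flags.

**Classification.** Each band is assigned to the panel taxon whose expected
size lies within ± 3 bp (panels with two expected sizes closer than twice
the tolerance are rejected at configuration time). A sample is `authentic`
if only authentic taxa are detected, `adulterant_detected` if only
non-authentic ones, `mixed` if both, `no_amplification` if the lane is
empty, and `unexplained_bands` if any band matches no taxon. Band intensity
is modeled only as the count of distinct co-migrating amplicons; real-gel
intensity effects (DNA quality, competition between pairs in one tube) are
out of computational scope.

## Synthetic panels

`generate_panel` emulates the data regime of a small ITS barcode survey of
closely related species: a 690-bp uniform-random ancestral sequence; per
taxon a fixed set of planted substitutions (defaults 18/10/16 for three
taxa, transition with probability 0.5 so both K2P terms are exercised); one
1-bp taxon-exclusive insertion in the third taxon; and per-sample
polymorphisms at rate 0.002 (one or two variable sites per sample, as in
near-clonal ITS data). Two conserved flanks, defaulting to columns
[70, 200) and [340, 460), mimic the ITS1/ITS2 spacers around the 5.8S gene
where the forward and reverse primers of such assays sit; at least 3 planted
sites per taxon land in each flank, and the flank geometry is chosen so any
cross-flank amplicon fits the default 100–400 bp design range. Planted
features never overlap, and random polymorphisms avoid planted columns and
the flanks, so the scanner's output is comparable to the planted truth
*exactly* — this is what makes 100%-precision/recall closed-loop tests
meaningful.

What the panels do **not** model: sequencing and PCR error, chimeric reads,
intragenomic ITS paralogs, alignment uncertainty (the emitted alignment is
correct by construction), taxa sharing derived states through incomplete
lineage sorting, and polymorphism *inside* conserved flanks. Passing the
closed-loop tests therefore demonstrates the pipeline's internal
correctness, not robustness to those real-data failure modes; on real
panels the conservative scanner rules (ambiguity disqualification, fixity
requirements) are the first line of defense.

With one sample per taxon every private polymorphism is indistinguishable
from a fixed difference — the defaults use four samples per taxon, mirroring
the survey design practice of sampling each species from several sites.

## Numerical and degenerate-input choices

* Saturated K2P input raises `SaturationError`; zero comparable sites raises
  `UndefinedDistanceError` — never NaN.
* NJ requires ≥ 3 taxa (`DegenerateInputError` otherwise); an all-zero
  matrix yields all-zero branch lengths.
* Consensus ties (equal base counts in a column) break deterministically in
  A < C < G < T order; determinism end to end is part of the contract
  (same seed ⇒ byte-identical outputs, tested).
* Bootstrap replicates that produce an undefined distance (a resampled
  alignment can lose all comparable sites for a pair) are skipped and do
  not count toward support.
* The acceptance script derives any seed it uses from `--seed` and keeps it
  below 2³¹.

## Known limitations

* The aligner's consensus-merge heuristic targets near-identical panels;
  deep divergence or long indels call for a dedicated MSA tool upstream
  (aligned FASTA can be supplied directly to every stage).
* Primer thermodynamics stop at Tm/GC windows plus the 3′ clamp; hairpin and
  cross-dimer screening beyond exact-footprint checks is out of scope.
* The classifier trusts the size ladder; co-migrating off-panel products
  from unconsidered species would be reported as (possibly misleading)
  taxon matches — panels should be designed against every plausible
  adulterant, not only the known ones.
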