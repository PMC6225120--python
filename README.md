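# scarkit

Design and in-silico validation of **multiplex SCAR marker panels** from
DNA-barcode alignments, for the authentication of processed biological
material (herbal medicines, foodstuffs) where morphology no longer tells
species apart.

## The problem

An official herbal material is often the dried root of one or two closely
related species, while look-alike relatives circulate in the same markets as
adulterants. A DNA barcode such as the nuclear ribosomal **ITS** region
separates such species cleanly — but full barcoding (amplify, sequence,
compare) is slow, costly, and fails on the degraded DNA of processed
material. A **SCAR** (sequence-characterized amplified region) assay fixes
both problems: species-specific primer pairs, anchored on diagnostic
polymorphisms, each amplify a short fragment *only* from their own species,
and the fragments are sized so that one multiplex PCR reaction reads out as
a band ladder on an agarose gel — one band per species present, no
sequencing required.

`scarkit` implements the full desk side of that workflow:

1. **Align** the labeled barcode panel (progressive alignment; for
   near-identical barcodes any sane parameters give the same answer).
2. **Characterize** it: Kimura 2-parameter distances under pairwise
   deletion, per-taxon intra/inter variability (mean ± SD), neighbor-joining
   tree with column-bootstrap monophyly support. The K2P distance separates
   transition (P) and transversion (Q) proportions:
   `d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)`.
3. **Scan** for diagnostic sites: columns where one taxon is fixed for a
   base no other sample carries (substitutions), and taxon-exclusive gap
   runs (indels).
4. **Design** primer candidates on the taxon consensus with a diagnostic
   base in the 3′-terminal window against every non-target (a 3′ mismatch
   blocks Taq extension), filtered by length, Tm, GC, and cross-taxon
   mismatch floors; then pick one pair per taxon maximizing the minimum
   pairwise product-size gap of the ladder.
5. **Simulate** the multiplex PCR (binding = mismatch budget + exact
   3′ clamp, both strands, cross-pair artifacts on request), render virtual
   gel lanes, and **classify** query samples as
   `authentic / adulterant_detected / mixed / no_amplification /
   unexplained_bands`.
6. **Generate** synthetic barcode panels with planted ground truth
   (`simulate-panel`), so every stage is testable end to end.

## Worked example

Simulate a three-taxon ITS-like panel (690 bp, 18/10/16 planted
species-specific substitutions, one 1-bp insertion, low intra-taxon
polymorphism), design a multiplex panel on it, and authenticate the samples:

```bash
scarkit simulate-panel --outdir panel --seed 7
scarkit design panel/panel.aligned.fasta --sheet panel/panel.samples.tsv \
        --out panel_designed.tsv
# INFO scarkit: panel sizes: {'taxonA': 382, 'taxonB': 260, 'taxonC': 100} (min gap 122 bp)
scarkit classify panel/panel.fasta --panel panel_designed.tsv \
        --authentic taxonA --out calls.tsv
```

`panel_designed.tsv` holds one primer pair per taxon in the conventional
panel layout:

```
taxon   primer_name  sequence                   product_size
taxonA  taxonA-F     CCCATAAATGTAGCCAGTGAGCTGT  382
taxonA  taxonA-R     AAAATGAGACGGATCGTTGAGCTTG  382
taxonB  taxonB-F     CCCCTAAGCTATACTAGGCAGTT    260
...
```

The three products (100, 260, 382 bp) are pairwise ≥ 122 bp apart — easily
resolved on a 1.5–2% gel. `calls.tsv` then reads the virtual gel per sample:

```
sample    bands  detected_taxa  status
taxonA-1  382    taxonA         authentic
taxonB-1  260    taxonB         adulterant_detected
...
```

Every `taxonA` sample shows exactly the 382-bp band (`authentic`); every
other sample shows exactly its own species' band (`adulterant_detected`).
A lane holding both would be called `mixed` — the signature of contaminated
material.

The same subcommands work on real data: any unaligned/aligned multi-FASTA
plus a two-column sample sheet (`id<TAB>taxon`), and any primer panel TSV in
the layout above (a published panel can be typed in directly and used with
`pcr`/`classify` without running design).

## Layout

| Module                | Role                                                        |
| --------------------- | ----------------------------------------------------------- |
| `scarkit.seqio`       | FASTA, sample sheet, primer TSV, report I/O                  |
| `scarkit.aligndist`   | progressive alignment, K2P, variability, NJ + bootstrap      |
| `scarkit.diagnostics` | diagnostic substitution/indel scan, anchoring windows        |
| `scarkit.scar_design` | Tm/GC filters, candidate enumeration, panel selection        |
| `scarkit.vpcr`        | binding sites, multiplex simulation, gel lanes, classifier   |
| `scarkit.fixtures`    | synthetic panels with planted truth                          |
| `scarkit.cli`         | `scarkit` command with the subcommands used above            |

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
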