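import pytest

import scarkit as sk

# Printed primer panel of the published ITS assay (three Angelica taxa);
# used as parsing input and for the synthetic-template worked example.
TABLE_PANEL_TSV = """\
taxon\tprimer_name\tsequence\tproduct_size
dahurica\tADA-F\tATCGGCGTCTTTCCAAAATGC\t183
dahurica\tADA-R\tGCACAACTTCTCAGGTGTGCCT\t183
anomala\tAAN-F\tAAAATCATTCAGGCGCGGAGAG\t259
anomala\tAAN-R\tAAACCGGCACAACTTCTCATGT\t259
japonica\tAJA-F\tGGCCACTCCTGGGTGGCCAGAG\t309
japonica\tAJA-R\tCGGGAGGCCAGTTTCCGCCAGA\t309
"""


@pytest.fixture(scope="session")
def assay_panel() -> sk.ScarPanel:
    """The published three-pair multiplex panel as a ScarPanel."""
    pairs = (
        sk.ScarPrimerPair("dahurica", "ATCGGCGTCTTTCCAAAATGC",
                          "GCACAACTTCTCAGGTGTGCCT", 183),
        sk.ScarPrimerPair("anomala", "AAAATCATTCAGGCGCGGAGAG",
                          "AAACCGGCACAACTTCTCATGT", 259),
        sk.ScarPrimerPair("japonica", "GGCCACTCCTGGGTGGCCAGAG",
                          "CGGGAGGCCAGTTTCCGCCAGA", 309),
    )
    return sk.ScarPanel.from_pairs(pairs)


@pytest.fixture(scope="session")
def panel_fixture():
    """Default synthetic panel: alignment, partition, planted truth (seed 1)."""
    return sk.generate_panel(sk.PanelConfig(seed=1))


@pytest.fixture(scope="session")
def designed_panel(panel_fixture):
    """A multiplex panel designed end-to-end on the seed-1 synthetic panel."""
    aln, part, _truth = panel_fixture
    summary = sk.scan_diagnostic_sites(aln, part)
    constraints = sk.DesignConstraints()
    candidates = {
        t: sk.enumerate_candidates(aln, part, summary, t, constraints)
        for t in part.taxa
    }
    return sk.select_multiplex_panel(
        candidates, constraints, alignment=aln, partition=part
    )
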