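"""Shared fixtures: a hand-built genome with known codon layout, and a
session-scoped synthetic demo bundle for pipeline-level tests."""

import pytest

from phagevolve.genome import Orf, PhageGenome, TrnaGene, revcomp

# ORF1 (+): 10 codons at 11..40; codon 2 = ACC (Thr), codon 3 = GGT (Gly),
# codon 8 = TAT (Tyr, one change from a stop).
ORF1_CODING = "ATG" "ACC" "GGT" "TTT" "AAA" "CCC" "GGG" "TAT" "CAT" "TAA"
# ORF2 (-): 5 codons whose reverse complement sits at 51..65.
ORF2_CODING = "ATG" "ACA" "GGT" "ACC" "TGA"


@pytest.fixture
def toy_genome() -> PhageGenome:
    seq = (
        "ACGTACGTAC"            # 1..10   intergenic
        + ORF1_CODING           # 11..40  ORF1 on +
        + "GGGGGGGGGG"          # 41..50  intergenic
        + revcomp(ORF2_CODING)  # 51..65  ORF2 on -
        + "ACGTA"               # 66..70  intergenic
    )
    return PhageGenome(
        seq,
        orfs=[Orf("gene1", 11, 40, "+"), Orf("gene2", 51, 65, "-")],
        trna_genes=[TrnaGene("trna1", "GCC", 66, 68)],
        id="toy",
    )


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory):
    """One synthetic input bundle shared by the pipeline-level tests."""
    from phagevolve.cli import generate_demo

    outdir = tmp_path_factory.mktemp("bundle")
    bundle = generate_demo(outdir, seed=11)
    bundle["dir"] = outdir
    return bundle
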