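"""Library reconciliation filters and mutation annotation."""

import itertools

import pandas as pd
import pytest

from phagevolve.genome import GenomeValidationError, revcomp
from phagevolve.synthetic import default_config, generate_genome, \
    simulate_evolution
from phagevolve.variants import (ReconciliationError, annotate_mutation,
                                 annotate_table, apply_strand_filter,
                                 check_phage_trna_adaptation,
                                 classify_codon_optimization,
                                 reconcile_libraries, PopulationMutationTable)

BASES = "ACGT"


def _lib(rows):
    cols = ["population", "library", "position", "ref", "alt", "type",
            "frequency", "fwd_reads", "rev_reads"]
    out = []
    for r in rows:
        out.append(dict(zip(["position", "ref", "alt", "frequency"], r),
                        population="p1", library="x", type="SNP",
                        fwd_reads=50, rev_reads=50))
    return pd.DataFrame(out, columns=cols)


# -- strand filter ----------------------------------------------------------

@pytest.mark.parametrize("fwd,rev,expected", [
    (10, 10, True),    # exactly at the 10-read threshold on both strands
    (9, 30, False),    # one strand below threshold
    (0, 0, False),
    (100, 9, False),
    (11, 10, True),
])
def test_strand_filter_requires_both_strands(fwd, rev, expected):
    assert apply_strand_filter(fwd, rev) is expected


def test_strand_filter_rejects_negative_counts():
    with pytest.raises(ValueError):
        apply_strand_filter(-1, 10)


# -- reconciliation ---------------------------------------------------------

def test_reconcile_averages_frequencies_present_in_both():
    a = _lib([(100, "A", "G", 0.02)])
    b = _lib([(100, "A", "G", 0.03)])
    tab = reconcile_libraries(a, b, "p1", "h1")
    assert len(tab) == 1
    assert tab.mutations["frequency"].iloc[0] == pytest.approx(0.025)


def test_reconcile_drops_sub_threshold_in_either_library():
    # 2%/0.5%: mean exceeds 1% but the per-library rule must drop it
    a = _lib([(100, "A", "G", 0.02)])
    b = _lib([(100, "A", "G", 0.005)])
    assert len(reconcile_libraries(a, b, "p1", "h1")) == 0


def test_reconcile_single_library_fallback_keeps_frequency():
    a = _lib([(100, "A", "G", 0.015)])
    tab = reconcile_libraries(a, None, "p1", "h1")
    assert tab.mutations["frequency"].iloc[0] == pytest.approx(0.015)


def test_reconcile_applies_strand_filter_per_library():
    a = _lib([(100, "A", "G", 0.05)])
    b = _lib([(100, "A", "G", 0.05)])
    b.loc[0, "fwd_reads"] = 9            # fails the strand rule in lib B only
    assert len(reconcile_libraries(a, b, "p1", "h1")) == 0


def test_reconcile_detects_inconsistent_reference():
    a = _lib([(100, "A", "G", 0.05)])
    b = _lib([(100, "C", "G", 0.05)])
    with pytest.raises(ReconciliationError):
        reconcile_libraries(a, b, "p1", "h1")


def test_filtering_is_monotone_in_thresholds():
    rng_rows = [(10 * i, "A", "G", f) for i, f in
                enumerate([0.005, 0.01, 0.02, 0.2, 0.9], start=1)]
    a, b = _lib(rng_rows), _lib(rng_rows)
    sizes = [len(reconcile_libraries(a, b, "p", "h", min_freq=mf))
             for mf in (0.001, 0.01, 0.05, 0.5)]
    assert sizes == sorted(sizes, reverse=True)
    strand_sizes = [len(reconcile_libraries(a, b, "p", "h", min_per_strand=m))
                    for m in (0, 10, 51)]
    assert strand_sizes == sorted(strand_sizes, reverse=True)


def test_duplicate_keys_rejected():
    df = pd.DataFrame({"position": [5, 5], "ref": ["A", "A"],
                       "alt": ["G", "G"], "type": ["SNP", "SNP"],
                       "frequency": [0.1, 0.2]})
    with pytest.raises(ValueError):
        PopulationMutationTable("p", "h", df)


# -- annotation -------------------------------------------------------------

def test_annotate_nonsynonymous_threonine_to_alanine(toy_genome):
    # A->G at the first base of codon 2 turns ACC (Thr) into GCC (Ala)
    ann = annotate_mutation(toy_genome, 14, "A", "G", "SNP")
    assert ann.effect == "nonsynonymous"
    assert (ann.ancestral_codon, ann.mutated_codon) == ("ACC", "GCC")
    assert ann.aa_change == "Thr2Ala"


def test_annotate_synonymous_third_position(toy_genome):
    # T->C at the third base of codon 3: GGT -> GGC, still Gly
    ann = annotate_mutation(toy_genome, 19, "T", "C", "SNP")
    assert ann.effect == "synonymous"
    assert ann.aa_change == "Gly3Gly"


def test_annotate_nonsense(toy_genome):
    # codon 8 TAT -> TAA
    ann = annotate_mutation(toy_genome, 34, "T", "A", "SNP")
    assert ann.effect == "nonsense"


def test_annotate_minus_strand_codon(toy_genome):
    # genome G->A at 61 is coding C->T in codon 2 of gene2: ACA -> ATA
    ann = annotate_mutation(toy_genome, 61, "G", "A", "SNP")
    assert ann.gene_id == "gene2"
    assert (ann.ancestral_codon, ann.mutated_codon) == ("ACA", "ATA")
    assert ann.effect == "nonsynonymous"


def test_annotate_indels_and_intergenic(toy_genome):
    assert annotate_mutation(toy_genome, 15, toy_genome.base_at(15), "-",
                             "DEL").effect == "frameshift"
    assert annotate_mutation(toy_genome, 15, "-", "G",
                             "INS").effect == "frameshift"
    seg = toy_genome.sequence[14:17]
    assert annotate_mutation(toy_genome, 15, seg, "-",
                             "DEL").effect == "inframe_indel"
    assert annotate_mutation(toy_genome, 5, toy_genome.base_at(5), "G",
                             "SNP").effect == "intergenic"


def test_annotate_rejects_reference_mismatch(toy_genome):
    wrong = "C" if toy_genome.base_at(14) != "C" else "G"
    with pytest.raises(GenomeValidationError):
        annotate_mutation(toy_genome, 14, wrong, "T", "SNP")


# -- codon optimization -----------------------------------------------------

def test_codon_optimization_examples():
    # GGC = revcomp(GCC): mutated pairs, ancestral GGU does not -> optimizing
    assert classify_codon_optimization("GGT", "GGC", {"GCC"}) == "optimizing"
    # both ancestral and mutated pair fully -> nonoptimizing
    assert classify_codon_optimization("GGT", "GGC", {"ACC", "GCC"}) \
        == "nonoptimizing"
    assert classify_codon_optimization("GGT", "GGC", {"GCC"},
                                       synonymous=False) == "not_applicable"


def _brute_force_pairs(codon, anticodon):
    """Independent check: position-by-position Watson-Crick complementarity
    of the codon against the reversed anticodon."""
    wc = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    c = codon.upper().replace("T", "U")
    a = anticodon.upper().replace("T", "U")[::-1]
    return all((x, y) in wc for x, y in zip(c, a))


def test_codon_optimization_matches_brute_force_over_all_anticodons():
    codons = ["".join(p) for p in itertools.product(BASES, repeat=3)]
    anticodons = ["".join(p).replace("T", "U")
                  for p in itertools.product(BASES, repeat=3)]
    for anticodon in anticodons:
        for anc in codons[::7]:          # stride keeps this brisk but broad
            for mut in codons[::5]:
                expect = ("optimizing"
                          if _brute_force_pairs(mut, anticodon)
                          and not _brute_force_pairs(anc, anticodon)
                          else "nonoptimizing")
                got = classify_codon_optimization(anc, mut, {anticodon})
                assert got == expect, (anc, mut, anticodon)


def test_phage_trna_adaptation(toy_genome):
    # toy phage carries anticodon GCC, whose codon partner is GGC
    assert check_phage_trna_adaptation("GGT", "GGC", toy_genome.trna_genes)
    assert not check_phage_trna_adaptation("GGC", "GGT", toy_genome.trna_genes)
    assert not check_phage_trna_adaptation("GGT", "GGC", [])


# -- round trip against the simulator's ground truth ------------------------

def test_annotation_recovers_simulated_effect_classes():
    """Every simulated SNP and indel annotates to its intended effect."""
    config = default_config(seed=3)
    genome = generate_genome(config)
    truth = simulate_evolution(genome, config)
    n_checked = 0
    for ts in truth.values():
        for m in ts.mutations:
            ann = annotate_mutation(genome, m.position, m.ref, m.alt, m.mtype)
            assert ann.effect == m.effect, m
            assert ann.gene_id == m.gene_id
            n_checked += 1
    assert n_checked > 100


def test_annotate_table_adds_host_optimization_columns(toy_genome):
    df = pd.DataFrame({"position": [19], "ref": ["T"], "alt": ["C"],
                       "type": ["SNP"], "frequency": [0.2]})
    tab = PopulationMutationTable("p1", "h1", df)
    out = annotate_table(toy_genome, tab, {"hostX": {"GCC"}, "hostY": {"AAA"}})
    row = out.mutations.iloc[0]
    assert row["effect"] == "synonymous"
    assert row["codon_opt_hostX"] == "optimizing"
    assert row["codon_opt_hostY"] == "nonoptimizing"
    # the change also adapts the codon to the phage's own tRNA here
    assert bool(row["phage_trna_adaptation"]) is True
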