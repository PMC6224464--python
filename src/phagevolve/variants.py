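"""Variant-table reconciliation and mutation annotation.

Each evolved population was sequenced as two technical libraries.  A
mutation is kept only if it appears at frequency >= 1% in *both* libraries
(applied per library, before any averaging) and, within each library, has
at least 10 reads of coverage on each strand at the site (guards against
strand-biased artifacts).  The retained frequency is the arithmetic mean of
the two library frequencies; when only one usable library exists the
single-library calls are retained unchanged.

Annotation places every retained mutation against the genome: effect class
(synonymous / nonsynonymous / nonsense / frameshift / inframe_indel /
intergenic), codon change and amino-acid change for SNPs inside ORFs, and —
for synonymous SNPs — whether the change optimizes the codon to a host's
tRNA repertoire under strict (no-wobble) Watson-Crick pairing.

Variant-table dialect (TSV): population, library, position, ref, alt,
type{SNP,INS,DEL}, frequency, fwd_reads, rev_reads.  ``fwd_reads`` and
``rev_reads`` are strand-specific coverage at the variant site.  INS rows
use ref="-" and alt=inserted bases (inserted after `position`); DEL rows
use ref=deleted bases starting at `position` and alt="-".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome import (
    PhageGenome,
    GenomeValidationError,
    aa3,
    anticodon_pairs_codon,
    translate_codon,
)

__all__ = [
    "MutationAnnotation",
    "PopulationMutationTable",
    "apply_strand_filter",
    "reconcile_libraries",
    "annotate_mutation",
    "annotate_table",
    "classify_codon_optimization",
    "check_phage_trna_adaptation",
    "read_variant_table",
    "read_population_table",
    "read_host_trnas",
]

VARIANT_COLUMNS = ["population", "library", "position", "ref", "alt", "type",
                   "frequency", "fwd_reads", "rev_reads"]

EFFECTS = ("synonymous", "nonsynonymous", "nonsense", "frameshift",
           "inframe_indel", "intergenic")


class ReconciliationError(ValueError):
    """Inconsistent reference alleles between the two libraries."""


@dataclass
class MutationAnnotation:
    gene_id: str                      # ORF id or "intergenic"
    effect: str                       # one of EFFECTS
    codon_index: int | None = None    # 1-based; SNPs in ORFs only
    ancestral_codon: str | None = None
    mutated_codon: str | None = None
    aa_change: str | None = None      # e.g. "Thr580Ala"
    codon_optimization: dict[str, str] = field(default_factory=dict)
    phage_trna_adaptation: bool | None = None


@dataclass
class PopulationMutationTable:
    """Filtered, averaged (and optionally annotated) mutations of one population."""

    population_id: str
    host_id: str
    mutations: pd.DataFrame  # columns: position, ref, alt, type, frequency, ...

    def __post_init__(self) -> None:
        keys = self.mutations[["position", "ref", "alt"]]
        if keys.duplicated().any():
            raise ValueError(
                f"population {self.population_id}: duplicate (position, ref, alt) keys")

    def __len__(self) -> int:
        return len(self.mutations)

    def keys(self) -> list[tuple[int, str, str]]:
        return [tuple(r) for r in
                self.mutations[["position", "ref", "alt"]].itertuples(index=False)]

    def to_tsv(self, path) -> None:
        out = self.mutations.copy()
        out.insert(0, "population", self.population_id)
        out.insert(1, "host", self.host_id)
        out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# filtering / reconciliation


def apply_strand_filter(fwd_reads: int, rev_reads: int,
                        min_per_strand: int = 10) -> bool:
    """True iff the site has >= ``min_per_strand`` reads on *each* strand."""
    if fwd_reads < 0 or rev_reads < 0:
        raise ValueError("negative read counts")
    return fwd_reads >= min_per_strand and rev_reads >= min_per_strand


def _filter_library(lib: pd.DataFrame, min_freq: float,
                    min_per_strand: int) -> pd.DataFrame:
    ok = (
        (lib["frequency"] >= min_freq)
        & (lib["fwd_reads"] >= min_per_strand)
        & (lib["rev_reads"] >= min_per_strand)
    )
    return lib.loc[ok]


def reconcile_libraries(lib_a: pd.DataFrame, lib_b: pd.DataFrame | None,
                        population_id: str = "", host_id: str = "",
                        min_freq: float = 0.01,
                        min_per_strand: int = 10) -> PopulationMutationTable:
    """Merge the two technical libraries of one population.

    Both thresholds are applied per library first; a mutation failing either
    filter in a library counts as absent from that library, and only
    mutations present in both libraries survive.  The retained frequency is
    the mean of the two library frequencies.  With ``lib_b=None``
    (single-library fallback) the filtered calls of ``lib_a`` are kept with
    their own frequencies.
    """
    key = ["position", "ref", "alt", "type"]
    fa = _filter_library(lib_a, min_freq, min_per_strand)

    if lib_b is None:
        merged = fa[key + ["frequency"]].copy()
    else:
        fb = _filter_library(lib_b, min_freq, min_per_strand)
        # consistency: the reference allele at a shared SNP position must agree
        refs = pd.concat([lib_a.loc[lib_a["type"] == "SNP", ["position", "ref"]],
                          lib_b.loc[lib_b["type"] == "SNP", ["position", "ref"]]])
        bad = refs.groupby("position")["ref"].nunique()
        if (bad > 1).any():
            pos = int(bad[bad > 1].index[0])
            raise ReconciliationError(
                f"libraries disagree on the reference allele at position {pos}")
        merged = fa[key + ["frequency"]].merge(
            fb[key + ["frequency"]], on=key, suffixes=("_a", "_b"))
        merged["frequency"] = (merged["frequency_a"] + merged["frequency_b"]) / 2.0
        merged = merged[key + ["frequency"]]

    merged = merged.sort_values(["position", "ref", "alt"]).reset_index(drop=True)
    return PopulationMutationTable(population_id, host_id, merged)


# ---------------------------------------------------------------------------
# annotation


def classify_codon_optimization(ancestral_codon: str, mutated_codon: str,
                                host_anticodons, *, synonymous: bool = True) -> str:
    """Classify a synonymous codon change against a host tRNA repertoire.

    ``optimizing``: the mutated codon forms full Watson-Crick pairing with at
    least one host anticodon while the ancestral codon pairs with none;
    anything else is ``nonoptimizing``.  Non-synonymous inputs are
    ``not_applicable``.
    """
    if not synonymous:
        return "not_applicable"
    anc_pairs = any(anticodon_pairs_codon(ancestral_codon, a) for a in host_anticodons)
    mut_pairs = any(anticodon_pairs_codon(mutated_codon, a) for a in host_anticodons)
    return "optimizing" if (mut_pairs and not anc_pairs) else "nonoptimizing"


def check_phage_trna_adaptation(ancestral_codon: str, mutated_codon: str,
                                phage_trnas) -> bool:
    """True iff a synonymous change adapts the codon to a phage-carried tRNA."""
    anticodons = [t.anticodon if hasattr(t, "anticodon") else t for t in phage_trnas]
    anc = any(anticodon_pairs_codon(ancestral_codon, a) for a in anticodons)
    mut = any(anticodon_pairs_codon(mutated_codon, a) for a in anticodons)
    return mut and not anc


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def annotate_mutation(genome: PhageGenome, position: int, ref: str, alt: str,
                      mtype: str,
                      host_trna_sets: dict[str, set[str]] | None = None
                      ) -> MutationAnnotation:
    """Annotate one mutation against the genome's reading frames."""
    orf = genome.orf_at(position)
    gene_id = orf.id if orf is not None else "intergenic"

    if mtype == "SNP":
        if len(ref) != 1 or len(alt) != 1:
            raise ValueError("SNP requires single-base ref and alt")
        if genome.base_at(position) != ref:
            raise GenomeValidationError(
                f"ref allele {ref} does not match genome at position {position}")
        if orf is None:
            return MutationAnnotation("intergenic", "intergenic")
        idx, off, anc_codon = genome.codon_context(orf, position)
        if orf.strand == "+":
            new_base = alt
        else:
            new_base = _COMPLEMENT[alt]
        mut_codon = anc_codon[:off] + new_base + anc_codon[off + 1:]
        anc_aa = translate_codon(anc_codon)
        mut_aa = translate_codon(mut_codon)
        if mut_aa == anc_aa:
            effect = "synonymous"
        elif mut_aa == "*":
            effect = "nonsense"
        else:
            effect = "nonsynonymous"
        ann = MutationAnnotation(
            gene_id, effect, codon_index=idx,
            ancestral_codon=anc_codon, mutated_codon=mut_codon,
            aa_change=f"{aa3(anc_aa)}{idx}{aa3(mut_aa)}",
        )
        if host_trna_sets is not None and effect == "synonymous":
            ann.codon_optimization = {
                host: classify_codon_optimization(anc_codon, mut_codon, acs)
                for host, acs in host_trna_sets.items()
            }
            ann.phage_trna_adaptation = check_phage_trna_adaptation(
                anc_codon, mut_codon, genome.trna_genes)
        elif host_trna_sets is not None:
            ann.codon_optimization = {h: "not_applicable" for h in host_trna_sets}
        return ann

    if mtype in ("INS", "DEL"):
        if mtype == "DEL":
            seg = genome.sequence[position - 1: position - 1 + len(ref)]
            if seg != ref:
                raise GenomeValidationError(
                    f"deleted sequence {ref} does not match genome at {position}")
            indel_len = len(ref)
        else:
            indel_len = len(alt.strip("-")) or len(alt)
        if orf is None:
            return MutationAnnotation("intergenic", "intergenic")
        effect = "frameshift" if indel_len % 3 else "inframe_indel"
        return MutationAnnotation(gene_id, effect)

    raise ValueError(f"unknown mutation type {mtype!r}")


def annotate_table(genome: PhageGenome, table: PopulationMutationTable,
                   host_trna_sets: dict[str, set[str]] | None = None
                   ) -> PopulationMutationTable:
    """Annotated copy of a reconciled mutation table (adds effect columns)."""
    rows = []
    hosts = sorted(host_trna_sets) if host_trna_sets else []
    for rec in table.mutations.itertuples(index=False):
        ann = annotate_mutation(genome, int(rec.position), rec.ref, rec.alt,
                                rec.type, host_trna_sets)
        row = {
            "gene_id": ann.gene_id,
            "effect": ann.effect,
            "codon_index": ann.codon_index,
            "ancestral_codon": ann.ancestral_codon,
            "mutated_codon": ann.mutated_codon,
            "aa_change": ann.aa_change,
            "phage_trna_adaptation": ann.phage_trna_adaptation,
        }
        for h in hosts:
            row[f"codon_opt_{h}"] = ann.codon_optimization.get(h, "not_applicable")
        rows.append(row)
    ann_df = pd.concat(
        [table.mutations.reset_index(drop=True),
         pd.DataFrame(rows, index=range(len(rows)))], axis=1)
    return PopulationMutationTable(table.population_id, table.host_id, ann_df)


# ---------------------------------------------------------------------------
# I/O


def read_variant_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str})
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant table {path} missing columns: {sorted(missing)}")
    return df


def read_population_table(path, population_id: str | None = None,
                          host_id: str | None = None) -> PopulationMutationTable:
    """Read back a (possibly annotated) population mutation TSV.

    The explicit ids are used when the table is empty (an evolved population
    with no retained mutations is a legitimate result).
    """
    df = pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str})
    if "population" not in df.columns:
        raise ValueError(f"{path}: not a population mutation table")
    pid = str(df["population"].iloc[0]) if len(df) else (population_id or "")
    host = str(df["host"].iloc[0]) if len(df) else (host_id or "")
    return PopulationMutationTable(
        pid, host, df.drop(columns=["population", "host"]))


def read_host_trnas(path) -> dict[str, set[str]]:
    """2-column TSV (host_id, anticodon) -> host -> set of anticodons."""
    df = pd.read_csv(path, sep="\t")
    return {h: set(g["anticodon"]) for h, g in df.groupby("host_id")}
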