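"""Phage genome container: sequence plus ORF and tRNA annotations.

This is the coordinate frame every other module works in.  All coordinates
are 1-based inclusive, the GFF3 convention, on the forward strand of the
reference sequence.  ORFs may lie on either strand; codon extraction for
minus-strand ORFs works on the reverse complement, with amino-acid numbering
from the ORF's own start codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO
from Bio.SeqUtils import seq3

__all__ = [
    "Orf",
    "TrnaGene",
    "PhageGenome",
    "GenomeValidationError",
    "revcomp",
    "translate_codon",
    "normalize_rna",
    "anticodon_pairs_codon",
    "read_genome",
    "write_genome",
]

STOP = "*"


class GenomeValidationError(ValueError):
    """Raised when annotations are inconsistent with the sequence."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (uppercase)."""
    return str(Seq(seq).reverse_complement())


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a DNA codon; '*' for stop."""
    return str(Seq(codon).translate())


def aa3(aa1: str) -> str:
    """Three-letter amino-acid name ('*' maps to 'Ter')."""
    return seq3(aa1)


def normalize_rna(triplet: str) -> str:
    """Uppercase a 3-letter anticodon/codon and map T->U (RNA alphabet)."""
    t = triplet.upper().replace("T", "U")
    if len(t) != 3 or any(c not in "ACGU" for c in t):
        raise ValueError(f"invalid triplet: {triplet!r}")
    return t


def anticodon_pairs_codon(codon: str, anticodon: str) -> bool:
    """Full Watson-Crick pairing test: no wobble allowed.

    A codon (5'->3') fully pairs with a tRNA anticodon (5'->3') iff the codon
    equals the reverse complement of the anticodon at all three positions.
    Both arguments accepted in DNA or RNA alphabet.
    """
    c = normalize_rna(codon)
    a = normalize_rna(anticodon)
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    return c == "".join(comp[b] for b in reversed(a))


@dataclass(frozen=True)
class Orf:
    id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GenomeValidationError(f"ORF {self.id}: bad strand {self.strand!r}")
        if self.end < self.start:
            raise GenomeValidationError(f"ORF {self.id}: end < start")
        if (self.end - self.start + 1) % 3 != 0:
            raise GenomeValidationError(
                f"ORF {self.id}: length {self.end - self.start + 1} not divisible by 3"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TrnaGene:
    id: str
    anticodon: str  # 5'->3', RNA alphabet
    start: int = 0
    end: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "anticodon", normalize_rna(self.anticodon))


@dataclass
class PhageGenome:
    """Sequence plus annotations; the shared reference for all mutations."""

    sequence: str
    orfs: list[Orf] = field(default_factory=list)
    trna_genes: list[TrnaGene] = field(default_factory=list)
    id: str = "synthetic_phage"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.validate()

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        n = len(self.sequence)
        spans = []
        for orf in self.orfs:
            if orf.end > n:
                raise GenomeValidationError(f"ORF {orf.id} extends past genome end")
            spans.append((orf.start, orf.end, orf.id))
        spans.sort()
        for (s1, e1, i1), (s2, e2, i2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise GenomeValidationError(f"ORFs {i1} and {i2} overlap")

    # -- coordinate helpers -------------------------------------------------

    def base_at(self, position: int) -> str:
        if not 1 <= position <= len(self.sequence):
            raise GenomeValidationError(f"position {position} outside genome")
        return self.sequence[position - 1]

    def orf_at(self, position: int) -> Orf | None:
        """The ORF containing a 1-based position, or None (intergenic)."""
        for orf in self.orfs:
            if orf.start <= position <= orf.end:
                return orf
        return None

    def coding_sequence(self, orf: Orf) -> str:
        """Coding-strand sequence of an ORF, 5'->3' (ATG ... stop)."""
        s = self.sequence[orf.start - 1 : orf.end]
        return revcomp(s) if orf.strand == "-" else s

    def codon_context(self, orf: Orf, position: int) -> tuple[int, int, str]:
        """Locate a genome position inside an ORF's reading frame.

        Returns (codon_index, offset_in_codon, codon), all on the coding
        strand: codon_index is 1-based (codon 1 is the start codon), offset
        is 0..2 from the codon's 5' end.
        """
        if not orf.start <= position <= orf.end:
            raise GenomeValidationError(f"position {position} not in ORF {orf.id}")
        if orf.strand == "+":
            off = position - orf.start
        else:
            off = orf.end - position
        idx = off // 3
        cds = self.coding_sequence(orf)
        return idx + 1, off % 3, cds[3 * idx : 3 * idx + 3]


# -- FASTA / GFF3 round trip ----------------------------------------------
#
# The GFF3 dialect is fixed: CDS features carry ID=<orf-id>, tRNA features
# carry ID=<id>;anticodon=<triplet>.  Only these two feature types are read.


def write_genome(genome: PhageGenome, fasta_path, gff3_path) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, description="")
    SeqIO.write([rec], str(fasta_path), "fasta")
    lines = ["##gff-version 3", f"##sequence-region {genome.id} 1 {len(genome)}"]
    for orf in genome.orfs:
        lines.append(
            "\t".join(
                [genome.id, "phagevolve", "CDS", str(orf.start), str(orf.end),
                 ".", orf.strand, "0", f"ID={orf.id}"]
            )
        )
    for t in genome.trna_genes:
        lines.append(
            "\t".join(
                [genome.id, "phagevolve", "tRNA", str(t.start), str(t.end),
                 ".", "+", ".", f"ID={t.id};anticodon={t.anticodon}"]
            )
        )
    with open(gff3_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_attrs(col: str) -> dict[str, str]:
    out = {}
    for part in col.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_genome(fasta_path, gff3_path) -> PhageGenome:
    rec = next(SeqIO.parse(str(fasta_path), "fasta"))
    orfs: list[Orf] = []
    trnas: list[TrnaGene] = []
    with open(gff3_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            ftype, start, end, strand = cols[2], int(cols[3]), int(cols[4]), cols[6]
            attrs = _parse_attrs(cols[8])
            if ftype == "CDS":
                orfs.append(Orf(attrs.get("ID", f"orf{len(orfs)+1}"), start, end, strand))
            elif ftype == "tRNA":
                trnas.append(
                    TrnaGene(attrs.get("ID", f"trna{len(trnas)+1}"),
                             attrs["anticodon"], start, end)
                )
    return PhageGenome(str(rec.seq), orfs, trnas, id=rec.id)
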