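"""Domain types shared by every pipeline stage.

All coordinates are 0-based half-open on the plus strand of the sequence
they annotate. GFF3 output converts to 1-based inclusive at write time
(:mod:`orthocat.io`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

__all__ = [
    "TranscriptContig",
    "ReferenceTranscript",
    "Assignment",
    "AssignmentClass",
    "CdsStatus",
    "CdsSource",
    "ClipRecord",
    "CatalogEntry",
    "OrthologTable",
    "reverse_complement",
    "sanitize_sequence",
    "STOP_CODONS",
    "translate",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# standard genetic code, DNA alphabet
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (involution)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str, selenoprotein: bool = False) -> str:
    """Translate a DNA CDS; UGA becomes U (selenocysteine) if flagged.

    Codons containing N translate to X.
    """
    aa = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if "N" in codon:
            aa.append("X")
        elif selenoprotein and codon == "TGA":
            aa.append("U")
        else:
            aa.append(_CODON_TABLE[codon])
    return "".join(aa)


def sanitize_sequence(seq: str) -> tuple[str, int]:
    """Uppercase ``seq`` and collapse non-ACGTN symbols to N.

    Returns the cleaned sequence and the number of replaced symbols.
    Assembler output contains at most N as an ambiguity code; anything
    else (IUPAC codes, stray characters) is treated as unknown rather
    than rejected.
    """
    seq = seq.upper()
    if set(seq) <= {"A", "C", "G", "T", "N"}:
        return seq, 0
    cleaned = []
    replaced = 0
    for ch in seq:
        if ch in "ACGTN":
            cleaned.append(ch)
        else:
            cleaned.append("N")
            replaced += 1
    return "".join(cleaned), replaced


@dataclass
class TranscriptContig:
    """A raw assembled transcript contig.

    ``graph_id`` carries optional assembly-graph provenance (e.g. the
    Trinity component encoded in the contig name). ``oriented`` stays
    False until orientation against the assigned ortholog is applied.
    """

    id: str
    sequence: str
    graph_id: str | None = None
    oriented: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"contig {self.id}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complemented(self, oriented: bool = True) -> "TranscriptContig":
        return replace(self, sequence=reverse_complement(self.sequence), oriented=oriented)


@dataclass
class ReferenceTranscript:
    """An annotated mRNA of the reference (or an extra ortholog) species."""

    accession: str
    gene_symbol: str
    mrna: str
    cds_start: int
    cds_end: int
    selenoprotein: bool = False
    species: str = "reference"
    partial: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0 <= self.cds_start < self.cds_end <= len(self.mrna)):
            raise ValueError(
                f"{self.accession}: CDS [{self.cds_start},{self.cds_end}) outside "
                f"mRNA of length {len(self.mrna)}"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError(f"{self.accession}: CDS length not divisible by 3")
        if not self.partial:
            cds = self.cds
            if not cds.startswith("ATG"):
                raise ValueError(f"{self.accession}: CDS lacks start codon")
            if cds[-3:] not in STOP_CODONS:
                raise ValueError(f"{self.accession}: CDS lacks stop codon")

    @property
    def cds(self) -> str:
        return self.mrna[self.cds_start : self.cds_end]


class AssignmentClass(str, enum.Enum):
    BBH = "BBH"  # best bidirectional hit
    SBH = "SBH"  # single best hit rescue


@dataclass
class Assignment:
    """A contig <-> reference pairing produced by the assignment stage."""

    contig_id: str
    reference_accession: str
    gene_symbol: str
    klass: AssignmentClass
    score: float
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")


class CdsStatus(str, enum.Enum):
    FULL_LENGTH = "full_length"
    PARTIAL_5P = "partial_5p"
    PARTIAL_3P = "partial_3p"
    PARTIAL_BOTH = "partial_both"
    INTERNAL = "internal"


class CdsSource(str, enum.Enum):
    ORTHOLOG_WINDOW = "ortholog_window"
    PREDICTOR = "predictor"
    LONGEST_ORF = "longest_orf"


@dataclass
class ClipRecord:
    end: str  # '5p' or '3p'
    removed_length: int
    reason: str  # polyA_end | promoter | intercoding_split | intercoding_center


@dataclass
class CatalogEntry:
    """A final catalog transcript: oriented, scaffolded, clipped, CDS-annotated.

    Exactly one entry exists per assigned reference accession (the
    one-to-one catalog property).
    """

    entry_id: str
    gene_symbol: str
    reference_accession: str
    sequence: str
    cds_start: int
    cds_end: int
    cds_status: CdsStatus
    cds_source: CdsSource
    completeness_fraction: float = 0.0
    clip_records: list[ClipRecord] = field(default_factory=list)
    scaffold_plan: object | None = None  # ScaffoldPlan, kept loose to avoid a cycle
    vector_flags: list = field(default_factory=list)
    assignment: Assignment | None = None
    source_contig_id: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.cds_start <= self.cds_end <= len(self.sequence)):
            raise ValueError(
                f"{self.entry_id}: CDS [{self.cds_start},{self.cds_end}) outside "
                f"sequence of length {len(self.sequence)}"
            )

    @property
    def cds_sequence(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]


class OrthologTable:
    """gene symbol -> {species -> [CDS accessions]} plus a sequence store.

    A species may list several isoform accessions for a gene; window
    construction picks the isoform most similar to the reference CDS.
    """

    def __init__(self) -> None:
        self._rows: dict[str, dict[str, list[str]]] = {}
        self._store: dict[str, str] = {}

    def add(self, gene_symbol: str, species: str, accession: str, sequence: str | None = None) -> None:
        self._rows.setdefault(gene_symbol, {}).setdefault(species, [])
        if accession not in self._rows[gene_symbol][species]:
            self._rows[gene_symbol][species].append(accession)
        if sequence is not None:
            self._store[accession] = sequence

    def add_sequence(self, accession: str, sequence: str) -> None:
        self._store[accession] = sequence

    def species_for(self, gene_symbol: str) -> dict[str, list[str]]:
        return self._rows.get(gene_symbol, {})

    def sequence(self, accession: str) -> str:
        return self._store[accession]

    def genes(self) -> list[str]:
        return sorted(self._rows)

    def validate(self) -> None:
        """Every listed accession must resolve to a sequence."""
        for gene, by_species in self._rows.items():
            for species, accs in by_species.items():
                for acc in accs:
                    if acc not in self._store:
                        raise ValueError(
                            f"ortholog table: {gene}/{species} accession {acc} "
                            "has no sequence"
                        )

    def __len__(self) -> int:
        return len(self._rows)
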