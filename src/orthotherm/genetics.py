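"""Core sequence types and genetic-code utilities.

Coding sequences are plain IUPAC DNA strings with an explicit reading-frame
offset; only complete codons are ever interpreted. Translation follows the
standard nuclear genetic code (vertebrate transcripts): any codon containing
a non-ACGT symbol translates to ``'X'`` and stop codons to ``'*'``, so that
downstream purge rules can key on those two symbols.

Codons are also exposed as integer indices (``16*b1 + 4*b2 + b3`` with
A,C,G,T = 0..3), the representation all vectorized counting in this package
runs on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: The 20 amino acids in alphabetical one-letter order; index order used by
#: every matrix in the package.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
STOP = "*"
AMBIGUOUS = "X"

#: Integer code for a stop in the 64-entry codon→aa lookup array.
STOP_CODE = 20


def codon_index(codon: str) -> int:
    """Integer index of an ACGT codon (16*b1 + 4*b2 + b3); -1 if ambiguous."""
    try:
        return (
            16 * BASE_INDEX[codon[0]]
            + 4 * BASE_INDEX[codon[1]]
            + BASE_INDEX[codon[2]]
        )
    except KeyError:
        return -1


def index_codon(idx: int) -> str:
    """Inverse of :func:`codon_index`."""
    return BASES[idx >> 4] + BASES[(idx >> 2) & 3] + BASES[idx & 3]


ALL_CODONS = tuple(index_codon(i) for i in range(64))


@dataclass(frozen=True)
class GeneticCode:
    """A codon translation table plus its synonymous codon families.

    ``table`` maps all 64 ACGT codons to a one-letter amino acid or ``'*'``;
    ``synonymous_families`` maps each amino acid to the (sorted) list of its
    codons. The standard code has 61 sense codons in 20 families and 3 stops.
    """

    table: Mapping[str, str]
    synonymous_families: Mapping[str, tuple[str, ...]]
    #: 64-entry lookup: codon index -> aa index 0..19, or STOP_CODE.
    aa_of_codon: np.ndarray = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        sense = [c for c, a in self.table.items() if a != STOP]
        stops = [c for c, a in self.table.items() if a == STOP]
        if len(sense) + len(stops) != 64:
            raise ValueError("genetic code must cover all 64 codons")
        arr = np.empty(64, dtype=np.int8)
        for codon, aa in self.table.items():
            arr[codon_index(codon)] = STOP_CODE if aa == STOP else AA_INDEX[aa]
        object.__setattr__(self, "aa_of_codon", arr)

    @classmethod
    def standard(cls) -> "GeneticCode":
        """The standard nuclear genetic code (NCBI table 1)."""
        bio = CodonTable.unambiguous_dna_by_id[1]
        table = dict(bio.forward_table)
        for stop in bio.stop_codons:
            table[stop] = STOP
        families: dict[str, tuple[str, ...]] = {}
        for aa in AMINO_ACIDS:
            families[aa] = tuple(sorted(c for c, a in table.items() if a == aa))
        return cls(table=table, synonymous_families=families)

    def translate_codon(self, codon: str) -> str:
        """One codon to one symbol; non-ACGT content yields 'X'."""
        aa = self.table.get(codon)
        return AMBIGUOUS if aa is None else aa


#: Module-level standard code; treat as read-only.
STANDARD_CODE = GeneticCode.standard()


@dataclass
class CodingSequence:
    """A coding nucleotide sequence with an explicit frame offset.

    Codon *i* (0-based) occupies nucleotides
    ``frame_offset + 3*i .. frame_offset + 3*i + 2``; a trailing partial
    codon is permitted but never interpreted.
    """

    id: str
    nucleotides: str
    species: str = ""
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("CodingSequence id must be non-empty")
        if self.frame_offset < 0:
            raise ValueError("frame_offset must be >= 0")
        self.nucleotides = self.nucleotides.upper()

    @property
    def n_codons(self) -> int:
        return max(0, (len(self.nucleotides) - self.frame_offset) // 3)

    def codon(self, i: int) -> str:
        start = self.frame_offset + 3 * i
        return self.nucleotides[start : start + 3]

    def codons(self, start: int = 0, end: int | None = None) -> list[str]:
        """Codons in the 0-based half-open codon range [start, end)."""
        if end is None:
            end = self.n_codons
        return [self.codon(i) for i in range(start, end)]


@dataclass
class ProteinSegment:
    """A translated codon range of a coding sequence.

    ``start_codon``/``end_codon`` are 0-based half-open codon coordinates in
    the source; ``len(residues) == end_codon - start_codon`` always holds.
    """

    id: str
    residues: str
    source_id: str
    start_codon: int
    end_codon: int

    def __post_init__(self) -> None:
        if len(self.residues) != self.end_codon - self.start_codon:
            raise ValueError(
                f"segment {self.id}: residue length {len(self.residues)} != "
                f"codon span {self.end_codon - self.start_codon}"
            )


def translate(cds: CodingSequence, code: GeneticCode = STANDARD_CODE) -> ProteinSegment:
    """Translate every complete codon of ``cds``.

    Raises ``ValueError`` if no complete codon remains after the frame
    offset. The trailing partial codon (if any) is dropped.
    """
    n = cds.n_codons
    if n == 0:
        raise ValueError(f"{cds.id}: no complete codon after frame offset")
    residues = "".join(code.translate_codon(c) for c in cds.codons(0, n))
    return ProteinSegment(
        id=cds.id, residues=residues, source_id=cds.id, start_codon=0, end_codon=n
    )


def gc_fraction(seq: str) -> float:
    """G+C fraction over the ACGT symbols of ``seq``.

    Non-ACGT symbols are excluded from both numerator and denominator;
    a sequence without any ACGT symbol is an error.
    """
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in BASES)
    if acgt == 0:
        raise ValueError("sequence contains no ACGT symbols")
    return (seq.count("G") + seq.count("C")) / acgt


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA I/O

def read_fasta(path: str | Path, species: str = "") -> list[CodingSequence]:
    """Read a FASTA file into coding sequences (frame offset 0).

    Duplicate record ids and empty records are rejected.
    """
    seqs: list[CodingSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        if len(rec.seq) == 0:
            raise ValueError(f"empty FASTA record {rec.id!r} in {path}")
        seen.add(rec.id)
        seqs.append(CodingSequence(id=rec.id, nucleotides=str(rec.seq), species=species))
    return seqs


def write_fasta(seqs: Iterable[CodingSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.nucleotides), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Vectorized codon helpers

def encode_codons(codons: Sequence[str]) -> np.ndarray:
    """Codon strings to int indices; gaps ('---') and ambiguous codons -> -1."""
    return np.fromiter((codon_index(c) for c in codons), dtype=np.int16, count=len(codons))


#: Boolean mask over codon indices: third base is A or T.
THIRD_BASE_AT = np.array([(i & 3) in (0, 3) for i in range(64)], dtype=bool)

#: Codon indices of the three stop codons of the standard code.
STOP_CODON_INDICES = np.flatnonzero(STANDARD_CODE.aa_of_codon == STOP_CODE)
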