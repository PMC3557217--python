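"""Back-translation of protein alignments to codon alignments.

Every residue column of a protein alignment becomes one codon column;
residue gaps become ``'---'``. Columns are classified once and consumed by
all downstream statistics:

* ``indel`` — a gap in either species; never contributes to any count;
* ``invalid`` — an in-frame stop or a non-ACGT symbol in either codon;
  these trip the pair-level purge upstream rather than being skipped;
* otherwise ``codon_identical`` / ``synonymous`` / ``nonsynonymous``, with
  an additional ``nt12_conserved`` flag (first and second bases identical).

Synonymy is defined purely by identical translation, so serine pairs that
cross the TCN/AGY family boundary are synonymous but never nt12-conserved —
exactly the columns the conditioned GC3 statistic excludes by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genetics import (
    GeneticCode,
    STANDARD_CODE,
    STOP_CODE,
    CodingSequence,
    codon_index,
    index_codon,
)
from .pairing import SegmentAlignment

GAP_IDX = -2
AMBIG_IDX = -1

# Column class codes (kept small for vectorized work).
INDEL = 0
CODON_IDENTICAL = 1
SYNONYMOUS = 2
NONSYNONYMOUS = 3
INVALID = 4

CLASS_NAMES = {
    INDEL: "indel",
    CODON_IDENTICAL: "codon_identical",
    SYNONYMOUS: "synonymous",
    NONSYNONYMOUS: "nonsynonymous",
    INVALID: "invalid",
}


@dataclass
class SegmentPair:
    """A codon-aligned orthologous segment pair with per-column classes.

    ``idx_a``/``idx_b`` hold codon indices with :data:`GAP_IDX` for gaps and
    :data:`AMBIG_IDX` for codons containing non-ACGT symbols; ``classes``
    holds one code per column and ``nt12_conserved`` flags non-indel valid
    columns whose first and second bases agree.
    """

    pair_id: str
    group_id: str | None
    species_a: str
    species_b: str
    idx_a: np.ndarray
    idx_b: np.ndarray
    #: raw aligned codon triplets, '---' for gaps (kept for serialization;
    #: ambiguous codons survive here even though idx_* collapses them).
    codons_a: list[str] = field(default_factory=list)
    codons_b: list[str] = field(default_factory=list)
    classes: np.ndarray = field(default=None, repr=False)
    nt12_conserved: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.idx_a) != len(self.idx_b):
            raise ValueError("aligned codon arrays differ in length")
        if not self.codons_a:
            self.codons_a = [
                "---" if c == GAP_IDX else index_codon(int(c)) for c in self.idx_a
            ]
            self.codons_b = [
                "---" if c == GAP_IDX else index_codon(int(c)) for c in self.idx_b
            ]
        if self.classes is None:
            self._classify()

    def _classify(self) -> None:
        a, b = self.idx_a, self.idx_b
        aa_of = STANDARD_CODE.aa_of_codon
        n = len(a)
        cls = np.empty(n, dtype=np.int8)
        indel = (a == GAP_IDX) | (b == GAP_IDX)
        ambig = ~indel & ((a == AMBIG_IDX) | (b == AMBIG_IDX))
        valid = ~indel & ~ambig
        aa_a = np.where(valid, aa_of[np.where(valid, a, 0)], -1)
        aa_b = np.where(valid, aa_of[np.where(valid, b, 0)], -1)
        stop = valid & ((aa_a == STOP_CODE) | (aa_b == STOP_CODE))
        good = valid & ~stop
        cls[indel] = INDEL
        cls[ambig | stop] = INVALID
        same_codon = good & (a == b)
        same_aa = good & (aa_a == aa_b)
        cls[same_codon] = CODON_IDENTICAL
        cls[same_aa & ~same_codon] = SYNONYMOUS
        cls[good & ~same_aa] = NONSYNONYMOUS
        nt12 = np.zeros(n, dtype=bool)
        nt12[good] = (a[good] >> 2) == (b[good] >> 2)
        self.classes = cls
        self.nt12_conserved = nt12

    # -- convenience masks -------------------------------------------------
    @property
    def n_columns(self) -> int:
        return len(self.idx_a)

    @property
    def n_invalid_columns(self) -> int:
        return int((self.classes == INVALID).sum())

    @property
    def aligned_mask(self) -> np.ndarray:
        """Non-indel, valid columns — the columns every statistic uses."""
        return (self.classes == CODON_IDENTICAL) | (self.classes == SYNONYMOUS) | (
            self.classes == NONSYNONYMOUS
        )

    @property
    def synonymous_mask(self) -> np.ndarray:
        """Amino-acid-conserved columns (codon-identical ones included)."""
        return (self.classes == CODON_IDENTICAL) | (self.classes == SYNONYMOUS)

    @property
    def exchanged_mask(self) -> np.ndarray:
        return self.classes == NONSYNONYMOUS

    def aa_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Amino-acid index arrays over aligned (valid) columns."""
        m = self.aligned_mask
        aa_of = STANDARD_CODE.aa_of_codon
        return aa_of[self.idx_a[m]], aa_of[self.idx_b[m]]

    def swapped(self) -> "SegmentPair":
        """The same pair with species A and B exchanged."""
        return SegmentPair(
            pair_id=self.pair_id,
            group_id=self.group_id,
            species_a=self.species_b,
            species_b=self.species_a,
            idx_a=self.idx_b.copy(),
            idx_b=self.idx_a.copy(),
            codons_a=list(self.codons_b),
            codons_b=list(self.codons_a),
        )


@dataclass
class ColumnSummary:
    """Per-pair column tallies; ``aligned == conserved + exchanged``."""

    aligned: int
    conserved: int
    exchanged: int
    synonymous: int
    nt12_conserved_synonymous: int
    indel: int
    invalid: int


def classify_columns(pair: SegmentPair) -> ColumnSummary:
    """Tally the column classes of a back-translated pair.

    Indel and invalid columns are excluded from ``aligned``; ``synonymous``
    counts all amino-acid-conserved columns (identical codons included).
    """
    cls = pair.classes
    conserved = int(pair.synonymous_mask.sum())
    exchanged = int(pair.exchanged_mask.sum())
    return ColumnSummary(
        aligned=conserved + exchanged,
        conserved=conserved,
        exchanged=exchanged,
        synonymous=conserved,
        nt12_conserved_synonymous=int((pair.synonymous_mask & pair.nt12_conserved).sum()),
        indel=int((cls == INDEL).sum()),
        invalid=int((cls == INVALID).sum()),
    )


def _codon_at(cds: CodingSequence, i: int) -> str:
    return cds.codon(i)


def backtranslate(
    alignment: SegmentAlignment,
    cds_a: CodingSequence,
    cds_b: CodingSequence,
    code: GeneticCode = STANDARD_CODE,
) -> SegmentPair:
    """Map a protein alignment back onto its coding sequences codon-wise.

    Each residue column becomes one codon column; translation consistency is
    verified per column and a mismatch raises naming the offending column.
    """
    if not alignment.aligned_a:
        raise ValueError(
            f"alignment {alignment.id_a}/{alignment.id_b} has no aligned strings "
            "(external hit? realign first)"
        )
    ia, ib = alignment.start_a, alignment.start_b
    cod_a: list[str] = []
    cod_b: list[str] = []
    for col, (ra, rb) in enumerate(zip(alignment.aligned_a, alignment.aligned_b)):
        if ra == "-":
            cod_a.append("---")
        else:
            c = _codon_at(cds_a, ia)
            if code.translate_codon(c) != ra:
                raise ValueError(
                    f"column {col}: codon {c} of {cds_a.id} translates to "
                    f"{code.translate_codon(c)!r}, alignment says {ra!r}"
                )
            cod_a.append(c)
            ia += 1
        if rb == "-":
            cod_b.append("---")
        else:
            c = _codon_at(cds_b, ib)
            if code.translate_codon(c) != rb:
                raise ValueError(
                    f"column {col}: codon {c} of {cds_b.id} translates to "
                    f"{code.translate_codon(c)!r}, alignment says {rb!r}"
                )
            cod_b.append(c)
            ib += 1
    if ia != alignment.end_a or ib != alignment.end_b:
        raise ValueError("alignment coordinates inconsistent with aligned strings")
    idx_a = np.array(
        [GAP_IDX if c == "---" else codon_index(c) for c in cod_a], dtype=np.int16
    )
    idx_b = np.array(
        [GAP_IDX if c == "---" else codon_index(c) for c in cod_b], dtype=np.int16
    )
    return SegmentPair(
        pair_id=f"{alignment.id_a}|{alignment.id_b}",
        group_id=alignment.group_id,
        species_a=cds_a.species,
        species_b=cds_b.species,
        idx_a=idx_a,
        idx_b=idx_b,
        codons_a=cod_a,
        codons_b=cod_b,
    )


def from_simulated(sim_pair) -> SegmentPair:
    """Fast constructor from a simulator pair (true ancestral alignment)."""
    return SegmentPair(
        pair_id=f"{sim_pair.record.seq_id_a}|{sim_pair.record.seq_id_b}",
        group_id=sim_pair.record.group_id,
        species_a=sim_pair.cds_a.species,
        species_b=sim_pair.cds_b.species,
        idx_a=sim_pair.aligned_a.astype(np.int16),
        idx_b=sim_pair.aligned_b.astype(np.int16),
    )


# ---------------------------------------------------------------------------
# Serialization

def write_pairs_fasta(pairs: list[SegmentPair], path: str | Path) -> None:
    """Paired gapped-FASTA: two records per pair, codons concatenated."""
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f">{p.pair_id}|{p.species_a}\n{''.join(p.codons_a)}\n")
            fh.write(f">{p.pair_id}|{p.species_b}\n{''.join(p.codons_b)}\n")


def read_pairs_fasta(path: str | Path) -> list[SegmentPair]:
    """Inverse of :func:`write_pairs_fasta`."""
    pairs: list[SegmentPair] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) % 4 != 0:
        raise ValueError(f"{path}: expected 4 lines per pair record")
    for k in range(0, len(lines), 4):
        h_a, seq_a, h_b, seq_b = lines[k : k + 4]
        pid_a, sp_a = h_a[1:].rsplit("|", 1)
        pid_b, sp_b = h_b[1:].rsplit("|", 1)
        if pid_a != pid_b:
            raise ValueError(f"{path}: mismatched pair ids {pid_a!r}/{pid_b!r}")
        cod_a = [seq_a[i : i + 3] for i in range(0, len(seq_a), 3)]
        cod_b = [seq_b[i : i + 3] for i in range(0, len(seq_b), 3)]
        idx_a = np.array(
            [GAP_IDX if c == "---" else codon_index(c) for c in cod_a], dtype=np.int16
        )
        idx_b = np.array(
            [GAP_IDX if c == "---" else codon_index(c) for c in cod_b], dtype=np.int16
        )
        pairs.append(
            SegmentPair(
                pair_id=pid_a, group_id=None, species_a=sp_a, species_b=sp_b,
                idx_a=idx_a, idx_b=idx_b, codons_a=cod_a, codons_b=cod_b,
            )
        )
    return pairs


def columns_table(pairs: list[SegmentPair]) -> pd.DataFrame:
    """Per-column TSV-ready table of codons, class and nt12 flag."""
    rows = []
    for p in pairs:
        for col in range(p.n_columns):
            rows.append(
                (
                    p.pair_id,
                    col,
                    p.codons_a[col],
                    p.codons_b[col],
                    CLASS_NAMES[int(p.classes[col])],
                    bool(p.nt12_conserved[col]),
                )
            )
    return pd.DataFrame(
        rows, columns=["pair_id", "column", "codon_a", "codon_b", "class", "nt12_conserved"]
    )
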