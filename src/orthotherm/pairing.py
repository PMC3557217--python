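"""Ortholog pairing: local protein alignment, best-pair-per-group, filters.

The pairing stage mirrors a BLASTP-based reciprocal workflow: every candidate
segment pair within an orthology group is aligned locally (Smith–Waterman,
BLOSUM62, affine gaps with BLAST-style cost ``open + L*extend``), the single
best alignment per group is kept, and pairs are then filtered on percent
identity, e-value (when hits come from an external table) and validity of
the underlying codon alignment (no in-frame stops, no ambiguity codes).

The aligner is exact (full dynamic programming, no heuristics) with a
deterministic traceback: ties prefer diagonal, then up (gap in the second
sequence), then left, and gap states close into a match state on ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .genetics import AMINO_ACIDS, ProteinSegment

#: Aligner alphabet: 20 amino acids, ambiguous 'X', stop '*'.
ALIGN_ALPHABET = AMINO_ACIDS + "X*"
_SYM_INDEX = {s: i for i, s in enumerate(ALIGN_ALPHABET)}

#: '*' must never sit inside a local alignment; a large negative score
#: guarantees it (local alignments can always restart at zero instead).
_STOP_SCORE = -(10**6)


def _blosum62_matrix() -> np.ndarray:
    """BLOSUM62 over ALIGN_ALPHABET; 'X' scores 0 against everything."""
    blosum = substitution_matrices.load("BLOSUM62")
    n = len(ALIGN_ALPHABET)
    m = np.zeros((n, n), dtype=np.int64)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            m[i, j] = int(blosum[a, b])
    stop = _SYM_INDEX["*"]
    m[stop, :] = _STOP_SCORE
    m[:, stop] = _STOP_SCORE
    return m


BLOSUM62 = _blosum62_matrix()


@dataclass(frozen=True)
class AlignmentScoring:
    """Substitution matrix plus affine gap parameters.

    A gap of length L costs ``gap_open + L * gap_extend`` (BLAST convention:
    existence 11, extension 1 means the first gapped residue costs 12).
    """

    matrix: np.ndarray = field(default_factory=lambda: BLOSUM62.copy())
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")


DEFAULT_SCORING = AlignmentScoring()


@dataclass
class SegmentAlignment:
    """A scored local alignment between two protein segments.

    ``aligned_a``/``aligned_b`` are equal-length strings with ``'-'`` gaps;
    codon ranges are 0-based half-open coordinates in each source CDS.
    External (BLAST-table) hits carry empty aligned strings until realigned.
    """

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    percent_identity: float
    start_a: int
    end_a: int
    start_b: int
    end_b: int
    evalue: float | None = None
    group_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")

    @property
    def length(self) -> int:
        return len(self.aligned_a)


def _encode(residues: str, which: str) -> np.ndarray:
    try:
        return np.fromiter(
            (_SYM_INDEX[r] for r in residues), dtype=np.int64, count=len(residues)
        )
    except KeyError as e:
        raise ValueError(
            f"sequence {which}: residue {e.args[0]!r} outside alphabet {ALIGN_ALPHABET!r}"
        ) from None


def percent_identity_of(aligned_a: str, aligned_b: str) -> float:
    """BLAST pident convention: identical pairs / alignment length (gaps count)."""
    if not aligned_a:
        return 0.0
    same = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-"
    )
    return 100.0 * same / len(aligned_a)


def align_local(
    a: ProteinSegment,
    b: ProteinSegment,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> SegmentAlignment:
    """Optimal Smith–Waterman local alignment of two protein segments.

    Exact affine-gap DP; the traceback starts at the maximum-scoring cell
    (row-major first on ties) and on ties prefers diagonal, then up, then
    left. An all-mismatch input yields an empty alignment with score 0.
    """
    if not a.residues or not b.residues:
        raise ValueError("cannot align empty protein segment")
    sa = _encode(a.residues, a.id)
    sb = _encode(b.residues, b.id)
    S, open_, ext = scoring.matrix, scoring.gap_open, scoring.gap_extend
    m, n = len(sa), len(sb)
    NEG = np.int64(-(10**9))

    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)  # gap in a (left moves)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)  # gap in b (up moves)
    jj = np.arange(n + 1, dtype=np.int64)
    sub_rows = S[sa][:, sb]  # m x n substitution scores

    for i in range(1, m + 1):
        F[i, 1:] = np.maximum(F[i - 1, 1:] - ext, H[i - 1, 1:] - open_ - ext)
        diag = H[i - 1, :-1] + sub_rows[i - 1]
        G = np.zeros(n + 1, dtype=np.int64)
        G[1:] = np.maximum(0, np.maximum(diag, F[i, 1:]))
        # E[i, j] = max_{j' < j} (G[j'] - open - (j - j') * ext), computed by
        # a running max of G + j*ext; opening from an E cell is dominated.
        run = np.maximum.accumulate(G + ext * jj)
        E[i, 1:] = run[:-1] - open_ - ext * jj[1:]
        H[i] = np.maximum(G, E[i])
        H[i, 0] = 0

    flat = int(np.argmax(H))
    i, j = divmod(flat, n + 1)
    best = int(H[i, j])
    if best <= 0:
        return SegmentAlignment(
            id_a=a.id, id_b=b.id, aligned_a="", aligned_b="", score=0.0,
            percent_identity=0.0, start_a=a.start_codon, end_a=a.start_codon,
            start_b=b.start_codon, end_b=b.start_codon,
        )

    out_a: list[str] = []
    out_b: list[str] = []
    state = "H"
    end_i, end_j = i, j
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + sub_rows[i - 1, j - 1]:
                out_a.append(a.residues[i - 1])
                out_b.append(b.residues[j - 1])
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = "F"
            elif H[i, j] == E[i, j]:
                state = "E"
            else:  # pragma: no cover - DP consistency guard
                raise AssertionError("inconsistent traceback")
        elif state == "F":  # up: consume a, gap in b
            out_a.append(a.residues[i - 1])
            out_b.append("-")
            closes = H[i - 1, j] - open_ - ext
            if F[i, j] == closes:
                state = "H"
            i -= 1
        else:  # "E", left: gap in a, consume b
            out_a.append("-")
            out_b.append(b.residues[j - 1])
            closes = H[i, j - 1] - open_ - ext
            if E[i, j] == closes:
                state = "H"
            j -= 1

    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    return SegmentAlignment(
        id_a=a.id,
        id_b=b.id,
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(best),
        percent_identity=percent_identity_of(aligned_a, aligned_b),
        start_a=a.start_codon + i,
        end_a=a.start_codon + end_i,
        start_b=b.start_codon + j,
        end_b=b.start_codon + end_j,
    )


# ---------------------------------------------------------------------------
# Pair selection and filtering

@dataclass
class PairSet:
    """At most one retained alignment per orthology group, plus the funnel.

    ``counters`` records the pair counts before/after every stage so the
    final report can show the filter funnel; ``multi_group_ids`` flags
    sequences that are best in more than one group (retained, but reported).
    """

    alignments: list[SegmentAlignment] = field(default_factory=list)
    counters: dict[str, int] = field(default_factory=dict)
    multi_group_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.alignments)


def select_best_pairs(hits: Iterable[SegmentAlignment]) -> PairSet:
    """Keep the single best alignment per orthology group.

    Best = highest score, ties broken by higher percent identity, then by
    lexicographically smallest ``(id_a, id_b)``.
    """
    by_group: dict[str, SegmentAlignment] = {}
    n_hits = 0
    for h in hits:
        if h.group_id is None:
            raise ValueError(f"hit {h.id_a}/{h.id_b} lacks a group_id")
        n_hits += 1
        cur = by_group.get(h.group_id)
        if cur is None or _pair_key(h) > _pair_key(cur):
            by_group[h.group_id] = h
    kept = [by_group[g] for g in sorted(by_group)]
    seen: dict[str, int] = {}
    for h in kept:
        for sid in (h.id_a, h.id_b):
            seen[sid] = seen.get(sid, 0) + 1
    multi = sorted(s for s, k in seen.items() if k > 1)
    return PairSet(
        alignments=kept,
        counters={"hits": n_hits, "groups": len(by_group), "best_pairs": len(kept)},
        multi_group_ids=multi,
    )


def _pair_key(h: SegmentAlignment):
    # ids negated lexicographically via tuple inversion trick: compare on
    # (score, identity, reversed-order ids) so the smallest id pair wins ties.
    return (h.score, h.percent_identity, _NegStr(h.id_a), _NegStr(h.id_b))


class _NegStr(str):
    """String with inverted ordering, for 'smallest id wins' tie-breaks."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def filter_pairs(
    pairs: PairSet,
    min_identity: float = 80.0,
    max_evalue: float = 1e-9,
    min_score: float = 50.0,
    strict_identity: bool = False,
) -> PairSet:
    """Identity / e-value filter.

    Pairs must have ``percent_identity >= min_identity`` (``>`` when
    ``strict_identity``). The e-value criterion applies only to pairs that
    carry an e-value (external hit tables); internally aligned pairs are
    instead required to reach ``min_score`` raw alignment score, since the
    in-repo aligner has no database context to calibrate e-values against.
    """
    if not 0.0 <= min_identity <= 100.0:
        raise ValueError("min_identity outside [0, 100]")
    if max_evalue <= 0.0:
        raise ValueError("max_evalue must be positive")
    kept = []
    for h in pairs.alignments:
        ok_id = (
            h.percent_identity > min_identity
            if strict_identity
            else h.percent_identity >= min_identity
        )
        ok_ev = h.evalue <= max_evalue if h.evalue is not None else h.score >= min_score
        if ok_id and ok_ev:
            kept.append(h)
    counters = dict(pairs.counters)
    counters["after_identity_evalue"] = len(kept)
    return PairSet(alignments=kept, counters=counters, multi_group_ids=pairs.multi_group_ids)


def purge_invalid(pairs: PairSet, codon_pairs: dict[str, "SegmentPair"]) -> tuple[PairSet, list["SegmentPair"]]:
    """Drop pairs whose aligned codon region contains a stop or ambiguity.

    ``codon_pairs`` maps ``pair_id`` (``id_a|id_b``) to the back-translated
    :class:`~orthotherm.codon_align.SegmentPair`. Returns the purged
    :class:`PairSet` together with the surviving codon alignments.
    """
    kept_aln, kept_cp = [], []
    removed = 0
    for h in pairs.alignments:
        key = f"{h.id_a}|{h.id_b}"
        cp = codon_pairs.get(key)
        if cp is None:
            raise ValueError(f"missing codon alignment for pair {key}")
        if cp.n_invalid_columns > 0:
            removed += 1
        else:
            kept_aln.append(h)
            kept_cp.append(cp)
    counters = dict(pairs.counters)
    counters["removed_stop_or_ambiguous"] = removed
    counters["after_purge"] = len(kept_aln)
    return (
        PairSet(alignments=kept_aln, counters=counters, multi_group_ids=pairs.multi_group_ids),
        kept_cp,
    )


# ---------------------------------------------------------------------------
# External tables

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_hits(path: str | Path) -> list[SegmentAlignment]:
    """Read a 12-column BLAST outfmt-6 style TSV into alignment stubs.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    The aligned strings are empty: external hits must be realigned with
    :func:`align_local` before back-translation.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS, comment="#")
    hits = []
    for row in df.itertuples(index=False):
        hits.append(
            SegmentAlignment(
                id_a=str(row.qseqid),
                id_b=str(row.sseqid),
                aligned_a="",
                aligned_b="",
                score=float(row.bitscore),
                percent_identity=float(row.pident),
                start_a=int(row.qstart) - 1,
                end_a=int(row.qend),
                start_b=int(row.sstart) - 1,
                end_b=int(row.send),
                evalue=float(row.evalue),
            )
        )
    return hits


def read_orthology(path: str | Path) -> pd.DataFrame:
    """Orthology assignment TSV: seq_id, group_id, bitscore, evalue."""
    df = pd.read_csv(path, sep="\t", dtype={"seq_id": str, "group_id": str})
    required = {"seq_id", "group_id", "bitscore", "evalue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"orthology table {path} missing columns {sorted(missing)}")
    if (df["evalue"] < 0).any():
        raise ValueError("negative e-value in orthology table")
    return df
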