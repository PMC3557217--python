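"""Synonymous codon-usage analysis.

Four related views of wobble-position (third codon base) composition:

* a paired ledger of GC3<->AT3 shifts over synonymous columns with
  conserved first and second bases — the conditioning that isolates pure
  third-position changes (and excludes cross-family serine pairs);
* per-codon usage-shift panels over the 59 informative sense codons
  (61 minus the invariant ATG and TGG families) with a Fisher exact test
  on the AT3/GC3-by-shift-sign contingency;
* a within-family correspondence analysis (WCA): correspondence analysis of
  codon counts after centering out amino-acid composition, so the leading
  axes reflect synonymous usage only; per-species covariance ellipses
  summarize the row clouds;
* mean GC content of the aligned coding regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genetics import (
    AMINO_ACIDS,
    STANDARD_CODE,
    STOP_CODE,
    THIRD_BASE_AT,
    index_codon,
)
from .codon_align import SegmentPair

#: Codon indices used for usage analyses: sense codons minus ATG and TGG.
INFORMATIVE_CODONS = np.array(
    [
        i
        for i in range(64)
        if STANDARD_CODE.aa_of_codon[i] != STOP_CODE
        and index_codon(i) not in ("ATG", "TGG")
    ],
    dtype=np.int16,
)
INFORMATIVE_NAMES = [index_codon(int(i)) for i in INFORMATIVE_CODONS]
_INF_POS = np.full(64, -1, dtype=np.int16)
_INF_POS[INFORMATIVE_CODONS] = np.arange(len(INFORMATIVE_CODONS))

#: G+C base count per codon index.
GC_PER_CODON = np.array(
    [sum(1 for b in index_codon(i) if b in "GC") for i in range(64)], dtype=np.int8
)


# ---------------------------------------------------------------------------
# GC3 ledger

@dataclass
class CodonPairLedger:
    """Bookkeeping of aligned synonymous codon pairs and their GC3 shifts.

    ``gc3_to_at3`` counts nt12-conserved synonymous columns where species A
    shows A/T in the third base while species B shows G/C (a GC3 loss along
    lineage A relative to B); ``at3_to_gc3`` is the reverse.
    """

    n_aligned_residue_pairs: int = 0
    n_synonymous_nt12_conserved: int = 0
    gc3_to_at3: int = 0
    at3_to_gc3: int = 0

    @property
    def net_gc3_loss_a(self) -> int:
        return self.gc3_to_at3 - self.at3_to_gc3

    def to_dict(self) -> dict:
        return {
            "n_aligned_residue_pairs": self.n_aligned_residue_pairs,
            "n_synonymous_nt12_conserved": self.n_synonymous_nt12_conserved,
            "gc3_to_at3": self.gc3_to_at3,
            "at3_to_gc3": self.at3_to_gc3,
            "net_gc3_loss_a": self.net_gc3_loss_a,
        }


def gc3_ledger(pairs: list[SegmentPair]) -> CodonPairLedger:
    """Accumulate the GC3/AT3 shift ledger over classified pairs.

    Only synonymous, nt12-conserved columns can contribute a shift; columns
    where both third bases fall on the same side (both A/T or both G/C)
    shift nothing.
    """
    led = CodonPairLedger()
    for p in pairs:
        m = p.synonymous_mask & p.nt12_conserved
        led.n_aligned_residue_pairs += int(p.aligned_mask.sum())
        led.n_synonymous_nt12_conserved += int(m.sum())
        a3 = THIRD_BASE_AT[p.idx_a[m]]
        b3 = THIRD_BASE_AT[p.idx_b[m]]
        led.gc3_to_at3 += int((a3 & ~b3).sum())
        led.at3_to_gc3 += int((~a3 & b3).sum())
    return led


# ---------------------------------------------------------------------------
# Codon counts and the shift table

def codon_counts(
    pairs: list[SegmentPair], positions: str = "synonymous"
) -> pd.DataFrame:
    """Per-species codon counts over the 59 informative codons.

    ``positions``: ``"synonymous"`` counts only amino-acid-conserved columns
    (the non-synonymous positions carry replacement signal, not codon-usage
    signal); ``"all"`` counts every aligned valid column.
    """
    if positions not in ("synonymous", "all"):
        raise ValueError("positions must be 'synonymous' or 'all'")
    tot_a = np.zeros(64, dtype=np.int64)
    tot_b = np.zeros(64, dtype=np.int64)
    for p in pairs:
        m = p.synonymous_mask if positions == "synonymous" else p.aligned_mask
        tot_a += np.bincount(p.idx_a[m], minlength=64)
        tot_b += np.bincount(p.idx_b[m], minlength=64)
    return pd.DataFrame(
        {
            "count_a": tot_a[INFORMATIVE_CODONS],
            "count_b": tot_b[INFORMATIVE_CODONS],
        },
        index=pd.Index(INFORMATIVE_NAMES, name="codon"),
    )


def codon_shift_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-codon usage frequencies, shift (A - B), AT3 flag and panel.

    Frequencies are normalized over the 59 informative codons per species,
    so the shifts sum to zero. Panel: ``A_higher`` (shift > 0), ``B_higher``
    (shift < 0) or ``zero`` for exact ties.
    """
    ca = counts["count_a"].to_numpy(dtype=float)
    cb = counts["count_b"].to_numpy(dtype=float)
    if ca.sum() == 0 or cb.sum() == 0:
        raise ValueError("zero total codon count for a species")
    fa = ca / ca.sum()
    fb = cb / cb.sum()
    shift = fa - fb
    at3 = THIRD_BASE_AT[INFORMATIVE_CODONS]
    aa = [AMINO_ACIDS[STANDARD_CODE.aa_of_codon[int(i)]] for i in INFORMATIVE_CODONS]
    panel = np.where(shift > 0, "A_higher", np.where(shift < 0, "B_higher", "zero"))
    return pd.DataFrame(
        {
            "aa": aa,
            "at3": at3,
            "freq_a": fa,
            "freq_b": fb,
            "shift": shift,
            "panel": panel,
        },
        index=counts.index,
    )


@dataclass
class ShiftContingency:
    """2x2 table: rows {AT3, GC3} x columns {shift > 0, shift < 0}."""

    table: np.ndarray
    n_zero: int = 0

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=np.int64)
        if self.table.shape != (2, 2) or np.any(self.table < 0):
            raise ValueError("contingency must be a non-negative 2x2 table")


def shift_contingency(shift_table: pd.DataFrame) -> ShiftContingency:
    at3 = shift_table["at3"].to_numpy(dtype=bool)
    s = shift_table["shift"].to_numpy()
    tab = np.array(
        [
            [(at3 & (s > 0)).sum(), (at3 & (s < 0)).sum()],
            [(~at3 & (s > 0)).sum(), (~at3 & (s < 0)).sum()],
        ],
        dtype=np.int64,
    )
    return ShiftContingency(tab, n_zero=int((s == 0).sum()))


def fisher_exact_2x2(table: ShiftContingency | np.ndarray) -> float:
    """Two-sided Fisher exact p (point-probability rule).

    Conditional on the margins, sums the hypergeometric probabilities of all
    tables whose point probability does not exceed the observed one.
    """
    tab = table.table if isinstance(table, ShiftContingency) else np.asarray(table)
    if tab.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if np.any(tab < 0):
        raise ValueError("negative cell in contingency table")
    _, p = stats.fisher_exact(tab, alternative="two-sided")
    return float(p)


# ---------------------------------------------------------------------------
# Within-family correspondence analysis

@dataclass
class Ellipse:
    """A covariance ellipse: center, 2x2 covariance, scale in SDs."""

    center: np.ndarray
    cov: np.ndarray
    scale: float

    @property
    def semi_axes(self) -> np.ndarray:
        vals = np.clip(np.linalg.eigvalsh(self.cov), 0.0, None)
        return self.scale * np.sqrt(vals[::-1])

    @property
    def angle_deg(self) -> float:
        vals, vecs = np.linalg.eigh(self.cov)
        major = vecs[:, int(np.argmax(vals))]
        return float(np.degrees(np.arctan2(major[1], major[0])))

    def to_dict(self) -> dict:
        return {
            "center": self.center.tolist(),
            "cov": self.cov.tolist(),
            "scale": self.scale,
            "semi_axes": self.semi_axes.tolist(),
            "angle_deg": self.angle_deg,
        }


@dataclass
class WCAResult:
    """Axes and coordinates of the within-family correspondence analysis."""

    eigenvalues: np.ndarray
    row_coords: pd.DataFrame  # index: (segment, species); columns: axis1..k
    col_coords: pd.DataFrame  # index: codon
    row_weights: np.ndarray
    ellipses: dict[str, Ellipse] = field(default_factory=dict)


def build_wca_counts(
    pairs: list[SegmentPair], positions: str = "synonymous", pooled: bool = False
) -> pd.DataFrame:
    """Codon-count rows for the WCA: one row per segment and species.

    ``pooled=True`` collapses each species to a single row.
    """
    rows = {}
    for p in pairs:
        m = p.synonymous_mask if positions == "synonymous" else p.aligned_mask
        ca = np.bincount(p.idx_a[m], minlength=64)[INFORMATIVE_CODONS]
        cb = np.bincount(p.idx_b[m], minlength=64)[INFORMATIVE_CODONS]
        rows[(p.pair_id, p.species_a)] = ca
        rows[(p.pair_id, p.species_b)] = cb
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=np.int64)
    df.columns = INFORMATIVE_NAMES
    df.index = pd.MultiIndex.from_tuples(df.index, names=["segment", "species"])
    if pooled:
        df = df.groupby(level="species").sum()
        df.index = pd.MultiIndex.from_arrays(
            [["pooled"] * len(df), df.index], names=["segment", "species"]
        )
    return df


def wca(
    counts: pd.DataFrame,
    n_axes: int = 2,
    ellipse_scale: float = 1.5,
) -> WCAResult:
    """Within-family correspondence analysis of a codon-count table.

    Rows are (segment, species) codon-count vectors over the 59 informative
    codons. Each row's counts are converted to within-family frequencies
    (codon count / that row's family total), family effects are centered out
    against the row-weighted mean profile, columns are scaled by the
    chi-square metric, and the row-weighted matrix is decomposed by SVD.
    Axis 1 is sign-oriented so the mean coordinate of AT3 codons is positive.

    Rows with zero total count are dropped; a rank-0 (all-identical) table
    is an error.
    """
    mat = counts.to_numpy(dtype=float)
    totals = mat.sum(axis=1)
    keep = totals > 0
    mat, totals = mat[keep], totals[keep]
    index = counts.index[keep]
    if mat.shape[0] < 2:
        raise ValueError("need at least two non-empty rows")

    fam = np.array(
        [STANDARD_CODE.aa_of_codon[int(i)] for i in INFORMATIVE_CODONS], dtype=np.int64
    )
    n_fam = 20
    w = totals / totals.sum()

    # within-family row frequencies; rows missing a family fall back to the
    # pooled within-family shares (a zero-information profile there)
    fam_tot = np.zeros((mat.shape[0], n_fam))
    np.add.at(fam_tot.T, fam, mat.T)
    pooled = mat.sum(axis=0)
    pooled_fam = np.zeros(n_fam)
    np.add.at(pooled_fam, fam, pooled)
    g = np.where(pooled_fam[fam] > 0, pooled / np.maximum(pooled_fam[fam], 1.0), 0.0)
    denom = fam_tot[:, fam]
    f = np.where(denom > 0, mat / np.where(denom > 0, denom, 1.0), g[None, :])

    m_j = w @ f
    if np.any(m_j <= 0):
        raise ValueError("a codon has zero mass across all rows")
    Z = (f - m_j[None, :]) / np.sqrt(m_j)[None, :]
    A = np.sqrt(w)[:, None] * Z
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    if s[0] < 1e-12:
        raise ValueError("degenerate table: no synonymous-usage variance")
    k = min(n_axes, int((s > 1e-12).sum()))
    U, s, V = U[:, :k], s[:k], Vt[:k].T

    row = (U * s) / np.sqrt(w)[:, None]
    col = V * s

    at3 = THIRD_BASE_AT[INFORMATIVE_CODONS]
    if col[at3, 0].mean() < 0:
        row[:, 0] *= -1
        col[:, 0] *= -1

    axes = [f"axis{i + 1}" for i in range(k)]
    row_df = pd.DataFrame(row, index=index, columns=axes)
    col_df = pd.DataFrame(col, index=pd.Index(INFORMATIVE_NAMES, name="codon"), columns=axes)

    ellipses: dict[str, Ellipse] = {}
    if isinstance(index, pd.MultiIndex) and "species" in index.names:
        species = index.get_level_values("species")
        for sp in sorted(set(species)):
            pts = row[np.asarray(species == sp)][:, : min(2, k)]
            if pts.shape[1] < 2:
                pts = np.column_stack([pts, np.zeros(len(pts))])
            center = pts.mean(axis=0)
            cov = np.cov(pts.T) if len(pts) > 1 else np.zeros((2, 2))
            ellipses[sp] = Ellipse(center=center, cov=np.atleast_2d(cov), scale=ellipse_scale)

    return WCAResult(
        eigenvalues=s**2,
        row_coords=row_df,
        col_coords=col_df,
        row_weights=w,
        ellipses=ellipses,
    )


# ---------------------------------------------------------------------------
# GC summaries

def mean_gc(pairs: list[SegmentPair]) -> dict:
    """Mean GC fraction (percent) of the gap-free aligned coding regions.

    The headline number is the unweighted mean over segments; the pooled
    (length-weighted) value and the per-segment values are also returned.
    """
    per_a, per_b = [], []
    gc_nt_a = gc_nt_b = nt_a = nt_b = 0
    for p in pairs:
        for idx, acc, side in ((p.idx_a, per_a, "a"), (p.idx_b, per_b, "b")):
            codons = idx[idx >= 0]
            if len(codons) == 0:
                continue
            gc = int(GC_PER_CODON[codons].sum())
            n = 3 * len(codons)
            acc.append(100.0 * gc / n)
            if side == "a":
                gc_nt_a, nt_a = gc_nt_a + gc, nt_a + n
            else:
                gc_nt_b, nt_b = gc_nt_b + gc, nt_b + n
    return {
        "mean_gc_a_pct": float(np.mean(per_a)),
        "mean_gc_b_pct": float(np.mean(per_b)),
        "pooled_gc_a_pct": 100.0 * gc_nt_a / nt_a,
        "pooled_gc_b_pct": 100.0 * gc_nt_b / nt_b,
        "per_segment_a": per_a,
        "per_segment_b": per_b,
    }
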