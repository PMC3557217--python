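"""Non-synonymous analysis: replacement counts, imbalance, net usage, ERK test.

From the classified codon alignments this module builds the 20x20 amino-acid
replacement count matrix C (C[i, j] = columns with residue i in species A
and j in species B; the diagonal holds conserved columns), its antisymmetric
imbalance transform D = C - C^T, per-amino-acid net usage for species A, and
the paired Wilcoxon signed-rank test on the per-segment counts of E+R+K
residues at exchanged positions — a classic proxy for thermal adaptation of
protein composition (charged residues trade off against polar ones in
cold-adapted enzymes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genetics import AMINO_ACIDS, AA_INDEX
from .codon_align import SegmentPair

ERK_INDICES = np.array([AA_INDEX[a] for a in "ERK"])


@dataclass
class ReplacementMatrix:
    """20x20 replacement counts; diagonal = conserved columns."""

    counts: np.ndarray
    species_a: str = "A"
    species_b: str = "B"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (20, 20):
            raise ValueError("replacement matrix must be 20x20")
        if np.any(self.counts < 0):
            raise ValueError("negative replacement counts")

    @property
    def total_exchanged(self) -> int:
        return int(self.counts.sum() - np.trace(self.counts))

    def to_frame(self) -> pd.DataFrame:
        aa = list(AMINO_ACIDS)
        return pd.DataFrame(self.counts, index=aa, columns=aa)


@dataclass
class ImbalanceMatrix:
    """Antisymmetric transform D[i, j] = C[i, j] - C[j, i].

    Positive D[i, j]: amino acid i is preferred in species A at positions
    where species B shows j.
    """

    values: np.ndarray
    species_a: str = "A"
    species_b: str = "B"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (20, 20):
            raise ValueError("imbalance matrix must be 20x20")
        if np.any(self.values + self.values.T != 0):
            raise ValueError("imbalance matrix must be antisymmetric")

    def to_frame(self) -> pd.DataFrame:
        aa = list(AMINO_ACIDS)
        return pd.DataFrame(self.values, index=aa, columns=aa)

    def lower_triangle_frame(self) -> pd.DataFrame:
        """The conventional printed layout: rows C..Y vs columns A..W.

        Cell (i, j) shows D[i, j] for row amino acid i (preferred in species
        A when positive) against column amino acid j; only the lower
        triangle is shown, the rest is blank.
        """
        aa = list(AMINO_ACIDS)
        out = pd.DataFrame("", index=aa[1:], columns=aa[:-1], dtype=object)
        for r in range(1, 20):
            for c in range(r):
                out.iloc[r - 1, c] = int(self.values[r, c])
        return out


def count_replacements(pairs: list[SegmentPair]) -> ReplacementMatrix:
    """Accumulate the replacement matrix over all aligned valid columns."""
    if not pairs:
        raise ValueError("no pairs to count")
    C = np.zeros((20, 20), dtype=np.int64)
    for p in pairs:
        if p.classes is None:
            raise ValueError(f"pair {p.pair_id} not classified")
        aa_a, aa_b = p.aa_indices()
        np.add.at(C, (aa_a, aa_b), 1)
    return ReplacementMatrix(C, species_a=pairs[0].species_a, species_b=pairs[0].species_b)


def imbalance(C: ReplacementMatrix) -> ImbalanceMatrix:
    """D = C - C^T; the diagonal (conserved counts) cancels exactly."""
    return ImbalanceMatrix(
        C.counts - C.counts.T, species_a=C.species_a, species_b=C.species_b
    )


def net_usage(D: ImbalanceMatrix) -> pd.Series:
    """Per-amino-acid net change for species A: net(i) = sum_j D[i, j].

    Antisymmetry forces the nets to sum to zero exactly.
    """
    return pd.Series(D.values.sum(axis=1), index=list(AMINO_ACIDS), name="net")


def aggregate_by_class(net: pd.Series, partition: dict[str, str]) -> pd.Series:
    """Sum net usage over a user-supplied amino-acid partition.

    ``partition`` maps each one-letter amino acid to a class label (e.g.
    polar/unpolar); amino acids left out are pooled under ``"other"``.
    """
    labels = {a: partition.get(a, "other") for a in AMINO_ACIDS}
    return net.groupby(labels).sum()


# ---------------------------------------------------------------------------
# ERK proxy

@dataclass
class ErkRecord:
    """Per-pair counts of E/R/K residues among exchanged positions."""

    pair_id: str
    erk_a: int
    erk_b: int
    exchanged: int


def erk_records(pairs: list[SegmentPair]) -> list[ErkRecord]:
    out = []
    for p in pairs:
        m = p.exchanged_mask
        aa_a, aa_b = p.aa_indices()
        exch = p.exchanged_mask[p.aligned_mask]
        ea = int(np.isin(aa_a[exch], ERK_INDICES).sum())
        eb = int(np.isin(aa_b[exch], ERK_INDICES).sum())
        out.append(ErkRecord(pair_id=p.pair_id, erk_a=ea, erk_b=eb, exchanged=int(m.sum())))
    return out


@dataclass
class ErkTestResult:
    records: list[ErkRecord]
    statistic: float
    p_value: float
    n_effective: int
    fraction_mode: bool = False


def erk_test(pairs: list[SegmentPair], fraction: bool = False) -> ErkTestResult:
    """Paired two-sided Wilcoxon signed-rank test on per-pair ERK counts.

    Differences ``d = erk_a - erk_b`` (or count/exchanged fractions with
    ``fraction=True``); zero differences are dropped (Wilcoxon's original
    rule). The null distribution is enumerated exactly when the effective n
    is at most 25 with untied |d|, otherwise the normal approximation with
    tie and continuity correction is used. All-zero differences yield
    p = 1.0 with a warning rather than an error.
    """
    records = erk_records(pairs)
    if not any(r.exchanged > 0 for r in records):
        raise ValueError("no pair has an exchanged position")
    if fraction:
        d = np.array(
            [
                (r.erk_a - r.erk_b) / r.exchanged
                for r in records
                if r.exchanged > 0
            ]
        )
    else:
        d = np.array([float(r.erk_a - r.erk_b) for r in records])
    nz = d[d != 0]
    if len(nz) == 0:
        warnings.warn("all ERK differences are zero; p = 1.0", stacklevel=2)
        return ErkTestResult(records, statistic=0.0, p_value=1.0, n_effective=0,
                             fraction_mode=fraction)
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        nz, zero_method="wilcox", alternative="two-sided", correction=True,
        method=method,
    )
    return ErkTestResult(
        records,
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        n_effective=len(nz),
        fraction_mode=fraction,
    )


def erk_table(records: list[ErkRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.pair_id, r.erk_a, r.erk_b, r.exchanged) for r in records],
        columns=["pair_id", "erk_a", "erk_b", "exchanged"],
    )
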