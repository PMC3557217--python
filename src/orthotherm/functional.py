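"""Functional-category profiling of orthology-term hits.

Sequences are annotated with orthology terms (e.g. metazoan NOGs) carrying
e-values; per sequence only the best hit below a stringent threshold is
kept, terms are pooled into single-letter COG/KOG functional categories,
coverage is computed against a reference gene set profiled the same way,
and terms overrepresented in one library are ranked by a per-term Fisher
exact test with Benjamini–Hochberg correction.

Because cDNA libraries here are normalized, counts are a presence/diversity
profile of the transcriptome, not expression levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .codon_usage import fisher_exact_2x2

HIT_COLUMNS = ["seq_id", "term_id", "evalue"]


def read_term_hits(path: str | Path) -> pd.DataFrame:
    """Read a term-hit TSV (seq_id, term_id, evalue[, bitscore])."""
    df = pd.read_csv(path, sep="\t", dtype={"seq_id": str, "term_id": str})
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"term hit table {path} missing columns {sorted(missing)}")
    bad = df["evalue"].isna() | (df["evalue"] < 0)
    if bad.any():
        raise ValueError(f"malformed hit row(s) at line(s) {list(df.index[bad] + 2)}")
    return df


def best_term_per_sequence(hits: pd.DataFrame, max_evalue: float = 1e-20) -> pd.DataFrame:
    """Minimum-e-value row per sequence, then threshold at ``max_evalue``.

    Ties on e-value break to the higher bitscore (when present), then to
    the lexicographically smallest term id. Idempotent and independent of
    input row order.
    """
    if hits.empty:
        return hits.copy()
    df = hits.copy()
    if "bitscore" not in df.columns:
        df["bitscore"] = 0.0
    df = df.sort_values(
        ["seq_id", "evalue", "bitscore", "term_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    best = df.groupby("seq_id", sort=True).head(1)
    best = best[best["evalue"] <= max_evalue]
    return best.reset_index(drop=True)


def read_term2cat(path: str | Path) -> pd.DataFrame:
    """term→category map TSV: term_id, categories (letter string), description."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if not {"term_id", "categories"} <= set(df.columns):
        raise ValueError(f"term2cat table {path} needs term_id and categories columns")
    return df


@dataclass
class CategoryProfile:
    """Counts per single-letter COG/KOG category.

    With full counting a term mapped to k categories contributes k
    increments, so the category counts can sum to more than the number of
    classified sequences.
    """

    counts: dict[str, float] = field(default_factory=dict)
    total_classified: int = 0
    unknown: int = 0

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, dtype=float).sort_index()


def pool_categories(
    hits: pd.DataFrame,
    term2cat: pd.DataFrame | dict[str, str],
    fractional: bool = False,
) -> CategoryProfile:
    """Pool best-hit terms into functional categories.

    ``fractional=True`` splits a multi-category term's single increment
    evenly over its categories instead of full counting. Terms absent from
    the map count under ``unknown`` and increment no category.
    """
    if isinstance(term2cat, pd.DataFrame):
        mapping = dict(zip(term2cat["term_id"], term2cat["categories"]))
    else:
        mapping = dict(term2cat)
    prof = CategoryProfile()
    for term in hits["term_id"] if not hits.empty else []:
        prof.total_classified += 1
        cats = mapping.get(term, "")
        if not cats:
            prof.unknown += 1
            continue
        inc = 1.0 / len(cats) if fractional else 1.0
        for c in cats:
            prof.counts[c] = prof.counts.get(c, 0.0) + inc
    return prof


def coverage_vs_reference(lib: CategoryProfile, ref: CategoryProfile) -> pd.DataFrame:
    """Per-category coverage = library count / reference count.

    Categories missing from the reference are reported with coverage NaN
    (undefined), not zero; coverage above 1 is legitimate. A count-weighted
    aggregate over categories defined in the reference is attached under the
    ``"(aggregate)"`` row.
    """
    cats = sorted(set(lib.counts) | set(ref.counts))
    rows = []
    lib_tot = ref_tot = 0.0
    for c in cats:
        lc = lib.counts.get(c, 0.0)
        rc = ref.counts.get(c, 0.0)
        cov = lc / rc if rc > 0 else float("nan")
        if rc > 0:
            lib_tot += lc
            ref_tot += rc
        rows.append((c, lc, rc, cov))
    agg = lib_tot / ref_tot if ref_tot > 0 else float("nan")
    rows.append(("(aggregate)", lib_tot, ref_tot, agg))
    return pd.DataFrame(rows, columns=["category", "lib_count", "ref_count", "coverage"])


def library_specific_terms(
    hits_a: pd.DataFrame, hits_b: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Rank terms by evidence of library-specific overrepresentation.

    For each term t the 2x2 table
    ``[[count_A(t), total_A - count_A(t)], [count_B(t), total_B - count_B(t)]]``
    is tested with the Fisher exact test; rows are ranked by p, then by
    |count difference|, with Benjamini–Hochberg q-values attached and a
    ``specific_at_q`` flag at the requested level.
    """
    ca = hits_a["term_id"].value_counts() if not hits_a.empty else pd.Series(dtype=int)
    cb = hits_b["term_id"].value_counts() if not hits_b.empty else pd.Series(dtype=int)
    na, nb = int(ca.sum()), int(cb.sum())
    terms = sorted(set(ca.index) | set(cb.index))
    rows = []
    for t in terms:
        a = int(ca.get(t, 0))
        b = int(cb.get(t, 0))
        p = fisher_exact_2x2(np.array([[a, na - a], [b, nb - b]]))
        rows.append((t, a, b, a - b, p))
    df = pd.DataFrame(rows, columns=["term_id", "count_a", "count_b", "difference", "p"])
    if df.empty:
        df["q"] = pd.Series(dtype=float)
        df["specific_at_q"] = pd.Series(dtype=bool)
        return df
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["specific_at_q"] = df["q"] < alpha
    df = df.sort_values(
        ["p", "difference"],
        key=lambda s: -s.abs() if s.name == "difference" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    return df
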