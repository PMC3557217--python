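"""Independent brute-force oracles used by the test suite.

Everything here is written as plain scalar Python, deliberately avoiding the
vectorized code paths of the package: per-cell dynamic programming for the
local aligner, full 2^n sign enumeration for the signed-rank test, full
hypergeometric enumeration for the Fisher test, and per-position string
rescans for the counting statistics.
"""

from __future__ import annotations

import math
from itertools import product

from orthotherm.genetics import STANDARD_CODE

NEG = float("-inf")


def sw_affine_oracle(a: str, b: str, score, open_=11, ext=1):
    """Exhaustive affine-gap Smith–Waterman; returns (score, aligned_a, aligned_b).

    Same gap model as the package (gap of length L costs open + L*ext) and
    the same traceback tie-break (diagonal, then up, then left; gap states
    close into match on ties), but computed cell by cell with explicit
    three-state recurrences.
    """
    m, n = len(a), len(b)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in a (left)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in b (up)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1] - ext, H[i][j - 1] - open_ - ext)
            F[i][j] = max(F[i - 1][j] - ext, H[i - 1][j] - open_ - ext)
            diag = H[i - 1][j - 1] + score(a[i - 1], b[j - 1])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
    best, bi, bj = 0.0, 0, 0
    for i in range(m + 1):
        for j in range(n + 1):
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j
    if best <= 0:
        return 0.0, "", ""
    out_a, out_b = [], []
    i, j, state = bi, bj, "H"
    while True:
        if state == "H":
            if H[i][j] == 0:
                break
            if i > 0 and j > 0 and H[i][j] == H[i - 1][j - 1] + score(a[i - 1], b[j - 1]):
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i, j = i - 1, j - 1
            elif H[i][j] == F[i][j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            out_a.append(a[i - 1])
            out_b.append("-")
            if F[i][j] == H[i - 1][j] - open_ - ext:
                state = "H"
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            if E[i][j] == H[i][j - 1] - open_ - ext:
                state = "H"
            j -= 1
    return best, "".join(reversed(out_a)), "".join(reversed(out_b))


def wilcoxon_exact_oracle(diffs) -> float:
    """Two-sided exact signed-rank p by full 2^n sign enumeration.

    Requires non-zero differences with untied absolute values. p =
    min(1, 2 * min(P(W+ <= w), P(W+ >= w))) under the uniform sign null.
    """
    d = [x for x in diffs if x != 0]
    n = len(d)
    ranks = sorted(range(n), key=lambda k: abs(d[k]))
    rank_of = [0] * n
    for r, k in enumerate(ranks):
        rank_of[k] = r + 1
    w_obs = sum(rank_of[k] for k in range(n) if d[k] > 0)
    values = []
    for signs in product([0, 1], repeat=n):
        values.append(sum(rank_of[k] for k in range(n) if signs[k]))
    total = len(values)
    le = sum(1 for v in values if v <= w_obs)
    ge = sum(1 for v in values if v >= w_obs)
    return min(1.0, 2.0 * min(le, ge) / total)


def fisher_exact_oracle(table) -> float:
    """Two-sided Fisher p by enumerating all tables with the given margins.

    Point-probability rule: sum the probabilities of all tables whose
    probability is <= the observed one (with a small relative tolerance for
    floating-point equality).
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_comb(n_, k_):
        return math.lgamma(n_ + 1) - math.lgamma(k_ + 1) - math.lgamma(n_ - k_ + 1)

    denom = log_comb(n, c1)

    def prob(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return math.exp(log_comb(r1, x) + log_comb(r2, c1 - x) - denom)

    p_obs = prob(a)
    total = 0.0
    for x in range(0, min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(1.0, total)


# ---------------------------------------------------------------------------
# Per-position string rescans

def rescan_classify(codons_a, codons_b):
    """Naive per-column classification of aligned codon triplet lists."""
    out = []
    for ca, cb in zip(codons_a, codons_b):
        if ca == "---" or cb == "---":
            out.append("indel")
            continue
        if any(ch not in "ACGT" for ch in ca + cb):
            out.append("invalid")
            continue
        aa = STANDARD_CODE.table[ca]
        ab = STANDARD_CODE.table[cb]
        if aa == "*" or ab == "*":
            out.append("invalid")
        elif ca == cb:
            out.append("codon_identical")
        elif aa == ab:
            out.append("synonymous")
        else:
            out.append("nonsynonymous")
    return out


def rescan_replacements(pairs):
    """20x20 replacement counts by direct string rescan."""
    from orthotherm.genetics import AA_INDEX

    C = [[0] * 20 for _ in range(20)]
    for p in pairs:
        for ca, cb, cls in zip(
            p.codons_a, p.codons_b, rescan_classify(p.codons_a, p.codons_b)
        ):
            if cls in ("codon_identical", "synonymous", "nonsynonymous"):
                C[AA_INDEX[STANDARD_CODE.table[ca]]][AA_INDEX[STANDARD_CODE.table[cb]]] += 1
    return C


def rescan_gc3(pairs):
    """GC3 ledger counts by direct string rescan."""
    n_aligned = n_syn12 = g2a = a2g = 0
    for p in pairs:
        for ca, cb, cls in zip(
            p.codons_a, p.codons_b, rescan_classify(p.codons_a, p.codons_b)
        ):
            if cls in ("codon_identical", "synonymous", "nonsynonymous"):
                n_aligned += 1
            if cls in ("codon_identical", "synonymous") and ca[:2] == cb[:2]:
                n_syn12 += 1
                a_at = ca[2] in "AT"
                b_at = cb[2] in "AT"
                if a_at and not b_at:
                    g2a += 1
                elif b_at and not a_at:
                    a2g += 1
    return {
        "n_aligned_residue_pairs": n_aligned,
        "n_synonymous_nt12_conserved": n_syn12,
        "gc3_to_at3": g2a,
        "at3_to_gc3": a2g,
    }
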