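#!/usr/bin/env python
"""Synonymous codon-usage analysis of the retained pairs.

Builds the GC3/AT3 shift ledger over nt12-conserved synonymous columns,
the per-codon usage-shift panels with the Fisher exact test on the
AT3/GC3-by-shift-sign contingency, the within-family correspondence
analysis with per-species covariance ellipses, and GC summaries.
"""

import json
from pathlib import Path

from orthotherm import codon_usage
from orthotherm.codon_align import read_pairs_fasta

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    pairs = read_pairs_fasta(ROOT / "codon_alignments.fasta")

    ledger = codon_usage.gc3_ledger(pairs)
    counts = codon_usage.codon_counts(pairs)
    shift = codon_usage.codon_shift_table(counts)
    cont = codon_usage.shift_contingency(shift)
    fisher_p = codon_usage.fisher_exact_2x2(cont)
    gc = codon_usage.mean_gc(pairs)
    res = codon_usage.wca(codon_usage.build_wca_counts(pairs))

    shift.to_csv(ROOT / "codon_shift_table.tsv", sep="\t")
    res.row_coords.round(10).to_csv(ROOT / "wca_row_coords.tsv", sep="\t")
    res.col_coords.round(10).to_csv(ROOT / "wca_col_coords.tsv", sep="\t")
    summary = {
        "ledger": ledger.to_dict(),
        "contingency": cont.table.tolist(),
        "n_zero_shift": cont.n_zero,
        "fisher_p": fisher_p,
        "mean_gc_a_pct": gc["mean_gc_a_pct"],
        "mean_gc_b_pct": gc["mean_gc_b_pct"],
        "wca_eigenvalues": [float(x) for x in res.eigenvalues],
        "wca_ellipses": {sp: e.to_dict() for sp, e in res.ellipses.items()},
    }
    (ROOT / "codon_summary.json").write_text(json.dumps(summary, indent=1))

    print(f"synonymous nt12-conserved pairs: {ledger.n_synonymous_nt12_conserved}")
    print(f"net GC3 loss (lineage A): {ledger.net_gc3_loss_a} "
          f"({ledger.gc3_to_at3} GC3->AT3 vs {ledger.at3_to_gc3} AT3->GC3)")
    print(f"shift contingency {cont.table.tolist()}  Fisher p = {fisher_p:.3g}")
    ca = res.ellipses["A"].center
    cb = res.ellipses["B"].center
    print(f"WCA ellipse centers: A=({ca[0]:+.4f},{ca[1]:+.4f}) "
          f"B=({cb[0]:+.4f},{cb[1]:+.4f}) (axis-1 separation carries the GC3 signal)")
    print(f"mean GC: A {gc['mean_gc_a_pct']:.3f}%  B {gc['mean_gc_b_pct']:.3f}%")


if __name__ == "__main__":
    main()
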