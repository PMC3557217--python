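"""End-to-end orchestration: configuration, the stage chain, and the report.

``run_all`` chains the full analysis — load or simulate the two species'
coding sequences and orthology tables, translate, align every candidate
pair within each orthology group, keep the best pair per group, apply the
identity/e-value filters, back-translate to codon alignments, purge pairs
with stops or ambiguity codes, and run the amino-acid and codon-usage
analyses — writing every intermediate table plus a consolidated JSON
report. Given the same configuration and seed the report is byte-identical
across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genetics import read_fasta, translate
from .simulate import PRESETS, SimulationParams, preset_params, emit_dataset
from .pairing import (
    PairSet,
    align_local,
    filter_pairs,
    read_orthology,
    select_best_pairs,
)
from .codon_align import SegmentPair, backtranslate, classify_columns, write_pairs_fasta, columns_table
from .pairing import purge_invalid
from . import aa_usage, codon_usage
from .functional import (
    best_term_per_sequence,
    coverage_vs_reference,
    library_specific_terms,
    pool_categories,
    read_term2cat,
    read_term_hits,
)

log = logging.getLogger("orthotherm")


@dataclass
class PipelineConfig:
    """Validated flat configuration for the full pipeline."""

    # inputs: either a simulation preset or explicit paths
    preset: str | None = None
    fasta_a: str | None = None
    fasta_b: str | None = None
    orthology_a: str | None = None
    orthology_b: str | None = None
    term_hits_a: str | None = None
    term_hits_b: str | None = None
    term_hits_ref: str | None = None
    term2cat: str | None = None
    # thresholds
    min_identity: float = 80.0
    strict_identity: bool = False
    max_evalue: float = 1e-9
    min_score: float = 50.0
    term_max_evalue: float = 1e-20
    ellipse_scale: float = 1.5
    wca_axes: int = 2
    codon_positions: str = "synonymous"
    # run
    outdir: str = "orthotherm_out"
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_RANGES = {
    "min_identity": (0.0, 100.0),
    "max_evalue": (1e-300, 1e3),
    "min_score": (0.0, 1e9),
    "term_max_evalue": (1e-300, 1e3),
    "ellipse_scale": (0.0, 10.0),
    "wca_axes": (1, 10),
}


def validate_config(raw: dict) -> PipelineConfig:
    """Normalize a flat key-value mapping into a :class:`PipelineConfig`.

    Unknown keys are rejected; every range violation is reported with its
    key. An empty mapping yields all defaults.
    """
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    errors = [f"unknown key {k!r}" for k in raw if k not in known]
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    for key, (lo, hi) in _RANGES.items():
        v = getattr(cfg, key)
        if not lo <= v <= hi:
            errors.append(f"{key}={v} outside [{lo}, {hi}]")
    if cfg.codon_positions not in ("synonymous", "all"):
        errors.append(f"codon_positions={cfg.codon_positions!r} not in ('synonymous', 'all')")
    if cfg.preset is not None and cfg.preset not in PRESETS:
        errors.append(f"preset={cfg.preset!r} unknown; have {sorted(PRESETS)}")
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    return cfg


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return validate_config(raw)


# ---------------------------------------------------------------------------
# Stage driver

def build_pairs(
    seqs_a,
    seqs_b,
    orth_a: pd.DataFrame,
    orth_b: pd.DataFrame,
    cfg: PipelineConfig,
) -> tuple[PairSet, list[SegmentPair], dict]:
    """Group → align → select-best → filter → back-translate → purge."""
    by_id_a = {s.id: s for s in seqs_a}
    by_id_b = {s.id: s for s in seqs_b}
    prots_a = {s.id: translate(s) for s in seqs_a}
    prots_b = {s.id: translate(s) for s in seqs_b}

    groups_a: dict[str, list[str]] = {}
    for row in orth_a.itertuples(index=False):
        groups_a.setdefault(row.group_id, []).append(row.seq_id)
    groups_b: dict[str, list[str]] = {}
    for row in orth_b.itertuples(index=False):
        groups_b.setdefault(row.group_id, []).append(row.seq_id)

    shared = sorted(set(groups_a) & set(groups_b))
    hits = []
    for g in shared:
        for ida in sorted(set(groups_a[g])):
            for idb in sorted(set(groups_b[g])):
                if ida not in prots_a or idb not in prots_b:
                    continue
                aln = align_local(prots_a[ida], prots_b[idb])
                if aln.length == 0:
                    continue
                aln.group_id = g
                hits.append(aln)
    best = select_best_pairs(hits)
    best.counters["groups_seen"] = len(shared)
    filtered = filter_pairs(
        best,
        min_identity=cfg.min_identity,
        max_evalue=cfg.max_evalue,
        min_score=cfg.min_score,
        strict_identity=cfg.strict_identity,
    )
    codon_pairs = {}
    for h in filtered.alignments:
        cp = backtranslate(h, by_id_a[h.id_a], by_id_b[h.id_b])
        codon_pairs[cp.pair_id] = cp
    purged, kept_pairs = purge_invalid(filtered, codon_pairs)
    funnel = dict(purged.counters)
    funnel["sequences_a"] = len(seqs_a)
    funnel["sequences_b"] = len(seqs_b)
    return purged, kept_pairs, funnel


def analyze(pairs: list[SegmentPair], cfg: PipelineConfig) -> dict:
    """All headline statistics from a purged set of classified pairs."""
    summaries = [classify_columns(p) for p in pairs]
    col_totals = {
        "aligned_residue_pairs": sum(s.aligned for s in summaries),
        "conserved": sum(s.conserved for s in summaries),
        "exchanged": sum(s.exchanged for s in summaries),
        "synonymous_nt12_conserved": sum(s.nt12_conserved_synonymous for s in summaries),
        "indel_columns": sum(s.indel for s in summaries),
    }

    C = aa_usage.count_replacements(pairs)
    D = aa_usage.imbalance(C)
    net = aa_usage.net_usage(D)
    try:
        erk = aa_usage.erk_test(pairs)
    except ValueError as e:
        log.warning("ERK test skipped: %s", e)
        erk = None

    ledger = codon_usage.gc3_ledger(pairs)
    counts = codon_usage.codon_counts(pairs, positions=cfg.codon_positions)
    shift = codon_usage.codon_shift_table(counts)
    cont = codon_usage.shift_contingency(shift)
    fisher_p = codon_usage.fisher_exact_2x2(cont)
    gc = codon_usage.mean_gc(pairs)

    wca_res = None
    try:
        wca_counts = codon_usage.build_wca_counts(pairs, positions=cfg.codon_positions)
        wca_res = codon_usage.wca(
            wca_counts, n_axes=cfg.wca_axes, ellipse_scale=cfg.ellipse_scale
        )
    except ValueError as e:
        log.warning("WCA skipped: %s", e)

    return {
        "column_totals": col_totals,
        "replacement": C,
        "imbalance": D,
        "net_usage": net,
        "erk": erk,
        "ledger": ledger,
        "codon_counts": counts,
        "shift_table": shift,
        "contingency": cont,
        "fisher_p": fisher_p,
        "gc": gc,
        "wca": wca_res,
    }


def run_all(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the report dict (also persisted)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        if cfg.preset is None and not (
            cfg.fasta_a and cfg.fasta_b and cfg.orthology_a and cfg.orthology_b
        ):
            raise ValueError("either a preset or all four input paths are required")
        if cfg.preset is not None:
            params = preset_params(cfg.preset, seed=cfg.seed)
            paths = emit_dataset(params, outdir / "data")
            fasta_a, fasta_b = paths["fasta_a"], paths["fasta_b"]
            orth_a_path, orth_b_path = paths["orthology_a"], paths["orthology_b"]
            species_a, species_b = params.species_a, params.species_b
        else:
            fasta_a, fasta_b = cfg.fasta_a, cfg.fasta_b
            orth_a_path, orth_b_path = cfg.orthology_a, cfg.orthology_b
            species_a, species_b = "A", "B"
        seqs_a = read_fasta(fasta_a, species=species_a)
        seqs_b = read_fasta(fasta_b, species=species_b)
        orth_a = read_orthology(orth_a_path)
        orth_b = read_orthology(orth_b_path)

        stage = "pairing"
        log.info("pairing %d x %d sequences", len(seqs_a), len(seqs_b))
        pair_set, pairs, funnel = build_pairs(seqs_a, seqs_b, orth_a, orth_b, cfg)
        if not pairs:
            raise RuntimeError("no pairs survived the filter chain")
        write_pairs_fasta(pairs, outdir / "codon_alignments.fasta")
        columns_table(pairs).to_csv(outdir / "columns.tsv", sep="\t", index=False)

        stage = "analysis"
        res = analyze(pairs, cfg)

        stage = "functional"
        functional = None
        if cfg.term_hits_a and cfg.term_hits_b and cfg.term2cat:
            functional = run_functional(cfg, outdir)

        stage = "report"
        report = _assemble_report(cfg, funnel, pair_set, pairs, res, functional)
        _write_outputs(outdir, res, report)
        return report
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e


def run_functional(cfg: PipelineConfig, outdir: Path) -> dict:
    t2c = read_term2cat(cfg.term2cat)
    hits_a = best_term_per_sequence(read_term_hits(cfg.term_hits_a), cfg.term_max_evalue)
    hits_b = best_term_per_sequence(read_term_hits(cfg.term_hits_b), cfg.term_max_evalue)
    prof_a = pool_categories(hits_a, t2c)
    prof_b = pool_categories(hits_b, t2c)
    out = {
        "profile_a": {k: v for k, v in sorted(prof_a.counts.items())},
        "profile_b": {k: v for k, v in sorted(prof_b.counts.items())},
        "unknown_a": prof_a.unknown,
        "unknown_b": prof_b.unknown,
    }
    if cfg.term_hits_ref:
        ref = pool_categories(
            best_term_per_sequence(read_term_hits(cfg.term_hits_ref), cfg.term_max_evalue),
            t2c,
        )
        cov_a = coverage_vs_reference(prof_a, ref)
        cov_b = coverage_vs_reference(prof_b, ref)
        cov_a.to_csv(outdir / "coverage_a.tsv", sep="\t", index=False)
        cov_b.to_csv(outdir / "coverage_b.tsv", sep="\t", index=False)
        out["aggregate_coverage_a"] = float(cov_a.iloc[-1]["coverage"])
        out["aggregate_coverage_b"] = float(cov_b.iloc[-1]["coverage"])
    ranked = library_specific_terms(hits_a, hits_b)
    ranked.to_csv(outdir / "library_specific_terms.tsv", sep="\t", index=False)
    out["n_specific_terms_q05"] = int(ranked["specific_at_q"].sum()) if not ranked.empty else 0
    return out


def _assemble_report(cfg, funnel, pair_set, pairs, res, functional) -> dict:
    led = res["ledger"]
    report = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "funnel": funnel,
        "multi_group_sequences": pair_set.multi_group_ids,
        "retained_pairs": len(pairs),
        "column_totals": res["column_totals"],
        "net_usage": {a: int(v) for a, v in res["net_usage"].items()},
        "erk": (
            {
                "statistic": res["erk"].statistic,
                "p_value": round(res["erk"].p_value, 10),
                "n_effective": res["erk"].n_effective,
            }
            if res["erk"] is not None
            else {"statistic": None, "p_value": None, "n_effective": 0}
        ),
        "gc3_ledger": led.to_dict(),
        "fisher": {
            "table": res["contingency"].table.tolist(),
            "n_zero_shift": res["contingency"].n_zero,
            "p_value": round(res["fisher_p"], 10),
        },
        "mean_gc": {
            "a_pct": round(res["gc"]["mean_gc_a_pct"], 6),
            "b_pct": round(res["gc"]["mean_gc_b_pct"], 6),
            "pooled_a_pct": round(res["gc"]["pooled_gc_a_pct"], 6),
            "pooled_b_pct": round(res["gc"]["pooled_gc_b_pct"], 6),
        },
    }
    if res["wca"] is not None:
        w = res["wca"]
        report["wca"] = {
            "eigenvalues": [round(float(x), 10) for x in w.eigenvalues],
            "ellipses": {sp: e.to_dict() for sp, e in sorted(w.ellipses.items())},
        }
    if functional is not None:
        report["functional"] = functional
    return report


def _write_outputs(outdir: Path, res: dict, report: dict) -> None:
    res["replacement"].to_frame().to_csv(outdir / "replacement_matrix.tsv", sep="\t")
    res["imbalance"].to_frame().to_csv(outdir / "imbalance_matrix.tsv", sep="\t")
    res["imbalance"].lower_triangle_frame().to_csv(
        outdir / "imbalance_lower_triangle.tsv", sep="\t"
    )
    res["net_usage"].to_csv(outdir / "net_usage.tsv", sep="\t")
    if res["erk"] is not None:
        aa_usage.erk_table(res["erk"].records).to_csv(
            outdir / "erk_per_pair.tsv", sep="\t", index=False
        )
    res["shift_table"].to_csv(outdir / "codon_shift_table.tsv", sep="\t")
    if res["wca"] is not None:
        res["wca"].row_coords.round(10).to_csv(outdir / "wca_row_coords.tsv", sep="\t")
        res["wca"].col_coords.round(10).to_csv(outdir / "wca_col_coords.tsv", sep="\t")
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    (outdir / "summary.txt").write_text(_summary_text(report))


def _summary_text(report: dict) -> str:
    led = report["gc3_ledger"]
    lines = [
        f"orthotherm {report['version']}  (config {report['config_hash']})",
        f"retained pairs: {report['retained_pairs']}",
        f"aligned residue pairs: {report['column_totals']['aligned_residue_pairs']}",
        f"synonymous nt12-conserved pairs: {led['n_synonymous_nt12_conserved']}",
        f"net GC3 loss (species A): {led['net_gc3_loss_a']}",
        f"Fisher p (AT3/GC3 vs shift sign): {report['fisher']['p_value']:.3g}",
        "ERK Wilcoxon p: "
        + (
            f"{report['erk']['p_value']:.3g}"
            if report["erk"]["p_value"] is not None
            else "n/a (no exchanged positions)"
        ),
        f"mean GC: A {report['mean_gc']['a_pct']:.3f}%  B {report['mean_gc']['b_pct']:.3f}%",
    ]
    top = sorted(report["net_usage"].items(), key=lambda kv: -abs(kv[1]))[:5]
    lines.append("largest net usage changes (species A): " + ", ".join(f"{a}:{v:+d}" for a, v in top))
    return "\n".join(lines) + "\n"
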