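"""Synthetic diverging ortholog pairs with known, injected signatures.

The generator emulates the data structure the comparative analysis assumes:
pairs of orthologous coding sequences derived from a common ancestor, with

* a configurable per-codon synonymous substitution probability, where the
  replacement codon is drawn within the synonymous family with weights
  ``1 + s * delta_at3 * [third base is A or T]`` (``s = +1`` for lineage A,
  ``-1`` for lineage B) — a lineage-specific wobble-position A/T preference;
* a configurable per-codon non-synonymous probability, the target amino acid
  drawn from a per-lineage row-stochastic 20x20 preference matrix and the
  codon uniformly within the target family;
* occasional whole-codon indels (frame always preserved);
* decoy sequences without an orthologous partner and a configurable fraction
  of corrupted orthology-table rows.

Every random draw flows from the single root seed through per-pair child
seeds derived by counter, so output is byte-identical across runs and
platforms for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genetics import (
    AMINO_ACIDS,
    STANDARD_CODE,
    THIRD_BASE_AT,
    CodingSequence,
    codon_index,
    index_codon,
)

# Amino-acid frequencies typical of vertebrate proteomes (order AMINO_ACIDS).
VERTEBRATE_AA_FREQS = np.array(
    [
        0.074, 0.025, 0.054, 0.068, 0.040,  # A C D E F
        0.066, 0.026, 0.044, 0.058, 0.099,  # G H I K L
        0.022, 0.036, 0.061, 0.047, 0.056,  # M N P Q R
        0.083, 0.053, 0.060, 0.012, 0.027,  # S T V W Y
    ]
)
VERTEBRATE_AA_FREQS /= VERTEBRATE_AA_FREQS.sum()

# Family lookup tables (standard code): FAM_CODONS[a, k] is the k-th codon
# index of amino acid a, padded with -1; FAM_SIZE[a] its family size.
_MAX_FAM = max(len(v) for v in STANDARD_CODE.synonymous_families.values())
FAM_CODONS = np.full((20, _MAX_FAM), -1, dtype=np.int16)
FAM_SIZE = np.zeros(20, dtype=np.int16)
for _a, _codons in STANDARD_CODE.synonymous_families.items():
    _i = AMINO_ACIDS.index(_a)
    FAM_SIZE[_i] = len(_codons)
    for _k, _c in enumerate(_codons):
        FAM_CODONS[_i, _k] = codon_index(_c)

AA_OF_CODON = STANDARD_CODE.aa_of_codon.astype(np.int16)

GAP = -2  # deleted ancestral codon in a lineage


def uniform_pref_matrix() -> np.ndarray:
    """Uniform off-diagonal, zero-diagonal row-stochastic 20x20 matrix."""
    m = np.full((20, 20), 1.0 / 19.0)
    np.fill_diagonal(m, 0.0)
    return m


def boosted_pref_matrix(boosts: dict[tuple[str, str], float]) -> np.ndarray:
    """Uniform preference matrix with selected source→target probabilities raised.

    ``boosts[(i, j)] = p`` forces row i to put probability mass ``p`` on
    target j, the remainder spread uniformly over the other 18 targets.
    """
    m = uniform_pref_matrix()
    for (src, dst), p in boosts.items():
        i, j = AMINO_ACIDS.index(src), AMINO_ACIDS.index(dst)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"boost for {src}->{dst} outside [0,1]")
        m[i] = (1.0 - p) / 18.0
        m[i, i] = 0.0
        m[i, j] = p
    return m


def avoid_target_matrix(m: np.ndarray, target: str, factor: float) -> np.ndarray:
    """Scale the probability of replacing *into* ``target`` by ``factor``.

    Every row other than ``target``'s own has its ``target`` column
    multiplied by ``factor`` and is renormalized. Combined with a boosted
    outflow row this creates a genuine net deficit of ``target`` in the
    lineage, not a mere retargeting (a row-stochastic matrix alone conserves
    each amino acid's total replacement rate, so boosting one outflow cell
    redistributes targets without changing the source's net balance).
    """
    m = np.asarray(m, dtype=float).copy()
    j = AMINO_ACIDS.index(target)
    for i in range(20):
        if i == j:
            continue
        m[i, j] *= factor
        s = m[i].sum()
        if s > 0:
            m[i] /= s
    return m


def _validate_pref(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (20, 20):
        raise ValueError(f"{name} must be 20x20")
    if np.any(m < 0):
        raise ValueError(f"{name} has negative entries")
    if np.any(np.abs(np.diagonal(m)) > 0):
        raise ValueError(f"{name} must have zero diagonal")
    if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError(f"{name} rows must sum to 1")
    return m


@dataclass
class SimulationParams:
    """All knobs of the ortholog-pair generator.

    Defaults mirror the study conditions the analysis was designed for:
    ~4,000 orthologous segment pairs of ~100 codons at ~96% translated
    identity, with a weak lineage-A wobble-position A/T preference whose
    expected net GC3 shift is a fraction of a percent of the synonymous
    columns.
    """

    n_pairs: int = 4155
    codon_length: int = 100
    p_syn: float = 0.10
    p_nonsyn: float = 0.02
    delta_at3: float = 0.05
    pref_matrix_a: np.ndarray = field(default_factory=uniform_pref_matrix)
    pref_matrix_b: np.ndarray = field(default_factory=uniform_pref_matrix)
    p_indel: float = 0.02
    n_decoys: int = 100
    p_misassign: float = 0.01
    seed: int = 0
    species_a: str = "A"
    species_b: str = "B"

    def __post_init__(self) -> None:
        for name in ("p_syn", "p_nonsyn", "p_indel", "p_misassign"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if not -1.0 <= self.delta_at3 <= 1.0:
            raise ValueError("delta_at3 outside [-1,1]")
        if self.n_pairs < 0 or self.n_decoys < 0:
            raise ValueError("counts must be non-negative")
        self.pref_matrix_a = _validate_pref(self.pref_matrix_a, "pref_matrix_a")
        self.pref_matrix_b = _validate_pref(self.pref_matrix_b, "pref_matrix_b")

    def replace(self, **kw) -> "SimulationParams":
        return dataclasses.replace(self, **kw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["pref_matrix_a"] = np.asarray(self.pref_matrix_a).round(12).tolist()
        d["pref_matrix_b"] = np.asarray(self.pref_matrix_b).round(12).tolist()
        return d


PRESETS: dict[str, dict] = {
    # all defaults: the study-scale conditions (see SimulationParams)
    "study": dict(),
    "null": dict(delta_at3=0.0),
    "at3_shift": dict(delta_at3=0.15),
    # lineage A replaces E preferentially by D and rarely gains E back:
    # the net E deficit / D surplus signature of a cold-adapted proteome
    "E2D_excess": dict(
        pref_matrix_a=avoid_target_matrix(
            boosted_pref_matrix({("E", "D"): 0.8}), "E", 0.05
        )
    ),
    "S_gain": dict(
        pref_matrix_a=boosted_pref_matrix(
            {(a, "S"): 0.4 for a in AMINO_ACIDS if a != "S"}
        )
    ),
    "demo": dict(n_pairs=150, codon_length=80, n_decoys=10, p_misassign=0.02),
}


def preset_params(name: str, **overrides) -> SimulationParams:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    kw = dict(PRESETS[name])
    kw.update(overrides)
    return SimulationParams(**kw)


# ---------------------------------------------------------------------------
# Ancestors

def _ancestor_codons(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    """One stop-free ancestor as a codon-index array."""
    aa = rng.choice(20, size=params.codon_length, p=VERTEBRATE_AA_FREQS)
    k = (rng.random(params.codon_length) * FAM_SIZE[aa]).astype(np.int64)
    return FAM_CODONS[aa, k].astype(np.int16)


def generate_ancestors(params: SimulationParams) -> list[CodingSequence]:
    """Deterministic list of ``n_pairs`` stop-free ancestral coding sequences.

    Amino acids are drawn from a fixed vertebrate-like frequency vector and
    codons uniformly within each synonymous family.
    """
    if params.codon_length < 10:
        raise ValueError("codon_length < 10: too short to align")
    out = []
    for i, ss in enumerate(np.random.SeedSequence(params.seed).spawn(params.n_pairs)):
        rng = np.random.default_rng(ss)
        idx = _ancestor_codons(params, rng)
        nt = "".join(index_codon(c) for c in idx)
        out.append(CodingSequence(id=f"anc{i:05d}", nucleotides=nt, species="ancestor"))
    return out


# ---------------------------------------------------------------------------
# Divergence

def _syn_cum_weights(delta_at3: float, sign: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-amino-acid cumulative synonymous-codon weights for one lineage."""
    w = np.zeros((20, _MAX_FAM))
    for a in range(20):
        for k in range(FAM_SIZE[a]):
            c = FAM_CODONS[a, k]
            w[a, k] = 1.0 + sign * delta_at3 * (1.0 if THIRD_BASE_AT[c] else 0.0)
    tot = w.sum(axis=1)
    cum = np.cumsum(w, axis=1)
    return cum, tot


def _diverge_idx(
    anc: np.ndarray,
    params: SimulationParams,
    lineage: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[int, int]], dict]:
    """Diverge an ancestral codon-index array along one lineage.

    Returns ``(per_ancestor_position, insertions, counts)`` where deleted
    positions hold :data:`GAP` and ``insertions`` is a list of
    ``(ancestor_position, codon_index)`` for codons inserted after that
    position. Per codon the event cascade is: synonymous resampling first,
    else non-synonymous replacement, else whole-codon indel.
    """
    if lineage not in ("A", "B"):
        raise ValueError("lineage must be 'A' or 'B'")
    sign = 1 if lineage == "A" else -1
    pref = params.pref_matrix_a if lineage == "A" else params.pref_matrix_b
    n = len(anc)
    out = anc.copy()
    u = rng.random((3, n))
    syn = u[0] < params.p_syn
    nonsyn = ~syn & (u[1] < params.p_nonsyn)
    indel = ~syn & ~nonsyn & (u[2] < params.p_indel)

    n_syn_changed = 0
    if syn.any():
        pos = np.flatnonzero(syn)
        aa = AA_OF_CODON[anc[pos]]
        cum, tot = _syn_cum_weights(params.delta_at3, sign)
        r = rng.random(len(pos)) * tot[aa]
        rank = (cum[aa] < r[:, None]).sum(axis=1)
        new = FAM_CODONS[aa, rank]
        out[pos] = new
        n_syn_changed = int((new != anc[pos]).sum())

    n_nonsyn = 0
    if nonsyn.any():
        pos = np.flatnonzero(nonsyn)
        aa = AA_OF_CODON[anc[pos]]
        cum = np.cumsum(pref, axis=1)
        r = rng.random(len(pos)) * cum[aa, -1]
        target = (cum[aa] < r[:, None]).sum(axis=1)
        k = (rng.random(len(pos)) * FAM_SIZE[target]).astype(np.int64)
        out[pos] = FAM_CODONS[target, k]
        n_nonsyn = len(pos)

    insertions: list[tuple[int, int]] = []
    n_del = 0
    if indel.any():
        for p in np.flatnonzero(indel):
            if rng.random() < 0.5:
                out[p] = GAP
                n_del += 1
            else:
                a = rng.choice(20, p=VERTEBRATE_AA_FREQS)
                c = FAM_CODONS[a, int(rng.random() * FAM_SIZE[a])]
                insertions.append((int(p), int(c)))

    counts = {
        "syn_changes": n_syn_changed,
        "nonsyn_changes": n_nonsyn,
        "deletions": n_del,
        "insertions": len(insertions),
    }
    return out, insertions, counts


def _idx_to_nt(per_pos: np.ndarray, insertions: list[tuple[int, int]]) -> str:
    ins = {}
    for p, c in insertions:
        ins.setdefault(p, []).append(c)
    parts: list[str] = []
    for p, c in enumerate(per_pos):
        if c != GAP:
            parts.append(index_codon(int(c)))
        for ci in ins.get(p, ()):
            parts.append(index_codon(ci))
    return "".join(parts)


def diverge(
    ancestor: CodingSequence,
    params: SimulationParams,
    lineage: str,
    rng: np.random.Generator | None = None,
) -> CodingSequence:
    """Public single-sequence divergence (see :func:`_diverge_idx`)."""
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(params.seed).spawn(1)[0]
        )
    anc = np.fromiter(
        (codon_index(c) for c in ancestor.codons()),
        dtype=np.int16,
        count=ancestor.n_codons,
    )
    if np.any(AA_OF_CODON[anc] == 20):
        raise ValueError(f"ancestor {ancestor.id} contains an in-frame stop")
    per_pos, insertions, _ = _diverge_idx(anc, params, lineage, rng)
    species = params.species_a if lineage == "A" else params.species_b
    return CodingSequence(
        id=f"{ancestor.id}_{lineage}",
        nucleotides=_idx_to_nt(per_pos, insertions),
        species=species,
    )


# ---------------------------------------------------------------------------
# Whole-dataset generation

@dataclass
class PairRecord:
    """Ground truth for one simulated ortholog pair."""

    ancestor_id: str
    seq_id_a: str
    seq_id_b: str
    group_id: str
    identity_pct: float
    counts_a: dict
    counts_b: dict


@dataclass
class SimulationTruth:
    params: SimulationParams
    per_pair: list[PairRecord]
    n_misassigned_a: int = 0
    n_misassigned_b: int = 0

    def to_jsonable(self) -> dict:
        return {
            "params": self.params.to_jsonable(),
            "per_pair": [dataclasses.asdict(p) for p in self.per_pair],
            "n_misassigned_a": self.n_misassigned_a,
            "n_misassigned_b": self.n_misassigned_b,
        }


def _translated_identity_pct(a: np.ndarray, b: np.ndarray) -> float:
    """Percent identical residues over ancestral positions present in both."""
    keep = (a != GAP) & (b != GAP)
    if not keep.any():
        return 0.0
    same = AA_OF_CODON[a[keep]] == AA_OF_CODON[b[keep]]
    return 100.0 * float(same.mean())


@dataclass
class SimulatedPair:
    """In-memory diverged pair, codon-index form, before FASTA round trips."""

    record: PairRecord
    aligned_a: np.ndarray  # -2 where gapped, else codon index
    aligned_b: np.ndarray
    cds_a: CodingSequence
    cds_b: CodingSequence


def simulate_pairs(params: SimulationParams) -> tuple[list[SimulatedPair], SimulationTruth]:
    """All ortholog pairs of a dataset, with truth, decoys excluded.

    The aligned arrays are the true ancestral alignment: one column per
    ancestral codon (deletions as gaps) plus one column per inserted codon
    (gap in the other lineage).
    """
    if params.codon_length < 10:
        raise ValueError("codon_length < 10: too short to align")
    root = np.random.SeedSequence(params.seed)
    pairs: list[SimulatedPair] = []
    truth = SimulationTruth(params=params, per_pair=[])
    for i, ss in enumerate(root.spawn(params.n_pairs)):
        rng = np.random.default_rng(ss)
        anc = _ancestor_codons(params, rng)
        pa, ins_a, ca = _diverge_idx(anc, params, "A", rng)
        pb, ins_b, cb = _diverge_idx(anc, params, "B", rng)
        ident = _translated_identity_pct(pa, pb)

        cols_a, cols_b = [], []
        ins_a_d: dict[int, list[int]] = {}
        ins_b_d: dict[int, list[int]] = {}
        for p, c in ins_a:
            ins_a_d.setdefault(p, []).append(c)
        for p, c in ins_b:
            ins_b_d.setdefault(p, []).append(c)
        for p in range(len(anc)):
            cols_a.append(int(pa[p]))
            cols_b.append(int(pb[p]))
            for c in ins_a_d.get(p, ()):
                cols_a.append(c)
                cols_b.append(GAP)
            for c in ins_b_d.get(p, ()):
                cols_a.append(GAP)
                cols_b.append(c)

        rec = PairRecord(
            ancestor_id=f"anc{i:05d}",
            seq_id_a=f"{params.species_a}_{i:05d}",
            seq_id_b=f"{params.species_b}_{i:05d}",
            group_id=f"NOG{i:05d}",
            identity_pct=ident,
            counts_a=ca,
            counts_b=cb,
        )
        cds_a = CodingSequence(
            id=rec.seq_id_a, nucleotides=_idx_to_nt(pa, ins_a), species=params.species_a
        )
        cds_b = CodingSequence(
            id=rec.seq_id_b, nucleotides=_idx_to_nt(pb, ins_b), species=params.species_b
        )
        pairs.append(
            SimulatedPair(
                record=rec,
                aligned_a=np.array(cols_a, dtype=np.int16),
                aligned_b=np.array(cols_b, dtype=np.int16),
                cds_a=cds_a,
                cds_b=cds_b,
            )
        )
        truth.per_pair.append(rec)
    return pairs, truth


def _decoys(params: SimulationParams, root: np.random.SeedSequence) -> tuple[list[CodingSequence], list[CodingSequence]]:
    """Partner-less decoy sequences for each species."""
    da, db = [], []
    for j, ss in enumerate(root.spawn(params.n_decoys)):
        rng = np.random.default_rng(ss)
        idx_a = _ancestor_codons(params, rng)
        idx_b = _ancestor_codons(params, rng)
        da.append(
            CodingSequence(
                id=f"{params.species_a}_decoy{j:04d}",
                nucleotides="".join(index_codon(int(c)) for c in idx_a),
                species=params.species_a,
            )
        )
        db.append(
            CodingSequence(
                id=f"{params.species_b}_decoy{j:04d}",
                nucleotides="".join(index_codon(int(c)) for c in idx_b),
                species=params.species_b,
            )
        )
    return da, db


def _orthology_table(
    seq_ids: list[str],
    group_ids: list[str],
    p_misassign: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, int]:
    """Orthology assignment rows; a fraction point at a wrong group."""
    n = len(seq_ids)
    groups = list(group_ids)
    corrupt = rng.random(n) < p_misassign
    n_bad = 0
    all_groups = sorted(set(group_ids))
    for i in np.flatnonzero(corrupt):
        if len(all_groups) < 2:
            break
        wrong = all_groups[int(rng.integers(len(all_groups)))]
        if wrong == groups[i]:
            wrong = all_groups[(all_groups.index(wrong) + 1) % len(all_groups)]
        groups[i] = wrong
        n_bad += 1
    bitscore = np.round(80.0 + 120.0 * rng.random(n), 1)
    evalue = 10.0 ** (-(15.0 + 45.0 * rng.random(n)))
    df = pd.DataFrame(
        {"seq_id": seq_ids, "group_id": groups, "bitscore": bitscore, "evalue": evalue}
    )
    return df, n_bad


def emit_dataset(params: SimulationParams, outdir: str | Path) -> dict[str, Path]:
    """Write the full synthetic dataset to ``outdir``.

    Produces one CDS FASTA and one orthology TSV per species plus a truth
    JSON; decoys are appended with no partner and their own singleton groups.
    Identical parameters (including seed) produce byte-identical files.
    """
    from .genetics import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pairs, truth = simulate_pairs(params)
    root = np.random.SeedSequence(params.seed + 1)
    decoys_a, decoys_b = _decoys(params, root)

    seqs_a = [p.cds_a for p in pairs] + decoys_a
    seqs_b = [p.cds_b for p in pairs] + decoys_b
    groups = [p.record.group_id for p in pairs]
    decoy_groups_a = [f"DNOGA{j:04d}" for j in range(params.n_decoys)]
    decoy_groups_b = [f"DNOGB{j:04d}" for j in range(params.n_decoys)]

    rng = np.random.default_rng(np.random.SeedSequence(params.seed + 2))
    tab_a, bad_a = _orthology_table(
        [s.id for s in seqs_a], groups + decoy_groups_a, params.p_misassign, rng
    )
    tab_b, bad_b = _orthology_table(
        [s.id for s in seqs_b], groups + decoy_groups_b, params.p_misassign, rng
    )
    truth.n_misassigned_a = bad_a
    truth.n_misassigned_b = bad_b

    paths = {
        "fasta_a": outdir / f"cds_{params.species_a}.fasta",
        "fasta_b": outdir / f"cds_{params.species_b}.fasta",
        "orthology_a": outdir / f"orthology_{params.species_a}.tsv",
        "orthology_b": outdir / f"orthology_{params.species_b}.tsv",
        "truth": outdir / "truth.json",
    }
    try:
        write_fasta(seqs_a, paths["fasta_a"])
        write_fasta(seqs_b, paths["fasta_b"])
        tab_a.to_csv(paths["orthology_a"], sep="\t", index=False, float_format="%.6g")
        tab_b.to_csv(paths["orthology_b"], sep="\t", index=False, float_format="%.6g")
        paths["truth"].write_text(json.dumps(truth.to_jsonable(), indent=1))
    except OSError as e:
        raise OSError(f"failed writing dataset to {outdir}: {e}") from e
    return paths
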