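import json

import numpy as np
import pytest
from scipy import stats

from orthotherm.genetics import STANDARD_CODE, translate
from orthotherm.simulate import (
    FAM_CODONS,
    FAM_SIZE,
    SimulationParams,
    boosted_pref_matrix,
    diverge,
    emit_dataset,
    generate_ancestors,
    preset_params,
    simulate_pairs,
    uniform_pref_matrix,
)


class TestParams:
    def test_probability_ranges_enforced(self):
        with pytest.raises(ValueError):
            SimulationParams(p_syn=1.5)
        with pytest.raises(ValueError):
            SimulationParams(delta_at3=-2)

    def test_pref_matrix_must_be_row_stochastic_with_zero_diagonal(self):
        bad = uniform_pref_matrix()
        bad[0, 0] = 0.1
        with pytest.raises(ValueError):
            SimulationParams(pref_matrix_a=bad)

    def test_boosted_matrix_rows_sum_to_one(self):
        m = boosted_pref_matrix({("E", "D"): 0.5})
        assert np.allclose(m.sum(axis=1), 1.0) and np.all(np.diag(m) == 0)


class TestAncestors:
    def test_same_seed_is_byte_identical(self):
        p = SimulationParams(n_pairs=5, codon_length=30, seed=1)
        a1 = generate_ancestors(p)
        a2 = generate_ancestors(p)
        assert [s.nucleotides for s in a1] == [s.nucleotides for s in a2]

    def test_zero_pairs_gives_empty_list(self):
        assert generate_ancestors(SimulationParams(n_pairs=0, codon_length=30)) == []

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            generate_ancestors(SimulationParams(n_pairs=1, codon_length=5))

    def test_ancestors_are_stop_free(self):
        for s in generate_ancestors(SimulationParams(n_pairs=20, codon_length=50, seed=3)):
            assert "*" not in translate(s).residues

    def test_within_family_codon_choice_uniform(self):
        """Per-family codon proportions match uniform within binomial 99% bounds."""
        p = SimulationParams(n_pairs=1000, codon_length=30, seed=7)
        counts = np.zeros(64)
        for s in generate_ancestors(p):
            for c in s.codons():
                counts[
                    "ACGT".index(c[0]) * 16 + "ACGT".index(c[1]) * 4 + "ACGT".index(c[2])
                ] += 1
        # familywise 99% band: Bonferroni over the ~61 per-codon comparisons
        alpha = 0.01 / 61
        for a in range(20):
            fam = FAM_CODONS[a, : FAM_SIZE[a]]
            tot = counts[fam].sum()
            if tot < 200 or FAM_SIZE[a] < 2:
                continue
            q = 1.0 / FAM_SIZE[a]
            lo, hi = stats.binom.ppf([alpha / 2, 1 - alpha / 2], tot, q)
            assert np.all(counts[fam] >= lo) and np.all(counts[fam] <= hi)


class TestDiverge:
    def test_zero_rates_reproduce_ancestor(self):
        p = SimulationParams(n_pairs=1, codon_length=40, p_syn=0, p_nonsyn=0, p_indel=0, seed=5)
        anc = generate_ancestors(p)[0]
        assert diverge(anc, p, "A").nucleotides == anc.nucleotides

    def test_at3_symmetry_when_delta_zero(self):
        p = SimulationParams(
            n_pairs=200, codon_length=100, delta_at3=0.0, p_indel=0, n_decoys=0,
            p_misassign=0.0, seed=11,
        )
        pairs, _ = simulate_pairs(p)
        def at3_frac(seqs):
            third = [nt for s in seqs for nt in s.nucleotides[2::3]]
            return sum(1 for b in third if b in "AT") / len(third)
        fa = at3_frac([sp.cds_a for sp in pairs])
        fb = at3_frac([sp.cds_b for sp in pairs])
        assert abs(fa - fb) < 0.01

    def test_at3_sign_recovered_across_seeds(self):
        """With delta_at3=0.5 lineage A's AT3 exceeds B's in >=95% of replicates."""
        wins = 0
        n_rep = 40
        for seed in range(n_rep):
            p = SimulationParams(
                n_pairs=60, codon_length=100, p_syn=0.3, delta_at3=0.5,
                p_indel=0, n_decoys=0, p_misassign=0.0, seed=seed,
            )
            pairs, _ = simulate_pairs(p)
            a3 = b3 = at_a = at_b = 0
            for sp in pairs:
                for nt in sp.cds_a.nucleotides[2::3]:
                    a3 += 1
                    at_a += nt in "AT"
                for nt in sp.cds_b.nucleotides[2::3]:
                    b3 += 1
                    at_b += nt in "AT"
            wins += (at_a / a3) > (at_b / b3)
        assert wins >= 0.95 * n_rep

    def test_identity_decreases_in_p_nonsyn(self):
        """Realized translated identity is monotone in p_nonsyn (Spearman)."""
        grid = [0.0, 0.01, 0.03, 0.06, 0.1, 0.2]
        means = []
        for pn in grid:
            vals = []
            for seed in range(5):
                p = SimulationParams(
                    n_pairs=30, codon_length=80, p_nonsyn=pn, p_indel=0,
                    n_decoys=0, p_misassign=0.0, seed=seed,
                )
                _, truth = simulate_pairs(p)
                vals.extend(r.identity_pct for r in truth.per_pair)
            means.append(np.mean(vals))
        rho, _ = stats.spearmanr(grid, means)
        assert rho == -1.0


class TestEmitDataset:
    def test_decoys_appended_and_files_deterministic(self, tmp_path):
        p = SimulationParams(n_pairs=20, codon_length=30, n_decoys=5, seed=9)
        paths1 = emit_dataset(p, tmp_path / "d1")
        paths2 = emit_dataset(p, tmp_path / "d2")
        fasta = paths1["fasta_a"].read_text()
        assert fasta.count(">") == 25
        for k in paths1:
            assert paths1[k].read_bytes() == paths2[k].read_bytes()

    def test_misassignment_rate_matches_truth(self, tmp_path):
        p = SimulationParams(
            n_pairs=200, codon_length=30, n_decoys=0, p_misassign=0.1, seed=13
        )
        paths = emit_dataset(p, tmp_path / "d")
        truth = json.loads(paths["truth"].read_text())
        n_bad = truth["n_misassigned_a"]
        lo, hi = stats.binom.ppf([0.005, 0.995], 200, 0.1)
        assert lo <= n_bad <= hi
        # corrupted rows really point at a wrong group
        import pandas as pd
        tab = pd.read_csv(paths["orthology_a"], sep="\t", dtype=str)
        expected = {f"A_{i:05d}": f"NOG{i:05d}" for i in range(200)}
        mism = sum(1 for r in tab.itertuples() if expected[r.seq_id] != r.group_id)
        assert mism == n_bad

    def test_preset_lookup(self):
        assert preset_params("E2D_excess").pref_matrix_a[
            3, 2  # E -> D in alphabetical one-letter order ACDEFGHIKLMNPQRSTVWY
        ] == pytest.approx(0.8)
        with pytest.raises(KeyError):
            preset_params("nope")


class TestSymmetryProperty:
    def test_uniform_preferences_give_mean_zero_imbalance(self):
        """Symmetric parameters: net usage is mean-zero over replicates."""
        from orthotherm.codon_align import from_simulated
        from orthotherm import aa_usage

        nets = []
        for seed in range(30):
            p = SimulationParams(
                n_pairs=40, codon_length=80, delta_at3=0.0, p_indel=0,
                n_decoys=0, p_misassign=0.0, seed=seed,
            )
            sim, _ = simulate_pairs(p)
            pairs = [from_simulated(s) for s in sim]
            D = aa_usage.imbalance(aa_usage.count_replacements(pairs))
            nets.append(aa_usage.net_usage(D).to_numpy())
        mean_net = np.mean(nets, axis=0)
        se = np.std(nets, axis=0, ddof=1) / np.sqrt(len(nets))
        # every amino acid's mean net within 4 standard errors of zero
        assert np.all(np.abs(mean_net) <= 4 * np.maximum(se, 1e-9))
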