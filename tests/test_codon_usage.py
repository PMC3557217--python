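import numpy as np
import pandas as pd
import pytest
from scipy import stats

from orthotherm.genetics import THIRD_BASE_AT, gc_fraction
from orthotherm.codon_usage import (
    INFORMATIVE_CODONS,
    INFORMATIVE_NAMES,
    ShiftContingency,
    build_wca_counts,
    codon_counts,
    codon_shift_table,
    fisher_exact_2x2,
    gc3_ledger,
    mean_gc,
    shift_contingency,
    wca,
)
from conftest import make_pair
from oracles import fisher_exact_oracle, rescan_gc3


class TestGc3Ledger:
    def test_gc3_to_at3_shift_counted(self):
        led = gc3_ledger([make_pair(["GCT"], ["GCC"])])
        assert led.gc3_to_at3 == 1 and led.at3_to_gc3 == 0
        assert led.net_gc3_loss_a == 1

    def test_same_side_third_bases_shift_nothing(self):
        led = gc3_ledger([make_pair(["GCT"], ["GCA"])])
        assert led.gc3_to_at3 == 0 and led.at3_to_gc3 == 0
        assert led.n_synonymous_nt12_conserved == 1

    def test_nt12_changed_synonymous_column_excluded(self):
        led = gc3_ledger([make_pair(["CTG"], ["TTG"])])  # Leu, first base differs
        assert led.n_synonymous_nt12_conserved == 0

    def test_nonsynonymous_columns_excluded(self):
        led = gc3_ledger([make_pair(["GAA"], ["GAT"])])  # E vs D
        assert led.n_synonymous_nt12_conserved == 0
        assert led.n_aligned_residue_pairs == 1

    def test_species_swap_negates_net(self, small_dataset):
        pairs, _ = small_dataset
        led = gc3_ledger(pairs)
        led_sw = gc3_ledger([p.swapped() for p in pairs])
        assert led.net_gc3_loss_a == -led_sw.net_gc3_loss_a
        assert led.gc3_to_at3 == led_sw.at3_to_gc3

    def test_matches_string_rescan_oracle(self, small_dataset):
        pairs, _ = small_dataset
        led = gc3_ledger(pairs)
        exp = rescan_gc3(pairs)
        assert led.n_aligned_residue_pairs == exp["n_aligned_residue_pairs"]
        assert led.n_synonymous_nt12_conserved == exp["n_synonymous_nt12_conserved"]
        assert led.gc3_to_at3 == exp["gc3_to_at3"]
        assert led.at3_to_gc3 == exp["at3_to_gc3"]

    def test_shift_counts_bounded_by_syn_columns(self, small_dataset):
        pairs, _ = small_dataset
        led = gc3_ledger(pairs)
        assert led.gc3_to_at3 + led.at3_to_gc3 <= led.n_synonymous_nt12_conserved


class TestShiftTable:
    def test_two_codon_arithmetic_example(self):
        counts = pd.DataFrame(
            {"count_a": 0, "count_b": 0},
            index=pd.Index(INFORMATIVE_NAMES, name="codon"),
        )
        counts.loc["GCT"] = [60, 40]
        counts.loc["GCC"] = [40, 60]
        tab = codon_shift_table(counts)
        assert tab.loc["GCT", "shift"] == pytest.approx(0.2)
        assert tab.loc["GCC", "shift"] == pytest.approx(-0.2)
        assert tab.loc["GCT", "panel"] == "A_higher" and bool(tab.loc["GCT", "at3"])
        assert tab.loc["GCC", "panel"] == "B_higher" and not tab.loc["GCC", "at3"]

    def test_identical_counts_all_zero_shift(self, small_dataset):
        pairs, _ = small_dataset
        counts = codon_counts(pairs)
        counts["count_b"] = counts["count_a"]
        tab = codon_shift_table(counts)
        assert (tab["shift"] == 0).all() and (tab["panel"] == "zero").all()

    def test_shifts_sum_to_zero(self, rng):
        counts = pd.DataFrame(
            {
                "count_a": rng.integers(0, 500, size=59),
                "count_b": rng.integers(0, 500, size=59),
            },
            index=pd.Index(INFORMATIVE_NAMES, name="codon"),
        )
        assert codon_shift_table(counts)["shift"].sum() == pytest.approx(0, abs=1e-12)

    def test_frequencies_normalized_over_59_codons(self, small_dataset):
        pairs, _ = small_dataset
        tab = codon_shift_table(codon_counts(pairs))
        assert len(tab) == 59
        assert tab["freq_a"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_total_is_error(self):
        counts = pd.DataFrame(
            {"count_a": 0, "count_b": 0},
            index=pd.Index(INFORMATIVE_NAMES, name="codon"),
        )
        with pytest.raises(ValueError):
            codon_shift_table(counts)

    def test_stop_met_trp_never_counted(self, small_dataset):
        pairs, _ = small_dataset
        counts = codon_counts(pairs)
        assert {"ATG", "TGG", "TAA", "TAG", "TGA"}.isdisjoint(set(counts.index))


class TestFisher:
    def test_diagonal_table(self):
        assert fisher_exact_2x2(np.array([[3, 0], [0, 3]])) == pytest.approx(0.1)

    def test_tiny_table_p_one(self):
        assert fisher_exact_2x2(np.array([[1, 0], [0, 1]])) == pytest.approx(1.0)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(np.array([[1, -1], [0, 1]]))

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        """200 random tables with margins <= 20 against full enumeration."""
        for _ in range(200):
            t = rng.integers(0, 11, size=(2, 2))
            got = fisher_exact_2x2(t)
            assert got == pytest.approx(fisher_exact_oracle(t.tolist()), rel=1e-7)

    def test_contingency_built_from_shift_table(self):
        counts = pd.DataFrame(
            {"count_a": 0, "count_b": 0},
            index=pd.Index(INFORMATIVE_NAMES, name="codon"),
        )
        counts.loc["GCT"] = [60, 40]   # AT3, positive shift
        counts.loc["GCC"] = [40, 60]   # GC3, negative shift
        counts.loc["GAA"] = [10, 10]   # zero shift after normalization
        counts.loc["GAG"] = [10, 10]
        cont = shift_contingency(codon_shift_table(counts))
        assert cont.table.tolist() == [[1, 0], [0, 1]]
        assert cont.n_zero == 2 + 55


class TestWca:
    @staticmethod
    def _two_cluster_counts(n_rows=40, shift=0.35, seed=5):
        """Rows differing only in third-base composition within families."""
        rng = np.random.default_rng(seed)
        at3 = THIRD_BASE_AT[INFORMATIVE_CODONS]
        rows, index = [], []
        for r in range(n_rows):
            sp = "A" if r % 2 == 0 else "B"
            bias = shift if sp == "A" else -shift
            w = np.where(at3, 1.0 + bias, 1.0 - bias)
            rows.append(rng.poisson(40.0 * w))
            index.append((f"seg{r//2}", sp))
        df = pd.DataFrame(
            rows,
            index=pd.MultiIndex.from_tuples(index, names=["segment", "species"]),
            columns=INFORMATIVE_NAMES,
        )
        return df

    def test_axis1_tracks_at3_on_two_cluster_table(self):
        res = wca(self._two_cluster_counts())
        at3 = THIRD_BASE_AT[INFORMATIVE_CODONS]
        rho, _ = stats.spearmanr(res.col_coords["axis1"], at3.astype(float))
        # midrank Spearman against a binary indicator is capped below 1:
        # normalize by the exact maximum for this tie structure (perfect
        # separation of the 30 AT3 from the 29 GC3 codons)
        rho_max, _ = stats.spearmanr(np.arange(59), np.sort(at3.astype(float)))
        assert abs(rho) / rho_max >= 0.9

    def test_axis1_sign_convention_at3_positive(self):
        res = wca(self._two_cluster_counts())
        at3 = THIRD_BASE_AT[INFORMATIVE_CODONS]
        assert res.col_coords["axis1"].to_numpy()[at3].mean() > 0

    def test_species_ellipses_separate_along_axis1(self):
        res = wca(self._two_cluster_counts())
        ca, cb = res.ellipses["A"].center, res.ellipses["B"].center
        assert abs(ca[0] - cb[0]) > 5 * abs(ca[1] - cb[1])
        assert ca[0] > cb[0]  # A is the AT3-shifted block

    def test_identical_rows_degenerate_error(self):
        df = pd.DataFrame(
            np.tile(np.arange(1, 60), (6, 1)),
            index=pd.MultiIndex.from_tuples(
                [(f"s{i}", "A") for i in range(6)], names=["segment", "species"]
            ),
            columns=INFORMATIVE_NAMES,
        )
        with pytest.raises(ValueError):
            wca(df)

    def test_weighted_row_mean_is_zero(self, rng):
        df = pd.DataFrame(
            rng.integers(0, 30, size=(25, 59)),
            index=pd.MultiIndex.from_tuples(
                [(f"s{i}", "A" if i % 2 else "B") for i in range(25)],
                names=["segment", "species"],
            ),
            columns=INFORMATIVE_NAMES,
        )
        res = wca(df)
        for ax in res.row_coords.columns:
            wmean = float(res.row_weights @ res.row_coords[ax].to_numpy())
            assert wmean == pytest.approx(0.0, abs=1e-9)

    def test_eigenvalues_nonnegative_nonincreasing(self, small_dataset):
        pairs, _ = small_dataset
        res = wca(build_wca_counts(pairs), n_axes=4)
        ev = res.eigenvalues
        assert np.all(ev >= 0) and np.all(np.diff(ev) <= 1e-12)

    def test_pooled_mode_gives_one_row_per_species(self, small_dataset):
        pairs, _ = small_dataset
        df = build_wca_counts(pairs, pooled=True)
        assert len(df) == 2


class TestMeanGc:
    def test_two_segment_example(self):
        pairs = [make_pair(["GGC", "CAT"], ["GGC", "CAT"]),
                 make_pair(["ATA", "TAT"], ["ATA", "TAT"])]
        gc = mean_gc(pairs)
        # segments: GGCCAT (4/6), ATATAT (0/6) -> mean 33.33%
        assert gc["mean_gc_a_pct"] == pytest.approx(100 * (4 / 6 + 0) / 2)

    def test_matches_string_oracle_on_simulated_pairs(self, small_dataset):
        pairs, _ = small_dataset
        gc = mean_gc(pairs)
        per_seg = [
            100 * gc_fraction("".join(c for c in p.codons_a if c != "---"))
            for p in pairs
        ]
        assert gc["mean_gc_a_pct"] == pytest.approx(np.mean(per_seg))

    def test_gaps_excluded_from_gc(self):
        p = make_pair(["GGG", "---"], ["GGG", "AAA"])
        gc = mean_gc([p])
        assert gc["mean_gc_a_pct"] == pytest.approx(100.0)
        assert gc["mean_gc_b_pct"] == pytest.approx(50.0)
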