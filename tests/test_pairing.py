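import numpy as np
import pytest

from orthotherm.genetics import AMINO_ACIDS, ProteinSegment
from orthotherm.pairing import (
    BLOSUM62,
    ALIGN_ALPHABET,
    PairSet,
    SegmentAlignment,
    align_local,
    filter_pairs,
    percent_identity_of,
    read_blast_hits,
    select_best_pairs,
)
from oracles import sw_affine_oracle


def seg(residues, id="s"):
    return ProteinSegment(
        id=id, residues=residues, source_id=id, start_codon=0, end_codon=len(residues)
    )


def blosum_score(x, y):
    return float(BLOSUM62[ALIGN_ALPHABET.index(x), ALIGN_ALPHABET.index(y)])


class TestAlignLocal:
    def test_blast_style_example(self):
        aln = align_local(seg("KAWAAK", "a"), seg("AWAA", "b"))
        assert (aln.aligned_a, aln.aligned_b) == ("AWAA", "AWAA")
        assert aln.score == 23  # 4 + 11 + 4 + 4 under BLOSUM62
        assert aln.percent_identity == 100.0

    def test_identical_sequences_score_diagonal_sum(self):
        s = "MKVLAWYHID"
        aln = align_local(seg(s, "a"), seg(s, "b"))
        assert aln.score == sum(blosum_score(x, x) for x in s)
        assert aln.percent_identity == 100.0

    def test_single_mismatch_identity(self):
        aln = align_local(seg("ACDEF", "a"), seg("ACDEY", "b"))
        assert aln.percent_identity == pytest.approx(80.0)

    def test_gap_columns_count_in_identity_denominator(self):
        assert percent_identity_of("AC-DE", "ACWDE") == pytest.approx(80.0)

    def test_coordinates_are_half_open_in_source(self):
        aln = align_local(seg("XXMKVLAW", "a"), seg("MKVLAW", "b"))
        assert (aln.start_a, aln.end_a) == (2, 8)
        assert (aln.start_b, aln.end_b) == (0, 6)

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            align_local(
                seg("MKV", "a"),
                ProteinSegment(id="b", residues="", source_id="b", start_codon=0, end_codon=0),
            )

    def test_bad_residue_rejected_with_name(self):
        with pytest.raises(ValueError, match="'B'"):
            align_local(seg("MKB", "a"), seg("MKV", "b"))

    def test_stop_never_inside_alignment(self):
        aln = align_local(seg("MKV*MKV", "a"), seg("MKVWMKV", "b"))
        assert "*" not in aln.aligned_a

    def test_matches_exhaustive_dp_oracle_on_random_short_pairs(self, rng):
        """Implementation equals per-cell DP oracle (score, strings) on 200 cases."""
        for _ in range(200):
            a = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(1, 13)))
            b = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(1, 13)))
            got = align_local(seg(a, "a"), seg(b, "b"))
            score, oa, ob = sw_affine_oracle(a, b, blosum_score)
            assert got.score == score, (a, b)
            assert (got.aligned_a, got.aligned_b) == (oa, ob), (a, b)

    def test_score_matches_biopython_aligner(self, rng):
        """Independent cross-check of optimal scores against Bio.Align."""
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -12
        aligner.extend_gap_score = -1
        for _ in range(50):
            a = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(3, 25)))
            b = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(3, 25)))
            got = align_local(seg(a, "a"), seg(b, "b"))
            assert got.score == max(aligner.score(a, b), 0.0)

    def test_score_symmetric_in_arguments(self, rng):
        for _ in range(50):
            a = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(2, 15)))
            b = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(2, 15)))
            assert align_local(seg(a, "a"), seg(b, "b")).score == align_local(
                seg(b, "b"), seg(a, "a")
            ).score


def mk_aln(id_a, id_b, score, identity, group, evalue=None):
    return SegmentAlignment(
        id_a=id_a, id_b=id_b, aligned_a="", aligned_b="", score=score,
        percent_identity=identity, start_a=0, end_a=0, start_b=0, end_b=0,
        evalue=evalue, group_id=group,
    )


class TestSelectBestPairs:
    def test_highest_score_wins(self):
        ps = select_best_pairs([mk_aln("a", "b", 50, 90, "g"), mk_aln("c", "d", 40, 95, "g")])
        assert [h.score for h in ps.alignments] == [50]

    def test_score_tie_breaks_on_identity(self):
        ps = select_best_pairs([mk_aln("a", "b", 50, 85, "g"), mk_aln("c", "d", 50, 90, "g")])
        assert ps.alignments[0].percent_identity == 90

    def test_full_tie_breaks_on_smallest_id_pair(self):
        ps = select_best_pairs([mk_aln("z", "z", 50, 90, "g"), mk_aln("a", "b", 50, 90, "g")])
        assert ps.alignments[0].id_a == "a"

    def test_equals_exhaustive_max_per_group(self, rng):
        hits = []
        for g in range(5):
            for k in range(4):
                hits.append(
                    mk_aln(f"a{g}_{k}", f"b{g}_{k}", float(rng.integers(10, 60)),
                           float(rng.integers(50, 100)), f"g{g}")
                )
        ps = select_best_pairs(hits)
        for g in range(5):
            grp = [h for h in hits if h.group_id == f"g{g}"]
            best = max(grp, key=lambda h: (h.score, h.percent_identity))
            got = [h for h in ps.alignments if h.group_id == f"g{g}"][0]
            assert (got.score, got.percent_identity) == (best.score, best.percent_identity)

    def test_sequence_best_in_multiple_groups_is_flagged(self):
        ps = select_best_pairs([mk_aln("a", "b", 50, 90, "g1"), mk_aln("a", "c", 40, 90, "g2")])
        assert ps.multi_group_ids == ["a"]

    def test_empty_input_gives_empty_pairset(self):
        assert len(select_best_pairs([])) == 0


class TestFilterPairs:
    def test_boundary_inclusive_by_default(self):
        ps = PairSet(alignments=[
            mk_aln("a", "b", 99, 96.0, "g1", evalue=1e-30),
            mk_aln("c", "d", 99, 80.0, "g2", evalue=1e-30),
            mk_aln("e", "f", 99, 79.9, "g3", evalue=1e-30),
        ])
        kept = filter_pairs(ps)
        assert [h.id_a for h in kept.alignments] == ["a", "c"]

    def test_strict_identity_flag_excludes_boundary(self):
        ps = PairSet(alignments=[mk_aln("c", "d", 99, 80.0, "g", evalue=1e-30)])
        assert len(filter_pairs(ps, strict_identity=True)) == 0

    def test_evalue_applied_when_present_score_otherwise(self):
        ps = PairSet(alignments=[
            mk_aln("a", "b", 99, 96, "g1", evalue=1e-5),   # fails evalue
            mk_aln("c", "d", 30, 96, "g2"),                # fails min_score
            mk_aln("e", "f", 99, 96, "g3"),                # passes on score
        ])
        kept = filter_pairs(ps)
        assert [h.id_a for h in kept.alignments] == ["e"]

    def test_survivors_equal_direct_threshold_scan(self, rng):
        hits = [
            mk_aln(f"a{i}", f"b{i}", 99, float(rng.uniform(60, 100)), f"g{i}", evalue=1e-30)
            for i in range(100)
        ]
        kept = filter_pairs(PairSet(alignments=hits))
        expected = {h.id_a for h in hits if h.percent_identity >= 80.0}
        assert {h.id_a for h in kept.alignments} == expected

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            filter_pairs(PairSet(), min_identity=150)
        with pytest.raises(ValueError):
            filter_pairs(PairSet(), max_evalue=-1)


class TestBlastTable:
    def test_outfmt6_round_trip_and_coordinates(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q1\ts1\t95.5\t100\t4\t1\t11\t110\t1\t100\t1e-30\t200\n")
        (hit,) = read_blast_hits(p)
        assert hit.percent_identity == 95.5
        assert (hit.start_a, hit.end_a) == (10, 110)
        assert hit.evalue == pytest.approx(1e-30) and hit.score == 200
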