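import itertools
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chimeradx import seqcore as sc

BL = sc.default_substitution_table()
IDX = sc.CHAR_INDEX


def oracle_global(a, b, gap_open=11.0, gap_extend=1.0):
    """Independent affine-gap DP over explicit (i, j, state) recursion."""

    @lru_cache(maxsize=None)
    def best(i, j, state):
        # state: 0 diagonal/start, 1 gap-in-b open, 2 gap-in-a open
        if i == 0 and j == 0:
            return 0.0 if state == 0 else -1e18
        cands = []
        if i > 0 and j > 0:
            prev = best(i - 1, j - 1, 0)
            cands.append(prev + BL[IDX[a[i - 1]], IDX[b[j - 1]]]
                         if state == 0 else -1e18)
        if state == 0:
            # close any pending gap: handled by entering from gap states
            cands.append(best(i, j, 1))
            cands.append(best(i, j, 2))
        if state == 1 and i > 0:
            cands.append(best(i - 1, j, 1) - gap_extend)
            cands.append(best(i - 1, j, 0) - gap_open - gap_extend)
        if state == 2 and j > 0:
            cands.append(best(i, j - 1, 2) - gap_extend)
            cands.append(best(i, j - 1, 0) - gap_open - gap_extend)
        return max(cands) if cands else -1e18

    return max(best(len(a), len(b), s) for s in range(3))


class TestGlobalAlign:
    def test_identity_alignment_scores_diagonal_sum(self):
        (ra, rb), score = sc.global_align("ACD", "ACD")
        assert (ra, rb) == ("ACD", "ACD")
        assert score == sum(BL[IDX[c], IDX[c]] for c in "ACD")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            sc.global_align("A", "")

    def test_illegal_residue_rejected(self):
        with pytest.raises(ValueError):
            sc.global_align("ACB?", "ACD")

    def test_textbook_pair_matches_oracle(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        (_, _), score = sc.global_align(a, b)
        assert score == pytest.approx(oracle_global(a, b))

    def test_exhaustive_small_pairs_match_oracle(self):
        alphabet = "ACDE"
        seqs = [''.join(p) for n in (1, 2, 3)
                for p in itertools.product(alphabet, repeat=n)]
        rng = np.random.default_rng(0)
        pairs = [(seqs[i], seqs[j])
                 for i, j in rng.integers(0, len(seqs), size=(300, 2))]
        for a, b in pairs:
            (ra, rb), score = sc.global_align(a, b)
            assert score == pytest.approx(oracle_global(a, b)), (a, b)
            assert ra.replace("-", "") == a and rb.replace("-", "") == b

    @given(st.text(alphabet="ACDEFGHIK", min_size=1, max_size=7),
           st.text(alphabet="ACDEFGHIK", min_size=1, max_size=7))
    @settings(max_examples=60, deadline=None)
    def test_alignment_rows_ungap_to_inputs(self, a, b):
        (ra, rb), _ = sc.global_align(a, b)
        assert ra.replace("-", "") == a
        assert rb.replace("-", "") == b
        assert len(ra) == len(rb)


class TestPercentIdentity:
    @pytest.mark.parametrize("pair,expected", [
        (("AAAA", "AAAA"), 1.0),
        (("AAAT", "AAAA"), 0.75),
        (("A--A", "AG-A"), 1.0),   # only doubly-ungapped columns count
        (("----", "AAAA"), 0.0),
    ])
    def test_examples(self, pair, expected):
        assert sc.percent_identity(pair) == pytest.approx(expected)

    def test_symmetry_and_length_check(self):
        assert sc.percent_identity(("AC-A", "AGGA")) == \
            sc.percent_identity(("AGGA", "AC-A"))
        with pytest.raises(ValueError):
            sc.percent_identity(("AA", "AAA"))


class TestProgressiveMSA:
    def test_two_sequences_match_pairwise(self):
        aln = sc.progressive_msa(["HEAGAWGHEE", "PAWHEAE"])
        (ra, rb), _ = sc.global_align("HEAGAWGHEE", "PAWHEAE")
        assert aln.rows[0][1] == ra
        assert aln.rows[1][1] == rb

    def test_identical_sequences_gap_free(self):
        aln = sc.progressive_msa(["MKVLA"] * 4)
        assert aln.n_columns == 5
        assert all("-" not in row for _, row in aln.rows)

    def test_round_trip_and_width(self):
        seqs = ["MKVLAWQE", "MKVLWQE", "MKVAWQEE", "MKLAWQE"]
        aln = sc.progressive_msa(seqs)
        for (rid, row), original in zip(aln.rows, seqs):
            assert row.replace("-", "") == original
        assert aln.n_columns >= max(len(s) for s in seqs)

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            sc.progressive_msa(["MKVLA"])


class TestTrimByOccupancy:
    def test_sparse_column_removed_and_boundary_kept(self):
        rows = [(f"s{i}", "A-") for i in range(3)] + \
               [(f"s{i}", "AA") for i in range(3, 10)]
        aln = sc.Alignment(rows)
        trimmed = sc.trim_by_occupancy(aln, 0.70)
        # column 2 has exactly 7/10 occupancy: inclusive threshold keeps it
        assert trimmed.n_columns == 2
        rows2 = [(f"s{i}", "A-") for i in range(8)] + \
                [(f"s{i}", "AA") for i in range(8, 10)]
        assert sc.trim_by_occupancy(sc.Alignment(rows2), 0.70).n_columns == 1

    def test_gap_free_unchanged_and_idempotent(self):
        aln = sc.Alignment([("a", "MKV"), ("b", "MRV")])
        t = sc.trim_by_occupancy(aln)
        assert t.rows == aln.rows
        mixed = sc.Alignment([("a", "M-KV-"), ("b", "MRK--"), ("c", "MRKV-")])
        once = sc.trim_by_occupancy(mixed, 0.70)
        twice = sc.trim_by_occupancy(once, 0.70)
        assert once.rows == twice.rows

    def test_threshold_validation(self):
        aln = sc.Alignment([("a", "MK")])
        with pytest.raises(ValueError):
            sc.trim_by_occupancy(aln, 0.0)


class TestTranslation:
    def test_forward_frame(self):
        assert sc.six_frame_translate("ATGAAA")[0] == "MK"

    def test_reverse_frame(self):
        assert sc.six_frame_translate("TTTCAT")[3] == "MK"

    def test_reverse_complement_swaps_frame_blocks(self):
        from Bio.Seq import Seq

        nt = "ATGAAATTTCCCGGGT"
        fwd = sc.six_frame_translate(nt)
        rev = sc.six_frame_translate(str(Seq(nt).reverse_complement()))
        assert fwd[:3] == rev[3:]
        assert fwd[3:] == rev[:3]

    def test_ambiguity_and_length_contract(self):
        assert sc.six_frame_translate("ATGNNN")[0] == "MX"
        with pytest.raises(ValueError):
            sc.six_frame_translate("AT")
        with pytest.raises(ValueError):
            sc.six_frame_translate("ATZ")


class TestLongestOrf:
    def test_longest_by_inspection(self):
        frames = ["MAAA*", "MA*", "", "", "", ""]
        res = sc.longest_orf(frames)
        assert res.sequence == "MAAA"
        assert res.found

    def test_no_methionine_flagged_empty(self):
        res = sc.longest_orf(["AAA", "KKK*", "", "", "", ""])
        assert res.sequence == ""
        assert not res.found

    def test_tie_broken_by_frame_order(self):
        res = sc.longest_orf(["MAA", "MCC", "", "", "", ""])
        assert res.sequence == "MAA"
        assert res.frame == 0


class TestNrDatabase:
    def test_identical_sequences_merged_with_provenance(self):
        recs = [
            sc.TaxLabeledSequence("sp1", "MKVLA", "Eukaryota", "familyA"),
            sc.TaxLabeledSequence("sp2", "MKVLA", "Eukaryota", "familyA"),
        ]
        db = sc.build_nr_database(recs)
        assert len(db) == 1
        assert db["sp1"].source_ids == {"sp1", "sp2"}

    def test_conflicting_taxonomy_becomes_unknown(self):
        recs = [
            sc.TaxLabeledSequence("x", "MKVLA", "Eukaryota", "familyA"),
            sc.TaxLabeledSequence("y", "MKVLA", "Bacteria", "familyA"),
        ]
        with pytest.warns(UserWarning):
            db = sc.build_nr_database(recs)
        assert db["x"].domain_of_life == "Unknown"

    def test_distinct_unmerged_and_idempotent(self):
        recs = [sc.TaxLabeledSequence(f"s{i}", "MKVLA" + "ACDE"[i], "Bacteria",
                                      "background") for i in range(4)]
        db = sc.build_nr_database(recs)
        assert len(db) == 4
        again = sc.build_nr_database(list(db))
        assert [(r.id, r.residues) for r in again] == \
            [(r.id, r.residues) for r in db]


def test_fasta_round_trip(tmp_path):
    records = [("seq1", "MKVLA" * 30), ("seq2", "MWRC")]
    path = tmp_path / "x.fasta"
    sc.write_fasta(path, records)
    assert sc.read_fasta(path) == records
    # 60-character wrapping
    assert max(len(l) for l in path.read_text().splitlines()) <= 61


def test_taxonomy_tsv_round_trip(tmp_path):
    tax = {"a": ("Eukaryota", "focal"), "b": ("Bacteria", "familyB")}
    path = tmp_path / "tax.tsv"
    sc.write_taxonomy_tsv(path, tax)
    assert sc.read_taxonomy_tsv(path) == tax
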