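import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chimeradx import profile_search as ps
from chimeradx.seqcore import Alignment, SequenceDatabase, TaxLabeledSequence


def _aln(rows):
    return Alignment([(f"s{i}", r) for i, r in enumerate(rows)])


class TestBuildProfile:
    def test_conserved_column_scores_highest(self):
        prof = ps.build_profile(_aln(["AKV", "AKV", "ARV"]),
                                background_freqs=np.full(20, 0.05))
        assert np.argmax(prof.match_scores[0, :20]) == 0  # A
        assert prof.match_scores[0, 0] == max(prof.match_scores[0, :20])

    def test_small_pseudocount_limit(self):
        bg = np.full(20, 0.05)
        prof = ps.build_profile(_aln(["ACD"]), pseudocount_weight=1e-9,
                                background_freqs=bg)
        # observed residue tends to log2(1/bg); others to the floor cap
        assert prof.match_scores[0, 0] == pytest.approx(np.log2(1 / 0.05), abs=1e-6)
        assert prof.match_scores[0, 5] <= ps.SCORE_FLOOR + 0.5

    def test_row_order_invariance(self):
        rows = ["MKVLA", "MRVLA", "MKVIA", "MKWLA"]
        p1 = ps.build_profile(_aln(rows))
        p2 = ps.build_profile(Alignment(
            [(f"s{i}", r) for i, r in enumerate(reversed(rows))]))
        assert np.allclose(p1.match_scores, p2.match_scores)

    def test_low_occupancy_columns_excluded(self):
        prof = ps.build_profile(_aln(["MK--", "MK--", "MKV-", "MKVA"]))
        # columns 3 (50%) kept, 4 (25%) dropped
        assert prof.source_columns == [1, 2, 3]

    def test_x_scores_zero_and_counts_nothing(self):
        prof = ps.build_profile(_aln(["MXV", "MKV"]))
        assert prof.match_scores[1, 20] == 0.0


class TestWindowProfiles:
    @pytest.mark.parametrize("length,window,step,expected", [
        (1133, 60, 1, 1074),
        (60, 60, 1, 1),
        (61, 60, 1, 2),
        (100, 30, 7, 11),
    ])
    def test_window_counts(self, length, window, step, expected):
        aln = _aln(["A" * length, "A" * length])
        wins = ps.window_profiles(aln, window_size=window, step=step)
        assert len(wins) == expected
        assert wins[0][0] == 1
        if len(wins) > 1:
            assert wins[1][0] == 1 + step

    @given(st.integers(10, 200), st.integers(1, 10), st.integers(1, 7))
    @settings(max_examples=40, deadline=None)
    def test_window_count_formula(self, length, window, step):
        window = min(window, length)
        aln = _aln(["M" * length])
        wins = ps.window_profiles(aln, window_size=window, step=step)
        assert len(wins) == (length - window) // step + 1

    def test_window_larger_than_alignment_rejected(self):
        with pytest.raises(ValueError):
            ps.window_profiles(_aln(["MKV"]), window_size=10)


class TestLocalScore:
    def test_self_hit_spans_full_sequence(self):
        seq = "MKVLAWQECD"
        prof = ps.build_profile(_aln([seq] * 5))
        score, env = ps.score_profile_local(prof, seq)
        assert score > 0
        assert (env.target_start, env.target_end) == (1, len(seq))
        assert (env.profile_start, env.profile_end) == (1, len(seq))

    def test_all_x_sequence_scores_zero(self):
        prof = ps.build_profile(_aln(["MKVLA"] * 3))
        score, env = ps.score_profile_local(prof, "XXXXXXX")
        assert score == 0.0
        assert env.empty

    def test_matches_exhaustive_gapless_segment_oracle(self):
        rng = np.random.default_rng(3)
        aas = "ARNDCQEGHILKMFPSTWYV"
        for _ in range(25):
            cols = rng.integers(2, 7)
            rows = ["".join(rng.choice(list(aas), size=cols)) for _ in range(3)]
            prof = ps.build_profile(_aln(rows), gap_open=1e9, gap_extend=1e9)
            seq = "".join(rng.choice(list(aas), size=int(rng.integers(2, 9))))
            score, env = ps.score_profile_local(prof, seq)
            # oracle: every gapless profile-span x sequence-span diagonal
            best = 0.0
            m = prof.n_columns
            for p0, j0 in itertools.product(range(m), range(len(seq))):
                total = 0.0
                for k in range(min(m - p0, len(seq) - j0)):
                    total += prof.match_scores[
                        p0 + k, ps.CHAR_INDEX[seq[j0 + k]]]
                    best = max(best, total)
            assert score == pytest.approx(best, abs=1e-9)


def _random_db(rng, n=30, length=(60, 150)):
    aas = "ARNDCQEGHILKMFPSTWYV"
    recs = []
    for i in range(n):
        seq = "".join(rng.choice(list(aas), size=int(rng.integers(*length))))
        recs.append(TaxLabeledSequence(f"r{i:02d}", seq, "Bacteria", "background"))
    return SequenceDatabase(recs)


class TestEvalueCalibration:
    def test_evalue_strictly_decreasing_and_scales_with_db(self):
        rng = np.random.default_rng(1)
        db = _random_db(rng)
        prof = ps.build_profile(_aln(["MKVLAWQECDMKVLAWQECD"] * 4))
        ps.calibrate_evalue(prof, db, n_decoys=150, seed=5)
        e = [ps.evalue(prof, s, len(db)) for s in (5.0, 10.0, 20.0, 40.0)]
        assert e == sorted(e, reverse=True)
        assert ps.evalue(prof, 10.0, 2 * len(db)) == pytest.approx(
            2 * ps.evalue(prof, 10.0, len(db)))

    def test_expected_false_positives_near_one_at_e1(self):
        """E-value definition: ~1 decoy per search at E <= 1."""
        rng = np.random.default_rng(7)
        db = _random_db(rng, n=40)
        prof = ps.build_profile(_aln(["MKVLAWQECDHEAGAWGHEE"] * 4))
        counts = []
        for rep in range(20):
            ps.calibrate_evalue(prof, db, n_decoys=150, seed=100 + rep)
            hits = ps.search_database(prof, db, e_threshold=1.0)
            counts.append(len(hits))
        mean = np.mean(counts)
        # Poisson(1) mean over 20 replicates, 3 sd tolerance
        assert abs(mean - 1.0) <= 3 * np.sqrt(1.0 / 20) + 0.35

    def test_degenerate_decoys_raise(self):
        db = SequenceDatabase(
            [TaxLabeledSequence(f"d{i}", "XXXXXXXXXX", "Unknown", "background")
             for i in range(5)])
        prof = ps.build_profile(_aln(["MKVLA"] * 3))
        with pytest.raises(ps.CalibrationError):
            ps.calibrate_evalue(prof, db, n_decoys=120, seed=0)

    def test_minimum_decoy_count_enforced(self):
        rng = np.random.default_rng(2)
        prof = ps.build_profile(_aln(["MKVLA"] * 3))
        with pytest.raises(ValueError):
            ps.calibrate_evalue(prof, _random_db(rng), n_decoys=50, seed=0)


class TestSearchDatabase:
    def test_uncalibrated_profile_rejected(self):
        rng = np.random.default_rng(4)
        prof = ps.build_profile(_aln(["MKVLA"] * 3))
        with pytest.raises(ps.UncalibratedProfileError):
            ps.search_database(prof, _random_db(rng), 0.01)

    def test_infinite_threshold_returns_every_record(self):
        rng = np.random.default_rng(5)
        db = _random_db(rng, n=15)
        prof = ps.build_profile(_aln(["MKVLAWQECD"] * 4))
        ps.calibrate_evalue(prof, db, n_decoys=120, seed=1)
        hits = ps.search_database(prof, db, e_threshold=np.inf)
        assert sorted(h.target_id for h in hits) == db.ids

    def test_empty_database(self):
        prof = ps.build_profile(_aln(["MKVLA"] * 3))
        prof.calibration = ps.EValueCalibration(5.0, 1.0, 100)
        assert ps.search_database(prof, SequenceDatabase([]), 0.01) == []

    def test_domainB_profile_recovers_bacterial_family(self, chimera_scenario):
        """Seeded ground truth: the domain-B profile finds >= 90% of the
        bacterial family members and no background sequences at E <= 0.01."""
        scen = chimera_scenario
        db = scen.database
        gt = scen.ground_truth
        segs = [(f, db[f].residues[gt.domain_spans[f]["domainB"][0] - 1:
                                   gt.domain_spans[f]["domainB"][1]])
                for f in gt.fusion_member_ids]
        prof = ps.build_profile(Alignment(segs))
        ps.calibrate_evalue(prof, db, n_decoys=150, seed=2)
        hits = ps.search_database(prof, db, 0.01)
        hit_ids = {h.target_id for h in hits}
        bacteria = [r.id for r in db
                    if r.category == "familyB" and r.domain_of_life == "Bacteria"]
        assert len(hit_ids & set(bacteria)) >= 0.9 * len(bacteria)
        background = {r.id for r in db if r.category == "background"}
        assert not hit_ids & background


class TestProvenance:
    def test_counts_conserve_totals_and_categories(self, chimera_scenario,
                                                   chimera_discovery):
        scen, state = chimera_scenario, chimera_discovery
        windows = ps.window_profiles(state.alignmentB, window_size=60, step=10)
        ps.calibrate_windows(windows, scen.database, n_decoys=100, seed=3)
        stack = ps.provenance_profile(windows, scen.database, 0.01)
        assert len(stack.window_starts) == len(windows)
        for counts, prof_pair in zip(stack.counts, windows):
            hits = ps.search_database(prof_pair[1], scen.database, 0.01)
            assert sum(counts.values()) == len(hits)

    def test_empty_database_gives_all_zero_profile(self):
        prof = ps.build_profile(_aln(["MKVLAWQECD" * 6] * 3))
        prof.calibration = ps.EValueCalibration(5.0, 1.0, 100)
        stack = ps.provenance_profile([(1, prof)], SequenceDatabase([]), 0.01)
        assert stack.totals() == [0]

    def test_majority_rules(self):
        stack = ps.ProvenanceProfile(
            [1, 2], [{"Bacteria": 3, "Eukaryota_focal": 2},
                     {"Bacteria": 1, "Eukaryota_other": 1}])
        assert stack.majority(0) == "Bacteria"
        assert stack.majority(1) is None           # tie: no strict majority
        assert stack.majority(1, min_hits=3) is None


@pytest.mark.parametrize("seed", range(1, 6))
def test_null_scenario_has_no_bacterial_majority_window(seed):
    """Vertically inherited domains show no bacterial-majority window at
    E <= 0.01: in the null scenario the bacterial family lies beyond the
    reach of 60-residue window profiles."""
    from chimeradx.discovery import iterate_discovery
    from chimeradx.seqcore import progressive_msa
    from chimeradx.simulate import ScenarioConfig, generate_scenario

    scen = generate_scenario(
        ScenarioConfig(seed=seed, scenario_kind="null_vertical"))
    db = scen.database
    state = iterate_discovery(db, scen.seed_alignment_A,
                              scen.seed_alignment_B, seed=seed)
    rows = [(i, db[i].residues) for i in state.accepted_ids]
    aln = progressive_msa([r for _, r in rows], ids=[i for i, _ in rows])
    windows = ps.window_profiles(aln, window_size=60, step=6)
    ps.calibrate_windows(windows, db, n_decoys=100, seed=seed + 17)
    stack = ps.provenance_profile(windows, db, 0.01)
    for i in range(len(stack.window_starts)):
        assert stack.majority(i, exclude_focal=True, min_hits=3) != "Bacteria"


def test_profile_tsv_round_trip(tmp_path):
    prof = ps.build_profile(_aln(["MKVLAWQE", "MKVIAWQE", "MRVLAWQE"]))
    prof.calibration = ps.EValueCalibration(7.5, 1.25, 150)
    path = tmp_path / "profile.tsv"
    ps.write_profile_tsv(path, prof)
    back = ps.read_profile_tsv(path)
    assert back.n_columns == prof.n_columns
    assert np.allclose(back.match_scores, prof.match_scores, atol=1e-4)
    assert back.calibration.location == pytest.approx(7.5)


def test_align_to_profile_contracts():
    prof = ps.build_profile(_aln(["MKVLAWQE"] * 4))
    assert ps.align_to_profile(prof, "MKVLAWQE") == "MKVLAWQE"
    row = ps.align_to_profile(prof, "MKLAWQE")
    assert len(row.replace("-", "")) == 7
    assert len([c for c in row if not c.islower()]) == prof.n_columns
    with pytest.raises(ValueError):
        ps.align_to_profile(prof, "")
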