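import numpy as np
import pytest

from matrixgc.matrix_gc import (
    BindingCall,
    MatrixGcConfig,
    best_qualifying_score,
    classify_gene,
    classify_gene_set,
    gc_content,
    gc_window,
)
from matrixgc.seqio import PromoterSeq

from conftest import random_seq
from oracles import classify_brute, gc_brute


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [("GCGC", 100.0), ("ATAT", 0.0), ("ATGC", 50.0)])
    def test_pure_cases(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_n_excluded_from_numerator_and_denominator(self):
        assert gc_content("GCNN") == pytest.approx(100.0)
        assert gc_content("ATGCNNNN") == pytest.approx(50.0)

    def test_matches_counting_oracle_on_random_sequence(self):
        rng = np.random.default_rng(13)
        seq = random_seq(rng, 500, n_rate=0.1)
        assert gc_content(seq) == pytest.approx(gc_brute(seq))

    def test_undefined_without_acgt(self):
        with pytest.raises(ValueError, match="undefined"):
            gc_content("NNNN")
        with pytest.raises(ValueError):
            gc_content("")


class TestGcWindow:
    def test_interior_match_gives_full_215bp_window(self):
        win = gc_window(1000, 300, width=15, flank=100)
        assert (win.start, win.end, win.clipped) == (200, 415, False)
        assert win.end - win.start == 215

    def test_left_truncation(self):
        win = gc_window(1000, 0, width=15, flank=100)
        assert (win.start, win.end, win.clipped) == (0, 115, True)

    def test_both_sides_truncated(self):
        win = gc_window(120, 50, width=15, flank=100)
        assert (win.start, win.end, win.clipped) == (0, 120, True)

    def test_out_of_range_position_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            gc_window(100, 90, width=15, flank=100)


class TestClassifyGene:
    def _embed(self, consensus, flank_seq_left, flank_seq_right, total_len=1000, pos=400):
        rng = np.random.default_rng(17)
        background = list(random_seq(rng, total_len))
        insert = flank_seq_left + consensus + flank_seq_right
        background[pos - len(flank_seq_left):pos - len(flank_seq_left) + len(insert)] = list(insert)
        return "".join(background)

    def test_consensus_in_gc_rich_context_is_bound(self, pwm, consensus):
        seq = self._embed(consensus, "GC" * 50, "CG" * 50)
        call = classify_gene(PromoterSeq("g", seq), pwm)
        assert call.bound
        assert call.best_percent_score == pytest.approx(100.0)
        assert call.best_gc >= 60

    def test_consensus_in_poly_at_context_fails_gc_filter(self, pwm, consensus):
        # window GC comes only from the motif itself: ~5%, far below 60%
        seq = "AT" * 200 + "A" * 100 + consensus + "T" * 100 + "TA" * 200
        call = classify_gene(PromoterSeq("g", seq), pwm, MatrixGcConfig())
        assert not call.bound
        assert call.n_passing_matches == 0

    def test_random_promoter_matches_brute_force_oracle(self, pwm):
        rng = np.random.default_rng(23)
        for _ in range(10):
            seq = random_seq(rng, 600, n_rate=0.02)
            call = classify_gene(PromoterSeq("g", seq), pwm)
            bound, n_passing = classify_brute(seq, pwm.weights.tolist(), 65.0, 60.0, 100)
            assert call.bound == bound
            assert call.n_passing_matches == n_passing

    def test_zero_gc_threshold_reduces_to_pwm_match_presence(self, pwm):
        from matrixgc.motif import scan_sequence

        rng = np.random.default_rng(29)
        cfg = MatrixGcConfig(gc_threshold=0)
        for _ in range(10):
            seq = random_seq(rng, 400)
            call = classify_gene(PromoterSeq("g", seq), pwm, cfg)
            has_match = len(scan_sequence(pwm, seq, threshold=65)) >= 1
            assert call.bound == has_match

    def test_bound_is_monotone_in_both_thresholds(self, pwm, consensus):
        seq = self._embed(consensus, "GCAT" * 25, "ATGC" * 25)
        prom = PromoterSeq("g", seq)
        for loose, tight in [((50, 40), (80, 40)), ((50, 40), (50, 70))]:
            loose_call = classify_gene(prom, pwm, MatrixGcConfig(pwm_threshold=loose[0], gc_threshold=loose[1]))
            tight_call = classify_gene(prom, pwm, MatrixGcConfig(pwm_threshold=tight[0], gc_threshold=tight[1]))
            assert loose_call.n_passing_matches >= tight_call.n_passing_matches
            assert loose_call.bound or not tight_call.bound

    def test_best_qualifying_score_matches_enumeration(self, pwm):
        from oracles import scan_brute

        rng = np.random.default_rng(31)
        seq = random_seq(rng, 500)
        best = best_qualifying_score(seq, pwm, gc_threshold=60.0, flank=100)
        qualifying = []
        for pos, _s, score, _k in scan_brute(pwm.weights.tolist(), seq, threshold=0):
            lo, hi = max(0, pos - 100), min(len(seq), pos + pwm.width + 100)
            if gc_brute(seq[lo:hi]) >= 60.0:
                qualifying.append(score)
        expected = max(qualifying) if qualifying else float("-inf")
        assert best == pytest.approx(expected, abs=1e-9)


class TestClassifyGeneSet:
    def test_constructed_truth_percentage(self, pwm, consensus):
        rng = np.random.default_rng(37)
        proms = []
        for i in range(4):  # pass both filters
            seq = "GC" * 100 + "G" * 85 + consensus + "C" * 100 + "".join(rng.choice(list("AT"), 500))
            proms.append(PromoterSeq(f"pos{i}", seq))
        for i in range(6):  # no motif, AT-only
            proms.append(PromoterSeq(f"neg{i}", "".join(rng.choice(list("AT"), 1000))))
        calls, summary = classify_gene_set(proms, pwm)
        assert summary["bound_percentage"] == pytest.approx(40.00)
        assert [c.bound for c in calls] == [True] * 4 + [False] * 6

    def test_all_n_promoters_give_zero_percent(self, pwm):
        proms = [PromoterSeq(f"g{i}", "N" * 500) for i in range(5)]
        _, summary = classify_gene_set(proms, pwm)
        assert summary["bound_percentage"] == 0.0

    def test_seeded_cohort_matches_end_to_end_oracle(self, pwm):
        rng = np.random.default_rng(41)
        proms = [PromoterSeq(f"g{i}", random_seq(rng, 400)) for i in range(50)]
        _, summary = classify_gene_set(proms, pwm)
        n_bound = sum(
            classify_brute(p.seq, pwm.weights.tolist(), 65.0, 60.0, 100)[0] for p in proms
        )
        assert summary["bound_percentage"] == pytest.approx(round(100.0 * n_bound / 50, 2))

    def test_empty_and_duplicate_inputs_rejected(self, pwm):
        with pytest.raises(ValueError, match="at least one"):
            classify_gene_set([], pwm)
        proms = [PromoterSeq("g", "ACGT" * 100), PromoterSeq("g", "AAAA" * 100)]
        with pytest.raises(ValueError, match="duplicate"):
            classify_gene_set(proms, pwm)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MatrixGcConfig(pwm_threshold=120)
        with pytest.raises(ValueError):
            MatrixGcConfig(flank=0)

    def test_binding_call_invariant(self, pwm, consensus):
        seq = "GC" * 100 + consensus + "CG" * 100
        call = classify_gene(PromoterSeq("g", seq), pwm)
        assert isinstance(call, BindingCall)
        assert call.bound == (call.n_passing_matches >= 1)
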