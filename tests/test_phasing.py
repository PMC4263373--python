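import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasitrack.phasing import (
    PositionMap,
    cycles_per_window,
    merge_clusters,
    merge_strands,
    phase_position,
    phasing_score,
    scan_windows,
    score_window,
)
from phasitrack.srio import AlignmentRecord, Library


def brute_force_best_register(abundance, counts, wstart, k, window_len):
    """Independent enumeration of every register of a window.

    Walks all window offsets explicitly instead of striding phase
    positions, and recomputes the score from the formula.
    """
    in_window = {
        p: a for p, a in abundance.items() if wstart <= p < wstart + window_len
    }
    total = sum(in_window.values())
    C = window_len // k
    best = None
    for r in range(k):
        phase_positions = [wstart + r + k * i for i in range(C)]
        P = sum(in_window.get(p, 0.0) for p in phase_positions)
        n = sum(1 for p in phase_positions if in_window.get(p, 0.0) > 0)
        U = total - P
        score = 0.0 if n < 3 else (n - 2) * math.log(1 + 10 * P / (1 + U))
        reads = sum(counts.get(p, 0) for p in phase_positions)
        if best is None or score > best[0]:
            best = (score, (wstart + r) % k, n, reads)
    return best


def _posmap(entries, chrom="chr1"):
    pm = PositionMap()
    for pos, rpm, copies in entries:
        pm.add(chrom, pos, rpm, copies)
    return pm


class TestCycleConstants:
    @pytest.mark.parametrize("k,expected", [(21, 23), (22, 22), (24, 20)])
    def test_cycles_in_500bp_window(self, k, expected):
        assert cycles_per_window(500, k) == expected

    def test_window_shorter_than_phase_is_error(self):
        with pytest.raises(ValueError):
            cycles_per_window(20, 21)


class TestMergeStrands:
    def test_duplex_partners_share_phase_position(self, lib):
        # plus 21-mer at [1000,1021) and its DCL4 partner at [998,1019)
        plus = AlignmentRecord("chr1", 1000, 21, "+")
        minus = AlignmentRecord("chr1", 998, 21, "-")
        assert phase_position(plus) == phase_position(minus) == 1000

    def test_plus_read_maps_at_start_minus_at_leftmost_zero(self):
        assert phase_position(AlignmentRecord("chr1", 5, 21, "+")) == 5
        assert phase_position(AlignmentRecord("chr1", 0, 21, "-")) == 2

    def test_pooling_normalizes_by_library_totals(self, lib):
        libs = {
            "wt_1": lib,
            "wt_2": Library("wt_2", "wildtype", 2, 2_000_000),
        }
        reads = {
            "wt_1": [AlignmentRecord("chr1", 100, 21, "+", copies=2)],
            "wt_2": [AlignmentRecord("chr1", 100, 21, "+", copies=2)],
        }
        pm = merge_strands(reads, libs, size_class=21)
        assert pm.abundance["chr1"][100] == pytest.approx(2.0 + 1.0)
        assert pm.count["chr1"][100] == 4

    def test_other_size_classes_excluded(self, lib):
        reads = {"wt_1": [AlignmentRecord("chr1", 100, 22, "+")]}
        pm = merge_strands(reads, {"wt_1": lib}, size_class=21)
        assert pm.abundance == {}


class TestPhasingScore:
    def test_below_three_occupied_cycles_scores_zero(self):
        assert phasing_score(1000.0, 0.0, 2) == 0.0
        assert phasing_score(1000.0, 0.0, 0) == 0.0

    def test_direct_arithmetic_values(self):
        assert phasing_score(100, 0, 5) == pytest.approx(3 * math.log(1001), rel=1e-9)
        assert phasing_score(100, 100, 10) == pytest.approx(
            8 * math.log(1 + 1000 / 101), rel=1e-9
        )

    def test_negative_inputs_are_hard_errors(self):
        with pytest.raises(ValueError):
            phasing_score(-1, 0, 5)

    @settings(max_examples=50, derandomize=True)
    @given(
        P=st.floats(0, 1e4), U=st.floats(0, 1e4),
        dP=st.floats(0, 100), n=st.integers(3, 23),
    )
    def test_monotone_in_p_and_antitone_in_u(self, P, U, dP, n):
        assert phasing_score(P + dP, U, n) >= phasing_score(P, U, n)
        assert phasing_score(P, U + dP, n) <= phasing_score(P, U, n)
        assert phasing_score(P, U, n + 1) >= phasing_score(P, U, n)


class TestScanWindows:
    def test_six_perfectly_phased_reads_qualify(self):
        # 6 in-phase 21-mers, 10 copies each, 10 RPM each, zero noise
        pm = _posmap([(1000 + 21 * i, 10.0, 10) for i in range(6)])
        windows = scan_windows(pm, k=21)
        assert windows  # several sliding windows cover the run
        for w in windows:
            assert (w.n, w.U) == (6, 0.0)
            assert w.inphase_reads == 60
            assert w.score == pytest.approx(4 * math.log(1 + 10 * 60.0), rel=1e-9)
            assert w.qualifies  # 4*ln(601) ~ 25.6 >= 25

    def test_four_in_register_reads_not_a_candidate(self):
        pm = _posmap([(1000 + 21 * i, 10.0, 1) for i in range(4)])
        assert scan_windows(pm, k=21, min_inphase_reads=5) == []

    def test_register_reported_modulo_k(self):
        pm = _posmap([(1003 + 21 * i, 50.0, 10) for i in range(8)])
        windows = scan_windows(pm, k=21)
        assert windows and all(w.register == 1003 % 21 for w in windows)

    def test_shift_by_k_preserves_score_and_register(self):
        entries = [(1000 + 21 * i, 10.0, 10) for i in range(6)] + [(1010, 3.0, 3)]
        pm = _posmap(entries)
        shifted = _posmap([(p + 21, a, c) for p, a, c in entries])
        w = score_window(pm, "chr1", 987, 21)
        ws = score_window(shifted, "chr1", 987 + 21, 21)
        assert ws.score == pytest.approx(w.score)
        assert ws.register == w.register

    def test_agrees_with_brute_force_on_random_windows(self):
        rng = random.Random(42)
        for trial in range(200):
            k = rng.choice([21, 22, 24])
            wstart = rng.randrange(0, 2000, 250)
            pm = PositionMap()
            for _ in range(rng.randrange(1, 40)):
                pos = wstart + rng.randrange(0, 500)
                copies = rng.randrange(1, 20)
                pm.add("chr1", pos, copies * 1.0, copies)
            w = score_window(pm, "chr1", wstart, k)
            score, register, n, reads = brute_force_best_register(
                pm.abundance["chr1"], pm.count["chr1"], wstart, k, 500
            )
            assert w.score == pytest.approx(score, rel=1e-9), (trial, k)
            assert (w.register, w.n, w.inphase_reads) == (register, n, reads)

    def test_uniform_noise_rarely_scores(self):
        rng = np.random.default_rng(19)
        n_qualifying = 0
        for _ in range(100):
            pm = PositionMap()
            for pos in rng.integers(0, 480, 60):
                pm.add("chr1", int(pos), 3.0, 3)
            for w in scan_windows(pm, k=21):
                n_qualifying += w.qualifies
        assert n_qualifying == 0


class TestClusters:
    def _win(self, start, score=30.0, k=21, chrom="chr1"):
        from phasitrack.phasing import PhaseWindow

        return PhaseWindow(chrom, start, 500, k, 0, 8, 100.0, 5.0, score, 50, qualifies=True)

    def test_overlapping_windows_merge(self):
        (c,) = merge_clusters([self._win(0), self._win(250, score=40.0)])
        assert (c.start, c.end) == (0, 750)
        assert c.score == 40.0

    def test_disjoint_windows_stay_separate(self):
        cs = merge_clusters([self._win(0), self._win(1000)])
        assert [(c.start, c.end) for c in cs] == [(0, 500), (1000, 1500)]

    def test_empty_input(self):
        assert merge_clusters([]) == []

    def test_lbl1_flagging(self):
        import pandas as pd

        from phasitrack.phasing import flag_lbl1_dependent

        clusters = merge_clusters([self._win(0), self._win(1000)])
        calls = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [0, 1000],
                "passes": [True, True],
                "direction": ["down_in_mutant", "up_in_mutant"],
            }
        )
        flag_lbl1_dependent(clusters, calls)
        assert clusters[0].lbl1_dependent is True
        assert clusters[1].lbl1_dependent is False
        flag_lbl1_dependent(clusters, None)
        assert clusters[0].lbl1_dependent is None
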