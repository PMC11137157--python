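from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import csslmap as cm
from csslmap.genotyper import (DEFAULT_MIN_INFORMATIVE, call_segments,
                               classify_window, consensus_marker_states,
                               refine_marker_states, scan_windows)
from csslmap.states import DON, HET, REC, UNKNOWN


def oracle_classify(n_rec: int, n_don: int, min_informative: int = 8) -> int:
    """Rational-arithmetic application of the printed ratio thresholds."""
    if n_rec + n_don < min_informative:
        return UNKNOWN
    ratio = Fraction(n_rec, n_don) if n_don else None
    if ratio is None or ratio > Fraction(11, 4):
        return REC
    if ratio < Fraction(2, 13):
        return DON
    return HET


class TestClassifyWindow:
    @pytest.mark.parametrize("n_rec,n_don,expected", [
        (12, 3, REC),       # 12:3 beats 11:4
        (11, 4, HET),       # boundary is not "larger than"
        (1, 14, DON),       # 1:14 is below 2:13
        (2, 13, HET),       # boundary is not "smaller than"
        (3, 2, UNKNOWN),    # only 5 informative calls
        (15, 0, REC),
        (0, 15, DON),
        (8, 0, REC),
    ])
    def test_printed_threshold_examples(self, n_rec, n_don, expected):
        assert classify_window(n_rec, n_don) == expected

    def test_full_enumeration_agrees_with_rational_oracle(self):
        for n_rec in range(16):
            for n_don in range(16 - n_rec):
                assert classify_window(n_rec, n_don) == oracle_classify(n_rec, n_don), \
                    (n_rec, n_don)

    @given(st.integers(0, 100), st.integers(0, 100))
    def test_agrees_with_oracle_beyond_window_size(self, n_rec, n_don):
        assert classify_window(n_rec, n_don) == oracle_classify(n_rec, n_don)

    @given(st.integers(0, 30), st.integers(0, 30))
    def test_mirrored_thresholds_swap_rec_and_don(self, n_rec, n_don):
        """Relabeling REC<->DON with mirrored thresholds swaps the states."""
        def mirrored(nr, nd):  # thresholds 4:11 / 13:2, i.e. the mirror image
            if nr + nd < DEFAULT_MIN_INFORMATIVE:
                return UNKNOWN
            if nd * 4 > nr * 11:
                return DON
            if nd * 13 < nr * 2:
                return REC
            return HET
        swap = {REC: DON, DON: REC, HET: HET, UNKNOWN: UNKNOWN}
        assert mirrored(n_don, n_rec) == swap[classify_window(n_rec, n_don)]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            classify_window(-1, 5)


class TestScanWindows:
    def test_exactly_one_window_for_fifteen_markers(self):
        calls = np.full(15, REC, dtype=np.int8)
        pos = np.arange(15) * 10
        assert len(scan_windows(calls, pos)) == 1

    def test_twenty_markers_step_one_gives_six_windows(self):
        calls = np.full(20, REC, dtype=np.int8)
        wcs = scan_windows(calls, np.arange(20) * 10)
        assert len(wcs) == 6

    def test_homogeneous_input_yields_homogeneous_states(self):
        calls = np.full(40, DON, dtype=np.int8)
        wcs = scan_windows(calls, np.arange(40) * 5)
        assert all(w.state == DON for w in wcs)

    def test_truncated_window_emitted_when_short(self):
        calls = np.full(10, REC, dtype=np.int8)
        wcs = scan_windows(calls, np.arange(10) * 10)
        assert len(wcs) == 1 and wcs[0].last_marker == 9

    def test_too_few_markers_yield_no_windows(self):
        wcs = scan_windows(np.full(5, REC, dtype=np.int8), np.arange(5))
        assert wcs == []

    def test_invalid_window_size_rejected(self):
        with pytest.raises(ValueError):
            scan_windows(np.full(15, REC, dtype=np.int8), np.arange(15),
                         window_size=0)


class TestConsensus:
    def test_single_window_propagates_state(self):
        calls = np.full(15, REC, dtype=np.int8)
        wcs = scan_windows(calls, np.arange(15))
        states = consensus_marker_states(wcs, 15)
        assert np.all(states == REC)

    def _fake_windows(self, spec):
        return [cm.WindowCall("", "", i, a, b, 0, 0, 0, 0, 0, s)
                for i, (a, b, s) in enumerate(spec)]

    def test_plurality_wins(self):
        # marker 0 covered by 2 REC and 1 HET window
        wcs = self._fake_windows([(0, 0, REC), (0, 0, REC), (0, 0, HET)])
        assert consensus_marker_states(wcs, 1)[0] == REC

    def test_tie_goes_to_het(self):
        wcs = self._fake_windows([(0, 0, REC), (0, 0, DON)])
        assert consensus_marker_states(wcs, 1)[0] == HET

    def test_only_unknown_windows_give_unknown(self):
        wcs = self._fake_windows([(0, 0, UNKNOWN)])
        assert consensus_marker_states(wcs, 1)[0] == UNKNOWN


class TestCallSegments:
    def test_midpoint_rule_example(self):
        states = np.array([REC, REC, REC, DON, DON], dtype=np.int8)
        pos = np.array([10, 20, 30, 40, 50])
        segs = call_segments(states, pos, 100)
        assert [(s.start, s.end, s.state) for s in segs] == \
            [(0, 35, REC), (35, 100, DON)]
        assert segs[0].right_uncertainty == (30, 40)
        assert segs[1].left_uncertainty == (30, 40)

    def test_homogeneous_line_single_segment(self):
        segs = call_segments(np.full(30, REC, dtype=np.int8),
                             np.arange(30) * 100, 5000)
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (0, 5000)

    def test_unknowns_absorbed_between_agreeing_flanks(self):
        states = np.array([REC, UNKNOWN, REC], dtype=np.int8)
        segs = call_segments(states, np.array([0, 10, 20]), 100)
        assert len(segs) == 1 and segs[0].state == REC

    def test_unknowns_go_to_longer_flank(self):
        states = np.array([REC, REC, REC, UNKNOWN, DON], dtype=np.int8)
        segs = call_segments(states, np.array([0, 10, 20, 30, 40]), 100)
        assert segs[0].n_markers == 4 and segs[1].n_markers == 1

    def test_all_unknown_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="UNKNOWN"):
            segs = call_segments(np.full(5, UNKNOWN, dtype=np.int8),
                                 np.arange(5), 100)
        assert segs == []


class TestRefinement:
    def test_het_zone_with_hom_raw_calls_is_resplit(self):
        # hom-hom transition artifact: consensus says HET, raw calls say R|D
        raw = np.array([REC] * 10 + [DON] * 10, dtype=np.int8)
        consensus = np.array([REC] * 5 + [HET] * 10 + [DON] * 5, dtype=np.int8)
        refined = refine_marker_states(consensus, raw)
        assert refined.tolist() == raw.tolist()

    def test_true_het_zone_is_kept(self):
        raw = np.array([REC] * 8 + [HET] * 12 + [REC] * 8, dtype=np.int8)
        consensus = np.array([REC] * 8 + [UNKNOWN] * 12 + [REC] * 8, dtype=np.int8)
        refined = refine_marker_states(consensus, raw)
        assert refined.tolist() == raw.tolist()

    def test_short_embedded_donor_segment_recovered(self):
        raw = np.array([REC] * 20 + [DON] * 8 + [REC] * 20, dtype=np.int8)
        consensus = np.array([REC] * 14 + [HET] * 20 + [REC] * 14, dtype=np.int8)
        refined = refine_marker_states(consensus, raw)
        assert refined.tolist() == raw.tolist()

    def test_isolated_call_errors_do_not_open_segments(self):
        raw = np.array([REC] * 10 + [DON] + [REC] * 10, dtype=np.int8)
        consensus = np.full(21, HET, dtype=np.int8)
        refined = refine_marker_states(consensus, raw)
        assert np.all(refined == REC)


class TestEndToEnd:
    def test_noiseless_breakpoints_inside_uncertainty(self, small_map):
        cfg = cm.SimConfig(n_lines=25, n_backcross=2, n_self=3, seed=21)
        truth = cm.simulate_cssl_population(small_map, cfg)
        m = cm.genotype_markers(truth, small_map, 400, 0.0, 0.0,
                                np.random.default_rng(22))
        segs = cm.call_population_segments(m, small_map)
        for line in truth.lines:
            for c in small_map.chromosomes:
                sel = m.chrom_slice(c.name)
                pos = m.positions[sel]
                ends, states = line.diploid_partition(c.name)
                sl = [s for s in segs[line.name] if s.chrom == c.name]
                unc = [s.right_uncertainty for s in sl[:-1]]
                for k in range(len(ends) - 1):
                    bp = int(ends[k])
                    lstart = 0 if k == 0 else int(ends[k - 1])
                    rend = int(ends[k + 1])
                    if ((pos >= lstart) & (pos < bp)).sum() < 15:
                        continue
                    if ((pos >= bp) & (pos < rend)).sum() < 15:
                        continue
                    assert any(u and u[0] <= bp <= u[1] for u in unc), \
                        (line.name, c.name, bp)

    def test_noiseless_marker_state_accuracy(self, small_map):
        """Called states match truth at >= 99.9% of markers when every true
        segment is well covered (noiseless input)."""
        cfg = cm.SimConfig(n_lines=30, n_backcross=2, n_self=4, seed=31)
        truth = cm.simulate_cssl_population(small_map, cfg)
        m = cm.genotype_markers(truth, small_map, 300, 0.0, 0.0,
                                np.random.default_rng(32))
        segs = cm.call_population_segments(m, small_map)
        total = match = 0
        for i, line in enumerate(truth.lines):
            # restrict to lines whose true segments all hold >= 30 markers
            ok = True
            for c in small_map.chromosomes:
                sel = m.chrom_slice(c.name)
                pos = m.positions[sel]
                ends, _ = line.diploid_partition(c.name)
                bounds = np.concatenate([[0], ends])
                if np.any(np.diff(np.searchsorted(pos, bounds)) < 30):
                    ok = False
            if not ok:
                continue
            for c in small_map.chromosomes:
                sel = m.chrom_slice(c.name)
                pos = m.positions[sel]
                true_states = line.state_at(c.name, pos)
                called = np.full(len(pos), -1, dtype=np.int8)
                for s in segs[line.name]:
                    if s.chrom == c.name:
                        called[(pos >= s.start) & (pos < s.end)] = s.state
                total += len(pos)
                match += int(np.sum(called == true_states))
        assert total > 0
        assert match / total >= 0.999

    def test_segments_partition_chromosomes(self, small_map, small_markers):
        segs = cm.call_population_segments(small_markers, small_map)
        for line, sl in segs.items():
            for c in small_map.chromosomes:
                chrom_segs = [s for s in sl if s.chrom == c.name]
                assert chrom_segs[0].start == 0
                assert chrom_segs[-1].end == c.length_bp
                for a, b in zip(chrom_segs, chrom_segs[1:]):
                    assert a.end == b.start
                    assert a.state != b.state
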