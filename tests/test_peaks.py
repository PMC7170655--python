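"""Candidate detection, shuffle-null FDR, significance, replicate intersection."""

import numpy as np
import pytest

from oracles import naive_fdr, naive_intersect, naive_runs
from tadakit.peaks import (
    Peak,
    PeakSet,
    call_candidate_peaks,
    estimate_fdr,
    filter_significant,
    intersect_replicates,
)


class TestCallCandidatePeaks:
    def test_isolated_enriched_fragment_never_a_peak(self, make_track):
        track = make_track([0.0, 3.0, 0.0, 0.0])
        assert call_candidate_peaks(track, 0.0, 2) == []

    def test_two_consecutive_fragments_form_one_peak(self, make_track):
        track = make_track([-1.0, 0.5, 0.7, -1.0])
        peaks = call_candidate_peaks(track, 0.0, 2)
        assert len(peaks) == 1
        p = peaks[0]
        assert (p.start, p.end, p.n_fragments) == (100, 300, 2)
        assert p.mean_occupancy == pytest.approx(0.6)

    def test_missing_fragments_break_runs(self, make_track):
        track = make_track([1.0, 1.0, 9.0, 1.0, 1.0], missing=[0, 0, 1, 0, 0])
        peaks = call_candidate_peaks(track, 0.0, 2)
        assert [(p.start, p.end) for p in peaks] == [(0, 200), (300, 500)]

    def test_matches_exhaustive_run_scan(self, make_track):
        rng = np.random.default_rng(21)
        values = rng.normal(0, 1, 2000)
        missing = rng.random(2000) < 0.05
        track = make_track(values, missing=missing)
        peaks = call_candidate_peaks(track, 0.3, 3)
        expected = naive_runs(values, missing, 0.3, 3)
        assert len(peaks) == len(expected)
        for p, (s, e, n, m) in zip(peaks, expected):
            assert (p.start, p.end, p.n_fragments) == (s * 100, e * 100, n)
            assert p.mean_occupancy == pytest.approx(m)


class TestEstimateFdr:
    def test_empty_candidates_give_empty_output(self, make_track):
        track = make_track(np.zeros(10))
        assert estimate_fdr([], track, 10, 1) == []

    def test_invalid_shuffle_count_rejected(self, make_track):
        track = make_track([1.0, 1.0, 0.0])
        cand = call_candidate_peaks(track)
        with pytest.raises(ValueError, match="n_shuffles"):
            estimate_fdr(cand, track, 0, 1)

    def test_planted_run_reaches_tiny_fdr_and_matches_oracle(self, make_track):
        rng = np.random.default_rng(42)
        values = rng.normal(0.0, 0.3, 5000)
        values[1000:1005] = 3.0
        track = make_track(values)
        cand = call_candidate_peaks(track)
        scored = estimate_fdr(cand, track, n_shuffles=30, seed=99)
        expected = naive_fdr(values, np.zeros(5000, bool), cand, 30, 99)
        assert np.allclose([p.fdr for p in scored], expected)
        planted = [p for p in scored if p.start <= 1000 * 100 < p.end]
        assert planted and planted[0].fdr < 1e-4

    def test_deterministic_given_seed(self, make_track):
        rng = np.random.default_rng(1)
        track = make_track(rng.normal(0, 1, 500))
        cand = call_candidate_peaks(track)
        a = estimate_fdr(cand, track, 20, 7)
        b = estimate_fdr(cand, track, 20, 7)
        assert [p.fdr for p in a] == [p.fdr for p in b]

    def test_fdr_monotone_in_length_and_occupancy(self, make_track):
        rng = np.random.default_rng(8)
        track = make_track(rng.normal(0, 1, 3000))
        scored = estimate_fdr(call_candidate_peaks(track), track, 50, 3)
        for a in scored:
            for b in scored:
                if a.n_fragments == b.n_fragments and a.mean_occupancy <= b.mean_occupancy:
                    assert a.fdr >= b.fdr
                if a.mean_occupancy == b.mean_occupancy and a.n_fragments <= b.n_fragments:
                    assert a.fdr >= b.fdr


class TestFilterSignificant:
    def _peak(self, start, fdr, chrom="c", n=2, m=1.0, end=None):
        return Peak(chrom, start, end if end is not None else start + 100, n, m, fdr)

    def test_strictly_below_threshold_only(self):
        peaks = [self._peak(0, 0.00005), self._peak(200, 0.0001), self._peak(400, 0.5)]
        kept = filter_significant(peaks, 0.0001)
        assert [(p.start, p.fdr) for p in kept] == [(0, 0.00005)]

    def test_empty_input(self):
        assert len(filter_significant([], 0.0001)) == 0

    def test_all_zero_fdr_retained(self):
        peaks = [self._peak(0, 0.0), self._peak(500, 0.0)]
        assert len(filter_significant(peaks, 1e-4)) == 2

    def test_unset_fdr_rejected(self):
        with pytest.raises(ValueError, match="no fdr"):
            filter_significant([Peak("c", 0, 100, 2, 1.0, None)])

    def test_book_ended_peaks_merged(self):
        peaks = [
            Peak("c", 0, 200, 2, 1.0, 0.0),
            Peak("c", 200, 500, 3, 2.0, 1e-6),
            Peak("c", 700, 800, 2, 1.0, 0.0),
        ]
        kept = filter_significant(peaks, 1e-4)
        assert [(p.start, p.end) for p in kept] == [(0, 500), (700, 800)]
        merged = kept.peaks[0]
        assert merged.n_fragments == 5
        assert merged.mean_occupancy == pytest.approx((1.0 * 2 + 2.0 * 3) / 5)
        assert merged.fdr == 0.0


class TestIntersectReplicates:
    def _ps(self, intervals, chrom="c"):
        return PeakSet([Peak(chrom, s, e, 2, 1.0, 0.0) for s, e in intervals])

    def test_identical_sets_preserved(self):
        ps = self._ps([(100, 500), (900, 1200)])
        final = intersect_replicates(ps, self._ps([(100, 500), (900, 1200)]))
        assert [(p.start, p.end) for p in final] == [(100, 500), (900, 1200)]

    def test_partial_overlap_union_span(self):
        final = intersect_replicates(self._ps([(100, 500)]), self._ps([(400, 900)]))
        assert [(p.start, p.end) for p in final] == [(100, 900)]

    def test_book_ended_intervals_do_not_intersect(self):
        final = intersect_replicates(self._ps([(100, 500)]), self._ps([(500, 900)]))
        assert len(final) == 0

    def test_disjoint_sets_empty(self):
        assert len(intersect_replicates(self._ps([(0, 100)]), self._ps([(500, 600)]))) == 0

    def test_final_peaks_carry_no_fdr(self):
        final = intersect_replicates(self._ps([(0, 100)]), self._ps([(50, 150)]))
        assert final.peaks[0].fdr is None

    def test_matches_graph_oracle_on_random_sets(self):
        rng = np.random.default_rng(17)

        def random_set():
            peaks = []
            for _ in range(200):
                chrom = f"chr{rng.integers(1, 4)}"
                s = int(rng.integers(0, 100_000))
                peaks.append(Peak(chrom, s, s + int(rng.integers(50, 2000)), 2, 1.0, 0.0))
            return PeakSet(peaks)

        r1, r2 = random_set(), random_set()
        final = intersect_replicates(r1, r2)
        assert [(p.chrom, p.start, p.end) for p in final] == naive_intersect(r1, r2)

    def test_containment_bound(self):
        rng = np.random.default_rng(23)
        mk = lambda: self._ps(
            sorted((int(s), int(s) + int(rng.integers(50, 500)))
                   for s in rng.integers(0, 50_000, 50))
        )
        r1, r2 = mk(), mk()
        final = intersect_replicates(r1, r2)
        assert len(final) <= min(len(r1), len(r2))
        for p in final:
            assert any(p.overlaps(q) for q in r1)
            assert any(p.overlaps(q) for q in r2)
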