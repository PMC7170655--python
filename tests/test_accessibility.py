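"""Accessible-region calling, metaprofiles, state enrichment, correlation."""

import numpy as np
import pytest

from oracles import naive_bin_value, naive_runs, naive_state_means
from tadakit.accessibility import (
    binding_accessibility_correlation,
    call_accessible_regions,
    metaprofile,
    state_enrichment,
)
from tadakit.genome import Region, RegionSet
from tadakit.tracks import FragmentTrack


class TestCallAccessibleRegions:
    def test_single_run_detected(self, make_track):
        values = np.zeros(20)
        values[5:8] = 50.0
        track = make_track(values, units="RPM")
        regions = call_accessible_regions(track, 0.95, 2)
        assert [(r.start, r.end) for r in regions] == [(500, 800)]

    def test_single_elevated_fragment_not_a_region(self, make_track):
        values = np.zeros(20)
        values[5] = 50.0
        track = make_track(values, units="RPM")
        assert len(call_accessible_regions(track, 0.9, 2)) == 0

    def test_degenerate_track_rejected(self, make_track):
        with pytest.raises(ValueError, match="quantile"):
            call_accessible_regions(make_track(np.ones(10), units="RPM"), 0.95, 2)

    def test_matches_run_scan_at_computed_threshold(self, make_track):
        rng = np.random.default_rng(6)
        values = rng.gamma(2.0, 10.0, 1000)
        track = make_track(values, units="RPM")
        regions = call_accessible_regions(track, 0.9, 2)
        thr = np.quantile(values, 0.9)
        expected = naive_runs(values, np.zeros(1000, bool), thr, 2)
        assert [(r.start // 100, r.end // 100) for r in regions] == [
            (s, e) for (s, e, _n, _m) in expected
        ]


class TestMetaprofile:
    def test_constant_track_flat_profile(self, make_track):
        track = make_track(np.full(100, 2.5))
        regions = RegionSet("r", [Region("chr1", 4000, 4200), Region("chr1", 6000, 6400)])
        mp = metaprofile(track, regions, flank=1000, bin_width=200)
        assert mp.matrix.shape == (2, 10)
        assert np.allclose(mp.matrix, 2.5)
        assert np.allclose(mp.mean_profile, 2.5)

    def test_symmetric_track_gives_palindromic_row(self, make_track):
        n = 101
        values = -np.abs(np.arange(n) - 50).astype(float)  # symmetric about fragment 50
        track = make_track(values)
        centre = 50 * 100 + 50  # midpoint of fragment 50
        regions = RegionSet("r", [Region("chr1", centre - 50, centre + 50)])
        mp = metaprofile(track, regions, flank=2000, bin_width=100)
        row = mp.matrix[0]
        assert np.allclose(row, row[::-1])

    def test_partial_overlap_bin_is_length_weighted(self, make_track):
        track = make_track([1.0, 3.0, 5.0], frag_len=100)
        # region centred at 150; one 100 bp bin [100, 200) covers 50 bp of two fragments
        regions = RegionSet("r", [Region("chr1", 100, 200)])
        mp = metaprofile(track, regions, flank=100, bin_width=100)
        assert mp.matrix[0, 0] == pytest.approx(naive_bin_value([1, 3, 5], [0, 0, 0], [0, 100, 200, 300], 50, 150))
        assert mp.matrix[0, 1] == pytest.approx(naive_bin_value([1, 3, 5], [0, 0, 0], [0, 100, 200, 300], 150, 250))

    def test_weight_conservation(self, make_track):
        rng = np.random.default_rng(13)
        values = rng.normal(0, 1, 400)
        missing = rng.random(400) < 0.1
        track = make_track(values, missing=missing)
        regions = RegionSet("r", [Region("chr1", 20_000, 20_400)])
        mp = metaprofile(track, regions, flank=2000, bin_width=200)
        centre = (20_000 + 20_400) // 2
        lo, hi = centre - 2000, centre + 2000
        covered = 0
        for i in range(400):
            if missing[i]:
                continue
            covered += max(0, min(hi, (i + 1) * 100) - max(lo, i * 100))
        assert mp.weights.sum() == pytest.approx(covered)

    def test_translation_equivariance(self, make_fmap):
        rng = np.random.default_rng(14)
        values = rng.normal(0, 1, 300)
        shift_frags = 50
        t1 = FragmentTrack(make_fmap(300), values, np.zeros(300, bool))
        rolled = np.roll(values, shift_frags)
        t2 = FragmentTrack(make_fmap(300), rolled, np.zeros(300, bool))
        r1 = RegionSet("r", [Region("chr1", 10_000, 10_200)])
        r2 = RegionSet("r", [Region("chr1", 10_000 + shift_frags * 100, 10_200 + shift_frags * 100)])
        m1 = metaprofile(t1, r1, flank=1000, bin_width=100)
        m2 = metaprofile(t2, r2, flank=1000, bin_width=100)
        assert np.allclose(m1.matrix, m2.matrix, equal_nan=True)

    def test_empty_regions_rejected(self, make_track):
        with pytest.raises(ValueError, match="empty"):
            metaprofile(make_track(np.zeros(10)), RegionSet("r", []), 1000, 100)

    def test_flank_must_be_multiple_of_bin_width(self, make_track):
        with pytest.raises(ValueError, match="multiple"):
            metaprofile(
                make_track(np.zeros(10)),
                RegionSet("r", [Region("chr1", 0, 100)]),
                flank=350,
                bin_width=100,
            )


class TestBindingAccessibilityCorrelation:
    def test_identity_and_reversal(self, make_fmap):
        fmap = make_fmap(10)
        a = FragmentTrack(fmap, np.arange(10.0), np.zeros(10, bool))
        b = FragmentTrack(fmap, -np.arange(10.0), np.zeros(10, bool))
        assert binding_accessibility_correlation(a, a) == pytest.approx(1.0)
        assert binding_accessibility_correlation(a, b) == pytest.approx(-1.0)

    def test_low_accessibility_planting_gives_negative_sign(self):
        from tadakit.simulate import SimConfig, simulate_damid, simulate_genome, simulate_truth
        from tadakit.tracks import occupancy_ratio, rpm_normalize

        cfg = SimConfig(
            chrom_length=1_000_000, n_bound_regions=40, low_accessibility_fraction=1.0
        )
        _seqs, fmap = simulate_genome(cfg, seed=3)
        truth = simulate_truth(cfg, fmap, seed=3)
        fusion, control = simulate_damid(truth, fmap)[0]
        rho = binding_accessibility_correlation(
            occupancy_ratio(fusion, control), rpm_normalize(control)
        )
        assert rho < 0


class TestStateEnrichment:
    def test_constant_track_zero_enrichment(self, make_track):
        track = make_track(np.full(30, 1.5))
        states = RegionSet("s", [Region("chr1", 0, 1000, "black"), Region("chr1", 1000, 3000, "TrxG")])
        enr = state_enrichment(track, states)
        assert enr.enrichment["black"] == pytest.approx(0.0)
        assert enr.enrichment["TrxG"] == pytest.approx(0.0)

    def test_single_elevated_state(self, make_track):
        values = np.zeros(30)
        values[0:10] = 1.0
        track = make_track(values)
        states = RegionSet("s", [Region("chr1", 0, 1000, "hot"), Region("chr1", 1000, 3000, "cold")])
        enr = state_enrichment(track, states)
        assert enr.state_means["hot"] == pytest.approx(1.0)
        assert enr.state_means["cold"] == pytest.approx(0.0)

    def test_matches_overlap_weighted_oracle(self, make_track):
        rng = np.random.default_rng(19)
        values = rng.normal(0, 1, 200)
        missing = rng.random(200) < 0.1
        track = make_track(values, missing=missing)
        edges = np.sort(rng.choice(np.arange(1, 20_000), 10, replace=False))
        bounds = [0, *edges.tolist(), 20_000]
        labels = [["black", "HP1", "TrxG"][i % 3] for i in range(len(bounds) - 1)]
        regions = [Region("chr1", s, e, lab) for s, e, lab in zip(bounds[:-1], bounds[1:], labels)]
        enr = state_enrichment(track, RegionSet("s", regions))
        oracle = naive_state_means(
            values, missing, list(range(0, 20_100, 100)), [(r.start, r.end, r.name) for r in regions]
        )
        for lab, mean in oracle.items():
            assert enr.state_means[lab] == pytest.approx(mean)

    def test_partition_property(self, make_track):
        rng = np.random.default_rng(20)
        values = rng.normal(0, 1, 100)
        track = make_track(values)
        states = RegionSet("s", [Region("chr1", 0, 10_000, "all")])
        enr = state_enrichment(track, states)
        frag_len = np.full(100, 100.0)
        assert enr.state_means["all"] == pytest.approx(np.average(values, weights=frag_len))
        assert enr.enrichment["all"] == pytest.approx(0.0)

    def test_overlapping_states_rejected(self, make_track):
        track = make_track(np.zeros(10))
        states = RegionSet("s", [Region("chr1", 0, 500, "a"), Region("chr1", 400, 900, "b")])
        with pytest.raises(ValueError, match="overlapping"):
            state_enrichment(track, states)
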