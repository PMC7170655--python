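"""Synthetic-data generator: determinism, distributions, ground truth."""

import numpy as np
import pytest

from tadakit.genome import build_fragment_map
from tadakit.simulate import (
    SimConfig,
    simulate_annotation,
    simulate_damid,
    simulate_dataset,
    simulate_de_table,
    simulate_genome,
    simulate_states,
    simulate_truth,
)
from tadakit.tracks import occupancy_ratio


class TestSimulateGenome:
    def test_same_seed_identical_output(self):
        cfg = SimConfig(chrom_length=50_000)
        s1, m1 = simulate_genome(cfg, 9)
        s2, m2 = simulate_genome(cfg, 9)
        assert s1 == s2 and m1 == m2

    def test_fragment_map_equals_rebuild_from_sequence(self):
        cfg = SimConfig(chrom_length=100_000)
        seqs, fmap = simulate_genome(cfg, 2)
        assert fmap == build_fragment_map(seqs)

    def test_fragment_count_matches_renewal_expectation(self):
        cfg = SimConfig(chrom_length=1_000_000, mean_gatc_spacing=200)
        _seqs, fmap = simulate_genome(cfg, 7)
        # renewal with mean gap 200, gap sd 196: count sd ~ sqrt(L*var/mean^3)
        expected = 1_000_000 / 200
        sd = np.sqrt(1_000_000 * 196**2 / 200**3)
        assert abs(fmap.n_fragments - expected) < 3 * sd

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(chrom_length=0)

    def test_too_dense_spacing_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(mean_gatc_spacing=10)


class TestSimulateAnnotation:
    def test_zero_genes(self):
        cfg = SimConfig(chrom_length=50_000, n_genes=0)
        _s, fmap = simulate_genome(cfg, 1)
        assert simulate_annotation(cfg, fmap, 1) == []

    def test_deterministic(self):
        cfg = SimConfig(chrom_length=200_000, n_genes=20)
        _s, fmap = simulate_genome(cfg, 1)
        assert simulate_annotation(cfg, fmap, 5) == simulate_annotation(cfg, fmap, 5)

    def test_invariants_hold_for_all_genes(self):
        cfg = SimConfig(chrom_length=2_000_000, n_genes=200)
        _s, fmap = simulate_genome(cfg, 3)
        genes = simulate_annotation(cfg, fmap, 3)
        assert len(genes) == 200
        genome = fmap.genome()
        by_chrom = {}
        for g in genes:
            assert 0 <= g.start < g.end <= genome[g.chrom]
            assert g.strand in "+-"
            assert g.exons
            prev_end = g.start
            for (s, e) in g.exons:
                assert g.start <= s < e <= g.end
                assert s >= prev_end
                prev_end = e
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2  # non-overlapping

    def test_infeasible_density_errors(self):
        cfg = SimConfig(chrom_length=60_000, n_genes=500)
        _s, fmap = simulate_genome(cfg, 1)
        with pytest.raises(ValueError, match="infeasible"):
            simulate_annotation(cfg, fmap, 1)


class TestSimulateDamid:
    def test_null_effect_mean_ratio_near_zero(self):
        cfg = SimConfig(chrom_length=4_500_000, n_bound_regions=0, n_genes=0)
        _s, fmap = simulate_genome(cfg, 5)
        assert fmap.n_fragments >= 20_000
        truth = simulate_truth(cfg, fmap, 5)
        fusion, control = simulate_damid(truth, fmap)[0]
        ratio = occupancy_ratio(fusion, control)
        assert abs(ratio.values[~ratio.missing].mean()) < 0.05

    def test_zero_coverage_all_zero(self):
        cfg = SimConfig(chrom_length=50_000, coverage=0.0, n_genes=0)
        _s, fmap = simulate_genome(cfg, 1)
        truth = simulate_truth(cfg, fmap, 1)
        fusion, control = simulate_damid(truth, fmap)[0]
        assert fusion.counts.sum() == 0 and control.counts.sum() == 0

    def test_planted_effect_recovered_across_seeds(self):
        cfg = SimConfig(chrom_length=500_000, n_genes=0)
        means = []
        for seed in range(1, 21):
            _s, fmap = simulate_genome(cfg, seed)
            truth = simulate_truth(cfg, fmap, seed)
            fusion, control = simulate_damid(truth, fmap)[0]
            ratio = occupancy_ratio(fusion, control)
            means.append(ratio.values[truth.effects > 0].mean())
        assert np.mean(means) == pytest.approx(2.0, abs=0.3)

    def test_replicates_differ_but_share_truth(self):
        cfg = SimConfig(chrom_length=100_000, n_genes=0)
        _s, fmap = simulate_genome(cfg, 4)
        truth = simulate_truth(cfg, fmap, 4)
        (f1, c1), (f2, c2) = simulate_damid(truth, fmap)
        assert not np.array_equal(f1.counts, f2.counts)
        assert not np.array_equal(c1.counts, c2.counts)


class TestSimulateDeTable:
    UNIVERSE = {f"g{i}" for i in range(400)}
    BOUND = {f"g{i}" for i in range(150)}

    def test_target_one_all_bound(self):
        table = simulate_de_table(self.BOUND, self.UNIVERSE, 1.0, 20, 20, seed=1)
        from tadakit.expression import classify_de

        up, down = classify_de(table)
        assert (up | down) <= self.BOUND
        assert len(up) == 20 and len(down) == 20

    def test_target_zero_disjoint_from_bound(self):
        table = simulate_de_table(self.BOUND, self.UNIVERSE, 0.0, 20, 20, seed=1)
        from tadakit.expression import classify_de

        up, down = classify_de(table)
        assert (up | down).isdisjoint(self.BOUND)

    def test_infeasible_target_errors(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_de_table({"g1"}, {"g1", "g2"}, 1.0, 5, 5, seed=1)

    def test_deterministic(self):
        t1 = simulate_de_table(self.BOUND, self.UNIVERSE, 0.5, 30, 30, seed=3)
        t2 = simulate_de_table(self.BOUND, self.UNIVERSE, 0.5, 30, 30, seed=3)
        assert t1.frame.equals(t2.frame)


class TestSimulateStates:
    def test_states_partition_each_chromosome(self):
        cfg = SimConfig(chrom_length=300_000, n_genes=0)
        _s, fmap = simulate_genome(cfg, 1)
        states = simulate_states(fmap, 1)
        pos = 0
        for r in sorted(states, key=lambda r: r.start):
            assert r.start == pos
            assert r.name is not None
            pos = r.end
        assert pos == int(fmap.boundaries("chr1")[-1])


class TestSimulateDataset:
    def test_fully_deterministic(self):
        cfg = SimConfig(chrom_length=300_000, n_genes=30, n_bound_regions=5)
        d1 = simulate_dataset(cfg, seed=6)
        d2 = simulate_dataset(cfg, seed=6)
        assert d1.sequences == d2.sequences
        assert d1.genes == d2.genes
        assert [r for r in d1.truth.regions] == [r for r in d2.truth.regions]
        for (fa, ca), (fb, cb) in zip(d1.replicates, d2.replicates):
            assert np.array_equal(fa.counts, fb.counts)
            assert np.array_equal(ca.counts, cb.counts)
        assert d1.de_table.frame.equals(d2.de_table.frame)
        assert d1.fpkm.frame.equals(d2.fpkm.frame)
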