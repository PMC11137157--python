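import numpy as np
import pytest

import csslmap as cm
from csslmap.simulate import Haplotype, _merge_runs
from csslmap.states import DON, MISSING, REC


def _gamete_batch(gmap, parent, n, seed):
    rng = np.random.default_rng(seed)
    return [cm.simulate_gamete(gmap, parent, rng) for _ in range(n)]


class TestGamete:
    def test_identical_parents_give_identical_gamete(self):
        gmap = cm.make_genetic_map([("c1", 1_000_000, 150.0)])
        rec = Haplotype.uniform(gmap, REC)
        g = cm.simulate_gamete(gmap, (rec, rec), np.random.default_rng(0))
        assert g.segments("c1") == [(0, 1_000_000, REC)]

    def test_crossover_count_matches_poisson_mean(self):
        gmap = cm.make_genetic_map([("c1", 10_000_000, 150.0)])
        f1 = (Haplotype.uniform(gmap, DON), Haplotype.uniform(gmap, REC))
        n = 2000
        counts = [len(g.data["c1"][0]) - 1 for g in _gamete_batch(gmap, f1, n, 1)]
        # run count - 1 undercounts crossovers that land between same-origin
        # runs, but from an all-DON x all-REC F1 every crossover switches
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(n)
        assert abs(mean - 1.5) < 3 * se + 1e-9

    def test_recombinant_fraction_matches_haldane(self):
        gmap = cm.make_genetic_map([("c1", 10_000_000, 100.0)])
        f1 = (Haplotype.uniform(gmap, DON), Haplotype.uniform(gmap, REC))
        p1, p2 = 4_000_000, 5_000_000  # 10 cM apart on the linear map
        n = 4000
        rec_frac_expected = 0.5 * (1 - np.exp(-0.2))
        flips = [int(g.origin_at("c1", p1) != g.origin_at("c1", p2))
                 for g in _gamete_batch(gmap, f1, n, 2)]
        obs = np.mean(flips)
        se = np.sqrt(rec_frac_expected * (1 - rec_frac_expected) / n)
        assert abs(obs - rec_frac_expected) < 3 * se

    def test_gamete_partitions_chromosome(self, small_map, small_population):
        for line in small_population.lines[:10]:
            line.hap1.validate(small_map)
            line.hap2.validate(small_map)


class TestPopulation:
    @pytest.mark.parametrize("n_bc", [1, 4])
    def test_donor_fraction_follows_backcross_law(self, n_bc):
        gmap = cm.make_genetic_map([("c1", 5_000_000, 100.0),
                                    ("c2", 5_000_000, 100.0)])
        cfg = cm.SimConfig(n_lines=400, n_backcross=n_bc, n_self=0, seed=n_bc)
        truth = cm.simulate_cssl_population(gmap, cfg)
        fr = np.array([truth.donor_fraction(l) for l in truth.lines])
        expected = 2.0 ** -(n_bc + 1)
        assert abs(fr.mean() - expected) < 3 * fr.std(ddof=1) / np.sqrt(len(fr))

    def test_selfing_drives_out_heterozygosity(self):
        gmap = cm.make_genetic_map([("c1", 5_000_000, 100.0)])
        cfg = cm.SimConfig(n_lines=150, n_backcross=1, n_self=8, seed=5)
        truth = cm.simulate_cssl_population(gmap, cfg)
        het = np.mean([truth.het_fraction(l) for l in truth.lines])
        don = np.mean([truth.donor_fraction(l) for l in truth.lines])
        assert het < 0.01 * max(don, 1e-9) or het < 1e-4

    def test_selection_caps_segment_count(self, small_map):
        cfg = cm.SimConfig(n_lines=15, n_backcross=2, n_self=2,
                           max_donor_segments=2, seed=6)
        truth = cm.simulate_cssl_population(small_map, cfg)
        assert all(truth.donor_segment_count(l) <= 2 for l in truth.lines)

    def test_unsatisfiable_selection_fails_naming_bound(self, small_map):
        cfg = cm.SimConfig(n_lines=2, n_backcross=1, n_self=8,
                           max_donor_segments=0, max_selection_attempts=5, seed=7)
        # a BC1S8 line is ~25% donor, almost all homozygous, so a line with
        # zero homozygous-donor segments is effectively unreachable
        with pytest.raises(RuntimeError, match="5 attempts"):
            cm.simulate_cssl_population(small_map, cfg)

    def test_same_seed_reproduces_population(self, small_map):
        cfg = cm.SimConfig(n_lines=10, n_backcross=2, n_self=1, seed=99)
        t1 = cm.simulate_cssl_population(small_map, cfg)
        t2 = cm.simulate_cssl_population(small_map, cfg)
        assert t1.to_dict() == t2.to_dict()

    def test_truth_serialization_round_trip(self, small_map, small_population, tmp_path):
        path = tmp_path / "truth.json"
        small_population.to_json(path)
        import json
        loaded = cm.SimTruth.from_dict(json.load(open(path)), small_map)
        assert loaded.to_dict() == small_population.to_dict()


class TestMarkers:
    def test_noiseless_calls_equal_truth(self, small_map, small_population):
        m = cm.genotype_markers(small_population, small_map, 50, 0.0, 0.0,
                                np.random.default_rng(1))
        for i, line in enumerate(small_population.lines):
            for c in small_map.chromosomes:
                sel = m.chrom_slice(c.name)
                np.testing.assert_array_equal(
                    m.calls[i, sel], line.state_at(c.name, m.positions[sel]))

    def test_all_missing_at_rate_one(self, small_map, small_population):
        m = cm.genotype_markers(small_population, small_map, 20, 0.0, 1.0,
                                np.random.default_rng(2))
        assert np.all(m.calls == MISSING)

    def test_error_rate_matches_binomial(self, small_map, small_population):
        m_clean = cm.genotype_markers(small_population, small_map, 850, 0.0, 0.0,
                                      np.random.default_rng(3))
        m_noisy = cm.genotype_markers(small_population, small_map, 850, 0.01, 0.0,
                                      np.random.default_rng(3))
        assert m_clean.positions.tolist() == m_noisy.positions.tolist()
        n = m_clean.calls.size
        assert n >= 1e5
        frac = np.mean(m_clean.calls != m_noisy.calls)
        se = np.sqrt(0.01 * 0.99 / n)
        assert abs(frac - 0.01) < 3 * se

    def test_zero_markers_rejected(self, small_map, small_population):
        with pytest.raises(ValueError, match="zero markers"):
            cm.genotype_markers(small_population, small_map, 0)


class TestPhenotypes:
    def test_null_model_variance(self, small_map):
        cfg = cm.SimConfig(n_lines=400, n_backcross=2, n_self=2, seed=11)
        truth = cm.simulate_cssl_population(small_map, cfg)
        spec = cm.QtlSpec(loci=[], residual_sd=2.0)
        y = cm.simulate_phenotypes(truth, spec, np.random.default_rng(4)).trait("trait")
        # sample variance of N(0, 4): SE ~ sd^2 * sqrt(2/(n-1))
        assert abs(np.var(y, ddof=1) - 4.0) < 3 * 4.0 * np.sqrt(2 / (len(y) - 1))

    def test_requested_pve_is_realized(self, small_map):
        cfg = cm.SimConfig(n_lines=600, n_backcross=1, n_self=2, seed=12)
        truth = cm.simulate_cssl_population(small_map, cfg)
        spec = cm.QtlSpec(loci=[("chr01", 2_500_000, 1.0)], pve=[0.15],
                          residual_sd=None)
        y = cm.simulate_phenotypes(truth, spec, np.random.default_rng(5)).trait("trait")
        dos = np.array([l.dosage_at("chr01", 2_500_000) for l in truth.lines])
        r2 = np.corrcoef(dos, y)[0, 1] ** 2
        se = (1 - 0.15) * np.sqrt(2 / len(y))  # delta-method scale for R^2
        assert abs(r2 - 0.15) < max(3 * se, 0.05)

    def test_zero_noise_gives_discrete_dosage_levels(self, small_map):
        cfg = cm.SimConfig(n_lines=60, n_backcross=1, n_self=1, seed=13)
        truth = cm.simulate_cssl_population(small_map, cfg)
        spec = cm.QtlSpec(loci=[("chr01", 2_500_000, 3.0)], residual_sd=0.0)
        y = cm.simulate_phenotypes(truth, spec, np.random.default_rng(6)).trait("trait")
        assert len(np.unique(np.round(y, 9))) <= 3
        levels = np.unique(np.round(y, 9))
        assert np.all(np.isin(levels, [0.0, 1.5, 3.0]))

    def test_pve_sum_must_stay_below_one(self):
        with pytest.raises(ValueError, match="PVE"):
            cm.QtlSpec(loci=[("c", 1, 1.0), ("c", 2, 1.0)],
                       pve=[0.6, 0.5]).validate()


def test_merge_runs_collapses_adjacent_equal_origins():
    ends = np.array([10, 20, 30], dtype=np.int64)
    orgs = np.array([REC, REC, DON], dtype=np.int8)
    e2, o2 = _merge_runs(ends, orgs)
    assert e2.tolist() == [20, 30] and o2.tolist() == [REC, DON]
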