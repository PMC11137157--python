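import numpy as np
import pytest

import csslmap as cm
from csslmap.bins import BinGenotypeMatrix, Tile
from csslmap.qtl import fit_additive, lod_from_rss, select_cofactors
from csslmap.states import DON, REC


def _binmat_from_states(states, chrom_len=100_000, line_prefix="L"):
    states = np.asarray(states, dtype=np.int8)
    n_lines, n_bins = states.shape
    bins = [Tile("chr01", i * chrom_len, (i + 1) * chrom_len) for i in range(n_bins)]
    return BinGenotypeMatrix([f"{line_prefix}{i}" for i in range(n_lines)],
                             bins, [1] * n_bins,
                             [(i, i + 1) for i in range(n_bins)], states, bins)


@pytest.fixture(scope="module")
def sim_scan_setup():
    """A BC2S3 population with a bin matrix built from ground truth."""
    gmap = cm.make_genetic_map([("chr01", 5_000_000, 100.0),
                                ("chr02", 5_000_000, 100.0)])
    cfg = cm.SimConfig(n_lines=200, n_backcross=2, n_self=3, seed=301)
    truth = cm.simulate_cssl_population(gmap, cfg)
    binmat = cm.merge_into_bins(
        cm.genotype_tiles(truth.to_segments(), cm.tile_genome(gmap)))
    return gmap, truth, binmat


class TestFitAdditive:
    def test_constant_phenotype(self):
        y = np.full(30, 3.0)
        x = np.tile([0.0, 0.5, 1.0], 10)
        rss, a, _ = fit_additive(y, x)
        assert rss == pytest.approx(0.0, abs=1e-18)
        assert a == pytest.approx(0.0, abs=1e-9)

    def test_exact_linear_fit_recovers_slope(self):
        x = np.tile([0.0, 0.5, 1.0], 12)
        y = 1.0 + 2.5 * x
        rss, a, se = fit_additive(y, x)
        assert rss == pytest.approx(0.0, abs=1e-18)
        assert a == pytest.approx(2.5)

    def test_permuted_labels_give_null_effect(self):
        rng = np.random.default_rng(0)
        x = rng.choice([0.0, 0.5, 1.0], size=100)
        y = rng.normal(size=100)
        effects = []
        for _ in range(1000):
            effects.append(fit_additive(y, rng.permutation(x))[1])
        effects = np.asarray(effects)
        assert abs(effects.mean()) < 3 * effects.std(ddof=1) / np.sqrt(len(effects))

    def test_rank_deficient_cofactors_warn_not_fail(self):
        rng = np.random.default_rng(1)
        x = rng.choice([0.0, 1.0], size=60)
        Z = np.column_stack([x, x])  # duplicated cofactor
        y = rng.normal(size=60)
        with pytest.warns(UserWarning, match="rank-deficient"):
            rss, a, _ = fit_additive(y, x, Z)
        assert np.isfinite(rss) and np.isfinite(a)


class TestLod:
    def test_equal_rss_gives_zero(self):
        assert lod_from_rss(5.0, 5.0, 100) == 0.0

    def test_arithmetic_identity(self):
        assert lod_from_rss(10 ** 0.1, 1.0, 100) == pytest.approx(5.0)

    def test_equals_gaussian_lrt_over_2ln10(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            rss0 = rng.uniform(1, 10)
            rss1 = rss0 * rng.uniform(0.3, 1.0)
            n = int(rng.integers(20, 400))
            lrt = n * np.log(rss0 / rss1)
            assert lod_from_rss(rss0, rss1, n) == pytest.approx(lrt / (2 * np.log(10)))

    def test_zero_rss1_capped(self):
        assert lod_from_rss(1.0, 0.0, 50) == pytest.approx(300.0)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            lod_from_rss(1.0, 1.0, 0)


class TestSelectCofactors:
    def test_null_phenotype_selects_nothing_almost_always(self, sim_scan_setup):
        _, _, binmat = sim_scan_setup
        rng = np.random.default_rng(3)
        D = binmat.dosage()
        n_empty = 0
        reps = 100
        for _ in range(reps):
            y = rng.normal(size=len(binmat.line_names))
            sel = select_cofactors(y, D, p_enter=1e-3)
            n_empty += len(sel) <= 1
        assert n_empty / reps >= 0.99

    def test_strong_qtl_bin_selected_first(self, sim_scan_setup):
        gmap, truth, binmat = sim_scan_setup
        spec = cm.QtlSpec(loci=[("chr01", 2_500_000, 1.0)], pve=[0.4],
                          residual_sd=None)
        y = cm.simulate_phenotypes(truth, spec, np.random.default_rng(4)).trait("trait")
        sel = select_cofactors(y, binmat.dosage(), p_enter=1e-3)
        b = binmat.bins[sel[0]]
        # first selected bin on the causal chromosome, near the QTL
        assert b.chrom == "chr01"
        assert abs((b.start + b.end) / 2 - 2_500_000) < 1_500_000

    def test_zero_max_cofactors_gives_empty_set(self, sim_scan_setup):
        _, _, binmat = sim_scan_setup
        y = np.random.default_rng(5).normal(size=len(binmat.line_names))
        assert select_cofactors(y, binmat.dosage(), max_cofactors=0) == []


class TestScan:
    def test_planted_qtl_detected_near_truth(self, sim_scan_setup):
        gmap, truth, binmat = sim_scan_setup
        spec = cm.QtlSpec(loci=[("chr01", 2_500_000, 1.0)], pve=[0.15],
                          residual_sd=None)
        y = cm.simulate_phenotypes(truth, spec, np.random.default_rng(6)).trait("trait")
        res = cm.BinQtlScan(y, binmat, gmap).fit()
        assert len(res.peaks) >= 1
        best = res.peaks.iloc[res.peaks.lod.idxmax()]
        assert best.chrom == "chr01"
        # distance from the causal locus to the nearest edge of the peak bin
        lo = gmap.cm_at(best.chrom, best.start)
        hi = gmap.cm_at(best.chrom, best.end)
        assert max(lo - 50.0, 50.0 - hi, 0.0) <= 10.0

    def test_monomorphic_bin_skipped_and_reported(self):
        rng = np.random.default_rng(7)
        states = rng.choice([REC, DON], size=(60, 5)).astype(np.int8)
        states[:, 2] = REC  # monomorphic
        binmat = _binmat_from_states(states)
        y = rng.normal(size=60)
        res = cm.BinQtlScan(y, binmat).fit(use_cofactors=False)
        assert 2 in res.skipped_bins
        assert np.isnan(res.lod[2])

    def test_lod_invariant_under_affine_phenotype_transform(self, sim_scan_setup):
        gmap, truth, binmat = sim_scan_setup
        y = np.random.default_rng(8).normal(size=len(binmat.line_names))
        r1 = cm.BinQtlScan(y, binmat, gmap).fit(use_cofactors=False)
        r2 = cm.BinQtlScan(3.0 * y - 7.0, binmat, gmap).fit(use_cofactors=False)
        np.testing.assert_allclose(r1.lod, r2.lod, rtol=1e-8, atol=1e-10)

    def test_no_cofactor_lod_matches_brute_force_likelihood(self, sim_scan_setup):
        """LOD at each bin equals the LRT/(2 ln 10) of an independent direct
        Gaussian likelihood evaluation."""
        gmap, truth, binmat = sim_scan_setup
        rng = np.random.default_rng(9)
        spec = cm.QtlSpec(loci=[("chr02", 1_000_000, 0.8)], pve=[0.2],
                          residual_sd=None)
        y = cm.simulate_phenotypes(truth, spec, rng).trait("trait")
        res = cm.BinQtlScan(y, binmat, gmap).fit(use_cofactors=False)
        D = binmat.dosage()
        for j in range(0, binmat.n_bins, max(1, binmat.n_bins // 15)):
            x = D[:, j]
            ok = ~np.isnan(x)
            yv, xv = y[ok], x[ok]
            if np.ptp(xv) == 0 or np.isnan(res.lod[j]):
                continue
            n = len(yv)
            # direct ML: sigma^2_hat = RSS/n under each model
            rss0 = np.sum((yv - yv.mean()) ** 2)
            X = np.column_stack([np.ones(n), xv])
            beta = np.linalg.lstsq(X, yv, rcond=None)[0]
            rss1 = np.sum((yv - X @ beta) ** 2)
            loglik_ratio = -n / 2 * np.log(rss1 / n) + n / 2 * np.log(rss0 / n)
            assert res.lod[j] == pytest.approx(loglik_ratio / np.log(10), rel=1e-6)

    def test_effect_recovered_without_noise(self, sim_scan_setup):
        gmap, truth, binmat = sim_scan_setup
        spec = cm.QtlSpec(loci=[("chr01", 2_500_000, 1.7)], residual_sd=0.0)
        y = cm.simulate_phenotypes(truth, spec, np.random.default_rng(10)).trait("trait")
        dosage = np.array([l.dosage_at("chr01", 2_500_000) for l in truth.lines])
        j = None  # find the bin containing the causal position
        for k, b in enumerate(binmat.bins):
            if b.chrom == "chr01" and b.start <= 2_500_000 < b.end:
                j = k
        rss, a, _ = fit_additive(y, binmat.dosage()[:, j])
        if np.array_equal(binmat.dosage()[:, j], dosage):
            assert a == pytest.approx(1.7, abs=1e-9)
        else:  # bin state may smooth over sub-bin breakpoints
            assert a == pytest.approx(1.7, rel=0.1)


class TestPermutationThreshold:
    def test_alpha_one_gives_minimum(self, sim_scan_setup):
        gmap, _, binmat = sim_scan_setup
        y = np.random.default_rng(11).normal(size=len(binmat.line_names))
        model = cm.BinQtlScan(y, binmat, gmap)
        thr = model.permutation_threshold(n_perm=100, alpha=1.0,
                                          rng=np.random.default_rng(1))
        lods = model._single_marker_lods(
            np.stack([np.random.default_rng(1).permutation(y)
                      for _ in range(100)], axis=1))
        assert thr <= lods.max(axis=0).min() + 1e-12

    def test_same_seed_same_threshold(self, sim_scan_setup):
        gmap, _, binmat = sim_scan_setup
        y = np.random.default_rng(12).normal(size=len(binmat.line_names))
        model = cm.BinQtlScan(y, binmat, gmap)
        t1 = model.permutation_threshold(200, 0.05, np.random.default_rng(5))
        t2 = model.permutation_threshold(200, 0.05, np.random.default_rng(5))
        assert t1 == t2

    def test_nperm_minimum_enforced(self, sim_scan_setup):
        gmap, _, binmat = sim_scan_setup
        y = np.zeros(len(binmat.line_names))
        with pytest.raises(ValueError):
            cm.BinQtlScan(y, binmat, gmap).permutation_threshold(n_perm=10)


def test_summary_mentions_peaks(sim_scan_setup=None):
    gmap = cm.make_genetic_map([("chr01", 2_000_000, 50.0)])
    rng = np.random.default_rng(13)
    states = rng.choice([REC, DON], size=(80, 20), p=[0.8, 0.2]).astype(np.int8)
    binmat = _binmat_from_states(states)
    y = rng.normal(size=80) + 2.0 * (states[:, 4] == DON)
    res = cm.BinQtlScan(y, binmat, gmap).fit(use_cofactors=False)
    text = res.summary()
    assert "LOD threshold" in text and "bins: 20" in text
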