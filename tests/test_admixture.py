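"""D-statistic engine: pattern definitions, brute-force counting oracle,
jackknife algebra, quartet enumeration and Bonferroni control."""

import itertools
import math

import numpy as np
import pytest

import coalscan as cs
from coalscan.admixture import (
    DerivedMatrix, QuartetConfig, SitePatternCounts, all_quartets,
    block_jackknife, bonferroni, count_patterns, d_statistic, dstat,
    dstat_batch, polarize,
)
from coalscan.genotypes import GenotypeMatrix


def matrix_from_rows(rows, taxa, windows=None):
    """rows: list of per-taxon allele tuples (one entry per site)."""
    geno = np.array(rows, dtype=np.int8)[:, :, None]
    n = len(rows)
    pos = np.arange(n, dtype=np.int64)
    win = np.asarray(windows, dtype=np.int32) if windows is not None else np.zeros(n, np.int32)
    return GenotypeMatrix(taxa, np.full(n, "1"), pos, geno, win)


TAXA = ("P1", "P2", "P3", "O")


class TestPolarize:
    def test_pattern_definitions(self):
        """O=A,P1=A,P2=B,P3=B is ABBA; O=A,P1=B,P2=A,P3=B is BABA."""
        m = matrix_from_rows([(0, 1, 1, 0), (1, 0, 1, 0)], TAXA)
        der = polarize(m, "O")
        q = QuartetConfig("P1", "P2", "P3", "O")
        c = count_patterns(der, q)
        assert (c.abba, c.baba) == (1.0, 1.0)

    def test_outgroup_derived_site_flipped(self):
        """When the outgroup carries the mutation, 'derived' means the
        other allele: (1,0,0,1) is then ABBA."""
        m = matrix_from_rows([(1, 0, 0, 1)], TAXA)
        c = count_patterns(polarize(m, "O"), QuartetConfig("P1", "P2", "P3", "O"))
        assert (c.abba, c.baba) == (1.0, 0.0)

    def test_all_equal_to_outgroup_uninformative(self):
        m = matrix_from_rows([(0, 0, 0, 0)], TAXA)
        c = count_patterns(polarize(m, "O"), QuartetConfig("P1", "P2", "P3", "O"))
        assert c.n_informative == 0.0

    def test_heterozygous_outgroup_dropped(self):
        geno = np.array([[(0, 0), (1, 1), (1, 1), (0, 1)],
                         [(0, 0), (1, 1), (1, 1), (0, 0)]], dtype=np.int8)
        m = GenotypeMatrix(TAXA, np.array(["1", "1"]), np.array([0, 1]), geno)
        der = polarize(m, "O")
        assert der.n_sites == 1 and der.n_dropped_outgroup == 1


class TestCountPatterns:
    def test_constructed_counts(self):
        rows = [(0, 1, 1, 0)] * 10  # 10 ABBA, 0 BABA
        c = count_patterns(polarize(matrix_from_rows(rows, TAXA), "O"),
                           QuartetConfig("P1", "P2", "P3", "O"))
        assert (c.abba, c.baba) == (10.0, 0.0)

    def test_swapping_p1_p2_swaps_counts(self):
        rng = np.random.default_rng(2)
        rows = rng.integers(0, 2, size=(300, 4))
        der = polarize(matrix_from_rows(rows, TAXA), "O")
        a = count_patterns(der, QuartetConfig("P1", "P2", "P3", "O"))
        b = count_patterns(der, QuartetConfig("P2", "P1", "P3", "O"))
        assert (a.abba, a.baba) == (b.baba, b.abba)

    def test_random_matrix_vs_bruteforce_classifier(self):
        """Vectorized counting equals a per-site brute-force classifier on
        a random 1,000-site matrix, per block."""
        rng = np.random.default_rng(5)
        rows = rng.integers(0, 2, size=(1000, 4))
        win = rng.integers(0, 7, size=1000)
        der = polarize(matrix_from_rows(rows, TAXA, windows=win), "O")
        q = QuartetConfig("P1", "P2", "P3", "O")
        c = count_patterns(der, q)
        # brute force
        abba = {}
        baba = {}
        for (p1, p2, p3, o), w in zip(rows, win):
            anc, d1, d2, d3 = o, p1 != o, p2 != o, p3 != o
            if (not d1) and d2 and d3:
                abba[w] = abba.get(w, 0) + 1
            elif d1 and (not d2) and d3:
                baba[w] = baba.get(w, 0) + 1
        assert c.abba == sum(abba.values())
        assert c.baba == sum(baba.values())
        blocks = sorted(set(abba) | set(baba))
        got_blocks = np.flatnonzero((c.block_abba + c.block_baba) > 0)
        # per-block tallies agree wherever informative sites exist
        uniq = np.unique(win)
        for k, w in enumerate(uniq):
            assert c.block_abba[k] == abba.get(w, 0)
            assert c.block_baba[k] == baba.get(w, 0)

    def test_missing_ingroup_site_skipped_for_quartet_only(self):
        rows = np.array([(0, 1, 1, 0), (-1, 1, 1, 0)], dtype=np.int8)
        der = polarize(matrix_from_rows(rows, TAXA), "O")
        c = count_patterns(der, QuartetConfig("P1", "P2", "P3", "O"))
        assert c.n_sites == 1 and c.abba == 1.0


class TestDStatistic:
    def test_arithmetic(self):
        mk = lambda a, b: SitePatternCounts(a, b, np.array([a]), np.array([b]), a + b)
        assert d_statistic(mk(30, 10)) == pytest.approx(0.5)
        assert d_statistic(mk(7, 7)) == 0.0
        assert d_statistic(mk(0, 17)) == -1.0

    def test_no_informative_sites_undefined_not_zero(self):
        c = SitePatternCounts(0, 0, np.zeros(3), np.zeros(3), 0)
        assert math.isnan(d_statistic(c))

    def test_antisymmetry_and_se_invariance(self):
        rng = np.random.default_rng(9)
        rows = rng.integers(0, 2, size=(2000, 4))
        win = rng.integers(0, 20, size=2000)
        der = polarize(matrix_from_rows(rows, TAXA, windows=win), "O")
        a = dstat(der, QuartetConfig("P1", "P2", "P3", "O"))
        b = dstat(der, QuartetConfig("P2", "P1", "P3", "O"))
        assert a.d == pytest.approx(-b.d, abs=1e-15)
        assert a.se == pytest.approx(b.se, rel=1e-12)


class TestBlockJackknife:
    def test_equal_blocks_reduce_to_unweighted_formula(self):
        """With identical per-block counts the Busing estimator equals the
        plain delete-one jackknife variance."""
        rng = np.random.default_rng(1)
        g = 25
        A = np.full(g, 40.0)
        B = np.full(g, 30.0)
        # perturb equally-sized blocks: same weight, different D_(-b)
        A += rng.integers(-5, 6, g)
        B -= A - 40.0  # keep m_b constant across blocks
        c = SitePatternCounts(A.sum(), B.sum(), A, B, int((A + B).sum()))
        se, z, p, used = block_jackknife(c)
        se_sites, _, _, _ = block_jackknife(c, weighting="sites")
        # site-weighted and block-weighted agree for equal blocks
        assert se_sites == pytest.approx(se, rel=1e-10)
        # unweighted delete-one oracle
        d_full = (A.sum() - B.sum()) / (A.sum() + B.sum())
        loo = np.array([
            ((A.sum() - A[i]) - (B.sum() - B[i])) / ((A.sum() - A[i]) + (B.sum() - B[i]))
            for i in range(g)
        ])
        var = (g - 1) / g * ((loo - loo.mean()) ** 2).sum()
        assert se == pytest.approx(np.sqrt(var), rel=1e-10)
        assert used == g

    def test_single_block_flagged(self):
        c = SitePatternCounts(10, 5, np.array([15.0, 0.0]), np.array([0.0, 0.0]), 15)
        se, z, p, used = block_jackknife(c)
        assert math.isnan(se) and used == 1

    def test_jackknife_se_tracks_empirical_sd(self, panel):
        """Mean jackknife SE within [0.8, 1.25] of the SD of D across
        independent replicate genomes (small-scale check; the full-size
        one lives in the acceptance suite)."""
        q = QuartetConfig("EUA", "EUB", "JPN", "WAR")
        ds, ses = [], []
        for seed in range(30):
            cfg = cs.SimulationConfig(panel, n_windows=400, window_length=5000,
                                      seed=300 + seed)
            sim = cs.simulate_genome(cfg, return_trees=False)
            r = dstat(polarize(sim.matrix, "WAR"), q)
            ds.append(r.d)
            ses.append(r.se)
        ratio = np.mean(ses) / np.std(ds, ddof=1)
        assert 0.7 < ratio < 1.4


class TestQuartetEnumeration:
    def test_counts(self):
        assert len(all_quartets(list("ABCO"), "O")) == 3
        taxa10 = [f"T{i}" for i in range(10)] + ["O"]
        assert len(all_quartets(taxa10, "O")) == 360  # 3 * C(10,3)

    def test_outgroup_never_ingroup(self):
        for q in all_quartets(list("ABCDO"), "O"):
            assert "O" not in (q.p1, q.p2, q.p3)

    def test_one_per_unordered_pair(self):
        qs = all_quartets(list("ABCDO"), "O")
        seen = {(frozenset((q.p1, q.p2)), q.p3) for q in qs}
        assert len(seen) == len(qs)

    def test_tree_constraint_keeps_consistent_only(self, panel):
        qs = all_quartets(panel.labels, "WAR", tree=panel.as_gene_tree())
        assert len(qs) == math.comb(10, 3)
        assert QuartetConfig("EUA", "EUB", "JPN", "WAR") in qs
        assert QuartetConfig("EUA", "JPN", "EUB", "WAR") not in qs


class TestBonferroni:
    def test_multiplication_and_cap(self):
        r1 = cs.QuartetResult(QuartetConfig(*TAXA), 1, 1, 0, 1, 0, p=0.001)
        r2 = cs.QuartetResult(QuartetConfig(*TAXA), 1, 1, 0, 1, 0, p=0.5)
        bonferroni([r1], m=10, alpha=0.01)
        bonferroni([r2], m=360)
        assert r1.p_bonferroni == pytest.approx(0.01)
        assert r2.p_bonferroni == 1.0

    def test_significance_called_on_adjusted_p(self):
        r = cs.QuartetResult(QuartetConfig(*TAXA), 1, 1, 0, 1, 0, p=0.0005)
        bonferroni([r], m=10, alpha=0.01)
        assert r.significant
        bonferroni([r], m=100, alpha=0.01)
        assert not r.significant


class TestBatchEqualsReference:
    def test_identical_results(self, null_genome):
        der = polarize(null_genome.matrix, "WAR")
        configs = all_quartets(der.taxa + ("WAR",), "WAR")[:40]
        fast = dstat_batch(der, configs)
        slow = [dstat(der, q) for q in configs]
        for f, s in zip(fast, slow):
            assert (f.abba, f.baba) == (s.abba, s.baba)
            assert f.d == pytest.approx(s.d, abs=1e-14) or (
                math.isnan(f.d) and math.isnan(s.d))
            if math.isfinite(s.se):
                assert f.se == pytest.approx(s.se, rel=1e-12)


class TestAdmixtureFraction:
    def test_null_fraction_near_zero(self, panel):
        """gamma = 0: f is within 2 SE of zero in most replicates."""
        hits = 0
        n = 12
        for seed in range(n):
            cfg = cs.SimulationConfig(panel, n_windows=1500, window_length=5000,
                                      seed=700 + seed, ploidy="diploid")
            sim = cs.simulate_genome(cfg, return_trees=False)
            f = cs.admixture_fraction(sim.matrix, "EUA", "SUM", "VER", "WAR",
                                      seed=seed)
            if math.isfinite(f.f_hat) and abs(f.f_hat) < 2 * f.se_f:
                hits += 1
        assert hits >= n - 2

    def test_pulse_recovered(self, panel):
        cfg = cs.SimulationConfig(
            panel, [cs.AdmixturePulse("VER", "SUM", 5e4, 0.10)],
            n_windows=4000, window_length=5000, seed=41, ploidy="diploid",
        )
        sim = cs.simulate_genome(cfg, return_trees=False)
        f = cs.admixture_fraction(sim.matrix, "EUA", "SUM", "VER", "WAR", seed=4)
        assert 0.05 < f.f_hat < 0.15

    def test_haploid_without_proxies_rejected(self, null_genome):
        with pytest.raises(ValueError, match="proxies"):
            cs.admixture_fraction(null_genome.matrix, "EUA", "SUM", "VER", "WAR")
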