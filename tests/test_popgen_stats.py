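"""Differentiation, LD and Mantel statistics against brute-force oracles."""

import math
from itertools import combinations

import numpy as np
import pytest

from hzkit.io_formats import GenotypePanel, PopulationMetadata
from hzkit.popgen_stats import (
    LDChainParams,
    diversity_summary,
    g_statistic,
    great_circle_km,
    jost_d,
    ld_pair_test,
    mantel_ibd,
    pairwise_dest,
    pairwise_fst,
    region_ld_scan,
    wc_theta,
)

from conftest import make_panel

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def oracle_wc_theta(pop_genotypes):
    """Loop-based Weir-Cockerham theta over diploid genotype lists.

    ``pop_genotypes``: list (per population) of lists of (a, b) genotype
    pairs for one locus; returns (sum_a, sum_abc).
    """
    r = len(pop_genotypes)
    ns = [len(p) for p in pop_genotypes]
    nbar = sum(ns) / r
    nc = (sum(ns) - sum(n * n for n in ns) / sum(ns)) / (r - 1)
    alleles = sorted({a for p in pop_genotypes for g in p for a in g})
    A = B = C = 0.0
    for al in alleles:
        ps = []
        hs = []
        for p in pop_genotypes:
            count = sum(int(g[0] == al) + int(g[1] == al) for g in p)
            ps.append(count / (2 * len(p)))
            hs.append(sum(1 for g in p if g[0] != g[1] and al in g) / len(p))
        pbar = sum(n * p for n, p in zip(ns, ps)) / sum(ns)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / sum(ns)
        a = (nbar / nc) * (
            s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        A += a
        B += b
        C += c
    return A, A + B + C


def oracle_jost_d(pop_genotypes):
    """Direct Hs/Ht computation of single-locus Jost's D."""
    r = len(pop_genotypes)
    ns = [len(p) for p in pop_genotypes]
    nh = r / sum(1 / n for n in ns)
    alleles = sorted({a for p in pop_genotypes for g in p for a in g})
    freqs = []
    for p in pop_genotypes:
        tot = 2 * len(p)
        freqs.append(
            {
                al: sum(int(g[0] == al) + int(g[1] == al) for g in p) / tot
                for al in alleles
            }
        )
    hs = sum(1 - sum(f[al] ** 2 for al in alleles) for f in freqs) / r
    ht = 1 - sum((sum(f[al] for f in freqs) / r) ** 2 for al in alleles)
    hs_est = 2 * nh / (2 * nh - 1) * hs
    ht_est = ht + hs_est / (2 * nh * r)
    return (ht_est - hs_est) / (1 - hs_est) * r / (r - 1)


def oracle_ld_exact_p(table):
    """Exhaustive-enumeration p for a 2x2 table with fixed margins.

    Weights are hypergeometric (proportional to 1/prod(x!)); the statistic
    is sum x log x (equivalent to G with margins fixed)."""
    table = np.asarray(table)
    r1, r2 = table.sum(axis=1)
    c1, c2 = table.sum(axis=0)

    def s_stat(t):
        return sum(x * math.log(x) for row in t for x in row if x > 0)

    s_obs = s_stat(table)
    num = den = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        t = [[k, r1 - k], [c1 - k, r2 - (c1 - k)]]
        if min(min(row) for row in t) < 0:
            continue
        w = 1.0
        for row in t:
            for x in row:
                w /= math.factorial(x)
        den += w
        if s_stat(t) >= s_obs - 1e-9:
            num += w
    return num / den


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


class TestDiversity:
    def test_all_heterozygous_locus(self):
        panel = make_panel({"p": [[(1, 2)], [(1, 2)], [(1, 2)], [(1, 2)]]})
        t = diversity_summary(panel)
        assert t.loc["p", "Ho"] == 1.0
        assert t.loc["p", "He"] == pytest.approx(0.5)

    def test_monomorphic_panel(self):
        panel = make_panel({"p": [[(1, 1), (2, 2)], [(1, 1), (2, 2)]]})
        t = diversity_summary(panel)
        assert t.loc["p", "Ho"] == 0.0
        assert t.loc["p", "He"] == 0.0
        assert t.loc["p", "alleles"] == 2  # one allele per locus

    def test_matches_counting_oracle(self):
        genos = [[(1, 2), (3, 3)], [(1, 1), (3, 4)], [(2, 2), (4, 4)], [(1, 2), (3, 4)]]
        panel = make_panel({"p": genos})
        t = diversity_summary(panel)
        # locus 1: het 2/4; freqs p1=4/8 p2=4/8 -> He=0.5
        # locus 2: het 2/4; freqs p3=4/8 p4=4/8 -> He=0.5
        assert t.loc["p", "Ho"] == pytest.approx(0.5)
        assert t.loc["p", "He"] == pytest.approx(0.5)
        assert t.loc["p", "uHe"] == pytest.approx(8 / 7 * 0.5)
        assert t.loc["p", "alleles"] == 4


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------


class TestTheta:
    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(0)
        genos = [
            [tuple(rng.integers(1, 5, 2)) for _ in range(3)] for _ in range(12)
        ]
        panel = make_panel({"a": genos, "b": [list(g) for g in genos]})
        theta, _ = wc_theta(panel)
        assert theta <= 0.01

    def test_matches_variance_components_oracle(self):
        pa = [(1, 1), (1, 2), (1, 1), (2, 2), (1, 2)]
        pb = [(2, 2), (2, 2), (1, 2), (2, 2)]
        panel = make_panel({"a": [[g] for g in pa], "b": [[g] for g in pb]})
        theta, _ = wc_theta(panel)
        a, abc = oracle_wc_theta([pa, pb])
        assert theta == pytest.approx(a / abc, abs=1e-10)

    def test_multilocus_matches_oracle(self):
        rng = np.random.default_rng(5)
        la = [[tuple(rng.integers(1, 4, 2)) for _ in range(3)] for _ in range(6)]
        lb = [[tuple(rng.integers(2, 6, 2)) for _ in range(3)] for _ in range(6)]
        panel = make_panel({"a": la, "b": lb})
        theta, _ = wc_theta(panel)
        num = den = 0.0
        for l in range(3):
            a, abc = oracle_wc_theta(
                [[g[l] for g in la], [g[l] for g in lb]]
            )
            num += a
            den += abc
        assert theta == pytest.approx(num / den, abs=1e-10)

    def test_invariant_to_relabeling_and_order(self):
        rng = np.random.default_rng(7)
        la = [[tuple(rng.integers(1, 4, 2))] for _ in range(6)]
        lb = [[tuple(rng.integers(2, 6, 2))] for _ in range(6)]
        panel = make_panel({"a": la, "b": lb})
        t1, _ = wc_theta(panel)
        relab = make_panel(
            {"b": lb, "a": la}  # swapped population order
        )
        t2, _ = wc_theta(relab, pops=["b", "a"])
        assert t1 == pytest.approx(t2, abs=1e-12)
        shifted = make_panel(
            {
                "a": [[(g[0][0] + 10, g[0][1] + 10)] for g in la],
                "b": [[(g[0][0] + 10, g[0][1] + 10)] for g in lb],
            }
        )
        t3, _ = wc_theta(shifted)
        assert t1 == pytest.approx(t3, abs=1e-12)


class TestJostD:
    def test_identical_populations_near_zero(self):
        # the bias correction assumes independent samples, so duplicated
        # samples sit slightly below zero; large n keeps |D| small
        rng = np.random.default_rng(1)
        genos = [[tuple(rng.integers(1, 6, 2)) for _ in range(5)] for _ in range(60)]
        panel = make_panel({"a": genos, "b": [list(g) for g in genos]})
        d, _ = jost_d(panel)
        assert abs(d) < 0.05

    def test_fixed_differences_give_one(self):
        panel = make_panel(
            {
                "a": [[(1, 1), (3, 3)]] * 4,
                "b": [[(2, 2), (4, 4)]] * 4,
            }
        )
        d, _ = jost_d(panel)
        assert d == pytest.approx(1.0, abs=1e-9)

    def test_matches_hs_ht_oracle(self):
        pa = [(1, 1), (1, 2), (2, 2), (1, 3)]
        pb = [(2, 3), (3, 3), (2, 2), (3, 3), (1, 3)]
        panel = make_panel({"a": [[g] for g in pa], "b": [[g] for g in pb]})
        d, _ = jost_d(panel)
        assert d == pytest.approx(oracle_jost_d([pa, pb]), abs=1e-10)


class TestBootstrapMatrices:
    def test_ci_brackets_estimate(self, study_fixture):
        panel, _ = study_fixture
        sub = panel.select_populations(["Kaiserslautern", "Cordoba", "Doninos"])
        mat = pairwise_fst(sub, n_bootstrap=200, seed=3)
        iu = np.triu_indices(3, k=1)
        ok = (mat.ci_low[iu] <= mat.estimate[iu] + 1e-9) & (
            mat.estimate[iu] <= mat.ci_high[iu] + 1e-9
        )
        assert ok.mean() >= 0.95
        assert np.allclose(np.diag(mat.estimate), 0.0)
        dmat = pairwise_dest(sub, n_bootstrap=200, seed=3)
        assert dmat.statistic == "Dest_Jost"
        assert np.allclose(dmat.estimate, dmat.estimate.T)

    def test_singleton_population_excluded(self):
        panel = make_panel(
            {
                "a": [[(1, 2)], [(1, 1)], [(2, 2)]],
                "solo": [[(1, 2)]],
                "b": [[(2, 2)], [(1, 2)], [(2, 2)]],
            }
        )
        with pytest.warns(UserWarning, match="solo"):
            mat = pairwise_fst(panel, n_bootstrap=20, seed=0)
        assert "solo" not in mat.populations


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------


class TestLD:
    def test_chain_matches_enumeration_on_2x2(self):
        # two biallelic loci arranged to give a genuine 2x2 genotype table
        genos = (
            [[(1, 1), (3, 3)]] * 6
            + [[(1, 1), (4, 4)]] * 2
            + [[(2, 2), (3, 3)]] * 2
            + [[(2, 2), (4, 4)]] * 5
        )
        panel = make_panel({"p": genos})
        res = ld_pair_test(
            panel, "L1", "L2", "p", LDChainParams(500, 50, 400), seed=9
        )
        table = np.array([[6, 2], [2, 5]])
        p_exact = oracle_ld_exact_p(table)
        assert res.p == pytest.approx(p_exact, abs=max(3 * res.se, 0.02))

    def test_perfect_association_significant(self):
        rng = np.random.default_rng(3)
        a = rng.integers(1, 3, size=30)
        genos = [[(x, x), (x + 10, x + 10)] for x in a]
        panel = make_panel({"p": genos})
        res = ld_pair_test(panel, "L1", "L2", "p", LDChainParams(500, 50, 200), seed=4)
        assert res.p <= 0.01

    def test_monomorphic_locus_untestable(self):
        genos = [[(1, 1), (3, 4)], [(1, 1), (3, 3)], [(1, 1), (4, 4)]]
        panel = make_panel({"p": genos})
        res = ld_pair_test(panel, "L1", "L2", "p", seed=0)
        assert not res.testable and res.p == 1.0

    def test_g_statistic_independence_zero(self):
        assert g_statistic(np.array([[4, 4], [2, 2]])) == pytest.approx(0.0, abs=1e-12)


class TestRegionScan:
    @staticmethod
    def _region_panel(n_loci, monomorphic=()):
        rng = np.random.default_rng(11)
        pops = {}
        for pop in ("p1", "p2"):
            inds = []
            for _ in range(12):
                g = []
                for l in range(n_loci):
                    if l in monomorphic:
                        g.append((1, 1))
                    else:
                        g.append(tuple(rng.integers(1, 4, 2)))
                inds.append(g)
            pops[pop] = inds
        return make_panel(pops)

    @pytest.mark.parametrize(
        "n_loci,mono,expected_pairs",
        [(12, (), 66), (12, (0,), 55), (7, (), 21)],
    )
    def test_testable_pair_accounting(self, n_loci, mono, expected_pairs):
        panel = self._region_panel(n_loci, mono)
        results, summary = region_ld_scan(
            panel, ["p1", "p2"], LDChainParams(100, 10, 50), seed=1
        )
        assert summary.loc[0, "n_testable_pairs"] == expected_pairs
        assert len(results) == expected_pairs

    def test_fisher_combination_bounds(self):
        panel = self._region_panel(4)
        results, _ = region_ld_scan(panel, ["p1", "p2"], LDChainParams(100, 10, 50), seed=2)
        for r in results:
            assert 0.0 <= r.p <= 1.0
            assert len(r.per_population) >= 1


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------


def _meta(coords):
    return [
        PopulationMetadata(p, "Ie", "allopatric", lat, lon)
        for p, (lat, lon) in coords.items()
    ]


def _stat_matrix(pops, mat):
    from hzkit.popgen_stats import PairwiseStatMatrix

    m = np.asarray(mat, dtype=float)
    return PairwiseStatMatrix("FST_WC", pops, m, m, m, 0)


class TestMantel:
    def test_distance_matrix_gives_r_one(self):
        coords = {
            "a": (40.0, 0.0),
            "b": (42.0, 1.0),
            "c": (44.0, -1.0),
            "d": (46.0, 2.0),
            "e": (48.0, 0.5),
        }
        pops = list(coords)
        k = len(pops)
        d = np.zeros((k, k))
        for i in range(k):
            for j in range(k):
                d[i, j] = great_circle_km(*coords[pops[i]], *coords[pops[j]])
        res = mantel_ibd(_stat_matrix(pops, d), _meta(coords), 499, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p <= 0.05

    def test_planted_outlier_removal_strengthens_signal(self):
        rng = np.random.default_rng(2)
        coords = {f"p{i}": (40 + i, float(i)) for i in range(8)}
        coords["island"] = (44.0, 3.5)
        pops = list(coords)
        k = len(pops)
        d = np.zeros((k, k))
        for i in range(k):
            for j in range(k):
                d[i, j] = great_circle_km(*coords[pops[i]], *coords[pops[j]])
        s = d / d.max() * 0.2 + rng.normal(0, 0.005, (k, k))
        s = (s + s.T) / 2
        np.fill_diagonal(s, 0)
        # the island's differentiation ignores geography entirely
        isl = pops.index("island")
        s[isl, :] = s[:, isl] = 0.4
        s[isl, isl] = 0.0
        full = mantel_ibd(_stat_matrix(pops, s), _meta(coords), 999, seed=1)
        dropped = mantel_ibd(
            _stat_matrix(pops, s), _meta(coords), 999, seed=1, drop=["island"]
        )
        assert dropped.r > full.r

    def test_too_few_populations_rejected(self):
        coords = {"a": (40.0, 0.0), "b": (41.0, 0.0), "c": (42.0, 0.0)}
        with pytest.raises(ValueError, match="4"):
            mantel_ibd(
                _stat_matrix(list(coords), np.zeros((3, 3))), _meta(coords), 99
            )
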