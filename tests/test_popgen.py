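"""SNP filters, heterozygosity statistics and Weir-Cockerham F_ST.

The F_ST oracle below is an independent scalar re-derivation of the 1984
variance-components estimator, written per locus from genotype counts with
explicit loops, to cross-check the vectorised implementation.
"""

import numpy as np
import pytest

from skyland.genotypes import MISSING
from skyland.popgen import (
    completeness_filter,
    het_stats,
    pairwise_fst,
    paralog_filter,
    quality_filter,
    simulate_hwe_panel,
    weir_cockerham_theta,
)
from skyland.synthetic import PopModel, inject_paralogs, simulate_genotypes

from conftest import geno_matrix


def wc_theta_oracle(pop_genos):
    """Independent two-population Weir-Cockerham multilocus theta.

    ``pop_genos`` is a list of two (samples, loci) arrays with -1 missing.
    Returns the ratio-of-sums estimate.
    """
    num = den = 0.0
    n_loci = pop_genos[0].shape[1]
    r = 2
    for locus in range(n_loci):
        ns, ps, hs = [], [], []
        for pg in pop_genos:
            col = pg[:, locus]
            col = col[col != -1]
            if len(col) == 0:
                ns.append(0.0)
                ps.append(0.0)
                hs.append(0.0)
                continue
            ns.append(float(len(col)))
            ps.append(float(col.sum()) / (2 * len(col)))
            hs.append(float((col == 1).sum()) / len(col))
        if min(ns) < 1 or sum(ns) < 3:
            continue
        nbar = sum(ns) / r
        nc = (sum(ns) - sum(n * n for n in ns) / sum(ns)) / (r - 1)
        pbar = sum(n * p for n, p in zip(ns, ps)) / sum(ns)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / sum(ns)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        if a + b + c != 0:
            num += a
            den += a + b + c
    return num / den


class TestQualityFilter:
    def test_qual_threshold_boundary(self):
        g = geno_matrix([[0, 0], [1, 1], [2, 2]], ["N", "C", "S"],
                        qual=np.array([29.0, 30.0]))
        out = quality_filter(g, min_mac=0, min_non_ref_ac=0)
        assert list(out.locus_ids) == ["l1"]

    def test_low_dp_genotypes_masked(self):
        g = geno_matrix([[1], [1], [1]], ["N", "C", "S"],
                        depth=np.array([[2], [3], [10]]))
        out = quality_filter(g, min_mac=0, min_non_ref_ac=0)
        assert list(out.genotypes[:, 0]) == [MISSING, 1, 1]

    def test_allele_count_boundaries(self):
        # non-ref allele count 5 -> removed; 6 -> kept
        g5 = geno_matrix([[1], [2], [2], [0], [0]], list("NCSNC"))
        g6 = geno_matrix([[2], [2], [2], [0], [0]], list("NCSNC"))
        assert quality_filter(g5).n_loci == 0
        assert quality_filter(g6).n_loci == 1

    def test_mac_boundary(self):
        # minor allele (ref) count 1 -> removed at mac 2
        g = geno_matrix([[2], [2], [2], [1]], list("NCSN"))
        assert quality_filter(g).n_loci == 0
        g2 = geno_matrix([[2], [2], [2], [1], [1]], list("NCSNC"))
        assert quality_filter(g2).n_loci == 1

    def test_six_rule_toy_panel(self):
        """Six loci each violating exactly one rule plus one clean locus."""
        # columns: qual<30 | triallelic | non-ref-ac 5 | non-ref-ac passes only
        #          until DP masking | all-low-DP | mac 1 | clean
        geno = np.array(
            [
                [1, 1, 1, 1, 1, 2, 1],
                [1, 1, 1, 1, 1, 2, 1],
                [2, 2, 1, 1, 1, 2, 2],
                [2, 2, 2, 2, 1, 2, 2],
                [0, 0, 0, 1, 1, 1, 1],
                [0, 0, 0, 1, 1, 2, 1],
            ],
            dtype=np.int8,
        )
        qual = np.array([29.0, 99, 99, 99, 99, 99, 99])
        biallelic = np.array([True, False, True, True, True, True, True])
        depth = np.full(geno.shape, 10)
        depth[:, 4] = 2  # every genotype below min DP
        depth[4:, 3] = 2  # mask the two hets that made mac pass
        g = geno_matrix(
            list(geno), list("NNCCSS"), qual=qual, biallelic_snp=biallelic,
            depth=depth,
        )
        out = quality_filter(g)
        assert list(out.locus_ids) == ["l6"]

    def test_idempotent(self):
        model = PopModel(n_snps=300, missing_rate=0.05, seed=4)
        g = simulate_genotypes(model)
        once = quality_filter(g)
        twice = quality_filter(once)
        np.testing.assert_array_equal(once.genotypes, twice.genotypes)
        assert list(once.locus_ids) == list(twice.locus_ids)


class TestCompletenessFilter:
    def test_strict_boundary(self):
        geno = np.full((3, 20), 0, dtype=np.int8)
        geno[0, 3:] = MISSING   # 15% called -> kept
        geno[1, 2:] = MISSING   # 10% called -> dropped
        g = geno_matrix(list(geno), ["N", "C", "S"])
        out, dropped = completeness_filter(g, 0.15)
        assert dropped == ["s1"]
        assert out.n_samples == 2

    def test_no_missingness_identity(self):
        g = geno_matrix([[0, 1], [1, 2]], ["N", "C"])
        out, dropped = completeness_filter(g)
        assert dropped == []
        assert out.n_samples == 2

    def test_all_dropped_is_error(self):
        g = geno_matrix([[MISSING], [MISSING]], ["N", "C"])
        with pytest.raises(ValueError):
            completeness_filter(g)


class TestHetStats:
    def test_counting_arithmetic(self):
        g = geno_matrix([[0], [0], [1], [1]], ["N", "N", "C", "C"])
        row = het_stats(g).iloc[0]
        assert row["p_hat"] == pytest.approx(0.75)
        assert row["ho"] == pytest.approx(0.5)
        assert row["he"] == pytest.approx(0.375)

    def test_all_het_and_monomorphic(self):
        g = geno_matrix([[1, 0], [1, 0]], ["N", "C"])
        stats = het_stats(g)
        assert stats.iloc[0]["ho"] == 1.0
        assert stats.iloc[0]["he"] == 0.5
        assert stats.iloc[1]["p_hat"] == 1.0
        assert stats.iloc[1]["he"] == 0.0


class TestParalogFilter:
    def test_excess_het_removed_deficit_kept(self):
        # locus 0: all het (ho 1 > he 0.5) removed; locus 1: ho < he kept
        g = geno_matrix([[1, 0], [1, 1], [1, 0], [1, 2]], list("NNCC"))
        out, removed = paralog_filter(g)
        assert list(out.locus_ids) == ["l1"]
        assert removed.index.tolist() == ["l0"]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        g = geno_matrix(rng.binomial(2, 0.4, (30, 50)), ["N"] * 10 + ["C"] * 10 + ["S"] * 10)
        once, _ = paralog_filter(g)
        twice, removed2 = paralog_filter(once)
        assert list(once.locus_ids) == list(twice.locus_ids)
        assert removed2.empty

    def test_removes_all_injected_paralogs(self):
        model = PopModel(n_snps=500, seed=9)
        g = inject_paralogs(simulate_genotypes(model), 0.2, seed=10)
        out, removed = paralog_filter(g)
        assert not out.paralog_truth.any()
        assert g.paralog_truth.sum() == 100
        assert set(g.locus_ids[g.paralog_truth]) <= set(removed.index)


class TestHwePanel:
    def test_shape_and_determinism(self):
        g1, stats = simulate_hwe_panel(100, 50, seed=3)
        g2, _ = simulate_hwe_panel(100, 50, seed=3)
        assert g1.n_loci == 100
        np.testing.assert_array_equal(g1.genotypes, g2.genotypes)

    def test_ho_matches_he_at_large_n(self):
        _, stats = simulate_hwe_panel(100, 10_000, seed=1)
        diff = stats["ho"] - stats["he"]
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 3 * se


class TestWeirCockerham:
    def test_fixed_difference_is_one(self):
        ga = np.zeros((20, 5), dtype=np.int8)
        gb = np.full((20, 5), 2, dtype=np.int8)
        theta, n_used = weir_cockerham_theta(ga, gb)
        assert theta == pytest.approx(1.0)
        assert n_used == 5

    def test_toy_table_matches_independent_oracle(self):
        # pop1: 6 REF-hom + 2 het; pop2: 1 REF-hom + 3 het + 4 ALT-hom
        ga = np.array([[0]] * 6 + [[1]] * 2, dtype=np.int8)
        gb = np.array([[0]] * 1 + [[1]] * 3 + [[2]] * 4, dtype=np.int8)
        theta, _ = weir_cockerham_theta(ga, gb)
        assert theta == pytest.approx(wc_theta_oracle([ga, gb]), abs=1e-12)

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            ga = rng.binomial(2, rng.uniform(0.1, 0.9), (12, 40)).astype(np.int8)
            gb = rng.binomial(2, rng.uniform(0.1, 0.9), (7, 40)).astype(np.int8)
            ga[rng.random(ga.shape) < 0.1] = MISSING
            gb[rng.random(gb.shape) < 0.1] = MISSING
            theta, _ = weir_cockerham_theta(ga, gb)
            assert theta == pytest.approx(wc_theta_oracle([ga, gb]), abs=1e-12)

    def test_panmictic_theta_near_zero(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.05, 0.95, 2_000)
        ga = rng.binomial(2, p, (300, 2_000)).astype(np.int8)
        gb = rng.binomial(2, p, (300, 2_000)).astype(np.int8)
        theta, _ = weir_cockerham_theta(ga, gb)
        assert abs(theta) < 0.01

    def test_pairwise_over_populations(self):
        model = PopModel(n_snps=500, seed=2)
        g = simulate_genotypes(model)
        results = {r.pair: r.theta for r in pairwise_fst(g)}
        assert set(results) == {("C", "N"), ("C", "S"), ("N", "S")}
        # deep south split, shallow north/central split
        assert results[("C", "N")] < results[("C", "S")]
        assert results[("C", "N")] < results[("N", "S")]

    def test_paralog_filter_does_not_decrease_theta(self):
        model = PopModel(n_snps=1_000, paralog_fraction=0.1, seed=5)
        g = simulate_genotypes(model)
        pre = {r.pair: r.theta for r in pairwise_fst(g)}
        filtered, _ = paralog_filter(g)
        post = {r.pair: r.theta for r in pairwise_fst(filtered)}
        for pair in pre:
            assert post[pair] >= pre[pair]
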