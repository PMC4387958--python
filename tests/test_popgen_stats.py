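import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from caprapop.popgen_stats import (
    UndefinedStatError,
    het_observed,
    ibs_matrix,
    inbreeding_f,
    maf_spectrum,
    mean_pi,
    polymorphism_partition,
    rare_fraction_from_counts,
    site_pi,
    tstv,
    tstv_from_counts,
    wc_fst,
)
from oracles import inbreeding_f_site_sum, make_matrix, wc_site_components


class TestPi:
    @pytest.mark.parametrize(
        "j,n,expected",
        [(1, 88, 2.0 / 88), (0, 88, 0.0), (2, 4, 2.0 / 3.0), (88, 88, 0.0)],
    )
    def test_site_pi_formula(self, j, n, expected):
        assert site_pi(j, n) == pytest.approx(expected, abs=1e-12)

    def test_mean_pi_over_qualifying_sites(self):
        # 3 samples, sites with alt counts 1, 3, 6(monomorphic), 0(monomorphic)
        m = make_matrix([[1, 1, 2, 0], [0, 1, 2, 0], [0, 1, 2, 0]])
        expected = (site_pi(1, 6) + site_pi(3, 6)) / 2
        assert mean_pi(m) == pytest.approx(expected, abs=1e-12)

    def test_sites_with_missing_genotypes_excluded(self):
        m = make_matrix([[1, -1], [0, 1], [0, 0]])
        assert mean_pi(m) == pytest.approx(site_pi(1, 6), abs=1e-12)

    def test_monomorphic_only_input_is_undefined(self):
        m = make_matrix([[0, 2], [0, 2]])
        with pytest.raises(UndefinedStatError):
            mean_pi(m)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_to_sample_order_and_allele_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.integers(0, 3, size=(6, 12)).astype(np.int8)
        m = make_matrix(d.tolist())
        try:
            base = mean_pi(m)
        except UndefinedStatError:
            return
        perm = rng.permutation(6)
        assert mean_pi(make_matrix(d[perm].tolist())) == pytest.approx(base)
        assert mean_pi(make_matrix((2 - d).tolist())) == pytest.approx(base)


class TestHoAndF:
    def test_het_fraction(self):
        m = make_matrix([[1, 1, 0], [0, 1, 2]])
        assert het_observed(m, 0) == pytest.approx(2.0 / 3.0)

    def test_all_hom_and_all_het(self):
        m = make_matrix([[0, 2, 0], [1, 1, 1]])
        assert het_observed(m, 0) == 0.0
        assert het_observed(m, 1) == 1.0

    def test_fully_homozygous_individual_has_f_one(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
        d[3] = np.where(d[3] == 1, 2, d[3])  # individual 3: no hets
        seg = (d.max(axis=0) > d.min(axis=0)) | (d == 1).any(axis=0)
        d = d[:, seg]
        m = make_matrix(d.tolist())
        assert inbreeding_f(m, 3) == pytest.approx(1.0, abs=1e-12)

    def test_hwe_individual_has_f_near_zero(self):
        rng = np.random.default_rng(1)
        n, m_sites = 30, 10_000
        p = rng.uniform(0.1, 0.9, m_sites)
        d = rng.binomial(2, np.tile(p, (n, 1))).astype(np.int8)
        keep = (d.max(axis=0) > d.min(axis=0))
        m = make_matrix(d[:, keep].tolist())
        assert abs(inbreeding_f(m, 0)) < 0.05

    def test_f_matches_scalar_per_site_summation(self):
        d = np.array(
            [[0, 1, 2, 1, 0], [1, 1, 0, 2, 1], [2, 0, 1, 1, 0], [0, 2, 2, 0, 1]],
            dtype=np.int8,
        )
        m = make_matrix(d.tolist())
        for i in range(4):
            assert inbreeding_f(m, i) == pytest.approx(
                inbreeding_f_site_sum(d, i), abs=1e-12
            )


class TestIbs:
    def test_identical_individuals_share_everything(self):
        m = make_matrix([[0, 1, 2], [0, 1, 2]])
        assert ibs_matrix(m)[0, 1] == 1.0

    def test_opposite_homozygotes_share_nothing(self):
        m = make_matrix([[0, 0], [2, 2]])
        assert ibs_matrix(m)[0, 1] == 0.0

    def test_hom_vs_het_shares_half(self):
        m = make_matrix([[0, 0], [1, 1]])
        assert ibs_matrix(m)[0, 1] == 0.5

    def test_symmetric_unit_diagonal_missing_excluded_pairwise(self):
        m = make_matrix([[0, 1, -1], [2, 1, 0], [1, -1, 0]])
        sim = ibs_matrix(m)
        assert np.allclose(sim, sim.T)
        assert np.all(np.diag(sim) == 1.0)
        assert sim[0, 1] == pytest.approx((0.0 + 1.0) / 2)  # third site dropped


class TestTsTv:
    def test_printed_counts_reproduce_published_ratio(self):
        assert tstv_from_counts(15_948_529, 6_540_478) == pytest.approx(
            2.44, abs=0.005
        )

    def test_equal_counts_unit_ratio(self):
        assert tstv_from_counts(10, 10) == 1.0

    def test_classification_of_substitutions(self):
        m = make_matrix(
            [[1, 1, 1]],
            refs=["A", "A", "C"],
            alts=["G", "C", "T"],
        )
        ts, tv, ratio = tstv(m.sites)
        assert (ts, tv) == (2, 1)

    def test_indels_skipped_and_zero_tv_sentinel(self):
        m = make_matrix([[1, 1]], refs=["A", "A"], alts=["AGG", "G"])
        ts, tv, ratio = tstv(m.sites)
        assert (ts, tv) == (1, 0) and ratio == float("inf")

    def test_multiallelic_snp_counts_each_alt(self):
        m = make_matrix([[1]], refs=["A"], alts=["G,C"])
        ts, tv, _ = tstv(m.sites)
        assert (ts, tv) == (1, 1)


class TestMafSpectrum:
    def test_printed_counts_reproduce_published_rare_fraction(self):
        frac = rare_fraction_from_counts(10_892_203, 24_022_850)
        assert frac * 100 == pytest.approx(45.3, abs=0.05)

    def test_singleton_is_rare_and_boundary_is_not(self):
        # 20 diploids: MAF 1/40 = 0.025 is rare; 2/40 = 0.05 exactly is not
        d = np.zeros((20, 2), dtype=np.int8)
        d[0, 0] = 1
        d[0, 1] = 2
        _, _, rare = maf_spectrum(make_matrix(d.tolist()))
        assert rare == pytest.approx(0.5)


class TestPartition:
    def test_private_and_shared_subsets(self):
        pop_map = {"s0": "A", "s1": "A", "s2": "B", "s3": "B"}
        #          siteA(A only)  siteAll  siteB(B only)
        d = [
            [1, 1, 0],
            [0, 1, 0],
            [0, 1, 1],
            [0, 0, 0],
        ]
        counts = polymorphism_partition(make_matrix(d), pop_map)
        assert counts[frozenset({"A"})] == 1
        assert counts[frozenset({"A", "B"})] == 1
        assert counts[frozenset({"B"})] == 1

    def test_counts_match_exhaustive_evaluation_and_sum_to_total(self):
        rng = np.random.default_rng(5)
        d = rng.integers(-1, 3, size=(9, 60)).astype(np.int8)
        pop_map = {f"s{i}": "ABC"[i % 3] for i in range(9)}
        m = make_matrix(d.tolist())
        counts = polymorphism_partition(m, pop_map)
        # scalar oracle
        expected: dict[frozenset, int] = {}
        for j in range(60):
            subset = set()
            for pop in "ABC":
                rows = [i for i in range(9) if pop_map[f"s{i}"] == pop]
                alleles = set()
                for i in rows:
                    x = d[i, j]
                    if x < 0:
                        continue
                    alleles |= {0, 1} if x == 1 else ({1} if x == 2 else {0})
                if len(alleles) >= 2:
                    subset.add(pop)
            if subset:
                key = frozenset(subset)
                expected[key] = expected.get(key, 0) + 1
        assert counts == expected
        assert sum(counts.values()) == sum(expected.values())


class TestWcFst:
    def test_components_match_scalar_textbook_oracle(self):
        d = [
            [0, 1, 2],
            [1, 1, 0],
            [2, 0, 1],
            [0, 1, 1],
            [2, 2, 0],
            [1, 2, 1],
            [2, 1, 0],
            [2, 2, 2],
        ]
        m = make_matrix(d)
        pop_map = {f"s{i}": ("P1" if i < 4 else "P2") for i in range(8)}
        res = wc_fst(m, pop_map)
        for row, j in enumerate(res.site_index):
            genos = [
                [d[i][j] for i in range(4)],
                [d[i][j] for i in range(4, 8)],
            ]
            a, b, c = wc_site_components(genos)
            assert res.a[row] == pytest.approx(a, abs=1e-12)
            assert res.b[row] == pytest.approx(b, abs=1e-12)
            assert res.c[row] == pytest.approx(c, abs=1e-12)
            assert res.theta_site[row] == pytest.approx(
                a / (a + b + c), abs=1e-12
            )

    def test_identical_population_compositions_give_near_zero(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0.05, 0.95, 10_000)
        d = rng.binomial(2, np.tile(p, (40, 1))).astype(np.int8)
        pop_map = {f"s{i}": ("P1" if i < 20 else "P2") for i in range(40)}
        res = wc_fst(make_matrix(d.tolist()), pop_map)
        assert abs(res.theta_weighted) < 0.01

    def test_fixed_difference_gives_theta_one(self):
        d = [[0, 0]] * 4 + [[2, 2]] * 4
        pop_map = {f"s{i}": ("P1" if i < 4 else "P2") for i in range(8)}
        res = wc_fst(make_matrix(d), pop_map)
        assert np.allclose(res.theta_site, 1.0)

    def test_weighted_theta_is_ratio_of_component_sums(self):
        rng = np.random.default_rng(13)
        d = rng.integers(0, 3, size=(12, 300)).astype(np.int8)
        pop_map = {f"s{i}": "AB"[i % 2] for i in range(12)}
        res = wc_fst(make_matrix(d.tolist()), pop_map)
        denom = res.a + res.b + res.c
        ok = denom > 0
        assert res.theta_weighted == pytest.approx(
            res.a[ok].sum() / denom[ok].sum(), abs=1e-14
        )

    def test_sites_with_tiny_populations_skipped_and_counted(self):
        d = [[1, 1], [0, -1], [1, 1], [2, 0]]
        pop_map = {"s0": "A", "s1": "A", "s2": "B", "s3": "B"}
        res = wc_fst(make_matrix(d), pop_map)
        assert res.n_skipped == 1
        assert len(res.site_index) == 1
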