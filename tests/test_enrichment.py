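"""Enrichment statistics: exact 2xk Fisher test, FST, Poisson regressions,
enriched-cluster designation, and the genome screen."""


import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exact_oracles import fisher_2xk_bruteforce, poisson_newton

from admixscreen.ancestry import AncestryClusters, QMatrix
from admixscreen.enrichment import (
    ContingencyTable2xK,
    _monte_carlo_p,
    build_allele_table,
    designate_enriched_cluster,
    fisher_exact_2xk,
    fst,
    poisson_ancestry_regression,
    screen_genome,
)
from admixscreen.harmonize import Dataset, union_merge
from admixscreen.simulate import Annotation, AnnotationCatalog
from admixscreen.variants import MISSING, GenotypeMatrix, VariantKey


def table(ref, alt, names=None):
    names = names or [f"c{i}" for i in range(len(ref))]
    return ContingencyTable2xK(names=names, ref_counts=ref, alt_counts=alt)


class TestBuildAlleleTable:
    def test_single_cluster_counts(self):
        t = build_allele_table(np.array([0, 1, 2]), ["A", "A", "A"], ["A"])
        assert t.ref_counts.tolist() == [3] and t.alt_counts.tolist() == [3]

    def test_column_total_is_twice_called_samples(self):
        t = build_allele_table(np.array([0, 1, 2, 1, 0]), ["A"] * 5, ["A"])
        assert t.column_totals.tolist() == [10]

    def test_two_cluster_hand_count(self):
        geno = np.array([0, 0, 2, 2, 2])
        labels = ["X", "X", "Y", "Y", "Y"]
        t = build_allele_table(geno, labels, ["X", "Y"])
        assert t.ref_counts.tolist() == [4, 0]
        assert t.alt_counts.tolist() == [0, 6]

    def test_missing_samples_contribute_nothing(self):
        t = build_allele_table(np.array([1, MISSING, MISSING]), ["A", "A", "B"], ["A", "B"])
        assert t.column_totals.tolist() == [2, 0]
        assert t.alt_counts.tolist() == [1, 0]


class TestFisherExact:
    def test_hand_enumerated_2x2(self):
        # margins (4,4 | 4,4): p = 17/35
        r = fisher_exact_2xk(table([3, 1], [1, 3]))
        assert r.method == "exact"
        assert r.p == pytest.approx(17 / 35, abs=1e-12)

    def test_single_observation_per_column(self):
        r = fisher_exact_2xk(table([1, 0], [0, 1]))
        assert r.p == pytest.approx(1.0, abs=1e-12)

    def test_modal_2x5_table_has_p_one(self):
        r = fisher_exact_2xk(table([2] * 5, [2] * 5))
        assert r.p == pytest.approx(1.0, abs=1e-12)

    def test_zero_total_columns_dropped(self):
        r = fisher_exact_2xk(table([3, 0, 1], [1, 0, 3]))
        assert r.p == pytest.approx(17 / 35, abs=1e-12)

    def test_single_remaining_column_gives_p_one(self):
        r = fisher_exact_2xk(table([3, 0], [1, 0]))
        assert r.p == 1.0

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2xk(table([0, 0], [0, 0]))

    def test_matches_bruteforce_oracle_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(150):
            k = int(rng.integers(2, 6))
            cols = rng.integers(1, 8, size=k)
            alt = np.array([rng.integers(0, c + 1) for c in cols])
            r = fisher_exact_2xk(table((cols - alt).tolist(), alt.tolist()))
            o = fisher_2xk_bruteforce(cols - alt, alt)
            assert r.p == pytest.approx(o, abs=1e-12)

    def test_matches_scipy_on_2x2(self):
        from scipy.stats import fisher_exact as scipy_fisher

        rng = np.random.default_rng(9)
        for _ in range(100):
            cols = rng.integers(1, 25, size=2)
            alt = np.array([rng.integers(0, c + 1) for c in cols])
            r = fisher_exact_2xk(table((cols - alt).tolist(), alt.tolist()))
            _, sp = scipy_fisher(np.array([cols - alt, alt]))
            assert r.p == pytest.approx(sp, abs=1e-9)

    def test_monte_carlo_within_four_se_of_exact(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            cols = rng.integers(5, 15, size=3)
            alt = np.array([rng.integers(0, c + 1) for c in cols])
            exact = fisher_exact_2xk(table((cols - alt).tolist(), alt.tolist()))
            assert exact.method == "exact"
            p_mc, se, _ = _monte_carlo_p(cols, alt, 100_000, np.random.default_rng(11))
            assert abs(p_mc - exact.p) <= 4 * se + 1e-5

    def test_upper_bound_dominates_exact_p(self):
        # the certified fallback must never understate the exact p-value
        from admixscreen.enrichment import _chernoff_upper_p

        rng = np.random.default_rng(12)
        for _ in range(20):
            cols = rng.integers(4, 12, size=3)
            alt = np.array([rng.integers(0, c + 1) for c in cols])
            exact = fisher_exact_2xk(table((cols - alt).tolist(), alt.tolist()))
            bound = _chernoff_upper_p(cols, alt)
            assert bound >= exact.p - 1e-12

    def test_extreme_large_table_certified_genome_wide(self):
        cols = np.full(5, 500)
        alt = np.array([400, 50, 50, 50, 50])
        r = fisher_exact_2xk(table(cols - alt, alt), mc_cutoff=3000, mc_reps=10_000, seed=1)
        assert r.p < 5e-8

    @given(perm=st.permutations(range(4)))
    @settings(max_examples=24, derandomize=True)
    def test_invariant_to_column_permutation(self, perm):
        ref, alt = [5, 2, 7, 1], [1, 4, 2, 3]
        base = fisher_exact_2xk(table(ref, alt)).p
        permuted = fisher_exact_2xk(table([ref[i] for i in perm], [alt[i] for i in perm])).p
        assert permuted == pytest.approx(base, abs=1e-12)


class TestFst:
    def test_identical_frequencies_give_zero(self):
        comp = fst(table([8, 8, 8], [2, 2, 2]), np.array([5, 5, 5]))
        assert comp.fst == pytest.approx(0.0, abs=1e-12)

    def test_fixed_opposite_clusters_give_one(self):
        comp = fst(table([10, 0], [0, 10]), np.array([5, 5]))
        assert comp.h_s_bar == pytest.approx(0.0, abs=1e-12)
        assert comp.h_t == pytest.approx(0.5, abs=1e-12)
        assert comp.fst == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_two_cluster_value(self):
        # q = (0.2, 0.8), equal sizes: H_S_bar = 0.32, H_T = 0.5, fst = 0.36
        comp = fst(table([8, 2], [2, 8]), np.array([5, 5]))
        assert comp.h_s_bar == pytest.approx(0.32, abs=1e-12)
        assert comp.fst == pytest.approx(0.36, abs=1e-12)

    def test_monomorphic_site_flagged_with_zero(self):
        comp = fst(table([10, 10], [0, 0]), np.array([5, 5]))
        assert comp.fst == 0.0 and comp.monomorphic

    def test_invariant_to_ref_alt_relabeling(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            ref = rng.integers(0, 20, size=4)
            alt = rng.integers(0, 20, size=4)
            if (ref + alt).sum() == 0:
                continue
            sizes = np.maximum((ref + alt) // 2, 1)
            assert fst(table(ref, alt), sizes).fst == pytest.approx(
                fst(table(alt, ref), sizes).fst, abs=1e-12)

    def test_invariant_to_column_permutation(self):
        ref, alt, sizes = [5, 2, 7], [1, 4, 2], np.array([3, 3, 5])
        base = fst(table(ref, alt), sizes).fst
        perm = [2, 0, 1]
        permuted = fst(table([ref[i] for i in perm], [alt[i] for i in perm]),
                       sizes[perm]).fst
        assert permuted == pytest.approx(base, abs=1e-12)

    def test_nondecreasing_in_divergence_of_one_cluster(self):
        # one cluster's alt count grows with totals fixed -> fst never drops
        values = []
        for a in range(10, 41, 5):
            values.append(fst(table([40 - a, 30, 30], [a, 10, 10]),
                              np.array([20, 20, 20])).fst)
        assert np.all(np.diff(values) >= -1e-12)

    def test_zero_size_rejected(self):
        with pytest.raises(ValueError):
            fst(table([1, 1], [1, 1]), np.array([0, 0]))


class TestPoissonRegression:
    def test_matches_newton_oracle_on_random_instances(self):
        rng = np.random.default_rng(14)
        for _ in range(25):
            n = int(rng.integers(30, 120))
            x = rng.random(n)
            slope, intercept = rng.normal(0, 0.8, size=2)
            y = rng.poisson(np.exp(intercept + slope * x))
            y = np.minimum(y, 2)  # genotype-like support
            if np.all(y == 0):
                continue
            fit = poisson_ancestry_regression(y, x, "AFR")
            b0, b1 = poisson_newton(y, x)
            assert fit.converged
            assert fit.intercept == pytest.approx(b0, abs=1e-6)
            assert fit.slope == pytest.approx(b1, abs=1e-6)

    def test_constant_genotype_one_gives_null_fit(self):
        fit = poisson_ancestry_regression(np.ones(50), np.linspace(0, 1, 50), "EUR")
        assert fit.intercept == pytest.approx(0.0, abs=1e-8)
        assert fit.slope == pytest.approx(0.0, abs=1e-8)

    def test_all_zero_genotypes_flagged_unconverged(self):
        fit = poisson_ancestry_regression(np.zeros(50), np.linspace(0, 1, 50), "AME")
        assert not fit.converged and np.isnan(fit.slope)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            poisson_ancestry_regression(np.ones(5), np.linspace(0, 1, 5), "AFR")

    def test_power_to_detect_unit_slope(self):
        rng = np.random.default_rng(15)
        detected = 0
        n_reps = 60
        for _ in range(n_reps):
            x = rng.random(500)
            y = np.minimum(rng.poisson(np.exp(-0.7 + 1.0 * x)), 2)
            fit = poisson_ancestry_regression(y, x, "AFR")
            detected += fit.converged and fit.slope > 0 and fit.wald_p < 0.05
        assert detected > 0.9 * n_reps


class TestDesignation:
    def test_highest_alternate_frequency_wins(self):
        t = table([2, 18, 18, 18, 18], [18, 2, 2, 2, 2], names=list("ABCDE"))
        assert designate_enriched_cluster(t) == "A"

    def test_tie_broken_by_larger_total_then_name(self):
        t = table([5, 50], [5, 50], names=["small", "big"])
        assert designate_enriched_cluster(t) == "big"
        t2 = table([5, 5], [5, 5], names=["b", "a"])
        assert designate_enriched_cluster(t2) == "a"

    def test_single_nonempty_column(self):
        t = table([0, 4], [0, 2], names=["empty", "only"])
        assert designate_enriched_cluster(t) == "only"

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError):
            designate_enriched_cluster(table([0, 0], [0, 0]))


def _toy_screen_inputs():
    """100-site cohort: site 0 strongly enriched in cluster A (alt 0.8 vs
    0.05 elsewhere, 150 diploid samples per cluster), 99 exchangeable null
    sites with identical genotype patterns in every cluster."""
    n_per, k = 150, 5
    names = list("ABCDE")
    rng = np.random.default_rng(16)
    labels = np.repeat(names, n_per)
    n = n_per * k

    strong = np.empty(n, dtype=np.int8)
    for c in range(k):
        freq = 0.8 if c == 0 else 0.05
        block = rng.binomial(2, freq, size=n_per)
        strong[c * n_per: (c + 1) * n_per] = block
    null_block = rng.binomial(2, 0.4, size=n_per).astype(np.int8)
    values = np.column_stack([strong] + [np.tile(null_block, k) for _ in range(99)])

    sites = [VariantKey("1", 1000 + j, "A", "G") for j in range(100)]
    g = GenotypeMatrix(samples=[f"s{i}" for i in range(n)], sites=sites, values=values)
    cohort = union_merge([Dataset("D", "WGS", g)])
    q = QMatrix(samples=cohort.samples,
                q=np.tile([1 / 3, 1 / 3, 1 / 3], (n, 1)))
    clusters = AncestryClusters(
        k=k,
        assignment=np.array([names.index(c) for c in labels]),
        centroids=np.tile([1 / 3, 1 / 3, 1 / 3], (k, 1)),
        names=names,
    )
    return cohort, clusters, q, sites


class TestScreen:
    def test_only_the_constructed_signal_passes_genome_wide(self):
        cohort, clusters, q, sites = _toy_screen_inputs()
        catalog = AnnotationCatalog()
        catalog.set(sites[0], Annotation(clinvar_class="pathogenic_lp",
                                         pharm_level="1A", label="toy"))
        res = screen_genome(cohort, clusters, q, catalog, alpha=5e-8, seed=1)
        assert [r.key for r in res.results] == [sites[0]]
        assert res.results[0].enriched_cluster == "A"
        assert [r.key for r in res.clinical] == [sites[0]]
        assert [r.key for r in res.pharmacogenomic] == [sites[0]]
        assert len(res.results[0].poisson_fits) == 3

    def test_alpha_one_returns_every_testable_site(self):
        cohort, clusters, q, _ = _toy_screen_inputs()
        res = screen_genome(cohort, clusters, q, alpha=1.01, seed=1)
        assert len(res.results) == 100

    def test_results_sorted_by_p(self):
        cohort, clusters, q, _ = _toy_screen_inputs()
        res = screen_genome(cohort, clusters, q, alpha=1.01, seed=1)
        ps = [r.fisher.p for r in res.results]
        assert ps == sorted(ps)

    def test_empty_cohort_returns_empty_result(self):
        cohort, clusters, q, _ = _toy_screen_inputs()
        empty = cohort.subset_sites([])
        res = screen_genome(empty, clusters, q, seed=1)
        assert res.results == [] and res.n_sites_tested == 0
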