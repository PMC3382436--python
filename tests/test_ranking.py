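"""Gene-set ranking statistics, permutation p-values and ranking order."""

import itertools

import numpy as np
import pytest

from setlevel import (
    GeneSet,
    GeneSetCollection,
    SyntheticSpec,
    gene_level_snr,
    generate,
    global_test_statistic,
    gsea_enrichment_score,
    permutation_pvalue,
    rank_gene_sets,
    samgs_statistic,
)
from setlevel.ranking import SNR_CAP, _pvalue_from_null

from conftest import make_dataset


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_es(scores, member_mask, w=1.0):
    """Literal running-sum walk down the phenotype-sorted gene list."""
    order = np.argsort(-scores, kind="stable")
    hits = member_mask[order]
    m = int(hits.sum())
    p = len(scores)
    weights = np.abs(scores[order]) ** w
    total = (weights * hits).sum()
    run, best = 0.0, 0.0
    for t in range(p):
        if hits[t]:
            run += weights[t] / total if total > 0 else 1.0 / m
        else:
            run -= 1.0 / (p - m)
        if abs(run) > abs(best):
            best = run
    return best


def balanced_labelings(n0, n1):
    """All distinct 0/1 labelings with the given class sizes."""
    n = n0 + n1
    for ones in itertools.combinations(range(n), n1):
        y = np.zeros(n, dtype=int)
        y[list(ones)] = 1
        yield y


# ---------------------------------------------------------------------------
# Signal-to-noise ratio
# ---------------------------------------------------------------------------

class TestSnr:
    def test_hand_computed_value(self):
        # class0 (1,3), class1 (0,2): (2-1)/(sd(1,3)+sd(0,2)) = 1/(2*sqrt(2))
        ds = make_dataset([[1, 3, 0, 2]], [0, 0, 1, 1])
        assert gene_level_snr(ds)[0] == pytest.approx(1 / (2 * np.sqrt(2)), abs=1e-10)

    def test_constant_gene_scores_zero(self):
        ds = make_dataset([[5, 5, 5, 5]], [0, 0, 1, 1])
        assert gene_level_snr(ds)[0] == 0.0

    def test_zero_variance_unequal_means_capped(self):
        ds = make_dataset([[2, 2, 0, 0]], [0, 0, 1, 1])
        assert gene_level_snr(ds)[0] == SNR_CAP

    def test_small_class_rejected(self):
        ds = make_dataset([[1, 2, 3]], [0, 1, 1])
        with pytest.raises(ValueError, match="2 samples per class"):
            gene_level_snr(ds)


# ---------------------------------------------------------------------------
# GSEA enrichment score
# ---------------------------------------------------------------------------

class TestGseaEs:
    def test_single_top_gene_scores_one(self):
        ds = make_dataset([[3, 4, 0, 1], [0, 1, 3, 4]], [0, 0, 1, 1])
        # gene 0 has positive SNR -> ranked first
        assert gsea_enrichment_score(ds, GeneSet("T", frozenset({"g0"}))) == 1.0

    def test_single_bottom_gene_scores_minus_one(self):
        ds = make_dataset([[3, 4, 0, 1], [0, 1, 3, 4]], [0, 0, 1, 1])
        assert gsea_enrichment_score(ds, GeneSet("B", frozenset({"g1"}))) == -1.0

    @pytest.mark.parametrize("members", [(0, 3), (0, 1), (2, 3), (1, 2), (0,), (3,)])
    @pytest.mark.parametrize("w", [0.0, 1.0, 2.0])
    def test_matches_exhaustive_walk_oracle(self, members, w):
        # 4 genes engineered to have association scores ~ (2, 1, -1, -2)
        rng = np.random.default_rng(42)
        base = np.array([2.0, 1.0, -1.0, -2.0])
        values = np.outer(base, np.array([1, 1, -1, -1])) + rng.normal(0, 0.05, (4, 4))
        ds = make_dataset(values, [0, 0, 1, 1])
        scores = gene_level_snr(ds)
        mask = np.zeros(4, dtype=bool)
        mask[list(members)] = True
        gs = GeneSet("X", frozenset(f"g{j}" for j in members))
        es = gsea_enrichment_score(ds, gs, weight_exponent=w)
        assert es == pytest.approx(brute_force_es(scores, mask, w), abs=1e-12)

    def test_es_bounded(self):
        ds, coll, _ = generate(SyntheticSpec(p=100, n0=6, n1=6, n_sets=8,
                                             set_size_min=5, set_size_max=8, seed=3))
        for s in coll:
            assert -1.0 <= gsea_enrichment_score(ds, s) <= 1.0

    def test_whole_gene_list_rejected(self):
        ds = make_dataset([[1, 2, 3, 4], [4, 3, 2, 1]], [0, 0, 1, 1])
        with pytest.raises(ValueError, match="proper subset|whole gene list"):
            gsea_enrichment_score(ds, GeneSet("ALL", frozenset({"g0", "g1"})))


# ---------------------------------------------------------------------------
# SAM-GS
# ---------------------------------------------------------------------------

class TestSamGs:
    def test_hand_computed_centroid_distance(self):
        # samples (genes x samples): class0 (0,0),(0,2); class1 (2,0),(2,2)
        values = np.array([[0, 0, 2, 2], [0, 2, 0, 2]], dtype=float)
        ds = make_dataset(values, [0, 0, 1, 1])
        gs = GeneSet("S", frozenset({"g0", "g1"}))
        assert samgs_statistic(ds, gs) == pytest.approx(2.0, abs=1e-12)

    def test_identical_classes_score_zero(self):
        values = np.array([[1, 2, 1, 2], [3, 4, 3, 4]], dtype=float)
        ds = make_dataset(values, [0, 0, 1, 1])
        assert samgs_statistic(ds, GeneSet("S", frozenset({"g0", "g1"}))) == 0.0

    def test_homogeneity_under_scaling(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(5, 8))
        ds1 = make_dataset(values, [0] * 4 + [1] * 4)
        ds2 = make_dataset(2 * values, [0] * 4 + [1] * 4)
        gs = GeneSet("S", frozenset(f"g{j}" for j in range(5)))
        assert samgs_statistic(ds2, gs) == pytest.approx(2 * samgs_statistic(ds1, gs))


# ---------------------------------------------------------------------------
# Global test
# ---------------------------------------------------------------------------

class TestGlobalTest:
    def test_orthogonal_gene_gives_zero(self):
        # standardized gene vector orthogonal to centered labels
        ds = make_dataset([[1, -1, 1, -1]], [0, 0, 1, 1])
        gs = GeneSet("S", frozenset({"g0"}))
        assert global_test_statistic(ds, gs) == pytest.approx(0.0, abs=1e-12)

    def test_aligned_gene_maximal_over_permutations(self):
        ds = make_dataset([[0, 0.2, 1, 1.3]], [0, 0, 1, 1])
        gs = GeneSet("S", frozenset({"g0"}))
        observed = global_test_statistic(ds, gs)
        stats = []
        for y in balanced_labelings(2, 2):
            d = make_dataset(ds.values, y)
            stats.append(global_test_statistic(d, gs))
        assert observed == pytest.approx(max(stats))

    def test_null_statistic_at_mid_quantile_over_exhaustive_permutations(self):
        # class-symmetric noise: observed Q should not be extreme
        rng = np.random.default_rng(7)
        values = rng.normal(size=(3, 4))
        stats = []
        for y in balanced_labelings(2, 2):
            d = make_dataset(values, y)
            stats.append(global_test_statistic(d, GeneSet("S", frozenset({"g0", "g1", "g2"}))))
        observed = stats[0]  # the (0,0,1,1) labeling is one of the six
        rank = sorted(stats).index(observed)
        assert 0 < rank < 5  # strictly inside the permutation distribution

    def test_all_constant_genes_rejected(self):
        ds = make_dataset([[1, 1, 1, 1], [2, 2, 2, 2]], [0, 0, 1, 1])
        with pytest.raises(ValueError, match="constant"):
            global_test_statistic(ds, GeneSet("S", frozenset({"g0", "g1"})))


# ---------------------------------------------------------------------------
# Permutation p-values
# ---------------------------------------------------------------------------

class TestPermutationPvalue:
    def test_add_one_formula(self):
        # observed strictly above all 99 permuted values
        assert _pvalue_from_null("GLOBAL", 10.0, np.zeros(99)) == pytest.approx(0.01)
        # constant statistic: every permutation ties the observation
        assert _pvalue_from_null("GLOBAL", 1.0, np.ones(99)) == 1.0
        # GSEA compares |stat|
        assert _pvalue_from_null("GSEA", -0.9, np.full(99, 0.5)) == pytest.approx(0.01)

    @pytest.mark.parametrize("method", ["GSEA", "SAMGS", "GLOBAL"])
    def test_matches_exhaustive_enumeration_oracle(self, method):
        rng = np.random.default_rng(11)
        values = rng.normal(size=(6, 4))
        values[0, 2:] += 2.0  # mild signal on one member gene
        ds = make_dataset(values, [0, 0, 1, 1])
        gs = GeneSet("S", frozenset({"g0", "g1", "g2"}))
        observed, p = permutation_pvalue(method, ds, gs, n_permutations=1999, seed=5)

        # exact enumeration over the 6 distinct balanced labelings
        def stat(y):
            d = make_dataset(values, y)
            if method == "GSEA":
                return gsea_enrichment_score(d, gs)
            if method == "SAMGS":
                return samgs_statistic(d, gs)
            return global_test_statistic(d, gs)

        null = np.array([stat(y) for y in balanced_labelings(2, 2)])
        if method == "GSEA":
            exact = (np.abs(null) >= abs(observed)).mean()
        else:
            exact = (null >= observed).mean()
        assert p == pytest.approx(exact, abs=0.05)

    def test_deterministic_under_seed(self, tiny_dataset):
        gs = GeneSet("S", frozenset({"g1", "g3"}))
        r1 = permutation_pvalue("SAMGS", tiny_dataset, gs, 99, seed=4)
        r2 = permutation_pvalue("SAMGS", tiny_dataset, gs, 99, seed=4)
        assert r1 == r2


# ---------------------------------------------------------------------------
# Collection ranking
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def planted():
    spec = SyntheticSpec(p=400, n0=20, n1=20, n_sets=2, set_size_min=10,
                         set_size_max=10, n_signal=1, delta=2.0, rho=0.0, seed=9)
    return generate(spec)


class TestRankGeneSets:

    @pytest.mark.parametrize("method", ["GSEA", "SAMGS", "GLOBAL"])
    def test_planted_set_ranked_first(self, planted, method):
        ds, coll, truth = planted
        res = rank_gene_sets(ds, coll, method, n_permutations=199, seed=1)
        assert res.entries[0].name == truth[0]

    def test_single_set_gets_rank_one(self, tiny_dataset):
        coll = GeneSetCollection([GeneSet("ONLY", frozenset({"g1", "g2"}))])
        res = rank_gene_sets(tiny_dataset, coll, "SAMGS", n_permutations=19, seed=0)
        assert [e.rank for e in res.entries] == [1]

    def test_collection_order_invariance(self, planted):
        ds, coll, _ = planted
        shuffled = GeneSetCollection(list(coll)[::-1])
        r1 = rank_gene_sets(ds, coll, "GLOBAL", n_permutations=99, seed=2)
        r2 = rank_gene_sets(ds, shuffled, "GLOBAL", n_permutations=99, seed=2)
        assert [(e.name, e.rank) for e in r1.entries] == [(e.name, e.rank) for e in r2.entries]

    def test_sample_and_gene_reordering_invariance(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(10, 12))
        y = [0] * 6 + [1] * 6
        ds = make_dataset(values, y)
        gs = GeneSet("S", frozenset({"g1", "g4", "g7"}))
        ref = (samgs_statistic(ds, gs), global_test_statistic(ds, gs),
               gsea_enrichment_score(ds, gs))
        perm_s = rng.permutation(12)
        perm_g = rng.permutation(10)
        ds2 = make_dataset(values[np.ix_(perm_g, perm_s)], np.array(y)[perm_s])
        # rename genes to follow the permutation
        ds2.gene_ids = [f"g{j}" for j in perm_g]
        ds2._gene_index = {g: k for k, g in enumerate(ds2.gene_ids)}
        got = (samgs_statistic(ds2, gs), global_test_statistic(ds2, gs),
               gsea_enrichment_score(ds2, gs))
        assert got == pytest.approx(ref, abs=1e-10)

    def test_empty_effective_sets_dropped_with_warning(self, tiny_dataset, caplog):
        coll = GeneSetCollection(
            [GeneSet("OK", frozenset({"g1", "g2"})), GeneSet("GONE", frozenset({"zz"}))]
        )
        with caplog.at_level("WARNING", logger="setlevel"):
            res = rank_gene_sets(tiny_dataset, coll, "SAMGS", n_permutations=19, seed=0)
        assert res.n == 1 and res.entries[0].name == "OK"
        assert any("GONE" in r.message for r in caplog.records)

    def test_nonnegative_statistics(self, planted):
        ds, coll, _ = planted
        for method in ("SAMGS", "GLOBAL"):
            res = rank_gene_sets(ds, coll, method, n_permutations=19, seed=0)
            assert all(e.statistic >= 0 for e in res.entries)

    def test_deterministic(self, planted):
        ds, coll, _ = planted
        r1 = rank_gene_sets(ds, coll, "GSEA", n_permutations=49, seed=8)
        r2 = rank_gene_sets(ds, coll, "GSEA", n_permutations=49, seed=8)
        assert r1.to_json() == r2.to_json()
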