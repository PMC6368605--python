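"""Co-expression networks: correlations, linkage, soft threshold, TOM,
module detection and hypergeometric enrichment, each against an
independent oracle where the spec prescribes one."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import voxgex as vg
from voxgex.datatypes import DonorSampleSet
from voxgex.network import _scale_free_fit


def _donor(expr, donor="d", genes=None):
    expr = np.asarray(expr, float)
    genes = genes or [f"g{i}" for i in range(expr.shape[1])]
    coords = np.tile(np.arange(expr.shape[0], dtype=float)[:, None], (1, 3))
    return DonorSampleSet(donor, coords, expr, genes)


class TestDonorAveragedCorrelation:
    def test_monotone_duplicate_gene_gives_unit_cells(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        donors = [_donor(np.column_stack([x, np.exp(x), rng.normal(size=50)]))]
        cor = vg.donor_averaged_correlation(donors, ["g0", "g1", "g2"])
        assert cor.loc["g0", "g1"] == pytest.approx(1.0)

    def test_independent_genes_near_zero(self):
        """Null bound: averaged |r_s| of independent genes stays small."""
        exceed = 0
        for rep in range(100):
            rng = np.random.default_rng(500 + rep)
            donors = [_donor(rng.normal(size=(500, 2)), donor=f"d{k}")
                      for k in range(3)]
            cor = vg.donor_averaged_correlation(donors, ["g0", "g1"])
            if abs(cor.loc["g0", "g1"]) >= 0.15:
                exceed += 1
        assert exceed <= 1

    def test_planted_modules_separate(self, study):
        truth, _, donors, _ = study
        genes = truth.gene_ids
        cor = vg.donor_averaged_correlation(donors, genes).to_numpy()
        labels = truth.module_labels()
        same = (labels[:, None] == labels[None, :]) & (labels[:, None] != 0)
        np.fill_diagonal(same, False)
        diff = (labels[:, None] != labels[None, :])
        assert cor[same].mean() > cor[diff].mean() + 0.3

    def test_constant_gene_flagged_and_averaged(self):
        rng = np.random.default_rng(2)
        d1 = _donor(np.column_stack([np.ones(30), rng.normal(size=30),
                                     rng.normal(size=30)]), "d1")
        x = rng.normal(size=(30, 3))
        d2 = _donor(x, "d2")
        with pytest.warns(UserWarning):
            cor = vg.donor_averaged_correlation([d1, d2], ["g0", "g1", "g2"])
        r2 = stats.spearmanr(x[:, 0], x[:, 1]).statistic
        assert cor.loc["g0", "g1"] == pytest.approx(r2)


def brute_force_linkage(dist, method, k):
    """Reference agglomeration recomputing inter-cluster distances each step."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    while len(clusters) > k:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            pair_d = [dist[i, j] for i in clusters[a] for j in clusters[b]]
            d = max(pair_d) if method == "complete" else np.mean(pair_d)
            if best is None or d < best[0]:
                best = (d, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(clusters.values()):
        labels[members] = lab
    return labels


def _same_partition(x, y):
    return len(set(zip(x, y))) == len(set(x)) == len(set(y))


class TestCompleteLinkage:
    def test_recovers_perfect_blocks(self):
        cor = np.eye(8)
        cor[:4, :4] = 1.0
        cor[4:, 4:] = 1.0
        labels = vg.complete_linkage_clusters(cor, 2)
        assert _same_partition(labels, [0] * 4 + [1] * 4)

    def test_k_equals_n_gives_singletons(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(6, 6))
        cor = np.corrcoef(a)
        labels = vg.complete_linkage_clusters(cor, 6)
        assert len(set(labels)) == 6

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_agglomeration(self, seed):
        rng = np.random.default_rng(seed)
        cor = np.corrcoef(rng.normal(size=(8, 30)))
        dist = 1.0 - cor
        np.fill_diagonal(dist, 0.0)
        for k in (2, 3, 4):
            ours = vg.complete_linkage_clusters(cor, k)
            ref = brute_force_linkage(dist, "complete", k)
            assert _same_partition(ours, ref)

    def test_k_too_large_errors(self):
        with pytest.raises(ValueError):
            vg.complete_linkage_clusters(np.eye(3), 4)


class TestCorrelationRank:
    def _library(self, seed=0, n=100):
        rng = np.random.default_rng(seed)
        cor = np.corrcoef(rng.normal(size=(n, 60)))
        genes = [f"g{i}" for i in range(n)]
        return pd.DataFrame(cor, index=genes, columns=genes)

    def test_strongest_correlate_is_top_one_percent(self):
        lib = self._library()
        target = lib.loc["g0"].drop("g0").idxmax()
        rank, pct = vg.correlation_rank("g0", target, lib)
        assert rank == 1
        assert pct == pytest.approx(100.0 / 99)

    def test_all_equal_shares_best_rank(self):
        n = 10
        cor = np.full((n, n), 0.5)
        np.fill_diagonal(cor, 1.0)
        genes = [f"g{i}" for i in range(n)]
        lib = pd.DataFrame(cor, index=genes, columns=genes)
        rank, pct = vg.correlation_rank("g0", "g5", lib)
        assert rank == 1

    def test_matches_brute_force_sort(self):
        lib = self._library(seed=3, n=50)
        others = lib.loc["g7"].drop("g7")
        for target in ["g0", "g20", "g49"]:
            rank, _ = vg.correlation_rank("g7", target, lib)
            ref = 1 + sum(v > others[target] for v in others)
            assert rank == ref

    def test_monotone_invariance(self):
        """Rank is unchanged by a strictly monotone transform of all
        expression values (Spearman correlations are)."""
        rng = np.random.default_rng(6)
        expr = rng.normal(size=(80, 12))
        genes = [f"g{i}" for i in range(12)]
        d1 = _donor(expr, genes=genes)
        d2 = _donor(np.exp(expr / 3), genes=genes)
        c1 = vg.donor_averaged_correlation([d1], genes)
        c2 = vg.donor_averaged_correlation([d2], genes)
        for target in genes[1:]:
            assert (vg.correlation_rank("g0", target, c1)
                    == vg.correlation_rank("g0", target, c2))

    def test_missing_gene_errors(self):
        lib = self._library(n=10)
        with pytest.raises(KeyError):
            vg.correlation_rank("g0", "nope", lib)


class TestSoftThreshold:
    def test_preferential_attachment_network_fits(self):
        """At beta = 1 the degree sequence of a preferential-attachment
        graph satisfies the scale-free criterion (R^2 >= 0.8)."""
        import networkx as nx
        g = nx.barabasi_albert_graph(2000, 1, seed=4)
        adj = nx.to_numpy_array(g)
        cor = adj.copy()
        np.fill_diagonal(cor, 1.0)
        beta, table = vg.select_soft_threshold(cor, [1])
        assert table["r_squared"].iloc[0] >= 0.8

    def test_constant_offdiagonal_degenerate(self):
        cor = np.full((10, 10), 0.5)
        np.fill_diagonal(cor, 1.0)
        beta, table = vg.select_soft_threshold(cor, [1, 2])
        assert table["r_squared"].isna().all()
        assert table.attrs["reached_target"] is False

    def test_mean_connectivity_nonincreasing_in_power(self, study):
        truth, _, donors, _ = study
        cor = vg.donor_averaged_correlation(donors, truth.gene_ids)
        _, table = vg.select_soft_threshold(cor, list(range(1, 13)))
        k = table["mean_connectivity"].to_numpy()
        assert (np.diff(k) <= 1e-12).all()

    def test_smallest_power_reaching_target_selected(self):
        import networkx as nx
        g = nx.barabasi_albert_graph(1500, 1, seed=9)
        cor = nx.to_numpy_array(g)
        np.fill_diagonal(cor, 1.0)
        beta, table = vg.select_soft_threshold(cor, [1, 2, 3])
        reached = table[table["r_squared"] >= 0.8]
        assert beta == reached["power"].iloc[0]


def brute_force_tom(a):
    """Hand-unrolled triple loop TOM."""
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            ell = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (ell + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestTOM:
    def test_complete_graph_gives_ones(self):
        n = 5
        a = np.ones((n, n))
        tom = vg.tom_similarity(a)
        np.testing.assert_allclose(tom, 1.0)

    def test_disconnected_pair_is_zero(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 0.0
        a[2, 3] = a[3, 2] = 0.9
        tom = vg.tom_similarity(a)
        assert tom[0, 2] == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, size=(6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        tom = vg.tom_similarity(a)
        np.testing.assert_allclose(tom, brute_force_tom(a), atol=1e-12)

    def test_bounds_and_symmetry(self, study):
        truth, _, donors, _ = study
        cor = vg.donor_averaged_correlation(donors, truth.gene_ids)
        adj = np.abs(cor.to_numpy()) ** 6
        np.fill_diagonal(adj, 0.0)
        tom = vg.tom_similarity(adj)
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            vg.tom_similarity(np.array([[0.0, 1.5], [1.5, 0.0]]))


class TestDetectModules:
    def test_planted_modules_recovered(self, study):
        from sklearn.metrics import adjusted_rand_score
        truth, _, donors, _ = study
        net = vg.build_network(donors, truth.gene_ids, cut_height=0.97,
                               min_module_size=4)
        planted = truth.module_labels()
        detected = net.module_labels
        # score only the planted-module genes (background is noise)
        sel = planted != 0
        assert adjusted_rand_score(planted[sel], detected[sel]) == 1.0

    def test_cut_height_near_one_gives_single_module(self, study):
        truth, _, donors, _ = study
        cor = vg.donor_averaged_correlation(donors, truth.gene_ids)
        adj = np.abs(cor.to_numpy()) ** 6
        np.fill_diagonal(adj, 0.0)
        tom = vg.tom_similarity(adj)
        labels = vg.detect_modules(tom, cut_height=1 - 1e-9, min_module_size=3)
        assert len(set(labels)) == 1 and labels[0] == 1

    def test_oversized_min_module_all_background(self, study):
        truth, _, donors, _ = study
        cor = vg.donor_averaged_correlation(donors, truth.gene_ids)
        adj = np.abs(cor.to_numpy()) ** 6
        np.fill_diagonal(adj, 0.0)
        tom = vg.tom_similarity(adj)
        labels = vg.detect_modules(tom, 0.5, min_module_size=len(labels_hint := truth.gene_ids) + 1)
        assert (labels == 0).all()


def exact_hypergeom_tail(N, K, n, k):
    """P(X >= k) by exact rational combinatorics."""
    total = Fraction(0)
    for kk in range(k, min(K, n) + 1):
        total += Fraction(comb(K, kk) * comb(N - K, n - kk), comb(N, n))
    return float(total)


class TestHypergeometricEnrichment:
    def _bg(self, n):
        return [f"g{i}" for i in range(n)]

    def test_query_identical_to_set(self):
        bg = self._bg(100)
        q = bg[:5]
        res = vg.hypergeometric_enrichment(q, {"s": bg[:5]}, bg)[0]
        assert res.p_hypergeom == pytest.approx(1 / comb(100, 5), rel=1e-12)

    def test_empty_set_gives_p_one(self):
        bg = self._bg(20)
        res = vg.hypergeometric_enrichment(bg[:4], {"s": []}, bg)[0]
        assert res.p_hypergeom == 1.0

    def test_matches_full_enumeration(self):
        """N=20, K=8, n=6, k=4 by exhaustive enumeration of all draws."""
        bg = self._bg(20)
        annotated = set(bg[:8])
        query = bg[4:10]  # overlap = 4
        res = vg.hypergeometric_enrichment(query, {"s": annotated}, bg)[0]
        assert res.overlap_count == 4
        hits = 0
        total = 0
        for draw in itertools.combinations(range(20), 6):
            total += 1
            if len(set(draw) & set(range(8))) >= 4:
                hits += 1
        assert res.p_hypergeom == pytest.approx(hits / total, rel=1e-12)

    @pytest.mark.parametrize("N,K,n,k", [(15, 5, 4, 2), (20, 8, 6, 4),
                                         (12, 6, 6, 6)])
    def test_matches_exact_rational_tail(self, N, K, n, k):
        bg = self._bg(N)
        annotated = bg[:K]
        query = bg[K - k:K - k + n]
        res = vg.hypergeometric_enrichment(query, {"s": annotated}, bg)[0]
        assert res.overlap_count == k
        assert res.p_hypergeom == pytest.approx(
            exact_hypergeom_tail(N, K, n, k), abs=1e-12)

    def test_query_outside_background_errors(self):
        with pytest.raises(ValueError):
            vg.hypergeometric_enrichment(["x"], {"s": ["g0"]}, self._bg(5))


class TestUtilities:
    def test_select_probes_keeps_highest_ds(self):
        table = pd.DataFrame({
            "gene_id": ["A", "A", "B"],
            "probe_id": ["p1", "p2", "p3"],
            "ds": [0.2, 0.9, 0.5],
        })
        out = vg.select_probes(table)
        assert list(out["probe_id"]) == ["p2", "p3"]

    def test_differential_expression_sets_filters(self):
        table = pd.DataFrame({
            "tissue": ["brain", "brain", "liver"],
            "gene_id": ["A", "B", "A"],
            "p_bonferroni": [0.01, 0.2, 0.04],
            "log_fold_change": [1.0, 2.0, 0.3],
        })
        sets = vg.differential_expression_sets(table)
        assert sets == {"brain": {"A"}}
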