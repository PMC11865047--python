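"""QC, normalization, batch correction, clustering and the ARI."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from mucinsig import preprocess as pp

from conftest import toy_counts


# ---------------------------------------------------------------------------
# adjusted Rand index
# ---------------------------------------------------------------------------

def ari_pair_counting_oracle(a, b):
    """Brute-force ARI from agreeing/disagreeing item pairs."""
    a, b = list(a), list(b)
    n = len(a)
    n11 = n10 = n01 = n00 = 0
    for i in range(n):
        for j in range(i + 1, n):
            sa, sb = a[i] == a[j], b[i] == b[j]
            n11 += sa and sb
            n10 += sa and not sb
            n01 += sb and not sa
            n00 += not sa and not sb
    num = 2.0 * (n11 * n00 - n10 * n01)
    den = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    return 1.0 if den == 0 else num / den


def set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def partition_to_labels(part, n):
    lab = [0] * n
    for k, block in enumerate(part):
        for item in block:
            lab[item] = k
    return lab


class TestAdjustedRandIndex:
    def test_identical_labelings(self):
        assert pp.adjusted_rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0

    def test_crossed_pairs_give_minus_half(self):
        assert pp.adjusted_rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == \
            pytest.approx(-0.5)

    def test_single_cluster_vs_split_gives_zero(self):
        assert pp.adjusted_rand_index([0, 0, 0, 0], [1, 1, 2, 2]) == \
            pytest.approx(0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pp.adjusted_rand_index([1, 2], [1, 2, 3])

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_matches_pair_counting_oracle_exhaustively(self, n):
        parts = [partition_to_labels(p, n)
                 for p in set_partitions(list(range(n)))]
        for la in parts:
            for lb in parts:
                assert pp.adjusted_rand_index(la, lb) == \
                    pytest.approx(ari_pair_counting_oracle(la, lb))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 3), min_size=2, max_size=30))
    def test_matches_sklearn_on_random_labelings(self, labels):
        rng = np.random.default_rng(len(labels))
        other = rng.integers(0, 3, size=len(labels))
        assert pp.adjusted_rand_index(labels, other) == \
            pytest.approx(adjusted_rand_score(labels, other))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

class TestQC:
    GENES = ["MT-ND1", "G1", "G2", "G3", "G4"]

    def toy(self):
        # c0: zero counts; c1: mito fraction 0.5; c2/c3: clean;
        # c4: only one gene detected
        M = np.array([[0, 0, 0, 0, 0],
                      [5, 2, 3, 0, 0],
                      [1, 10, 10, 10, 10],
                      [0, 8, 9, 7, 6],
                      [0, 12, 0, 0, 0]])
        return toy_counts(M, self.GENES)

    def test_toy_survivors_match_hand_enumeration(self):
        params = pp.PipelineParams(min_genes_per_cell=2, max_mito_frac=0.2,
                                   doublet_quantile=0.0)
        out = pp.qc_filter_cells(self.toy(), params)
        assert list(out.cell_ids) == ["c2", "c3"]

    def test_zero_count_cell_removed(self):
        params = pp.PipelineParams(min_genes_per_cell=1, max_mito_frac=0.99)
        out = pp.qc_filter_cells(self.toy(), params)
        assert "c0" not in out.cell_ids

    def test_no_threshold_binding_is_identity(self):
        counts = self.toy().subset_cells([True, True, True, True, True])
        params = pp.PipelineParams(min_genes_per_cell=1, max_mito_frac=0.99,
                                   doublet_quantile=0.0)
        out = pp.qc_filter_cells(counts, params)
        assert list(out.cell_ids) == ["c1", "c2", "c3", "c4"]

    def test_all_cells_removed_names_binding_threshold(self):
        params = pp.PipelineParams(min_genes_per_cell=100)
        with pytest.raises(ValueError, match="min_genes_per_cell"):
            pp.qc_filter_cells(self.toy(), params)

    def test_idempotent_at_default_params(self, small_cohort):
        _, counts, _, _ = small_cohort
        params = pp.PipelineParams(min_genes_per_cell=50)
        once = pp.qc_filter_cells(counts, params)
        twice = pp.qc_filter_cells(once, params)
        assert list(once.cell_ids) == list(twice.cell_ids)

    def test_doublet_score_flags_synthetic_doublets(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(5.0, size=(40, 60))
        b = rng.poisson(np.linspace(0.5, 12, 60), size=(40, 60))
        singlets = np.vstack([a, b])
        pairs = rng.choice(80, size=(10, 2))
        doublets = singlets[pairs[:, 0]] + singlets[pairs[:, 1]]
        counts = toy_counts(np.vstack([singlets, doublets]),
                            [f"G{i}" for i in range(60)])
        scores = pp.doublet_scores(counts, random_state=1)
        assert scores[80:].mean() > scores[:80].mean()


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class TestNormalize:
    def test_log_layer_closed_form(self):
        counts = toy_counts([[3, 9997], [5000, 5000]], ["GA", "GB"])
        expr = pp.normalize_and_scale(counts)
        assert expr.matrix[0, 0] == pytest.approx(np.log1p(3.0))
        assert expr.matrix[1, 0] == pytest.approx(np.log1p(5000.0))

    def test_zero_count_gives_zero_log_value(self):
        counts = toy_counts([[0, 10], [5, 5]], ["GA", "GB"])
        expr = pp.normalize_and_scale(counts)
        assert expr.matrix[0, 0] == 0.0

    def test_doubling_counts_leaves_log_layer_unchanged(self):
        rng = np.random.default_rng(0)
        M = rng.poisson(3.0, size=(20, 30))
        e1 = pp.normalize_and_scale(toy_counts(M, [f"G{i}" for i in range(30)]))
        e2 = pp.normalize_and_scale(toy_counts(2 * M,
                                               [f"G{i}" for i in range(30)]))
        np.testing.assert_allclose(e1.matrix, e2.matrix)

    def test_equal_depth_scaled_layer_is_zscore(self):
        rng = np.random.default_rng(1)
        M = rng.integers(0, 9, size=(30, 9))
        pad = M.sum(axis=1).max() - M.sum(axis=1)    # equalize cell depths
        M = np.column_stack([M, pad])
        counts = toy_counts(M, [f"G{i}" for i in range(10)])
        expr = pp.normalize_and_scale(counts)
        L = expr.matrix
        z = (L - L.mean(axis=0)) / np.where(L.std(axis=0) > 0,
                                            L.std(axis=0), 1.0)
        np.testing.assert_allclose(expr.scaled, z, atol=1e-8)

    def test_constant_gene_scales_to_zero(self):
        M = np.array([[5, 5], [5, 5], [5, 5]])
        expr = pp.normalize_and_scale(toy_counts(M, ["GA", "GB"]))
        assert np.all(expr.scaled == 0)


# ---------------------------------------------------------------------------
# batch correction
# ---------------------------------------------------------------------------

class TestCorrectBatch:
    def test_single_batch_is_identity(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 5))
        out = pp.correct_batch(X, ["b1"] * 50)
        np.testing.assert_array_equal(out, X)

    def test_constant_shift_removed_exactly_with_one_cluster(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(300, 6))
        delta = np.array([3.0, -1.0, 2.0, 0.5, 0.0, -4.0])
        emb = np.vstack([X, X + delta])
        batches = ["a"] * 300 + ["b"] * 300
        corrected = pp.correct_batch(emb, batches, n_soft_clusters=1)
        gap = corrected[:300].mean(axis=0) - corrected[300:].mean(axis=0)
        assert np.abs(gap).max() < 1e-6

    def test_mixing_improves_and_lineages_survive(self):
        # planted 3-blob, 2-batch embedding in a PC-like geometry: batch
        # shift smaller than lineage separation, isotropic noise
        rng = np.random.default_rng(2)
        d = 10
        centers = np.zeros((3, d))
        centers[0, 0] = centers[1, 1] = centers[2, 2] = 12.0
        lin = rng.integers(0, 3, size=600)
        X = centers[lin] + rng.normal(scale=2.0, size=(600, d))
        batches = np.where(np.arange(600) % 2 == 0, "a", "b")
        shift = np.zeros(d)
        shift[3] = 5.0
        X[batches == "b"] += shift
        corrected = pp.correct_batch(X, batches, random_state=0)
        for k in range(3):
            gap = (corrected[(lin == k) & (batches == "a")].mean(axis=0)
                   - corrected[(lin == k) & (batches == "b")].mean(axis=0))
            assert np.linalg.norm(gap) < 1.0
        # lineage centroids remain separated
        cents = np.stack([corrected[lin == k].mean(axis=0) for k in range(3)])
        assert np.linalg.norm(cents[0] - cents[1]) > 8


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _blob_expr(seed=0, n=150, sep=8.0):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(n, 30))
    B = rng.normal(size=(n, 30)) + sep
    scaled = np.vstack([A, B])
    meta = pd.DataFrame({"sample_id": "s", "patient": "p",
                         "condition": "normal", "site": "x", "batch": "b"},
                        index=[f"c{i}" for i in range(2 * n)])
    return pp.LogExpression(scaled, scaled, meta,
                            pd.Index([f"G{i}" for i in range(30)]),
                            np.ones(2 * n))


class TestClustering:
    def test_two_separated_blobs_recovered_exactly(self):
        expr = _blob_expr()
        labels = np.array([0] * 150 + [1] * 150)
        cl = pp.embed_and_cluster(expr)
        assert pp.adjusted_rand_index(cl.labels.to_numpy(), labels) == 1.0

    def test_cell_order_permutation_gives_same_partition(self):
        expr = _blob_expr()
        cl1 = pp.embed_and_cluster(expr)
        rng = np.random.default_rng(3)
        perm = rng.permutation(300)
        expr_p = pp.LogExpression(expr.matrix[perm], expr.scaled[perm],
                                  expr.cell_meta.iloc[perm],
                                  expr.gene_ids, expr.totals[perm])
        cl2 = pp.embed_and_cluster(expr_p)
        assert pp.adjusted_rand_index(
            cl1.labels.to_numpy()[perm], cl2.labels.to_numpy()) == 1.0

    def test_lower_resolution_never_more_clusters(self):
        expr = _blob_expr()
        hi = pp.embed_and_cluster(expr, pp.PipelineParams())
        lo = pp.embed_and_cluster(
            expr, pp.PipelineParams(cluster_resolution=0.1))
        assert lo.labels.nunique() <= hi.labels.nunique()

    def test_rank_reduced_when_few_cells(self):
        expr = _blob_expr(n=8)
        cl = pp.embed_and_cluster(expr)
        assert cl.embedding.shape[1] < 20

    def test_cluster_ids_contiguous_from_zero(self, small_cohort):
        _, counts, _, _ = small_cohort
        _, clusters, _ = pp.cluster_pipeline(counts)
        uniq = np.unique(clusters.labels.to_numpy())
        assert np.array_equal(uniq, np.arange(len(uniq)))
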