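"""Quality control, normalization, batch-aware embedding and clustering.

The entry object is a sparse cells x genes count matrix with per-cell study
metadata (sample, patient, condition, anatomic site, experimental batch).
Cells are QC-filtered, counts are normalized to log counts-per-10k, a
depth-regressed scaled layer feeds PCA, a soft-k-means batch correction
removes per-batch centroid offsets in PC space, and a shared-nearest-neighbor
graph is partitioned by modularity (Leiden) at a fixed resolution.  The
Adjusted Rand Index quantifies batch mixing of the resulting clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import comb
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger("mucinsig")

#: columns every per-cell metadata table must carry
META_COLUMNS = ("sample_id", "patient", "condition", "site", "batch")

#: prefixes identifying mitochondrial and ribosomal genes
MITO_PREFIX = "MT-"
RIBO_PREFIXES = ("RPS", "RPL")

#: value cap for the scaled (z-scored residual) expression layer
SCALE_CAP = 10.0


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class PipelineParams:
    """Tunable constants for the whole pipeline.

    The clustering, differential-expression and filtering defaults are the
    analysis constants of the study design this package reproduces: 20
    principal components, Leiden resolution 1.0, Wilcoxon DE at |log2FC| >=
    0.5 with min.pct 0.25 and Bonferroni alpha 0.05, 10 Mb CNV windows,
    per-sample epithelial cellularity floor of 10 cells, per-site tumor
    cellularity floor of 20 cells, and a 2.0-fold decoy log-p confidence
    factor for proteomics.
    """

    min_genes_per_cell: int = 200
    max_mito_frac: float = 0.2
    doublet_quantile: float = 0.0
    n_pcs: int = 20
    cluster_resolution: float = 1.0
    de_log2fc: float = 0.5
    de_min_pct: float = 0.25
    de_alpha: float = 0.05
    window_mb: float = 10.0
    min_cells_sample: int = 10
    min_cells_site: int = 20
    decoy_factor: float = 2.0
    min_genes_per_window: int = 5
    random_state: int = 0

    def validate(self) -> None:
        for name in ("min_genes_per_cell", "n_pcs", "cluster_resolution",
                     "de_log2fc", "de_min_pct", "de_alpha", "window_mb",
                     "min_cells_sample", "min_cells_site", "decoy_factor",
                     "min_genes_per_window", "max_mito_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PipelineParams.{name} must be positive")
        if not 0.0 <= self.doublet_quantile < 1.0:
            raise ValueError("doublet_quantile must be in [0, 1)")

    def replace(self, **kw) -> "PipelineParams":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Sparse cells x genes integer counts plus per-cell study metadata."""

    matrix: sp.csr_matrix
    cell_meta: pd.DataFrame
    gene_ids: pd.Index

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.gene_ids = pd.Index(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def cell_ids(self) -> pd.Index:
        return self.cell_meta.index

    def validate(self) -> None:
        if self.matrix.shape != (len(self.cell_meta), len(self.gene_ids)):
            raise ValueError("matrix shape does not match metadata/genes")
        if not self.gene_ids.is_unique:
            raise ValueError("gene_ids must be unique")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.matrix.nnz and np.any(self.matrix.data != np.round(self.matrix.data)):
            raise ValueError("counts must be integral")
        missing = [c for c in META_COLUMNS if c not in self.cell_meta.columns]
        if missing:
            raise ValueError(f"cell_meta missing columns {missing}")
        if self.cell_meta[list(META_COLUMNS)].isna().any().any():
            raise ValueError("cell_meta contains missing values")

    def subset_cells(self, mask_or_ids) -> "CountMatrix":
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        else:
            idx = self.cell_meta.index.get_indexer(arr)
        return CountMatrix(self.matrix[idx], self.cell_meta.iloc[idx].copy(),
                           self.gene_ids)


@dataclass
class LogExpression:
    """Normalized expression: a log layer and a depth-regressed scaled layer.

    ``matrix`` holds log1p(1e4 * count / cell_total); ``scaled`` holds
    per-gene residuals of the log values regressed on total counts,
    standardized to unit variance and capped at +/-SCALE_CAP.
    """

    matrix: np.ndarray
    scaled: np.ndarray
    cell_meta: pd.DataFrame
    gene_ids: pd.Index
    totals: np.ndarray

    @property
    def cell_ids(self) -> pd.Index:
        return self.cell_meta.index

    def gene_column(self, gene: str) -> np.ndarray:
        j = self.gene_ids.get_loc(gene)
        return self.matrix[:, j]


@dataclass
class ClusterLabels:
    labels: pd.Series                 # per-cell integer cluster id
    embedding: np.ndarray             # cells x n_pcs

    def __post_init__(self) -> None:
        uniq = np.unique(self.labels.to_numpy())
        if len(uniq) and not np.array_equal(uniq, np.arange(len(uniq))):
            remap = {old: new for new, old in enumerate(uniq)}
            self.labels = self.labels.map(remap)


# ---------------------------------------------------------------------------
# adjusted Rand index
# ---------------------------------------------------------------------------

def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected partition agreement from the pair-counting formula.

    ARI = (index - expected) / (max_index - expected) over the contingency
    table of the two labelings; 1 for identical partitions, ~0 under
    independence.  Raises on length mismatch.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ct = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(ct, (ai, bi), 1)
    n = a.size
    sum_ij = comb(ct, 2).sum()
    sum_a = comb(ct.sum(axis=1), 2).sum()
    sum_b = comb(ct.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:          # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def doublet_scores(counts: CountMatrix, n_doublets: int | None = None,
                   random_state: int = 0) -> np.ndarray:
    """Similarity of each cell to synthetic cell-pair averages.

    Synthetic doublets are sums of seeded random cell pairs; each cell's
    score is its maximal Pearson correlation (on log CP10K profiles) to any
    synthetic doublet.  A stand-in for dedicated doublet callers.
    """
    n = counts.n_cells
    if n < 4:
        return np.zeros(n)
    rng = np.random.default_rng(random_state)
    n_doublets = n_doublets or min(200, n)
    pairs = np.stack([rng.choice(n, size=n_doublets),
                      rng.choice(n, size=n_doublets)], axis=1)
    X = counts.matrix.toarray().astype(float)
    doublets = X[pairs[:, 0]] + X[pairs[:, 1]]

    def lognorm(M):
        tot = M.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        return np.log1p(1e4 * M / tot)

    A = lognorm(X)
    B = lognorm(doublets)
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    A /= np.maximum(np.linalg.norm(A, axis=1, keepdims=True), 1e-12)
    B /= np.maximum(np.linalg.norm(B, axis=1, keepdims=True), 1e-12)
    return (A @ B.T).max(axis=1)


def qc_filter_cells(counts: CountMatrix,
                    params: PipelineParams | None = None) -> CountMatrix:
    """Drop low-quality cells and putative doublets.

    Removes cells with fewer detected genes than ``min_genes_per_cell``,
    mitochondrial fraction (genes prefixed ``MT-``) above ``max_mito_frac``,
    and the top ``doublet_quantile`` fraction by doublet score.  Logs the
    number removed per criterion; raises if nothing survives.
    """
    params = params or PipelineParams()
    params.validate()
    counts.validate()
    X = counts.matrix
    genes_detected = np.asarray((X > 0).sum(axis=1)).ravel()
    totals = np.asarray(X.sum(axis=1)).ravel().astype(float)
    mito = np.array([g.startswith(MITO_PREFIX) for g in counts.gene_ids])
    mito_counts = (np.asarray(X[:, mito].sum(axis=1)).ravel()
                   if mito.any() else np.zeros(counts.n_cells))
    mito_frac = np.divide(mito_counts, totals, out=np.zeros_like(totals),
                          where=totals > 0)

    low_genes = genes_detected < params.min_genes_per_cell
    high_mito = mito_frac > params.max_mito_frac
    if params.doublet_quantile > 0:
        scores = doublet_scores(counts, random_state=params.random_state)
        cutoff = np.quantile(scores, 1.0 - params.doublet_quantile)
        doublet = scores > cutoff
    else:
        doublet = np.zeros(counts.n_cells, dtype=bool)

    keep = ~(low_genes | high_mito | doublet)
    logger.info("QC: removed %d low-gene, %d high-mito, %d doublet of %d cells",
                int(low_genes.sum()), int(high_mito.sum()),
                int(doublet.sum()), counts.n_cells)
    if not keep.any():
        binding = ("min_genes_per_cell" if low_genes.all() else
                   "max_mito_frac" if high_mito.all() else "doublet_quantile")
        raise ValueError(f"QC removed all cells; binding threshold: {binding}")
    return counts.subset_cells(keep)


# ---------------------------------------------------------------------------
# normalization / scaling
# ---------------------------------------------------------------------------

def normalize_and_scale(counts: CountMatrix) -> LogExpression:
    """log CP10K normalization plus depth-regressed, capped z-scores.

    The log layer is log1p(1e4 * c / total).  The scaled layer regresses each
    gene's log values on total cell counts (ordinary least squares),
    standardizes the residuals, and caps them at +/-SCALE_CAP; genes with
    zero residual variance scale to 0.
    """
    X = counts.matrix.toarray().astype(np.float64)
    totals = X.sum(axis=1)
    safe = np.where(totals > 0, totals, 1.0)
    log_layer = np.log1p(1e4 * X / safe[:, None])

    # residual of each gene on centered depth: slope via shared covariate
    d = totals - totals.mean()
    denom = float(d @ d)
    if denom > 0:
        slopes = (d @ log_layer) / denom
        resid = log_layer - log_layer.mean(axis=0) - np.outer(d, slopes)
    else:
        resid = log_layer - log_layer.mean(axis=0)
    sd = resid.std(axis=0)
    scaled = np.divide(resid, sd, out=np.zeros_like(resid), where=sd > 0)
    np.clip(scaled, -SCALE_CAP, SCALE_CAP, out=scaled)
    return LogExpression(log_layer, scaled, counts.cell_meta.copy(),
                         counts.gene_ids, totals)


# ---------------------------------------------------------------------------
# embedding + batch correction
# ---------------------------------------------------------------------------

def pca_embed(scaled: np.ndarray, n_pcs: int = 20,
              random_state: int = 0) -> np.ndarray:
    n_pcs_eff = min(n_pcs, scaled.shape[0] - 1, scaled.shape[1])
    if n_pcs_eff < n_pcs:
        logger.warning("reducing PCA rank from %d to %d", n_pcs, n_pcs_eff)
    pca = PCA(n_components=n_pcs_eff, svd_solver="full",
              random_state=random_state)
    return pca.fit_transform(scaled)


def correct_batch(embedding: np.ndarray, batches,
                  n_soft_clusters: int = 10, sigma: float = 0.5,
                  diversity_strength: float = 2.0,
                  max_iter: int = 30, tol: float = 1e-6,
                  random_state: int = 0) -> np.ndarray:
    """Soft-k-means batch correction of a PC embedding.

    Each iteration fits soft k-means responsibilities in the current
    embedding -- reweighted by a batch-diversity penalty that favors
    clusters in which a cell's batch is under-represented, so equivalent
    populations from different batches share clusters -- then moves every
    cell by the responsibility-weighted offset between its batch's
    per-cluster centroid and the global cluster centroid.  With a single
    batch the input is returned unchanged.  The contract is that batch
    mixing improves while planted biological separation is preserved.
    """
    batches = np.asarray(batches)
    if embedding.shape[0] != batches.shape[0]:
        raise ValueError("embedding and batch labels length mismatch")
    uniq = np.unique(batches)
    if len(uniq) < 2:
        logger.info("single batch; batch correction is a no-op")
        return embedding.copy()

    rng = np.random.default_rng(random_state)
    X = embedding.astype(np.float64).copy()
    n = X.shape[0]
    K = max(1, min(n_soft_clusters, n // 5))
    centroids = X[rng.choice(n, size=K, replace=False)]
    batch_idx = np.searchsorted(uniq, batches)
    pi_b = np.bincount(batch_idx, minlength=len(uniq)) / n

    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        scale = sigma * max(d2.min(axis=1).mean(), 1e-12)
        base = -d2 / scale

        def _softmax(logits):
            logits = logits - logits.max(axis=1, keepdims=True)
            R = np.exp(logits)
            return R / R.sum(axis=1, keepdims=True)

        R = _softmax(base)
        if K > 1:
            # incremental block updates keep the diversity penalty stable
            # (full recomputation oscillates between batch-pure states)
            O = np.zeros((len(uniq), K))
            np.add.at(O, batch_idx, R)
            Nk = R.sum(axis=0)
            order = rng.permutation(n)
            block = max(1, n // 20)
            for _ in range(3):
                for start in range(0, n, block):
                    rows = order[start:start + block]
                    np.add.at(O, batch_idx[rows], -R[rows])
                    Nk -= R[rows].sum(axis=0)
                    E = pi_b[:, None] * Nk[None, :]
                    penalty = diversity_strength * (np.log(E + 1.0)
                                                    - np.log(O + 1.0))
                    R[rows] = _softmax(base[rows] + penalty[batch_idx[rows]])
                    np.add.at(O, batch_idx[rows], R[rows])
                    Nk += R[rows].sum(axis=0)

        wsum = R.sum(axis=0)
        mu = (R.T @ X) / np.maximum(wsum, 1e-12)[:, None]
        shift = np.zeros_like(X)
        for b in uniq:
            mask = batches == b
            wb = R[mask].sum(axis=0)
            ok = wb > 1e-8
            mu_b = np.zeros_like(mu)
            mu_b[ok] = (R[mask].T @ X[mask])[ok] / wb[ok, None]
            mu_b[~ok] = mu[~ok]
            shift[mask] = R[mask] @ (mu_b - mu)
        X -= shift
        centroids = (R.T @ X) / np.maximum(wsum, 1e-12)[:, None]
        if np.abs(shift).max() < tol:
            break
    return X


# ---------------------------------------------------------------------------
# graph clustering
# ---------------------------------------------------------------------------

def _snn_graph(embedding: np.ndarray, n_neighbors: int = 15,
               prune: float | None = None):
    """Shared-nearest-neighbor graph with Jaccard edge weights."""
    n = embedding.shape[0]
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    A = nn.kneighbors_graph(embedding, mode="connectivity")  # includes self
    S = (A @ A.T).tocoo()                                    # shared-neighbor counts
    union = (2 * (k + 1)) - S.data
    jacc = S.data / union
    keep = jacc >= (prune if prune is not None else 1.0 / 15.0)
    rows, cols, w = S.row[keep], S.col[keep], jacc[keep]
    off = rows < cols
    return rows[off], cols[off], w[off], n


def embed_and_cluster(expr: LogExpression, params: PipelineParams | None = None,
                      embedding: np.ndarray | None = None,
                      n_neighbors: int = 15) -> ClusterLabels:
    """PCA + SNN graph + Leiden modularity clustering at fixed resolution.

    A precomputed (e.g. batch-corrected) embedding may be supplied; otherwise
    PCA on the scaled layer is used.  Deterministic given the seed in
    ``params.random_state``; modularity ties are broken by the seeded
    optimizer order.
    """
    params = params or PipelineParams()
    params.validate()
    if embedding is None:
        embedding = pca_embed(expr.scaled, params.n_pcs, params.random_state)
    rows, cols, w, n = _snn_graph(embedding, n_neighbors=n_neighbors)
    g = ig.Graph(n=n, edges=list(zip(rows.tolist(), cols.tolist())))
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights=w.tolist(), resolution_parameter=params.cluster_resolution,
        seed=params.random_state, n_iterations=5)
    labels = pd.Series(part.membership, index=expr.cell_ids, name="cluster")
    return ClusterLabels(labels=labels, embedding=embedding)


def cluster_pipeline(counts: CountMatrix,
                     params: PipelineParams | None = None,
                     batch_correct: bool = True):
    """QC -> normalize -> PCA -> batch correction -> clustering.

    Returns ``(expr, clusters, report)`` where report carries the ARI of the
    cluster labels against the experimental batch labels (the batch-mixing
    diagnostic; low is well mixed).
    """
    params = params or PipelineParams()
    filtered = qc_filter_cells(counts, params)
    expr = normalize_and_scale(filtered)
    emb = pca_embed(expr.scaled, params.n_pcs, params.random_state)
    if batch_correct:
        emb = correct_batch(emb, expr.cell_meta["batch"].to_numpy(),
                            random_state=params.random_state)
    clusters = embed_and_cluster(expr, params, embedding=emb)
    report = {
        "n_cells": int(expr.matrix.shape[0]),
        "n_clusters": int(clusters.labels.nunique()),
        "ari_cluster_vs_batch": adjusted_rand_index(
            clusters.labels.to_numpy(), expr.cell_meta["batch"].to_numpy()),
    }
    return expr, clusters, report
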