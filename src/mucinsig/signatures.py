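"""Differential expression and four-way tumor signature derivation.

Condition contrasts use a per-gene Wilcoxon rank-sum test on log-normalized
expression with Seurat-flavored fold changes, a min.pct detection filter,
Bonferroni correction and exclusion of ribosomal genes.  Four disjoint
signature sets are assembled from the tumor-vs-normal contrasts: a normal
appendiceal set, a shared AMN+PMP tumor set, and AMN- and PMP-unique sets.
A simple mean-of-z-scores signature score is provided for per-cell program
activity (e.g. gel-forming mucin, exhaustion or cytotoxicity programs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import LogExpression, PipelineParams, RIBO_PREFIXES

logger = logging.getLogger("mucinsig")


# ---------------------------------------------------------------------------
# pairwise DE
# ---------------------------------------------------------------------------

def _is_ribosomal(gene: str) -> bool:
    return any(gene.startswith(p) for p in RIBO_PREFIXES)


#: below this pooled size the rank-sum p-value is computed by exhaustive
#: permutation enumeration (handles ties exactly)
EXACT_WILCOXON_MAX_N = 16


def _exact_rank_sum_p(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Exact two-sided rank-sum p per gene by permutation enumeration.

    Two-sided p = P(|R - E[R]| >= |r_obs - E[R]|) over all assignments of
    the pooled values to a group of size n_A, where R is group A's rank
    sum; midranks handle ties.
    """
    from itertools import combinations

    na, p = A.shape[0], A.shape[1]
    pooled = np.vstack([A, B])
    n = pooled.shape[0]
    ranks = stats.rankdata(pooled, axis=0)
    combs = np.array(list(combinations(range(n), na)))
    out = np.empty(p)
    for j in range(p):
        r = ranks[:, j]
        obs = r[:na].sum()
        all_sums = r[combs].sum(axis=1)
        center = r.sum() * na / n
        out[j] = float(np.mean(np.abs(all_sums - center)
                               >= np.abs(obs - center) - 1e-9))
    return out


def pairwise_de(expr: LogExpression, cells_a, cells_b,
                params: PipelineParams | None = None,
                label: str = "A_vs_B") -> pd.DataFrame:
    """Wilcoxon rank-sum DE of group A over group B on the log layer.

    Genes detected in fewer than ``de_min_pct`` of cells in both groups are
    skipped.  log2FC = log2((mean(expm1 A)+1) / (mean(expm1 B)+1)).  P-values
    are Bonferroni-corrected over the tested genes; a gene with all tied
    values gets p = 1.  ``significant`` marks adjusted p < de_alpha and
    log2FC >= de_log2fc, with ribosomal (RPS/RPL) genes excluded from the
    significant set.
    """
    params = params or PipelineParams()
    ia = expr.cell_ids.get_indexer(pd.Index(cells_a))
    ib = expr.cell_ids.get_indexer(pd.Index(cells_b))
    if (ia < 0).any() or (ib < 0).any():
        raise ValueError("cell ids missing from expression matrix")
    if len(ia) < 3 or len(ib) < 3:
        raise ValueError("each group needs >= 3 cells")
    A = expr.matrix[ia]
    B = expr.matrix[ib]

    pct_a = (A > 0).mean(axis=0)
    pct_b = (B > 0).mean(axis=0)
    tested = (pct_a >= params.de_min_pct) | (pct_b >= params.de_min_pct)
    if not tested.any():
        raise ValueError("no genes pass the min.pct detection filter")
    At, Bt = A[:, tested], B[:, tested]

    log2fc = np.log2((np.expm1(At).mean(axis=0) + 1.0)
                     / (np.expm1(Bt).mean(axis=0) + 1.0))

    pvals = np.ones(At.shape[1])
    pooled_var = np.vstack([At, Bt]).var(axis=0)
    varying = pooled_var > 0
    if varying.any():
        if len(ia) + len(ib) <= EXACT_WILCOXON_MAX_N:
            pvals[varying] = _exact_rank_sum_p(At[:, varying], Bt[:, varying])
        else:
            res = stats.mannwhitneyu(At[:, varying], Bt[:, varying], axis=0,
                                     alternative="two-sided",
                                     method="asymptotic")
            pvals[varying] = res.pvalue
    n_tested = int(tested.sum())
    padj = np.minimum(pvals * n_tested, 1.0)

    genes = expr.gene_ids[tested]
    ribo = np.array([_is_ribosomal(g) for g in genes])
    out = pd.DataFrame({
        "gene": genes,
        "log2fc": log2fc,
        "pct_a": pct_a[tested],
        "pct_b": pct_b[tested],
        "p_value": pvals,
        "p_adj": padj,
        "ribosomal": ribo,
        "comparison": label,
    }).set_index("gene")
    out["significant"] = ((out["p_adj"] < params.de_alpha)
                          & (out["log2fc"].abs() >= params.de_log2fc)
                          & ~out["ribosomal"])
    out.attrs["gene_universe"] = hash(tuple(expr.gene_ids))
    if ribo.any():
        logger.info("%d ribosomal genes barred from the significant set (%s)",
                    int(ribo.sum()), label)
    return out


def condition_de(expr: LogExpression, condition_a: str, condition_b: str,
                 cell_mask=None, params: PipelineParams | None = None
                 ) -> pd.DataFrame:
    """Convenience contrast between two conditions (optionally on a subset,
    e.g. epithelial cells only)."""
    meta = expr.cell_meta
    base = np.ones(len(meta), dtype=bool) if cell_mask is None \
        else np.asarray(cell_mask, dtype=bool)
    cells_a = meta.index[base & (meta["condition"] == condition_a).to_numpy()]
    cells_b = meta.index[base & (meta["condition"] == condition_b).to_numpy()]
    return pairwise_de(expr, cells_a, cells_b, params,
                       label=f"{condition_a}_vs_{condition_b}")


# ---------------------------------------------------------------------------
# signature sets
# ---------------------------------------------------------------------------

@dataclass
class SignatureSets:
    """The four disjoint derived gene lists."""

    normal_specific: list[str]
    shared_tumor: list[str]
    amn_unique: list[str]
    pmp_unique: list[str]

    def as_dict(self) -> dict[str, list[str]]:
        return {"normal_specific": list(self.normal_specific),
                "shared_tumor": list(self.shared_tumor),
                "amn_unique": list(self.amn_unique),
                "pmp_unique": list(self.pmp_unique)}

    def validate_disjoint(self) -> None:
        sets = [set(v) for v in self.as_dict().values()]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise ValueError(f"signature sets overlap: {sorted(overlap)}")


def _up_genes(de: pd.DataFrame, params: PipelineParams) -> set[str]:
    up = de[(de["significant"]) & (de["log2fc"] >= params.de_log2fc)]
    return set(up.index)


def derive_signatures(de_amn_vs_n: pd.DataFrame, de_pmp_vs_n: pd.DataFrame,
                      de_n_vs_amn: pd.DataFrame, de_n_vs_pmp: pd.DataFrame,
                      params: PipelineParams | None = None,
                      normal_rule: str = "both") -> SignatureSets:
    """Assemble the four disjoint signature sets from four DE tables.

    shared = up in AMN-vs-N and up in PMP-vs-N; amn_unique = up in AMN-vs-N
    only; pmp_unique = up in PMP-vs-N only; normal = up in N-vs-AMN and
    (``normal_rule='both'``, default) up in N-vs-PMP.  With
    ``normal_rule='either'`` one normal contrast suffices, and any gene also
    claimed by a tumor set is removed from the normal set to keep the four
    sets disjoint.
    """
    params = params or PipelineParams()
    tables = (de_amn_vs_n, de_pmp_vs_n, de_n_vs_amn, de_n_vs_pmp)
    universes = {t.attrs.get("gene_universe") for t in tables}
    if len(universes) != 1:
        raise ValueError("DE tables were computed on different gene universes")

    up_amn = _up_genes(de_amn_vs_n, params)
    up_pmp = _up_genes(de_pmp_vs_n, params)
    up_n_amn = _up_genes(de_n_vs_amn, params)
    up_n_pmp = _up_genes(de_n_vs_pmp, params)

    shared = up_amn & up_pmp
    amn_only = up_amn - up_pmp
    pmp_only = up_pmp - up_amn
    if normal_rule == "both":
        normal = up_n_amn & up_n_pmp
    elif normal_rule == "either":
        normal = (up_n_amn | up_n_pmp) - (shared | amn_only | pmp_only)
    else:
        raise ValueError("normal_rule must be 'both' or 'either'")

    sets = SignatureSets(sorted(normal), sorted(shared),
                         sorted(amn_only), sorted(pmp_only))
    sets.validate_disjoint()
    return sets


# ---------------------------------------------------------------------------
# mean signature scoring
# ---------------------------------------------------------------------------

def mean_signature_score(expr: LogExpression, gene_set,
                         min_present_frac: float = 0.5) -> pd.Series:
    """Mean of per-gene z-scored log expression over a gene set.

    At least ``min_present_frac`` of the set must be present in the matrix;
    missing genes are logged.  A singleton set returns that gene's z-score.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    present = [g for g in gene_set if g in expr.gene_ids]
    missing = sorted(set(gene_set) - set(present))
    if missing:
        logger.info("signature scoring: %d genes absent: %s",
                    len(missing), missing[:10])
    if len(present) < min_present_frac * len(gene_set):
        raise ValueError(
            f"only {len(present)}/{len(gene_set)} signature genes present")
    idx = expr.gene_ids.get_indexer(present)
    X = expr.matrix[:, idx]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    Z = np.divide(X - mu, sd, out=np.zeros_like(X), where=sd > 0)
    return pd.Series(Z.mean(axis=1), index=expr.cell_ids, name="score")


# ---------------------------------------------------------------------------
# GMT IO
# ---------------------------------------------------------------------------

def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0]:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
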