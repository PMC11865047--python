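"""Single-sample rank-based gene-set enrichment and cohort validation.

Scores follow the GSVA recipe: each gene's expression is transformed by a
Gaussian-kernel ECDF across units (cells or bulk samples; bandwidth sd/4),
genes are ranked within each unit, and the enrichment score is the signed
difference of the maximal positive and negative deviations of a weighted
Kolmogorov-Smirnov random walk over the ranked list (in-set steps weighted
by the symmetric rank statistic |rank - (p+1)/2|; out-of-set steps
uniform).  Positive scores mean the set concentrates at high ranks in that
unit.  Condition-level differences in scores are tested with one-way ANOVA
plus Tukey's HSD; the bulk-cohort validation reports percent of samples
with positive scores per signature and the Spearman correlation between
the shared (goblet) and PMP-unique (metastasis) signature scores.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .signatures import SignatureSets

logger = logging.getLogger("mucinsig")

#: Gaussian-kernel ECDF bandwidth = per-gene sd / KCDF_BANDWIDTH_DIV
KCDF_BANDWIDTH_DIV = 4.0


# ---------------------------------------------------------------------------
# GSVA-style scores
# ---------------------------------------------------------------------------

def gaussian_kcdf(X: np.ndarray) -> np.ndarray:
    """Across-unit Gaussian-kernel cumulative distribution per gene.

    z[i, j] = mean_k Phi((x[i, j] - x[k, j]) / h_j), h_j = sd_j / 4.
    """
    n, p = X.shape
    sd = X.std(axis=0, ddof=1) if n > 1 else np.ones(X.shape[1])
    h = np.maximum(sd / KCDF_BANDWIDTH_DIV, 1e-12)
    Z = np.empty_like(X, dtype=float)
    # chunk genes to bound the n x n x chunk broadcast
    chunk = max(1, int(4e6 // max(n * n, 1)))
    for j0 in range(0, p, chunk):
        j1 = min(j0 + chunk, p)
        diff = (X[:, None, j0:j1] - X[None, :, j0:j1]) / h[None, None, j0:j1]
        Z[:, j0:j1] = stats.norm.cdf(diff).mean(axis=1)
    return Z


def _walk_scores(Z: np.ndarray, in_set: np.ndarray, tau: float,
                 mx_diff: bool) -> np.ndarray:
    """Weighted KS random-walk enrichment score per unit (row of Z)."""
    n, p = Z.shape
    order = np.argsort(-Z, axis=1, kind="stable")
    ranks = np.arange(1, p + 1, dtype=float)
    weight = np.abs(ranks - (p + 1) / 2.0) ** tau     # large at both extremes
    member = in_set[order]                            # n x p, reordered
    w_in = np.where(member, weight[None, :], 0.0)
    denom_in = w_in.sum(axis=1, keepdims=True)
    denom_out = float(p - in_set.sum())
    step = np.where(member, 0.0, 1.0)
    walk = (np.cumsum(w_in, axis=1) / np.maximum(denom_in, 1e-12)
            - np.cumsum(step, axis=1) / max(denom_out, 1e-12))
    if mx_diff:
        return walk.max(axis=1).clip(min=0) + walk.min(axis=1).clip(max=0)
    amax = np.abs(walk).argmax(axis=1)
    return walk[np.arange(n), amax]


def rank_enrichment_score(expression: pd.DataFrame,
                          gene_sets: dict[str, list[str]],
                          tau: float = 1.0, mx_diff: bool = True,
                          min_set_genes: int = 3,
                          kcdf: str = "gaussian") -> pd.DataFrame:
    """GSVA-style per-unit enrichment scores for each gene set.

    ``expression`` is units x genes.  Constant gene columns are dropped
    (logged); a set with fewer than ``min_set_genes`` present genes raises.
    ``kcdf='gaussian'`` (default) smooths the across-unit CDF with a
    Gaussian kernel; ``kcdf='ecdf'`` uses the raw empirical CDF, which
    makes scores exactly invariant to any per-gene strictly increasing
    transform (the Gaussian kernel is only approximately so).
    """
    if expression.shape[0] < 3:
        raise ValueError("need >= 3 units")
    X = expression.to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    if not keep.all():
        logger.info("dropping %d constant gene rows", int((~keep).sum()))
    X = X[:, keep]
    genes = expression.columns[keep]
    if kcdf == "gaussian":
        Z = gaussian_kcdf(X)
    elif kcdf == "ecdf":
        Z = stats.rankdata(X, axis=0) / X.shape[0]
    else:
        raise ValueError("kcdf must be 'gaussian' or 'ecdf'")
    col = {g: j for j, g in enumerate(genes)}

    out = {}
    for name, members in gene_sets.items():
        in_set = np.zeros(len(genes), dtype=bool)
        present = [col[g] for g in members if g in col]
        if len(present) < min_set_genes:
            raise ValueError(
                f"gene set '{name}': only {len(present)} genes present "
                f"(need >= {min_set_genes})")
        in_set[present] = True
        out[name] = _walk_scores(Z, in_set, tau, mx_diff)
    return pd.DataFrame(out, index=expression.index)


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD
# ---------------------------------------------------------------------------

def condition_anova_tukey(scores: pd.DataFrame, groups,
                          alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA per gene set with Tukey HSD pairwise comparisons.

    Groups with a single unit are dropped with a warning.  Degenerate
    constant data reports no difference (F = 0, p = 1, logged).  Returns a
    long table of (gene_set, pair) rows with mean difference, direction and
    studentized-range adjusted p.
    """
    groups = pd.Series(np.asarray(groups), index=scores.index)
    sizes = groups.value_counts()
    usable = sorted(sizes.index[sizes >= 2])
    if len(usable) < len(sizes):
        logger.warning("dropping singleton groups: %s",
                       sorted(set(sizes.index) - set(usable)))
    if len(usable) < 2:
        raise ValueError("need >= 2 groups with >= 2 units")

    rows = []
    for name in scores.columns:
        data = [scores.loc[(groups == g).to_numpy(), name].to_numpy()
                for g in usable]
        if np.ptp(np.concatenate(data)) == 0:
            logger.info("constant scores for %s; reported as no difference",
                        name)
            f_stat, f_p = 0.0, 1.0
            for i, j in _pairs(len(usable)):
                rows.append(_tukey_row(name, usable[i], usable[j],
                                       0.0, 1.0, f_stat, f_p))
            continue
        f_stat, f_p = stats.f_oneway(*data)
        tk = stats.tukey_hsd(*data)
        for i, j in _pairs(len(usable)):
            diff = float(np.mean(data[i]) - np.mean(data[j]))
            rows.append(_tukey_row(name, usable[i], usable[j], diff,
                                   float(tk.pvalue[i, j]),
                                   float(f_stat), float(f_p)))
    out = pd.DataFrame(rows)
    out["significant"] = out["p_adj"] < alpha
    return out


def _pairs(k):
    return [(i, j) for i in range(k) for j in range(i + 1, k)]


def _tukey_row(name, ga, gb, diff, p_adj, f_stat, f_p):
    return {"gene_set": name, "group_a": ga, "group_b": gb,
            "mean_diff": diff, "direction": int(np.sign(diff)),
            "p_adj": p_adj, "anova_f": f_stat, "anova_p": f_p}


# ---------------------------------------------------------------------------
# cohort validation
# ---------------------------------------------------------------------------

def cohort_validation(bulk: pd.DataFrame, signatures: SignatureSets,
                      min_samples: int = 10) -> dict:
    """Validate the derived signatures on a bulk expression cohort.

    Computes GSVA-style scores per signature, the percent of samples with a
    strictly positive score per signature (zeros count negative), and the
    Spearman correlation (with p-value) between the shared-tumor (goblet)
    and PMP-unique (metastasis) scores across samples.
    """
    if bulk.shape[0] < min_samples:
        raise ValueError(f"cohort has {bulk.shape[0]} samples; "
                         f"need >= {min_samples} for a stable correlation")
    sets = {k: v for k, v in signatures.as_dict().items() if v}
    scores = rank_enrichment_score(bulk, sets)
    percent_positive = {k: float(100.0 * (scores[k] > 0).mean())
                        for k in scores.columns}
    rho, p = stats.spearmanr(scores["shared_tumor"], scores["pmp_unique"])
    return {"scores": scores,
            "percent_positive": percent_positive,
            "spearman_rho": float(rho),
            "spearman_p": float(p),
            "n_samples": int(bulk.shape[0])}
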