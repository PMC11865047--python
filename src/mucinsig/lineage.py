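"""Reference-correlation cell-type assignment and differential abundance.

Cells are assigned to lineages/epithelial subtypes by Spearman correlation
to reference centroids over marker genes (with a fine-tuning pass between
the top two candidates), samples with too few epithelial cells are dropped,
and per-condition differences in cell-type composition are tested with a
sample-level binomial GLM (Wald z per contrast, Benjamini-Hochberg across
cell types).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .preprocess import LogExpression

logger = logging.getLogger("mucinsig")

#: gel-forming mucin / goblet program markers
GOBLET_MARKERS = ("MUC2", "TFF3", "SPINK4", "CLCA1", "SPDEF", "FCGBP")

MIN_GENE_OVERLAP = 20


# ---------------------------------------------------------------------------
# reference profiles
# ---------------------------------------------------------------------------

@dataclass
class ReferenceProfile:
    """Per-type mean log-expression centroids plus marker gene sets."""

    centroids: pd.DataFrame            # type x gene
    marker_sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.centroids.index.is_unique:
            raise ValueError("duplicate cell types in reference")
        if not np.isfinite(self.centroids.to_numpy()).all():
            raise ValueError("reference centroids must be finite")
        universe = set(self.centroids.columns)
        for t, markers in self.marker_sets.items():
            missing = set(markers) - universe
            if missing:
                raise ValueError(f"markers for '{t}' absent from reference: "
                                 f"{sorted(missing)}")

    @property
    def cell_types(self) -> list[str]:
        return list(self.centroids.index)

    def marker_union(self, types=None) -> list[str]:
        types = types if types is not None else self.cell_types
        out: set[str] = set()
        for t in types:
            out |= set(self.marker_sets.get(t, []))
        return sorted(out)


def build_reference_profile(expr: LogExpression, labels: pd.Series,
                            marker_sets: dict[str, list[str]]
                            ) -> ReferenceProfile:
    """Centroids = per-type mean log expression of a labeled reference."""
    labels = labels.reindex(expr.cell_ids)
    cents = {}
    for t in sorted(labels.dropna().unique()):
        cents[t] = expr.matrix[(labels == t).to_numpy()].mean(axis=0)
    centroids = pd.DataFrame(cents, index=expr.gene_ids).T
    markers = {t: [g for g in gs if g in expr.gene_ids]
               for t, gs in marker_sets.items()}
    return ReferenceProfile(centroids=centroids, marker_sets=markers)


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def _spearman_to_centroids(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Spearman correlation of each row of X to each row of C."""
    RX = rankdata(X, axis=1)
    RC = rankdata(C, axis=1)
    RX = RX - RX.mean(axis=1, keepdims=True)
    RC = RC - RC.mean(axis=1, keepdims=True)
    nx = np.linalg.norm(RX, axis=1, keepdims=True)
    nc = np.linalg.norm(RC, axis=1, keepdims=True)
    nx[nx == 0] = 1.0
    nc[nc == 0] = 1.0
    return (RX / nx) @ (RC / nc).T


def assign_by_reference(expr: LogExpression, ref: ReferenceProfile,
                        fine_tune: bool = True) -> pd.DataFrame:
    """Assign each cell to the best Spearman-correlated reference type.

    Correlations are computed over the union of the reference marker genes
    (>= MIN_GENE_OVERLAP genes shared with the matrix required); the
    optional fine-tuning pass re-scores each cell's top two candidates on
    just their own markers.  Ties break deterministically by type-name
    order.  Returns a frame with lineage label, score and retained flag.
    """
    if len(ref.cell_types) < 2:
        raise ValueError("need >= 2 reference types")
    types = sorted(ref.cell_types)
    genes = [g for g in ref.marker_union() if g in expr.gene_ids]
    if len(genes) < MIN_GENE_OVERLAP:
        raise ValueError(
            f"only {len(genes)} marker genes overlap the matrix "
            f"(need >= {MIN_GENE_OVERLAP})")
    gi = expr.gene_ids.get_indexer(genes)
    X = expr.matrix[:, gi]
    C = ref.centroids.loc[types, genes].to_numpy()
    corr = _spearman_to_centroids(X, C)

    # argmax with ties to the alphabetically first type
    best = np.argmax(np.round(corr, 12), axis=1)
    score = corr[np.arange(len(best)), best]
    labels = np.array(types, dtype=object)[best]

    if fine_tune:
        order = np.argsort(-np.round(corr, 12), axis=1, kind="stable")
        top2 = order[:, :2]
        # group cells by their candidate pair to keep this vectorized
        pair_key = top2.min(axis=1) * len(types) + top2.max(axis=1)
        for key in np.unique(pair_key):
            t1, t2 = types[key // len(types)], types[key % len(types)]
            sub_genes = [g for g in ref.marker_union([t1, t2])
                         if g in expr.gene_ids]
            if len(sub_genes) < 3:
                continue
            rows = np.flatnonzero(pair_key == key)
            gj = expr.gene_ids.get_indexer(sub_genes)
            c2 = _spearman_to_centroids(
                expr.matrix[np.ix_(rows, gj)],
                ref.centroids.loc[[t1, t2], sub_genes].to_numpy())
            pick = np.argmax(np.round(c2, 12), axis=1)
            labels[rows] = np.where(pick == 0, t1, t2)
            score[rows] = c2[np.arange(len(rows)), pick]

    return pd.DataFrame({"lineage": labels, "score": score,
                         "retained": True}, index=expr.cell_ids)


# ---------------------------------------------------------------------------
# cellularity filter
# ---------------------------------------------------------------------------

def filter_sample_cellularity(assignment: pd.DataFrame, cell_meta: pd.DataFrame,
                              min_cells: int = 10,
                              label: str = "epithelial") -> dict:
    """Drop samples with fewer than ``min_cells`` cells of ``label``.

    A sample with exactly ``min_cells`` is retained.  Returns retained and
    dropped sample lists with their counts; an empty result only warns.
    """
    is_label = assignment["lineage"] == label
    counts = (cell_meta.loc[assignment.index[is_label], "sample_id"]
              .value_counts()
              .reindex(cell_meta["sample_id"].unique(), fill_value=0))
    retained = counts.index[counts >= min_cells].tolist()
    dropped = counts.index[counts < min_cells].tolist()
    if not retained:
        logger.warning("no samples pass the %d-cell %s floor", min_cells, label)
    if dropped:
        logger.info("dropped low-cellularity samples: %s",
                    {s: int(counts[s]) for s in dropped})
    return {"retained": retained, "dropped": dropped,
            "counts": counts.to_dict()}


# ---------------------------------------------------------------------------
# differential abundance
# ---------------------------------------------------------------------------

def abundance_test(assignment: pd.DataFrame, cell_meta: pd.DataFrame,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Binomial GLM of per-sample cell-type composition on condition.

    The observational unit is the sample: for each cell type t, the counts
    (cells of type t, other cells) per sample are modeled on condition with
    a logit link; each non-reference condition coefficient yields a Wald
    z-test (log-odds estimate), adjusted across cell types per contrast by
    Benjamini-Hochberg.  Complete separation is flagged and re-fit with a
    0.5 pseudo-count per sample.
    """
    meta = cell_meta.loc[assignment.index]
    tab = (pd.DataFrame({"sample_id": meta["sample_id"],
                         "lineage": assignment["lineage"]})
           .groupby(["sample_id", "lineage"]).size().unstack(fill_value=0))
    cond = meta.drop_duplicates("sample_id").set_index("sample_id")["condition"]
    cond = cond.reindex(tab.index)
    if cond.nunique() < 2:
        raise ValueError("abundance_test needs >= 2 conditions")
    if len(tab) < 2:
        raise ValueError("abundance_test needs >= 2 samples")

    conditions = sorted(cond.unique())
    reference = conditions[0]
    design = pd.get_dummies(pd.Categorical(cond, categories=conditions),
                            drop_first=True, dtype=float)
    design.insert(0, "intercept", 1.0)
    totals = tab.sum(axis=1)

    rows = []
    for ctype in tab.columns:
        k = tab[ctype].to_numpy(dtype=float)
        if k.sum() == 0:
            logger.warning("cell type %s absent from all samples; skipped",
                           ctype)
            continue
        endog = np.column_stack([k, totals.to_numpy(dtype=float) - k])

        def _fit(endog_):
            model = sm.GLM(endog_, design.to_numpy(),
                           family=sm.families.Binomial())
            return model.fit(maxiter=200)

        res = _fit(endog)
        separated = (not np.isfinite(res.bse).all()) or np.any(
            np.abs(res.params) > 15)
        if separated:
            logger.warning("complete separation for %s; penalized refit "
                           "with 0.5 pseudo-counts", ctype)
            res = _fit(endog + 0.5)
        for j, col in enumerate(design.columns[1:], start=1):
            rows.append({
                "cell_type": ctype,
                "contrast": f"{col}_vs_{reference}",
                "log_odds": float(res.params[j]),
                "se": float(res.bse[j]),
                "z": float(res.params[j] / res.bse[j]),
                "p_value": float(res.pvalues[j]),
                "separated": bool(separated),
            })
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    for contrast, grp in out.groupby("contrast"):
        out.loc[grp.index, "p_adj"] = multipletests(
            grp["p_value"], method="fdr_bh")[1]
    out["significant"] = out["p_adj"] < alpha
    return out


def subtype_proportions(assignment: pd.DataFrame,
                        cell_meta: pd.DataFrame) -> pd.DataFrame:
    """Per-sample cell-type proportions (rows sum to 1)."""
    meta = cell_meta.loc[assignment.index]
    tab = (pd.DataFrame({"sample_id": meta["sample_id"],
                         "lineage": assignment["lineage"]})
           .groupby(["sample_id", "lineage"]).size().unstack(fill_value=0))
    return tab.div(tab.sum(axis=1), axis=0)
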