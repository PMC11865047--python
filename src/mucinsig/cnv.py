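"""Expression-based copy-number inference and chromosomal instability.

Tumor copy-number profiles are inferred from smoothed, reference-relative
expression: per-gene log2 expression is centered on a normal-cell reference,
averaged over >=10 Mb genomic windows, re-centered per cell, and discretized
into six states (1 complete loss, 2 single-copy loss, 3 neutral, 4
single-copy gain, 5 two-copy gain, 6 higher amplification).  Chromosomal
instability is summarized per sample as the fraction of windowed genome
whose consensus state is non-neutral (FGA), compared between groups with a
Welch t-test.

State-call thresholds are calibrated to the dosage model log2(copies/2)
with copies {1:~0, 2:1, 3:2, 4:3, 5:4, 6:>4}; they are configurable and
logged because expression attenuation at low counts shrinks observed log
ratios toward zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import LogExpression, PipelineParams

logger = logging.getLogger("mucinsig")

LN2 = float(np.log(2.0))

#: minimum number of reference cells for a usable baseline
MIN_REFERENCE_CELLS = 30

#: centered log2 values are clipped to +/- this bound
RELATIVE_CLIP = 3.0

#: genes below this mean CP10K across cells are excluded from CNV smoothing
MIN_MEAN_CP10K = 1.0


# ---------------------------------------------------------------------------
# annotation and windows
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """gene -> (chromosome, start, end), 1-based inclusive coordinates."""

    table: pd.DataFrame   # index gene; columns chrom, start, end

    def __post_init__(self) -> None:
        t = self.table
        for c in ("chrom", "start", "end"):
            if c not in t.columns:
                raise ValueError(f"annotation missing column '{c}'")
        if (t["start"] >= t["end"]).any():
            raise ValueError("annotation requires start < end")
        if not t.index.is_unique:
            raise ValueError("duplicate genes in annotation")
        self.table = t.sort_values(["chrom", "start"], kind="mergesort")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def chrom_lengths(self) -> dict[str, int]:
        return self.table.groupby("chrom")["end"].max().to_dict()

    @classmethod
    def read_tsv(cls, path) -> "GeneAnnotation":
        t = pd.read_csv(path, sep="\t")
        return cls(t.set_index("gene"))

    def write_tsv(self, path) -> None:
        self.table.reset_index(names="gene").to_csv(path, sep="\t", index=False)


def make_windows(annotation: GeneAnnotation, window_mb: float = 10.0,
                 min_genes_per_window: int = 5,
                 genes: pd.Index | None = None) -> pd.DataFrame:
    """Tile each chromosome into >=``window_mb`` windows and assign genes.

    The terminal remainder of a chromosome is merged into the previous
    window, so every window spans at least ``window_mb`` megabases (a
    chromosome shorter than one window becomes a single whole-chromosome
    window, with a warning).  Windows with fewer than
    ``min_genes_per_window`` member genes (genes assigned by midpoint) are
    merged with their neighbor on the same chromosome.
    """
    wbp = int(round(window_mb * 1e6))
    ann = annotation.table
    if genes is not None:
        ann = ann.loc[ann.index.intersection(genes)]
    rows = []
    for chrom, length in sorted(annotation.chrom_lengths().items()):
        n_win = max(1, int(length // wbp))
        if length < wbp:
            logger.warning("chromosome %s shorter than one window", chrom)
        edges = [i * wbp for i in range(n_win)] + [int(length)]
        sub = ann[ann["chrom"] == chrom]
        mid = (sub["start"] + sub["end"]) // 2
        assigned = np.minimum((mid // wbp).astype(int), n_win - 1)
        chrom_rows = []
        for w in range(n_win):
            members = list(sub.index[assigned == w])
            chrom_rows.append({"chrom": chrom, "start": edges[w] + 1,
                               "end": edges[w + 1], "genes": members})
        # merge under-populated windows with a neighbor (prefer previous)
        merged: list[dict] = []
        for row in chrom_rows:
            if merged and len(row["genes"]) < min_genes_per_window:
                merged[-1]["end"] = row["end"]
                merged[-1]["genes"] = merged[-1]["genes"] + row["genes"]
            else:
                merged.append(row)
        while len(merged) > 1 and len(merged[0]["genes"]) < min_genes_per_window:
            nxt = merged.pop(1)
            merged[0]["end"] = nxt["end"]
            merged[0]["genes"] = merged[0]["genes"] + nxt["genes"]
        rows.extend(merged)
    win = pd.DataFrame(rows)
    win["length_bp"] = win["end"] - win["start"] + 1
    if not len(win):
        raise ValueError("no windows could be constructed")
    return win


@dataclass
class CNVMatrix:
    """Cells x windows continuous scores and discrete six-state calls."""

    windows: pd.DataFrame          # chrom, start, end, genes, length_bp
    scores: np.ndarray             # cells x windows, centered log2 ratios
    cell_ids: pd.Index
    states: np.ndarray | None = None

    @property
    def n_windows(self) -> int:
        return len(self.windows)


# ---------------------------------------------------------------------------
# relative expression and smoothing
# ---------------------------------------------------------------------------

def compute_relative_expression(expr: LogExpression, reference_ids,
                                clip: float = RELATIVE_CLIP) -> pd.DataFrame:
    """Per-gene log2 expression centered on the normal-reference mean.

    The log layer is rescaled to base 2 and each gene's reference-cell mean
    is subtracted, so reference cells average 0 per gene; values are clipped
    to +/-``clip``.  Requires at least MIN_REFERENCE_CELLS reference cells
    (pool normal epithelium with non-epithelial cells if short).
    """
    ref_idx = expr.cell_ids.get_indexer(pd.Index(reference_ids))
    if (ref_idx < 0).any():
        raise ValueError("reference ids missing from expression matrix")
    if len(ref_idx) < MIN_REFERENCE_CELLS:
        raise ValueError(
            f"need >= {MIN_REFERENCE_CELLS} reference cells "
            f"(got {len(ref_idx)}); pool normal and non-epithelial cells")
    log2x = expr.matrix / LN2
    centered = log2x - log2x[ref_idx].mean(axis=0)
    np.clip(centered, -clip, clip, out=centered)
    return pd.DataFrame(centered, index=expr.cell_ids, columns=expr.gene_ids)


def smooth_windows(relative: pd.DataFrame, annotation: GeneAnnotation,
                   params: PipelineParams | None = None,
                   recenter: bool = True,
                   gene_weights: pd.Series | None = None) -> CNVMatrix:
    """Average centered values over genomic windows; re-center per cell.

    Window score = mean centered log2 value over member genes present in
    ``relative`` (optionally a weighted mean with per-gene ``gene_weights``;
    the pipeline weights by reference expression so weakly expressed genes,
    whose log ratios attenuate toward zero, do not dilute the window);
    after smoothing the per-cell median across windows is subtracted (cells
    are expected mostly neutral).  Genes without annotation are excluded
    with a logged count.
    """
    params = params or PipelineParams()
    genes = relative.columns
    unannotated = genes.difference(annotation.genes)
    if len(unannotated):
        logger.info("excluding %d genes without annotation", len(unannotated))
    win = make_windows(annotation, params.window_mb,
                       params.min_genes_per_window, genes=genes)
    X = relative.to_numpy()
    col = {g: j for j, g in enumerate(genes)}
    wvec = (gene_weights.reindex(genes).fillna(0.0).to_numpy()
            if gene_weights is not None else np.ones(len(genes)))
    scores = np.zeros((X.shape[0], len(win)))
    kept_members = []
    for w, members in enumerate(win["genes"]):
        idx = [col[g] for g in members if g in col]
        kept_members.append([g for g in members if g in col])
        if idx:
            wk = wvec[idx]
            if wk.sum() <= 0:
                wk = np.ones(len(idx))
            scores[:, w] = (X[:, idx] @ wk) / wk.sum()
    win = win.copy()
    win["genes"] = kept_members
    win["n_genes"] = [len(m) for m in kept_members]
    if recenter:
        scores = scores - np.median(scores, axis=1, keepdims=True)
    return CNVMatrix(windows=win.reset_index(drop=True), scores=scores,
                     cell_ids=relative.index)


# ---------------------------------------------------------------------------
# state calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateThresholds:
    """Breakpoints on the window score s (centered log2 ratio).

    s <= loss2 -> 1; loss2 < s <= loss1 -> 2; |s| < neutral -> 3;
    neutral <= s < gain1_hi -> 4; gain1_hi <= s < gain2_hi -> 5;
    s >= gain2_hi -> 6.
    """

    loss2: float = -1.5
    loss1: float = -0.25
    neutral: float = 0.25
    gain1_hi: float = 0.8
    gain2_hi: float = 1.4


def call_states(scores: np.ndarray,
                thresholds: StateThresholds | None = None) -> np.ndarray:
    th = thresholds or StateThresholds()
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).all():
        raise ValueError("window scores must be finite")
    states = np.full(s.shape, 3, dtype=int)
    states[s <= th.loss2] = 1
    states[(s > th.loss2) & (s <= th.loss1)] = 2
    states[(s >= th.neutral) & (s < th.gain1_hi)] = 4
    states[(s >= th.gain1_hi) & (s < th.gain2_hi)] = 5
    states[s >= th.gain2_hi] = 6
    return states


def cnv_pipeline(expr: LogExpression, annotation: GeneAnnotation,
                 reference_ids, params: PipelineParams | None = None,
                 min_mean_cp10k: float = MIN_MEAN_CP10K,
                 thresholds: StateThresholds | None = None) -> CNVMatrix:
    """Reference-centering, windowed smoothing and six-state calling.

    Genes with mean CP10K below ``min_mean_cp10k`` are excluded first: their
    log ratios are dominated by sampling noise and attenuate window means.
    """
    params = params or PipelineParams()
    mean_cp10k = np.expm1(expr.matrix).mean(axis=0)
    keep = mean_cp10k >= min_mean_cp10k
    logger.info("CNV: %d of %d genes pass mean-expression filter",
                int(keep.sum()), len(keep))
    sub = LogExpression(expr.matrix[:, keep], expr.scaled[:, keep],
                        expr.cell_meta, expr.gene_ids[keep], expr.totals)
    rel = compute_relative_expression(sub, reference_ids)
    ref_idx = sub.cell_ids.get_indexer(pd.Index(reference_ids))
    ref_mean = pd.Series(np.expm1(sub.matrix[ref_idx]).mean(axis=0),
                         index=sub.gene_ids)
    # sqrt weights: favor well-measured genes (whose log ratios attenuate
    # least) without letting a single highly expressed gene dominate
    cnv = smooth_windows(rel, annotation, params,
                         gene_weights=np.sqrt(ref_mean))
    cnv.states = call_states(cnv.scores, thresholds)
    return cnv


# ---------------------------------------------------------------------------
# fraction of genome altered
# ---------------------------------------------------------------------------

def _modal_states(states: np.ndarray) -> np.ndarray:
    """Per-window modal state over cells; ties broken toward neutral (3)."""
    out = np.empty(states.shape[1], dtype=int)
    for w in range(states.shape[1]):
        vals, counts = np.unique(states[:, w], return_counts=True)
        top = counts.max()
        winners = vals[counts == top]
        out[w] = 3 if 3 in winners else winners.min()
    return out


def fraction_genome_altered(cnv: CNVMatrix, cell_mask,
                            params: PipelineParams | None = None,
                            weight: str = "length") -> float:
    """Fraction of windowed genome whose modal state is non-neutral.

    The sample profile is the modal state per window across the sample's
    cells; FGA weights windows by bp length by default (``weight='genes'``
    weights by member gene count).  Requires >= ``min_cells_sample`` cells.
    """
    params = params or PipelineParams()
    if cnv.states is None:
        raise ValueError("call_states must run before FGA")
    if cnv.n_windows == 0:
        raise ValueError("no windows")
    mask = np.asarray(cell_mask, dtype=bool)
    if mask.sum() < params.min_cells_sample:
        raise ValueError(
            f"sample has {int(mask.sum())} cells; "
            f"minimum is {params.min_cells_sample}")
    modal = _modal_states(cnv.states[mask])
    if weight == "length":
        w = cnv.windows["length_bp"].to_numpy(dtype=float)
    elif weight == "genes":
        w = cnv.windows["n_genes"].to_numpy(dtype=float)
    else:
        raise ValueError("weight must be 'length' or 'genes'")
    return float(w[modal != 3].sum() / w.sum())


def per_cell_fga(cnv: CNVMatrix, weight: str = "length") -> np.ndarray:
    """Diagnostic per-cell FGA (no consensus)."""
    if cnv.states is None:
        raise ValueError("call_states must run before FGA")
    w = (cnv.windows["length_bp"] if weight == "length"
         else cnv.windows["n_genes"]).to_numpy(dtype=float)
    altered = (cnv.states != 3).astype(float)
    return altered @ w / w.sum()


def compare_cin(fga: pd.Series, groups: pd.Series) -> tuple[float, float]:
    """Welch two-sample t-test on per-sample FGA values.

    Returns (t, p).  Both groups need >= 2 samples; if both groups are
    constant with equal means, p = 1 by convention (logged).
    """
    fga, groups = pd.Series(fga), pd.Series(groups)
    uniq = pd.unique(groups)
    if len(uniq) != 2:
        raise ValueError("compare_cin expects exactly two groups")
    a = fga[groups == uniq[0]].to_numpy(dtype=float)
    b = fga[groups == uniq[1]].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 samples")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            logger.info("zero variance and equal means; p = 1 by convention")
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
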