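"""Clonal phylogenies over metastatic-site consensus CNV profiles.

Each multi-site patient contributes one consensus six-state CNV profile per
anatomic site (modal state per window over that site's tumor epithelial
cells, ties resolved toward neutral).  Profiles are compared with a
bp-length-weighted L1 distance, a neighbor-joining tree is built over the
sites plus an explicit all-neutral diploid reference leaf, and the tree is
rooted at the diploid leaf's attachment so root-to-leaf path length tracks
accumulated aneuploidy.  Between-site expression differences delegate to
the Wilcoxon machinery in :mod:`mucinsig.signatures`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .cnv import CNVMatrix, _modal_states
from .preprocess import LogExpression, PipelineParams
from .signatures import pairwise_de

logger = logging.getLogger("mucinsig")

DIPLOID_ROOT = "diploid"


# ---------------------------------------------------------------------------
# consensus profiles and distances
# ---------------------------------------------------------------------------

def consensus_profile(cnv: CNVMatrix, site_labels,
                      params: PipelineParams | None = None) -> pd.DataFrame:
    """Per-site modal CNV state per window (ties toward state 3).

    Sites with fewer than ``min_cells_site`` cells are excluded with a log
    note.  Returns a sites x windows integer frame on the CNV window grid.
    """
    params = params or PipelineParams()
    if cnv.states is None:
        raise ValueError("call_states must run before consensus profiles")
    labels = pd.Series(np.asarray(site_labels), index=cnv.cell_ids)
    profiles = {}
    for site in sorted(labels.unique()):
        mask = (labels == site).to_numpy()
        if mask.sum() < params.min_cells_site:
            logger.info("site %s has %d cells (< %d); excluded",
                        site, int(mask.sum()), params.min_cells_site)
            continue
        profiles[site] = _modal_states(cnv.states[mask])
    if not profiles:
        raise ValueError("no site passes the per-site cell floor")
    return pd.DataFrame(profiles).T


def profile_distance(p, q, window_bp) -> float:
    """bp-length-weighted mean L1 distance between two state vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    w = np.asarray(window_bp, dtype=float)
    if p.shape != q.shape or p.shape != w.shape:
        raise ValueError("profiles must share one window grid")
    return float((w * np.abs(p - q)).sum() / w.sum())


def distance_matrix(profiles: pd.DataFrame, window_bp) -> pd.DataFrame:
    names = list(profiles.index)
    D = pd.DataFrame(0.0, index=names, columns=names)
    for a, b in combinations(names, 2):
        d = profile_distance(profiles.loc[a], profiles.loc[b], window_bp)
        D.loc[a, b] = D.loc[b, a] = d
    return D


# ---------------------------------------------------------------------------
# tree building
# ---------------------------------------------------------------------------

@dataclass
class ClonalTree:
    """Rooted tree over site profiles with an explicit diploid leaf."""

    tree: TreeNode
    distances: pd.DataFrame

    @property
    def newick(self) -> str:
        return str(self.tree).strip()

    def root_to_leaf_distance(self, leaf: str) -> float:
        return float(self.tree.find(leaf).accumulate_to_ancestor(self.tree))

    def write(self, path) -> None:
        self.tree.write(path, format="newick")


def build_tree(profiles: pd.DataFrame, windows: pd.DataFrame,
               root_name: str = DIPLOID_ROOT) -> ClonalTree:
    """Neighbor-joining tree over site profiles plus the diploid root.

    An all-neutral (state 3) profile named ``root_name`` is appended if
    absent.  Negative NJ branch lengths are clamped to zero (logged), leaf
    order is sorted for determinism, and the tree is re-rooted at the
    diploid leaf's attachment node.  With fewer than three profiles a
    degenerate two-leaf tree is returned with a warning.
    """
    profiles = profiles.copy()
    if root_name not in profiles.index:
        profiles.loc[root_name] = 3
    profiles = profiles.loc[sorted(profiles.index,
                                   key=lambda s: (s != root_name, s))]
    window_bp = windows["length_bp"].to_numpy(dtype=float)
    D = distance_matrix(profiles, window_bp)

    if len(profiles) < 3:
        logger.warning("fewer than 3 profiles; returning a two-leaf tree")
        a, b = D.index
        d = D.loc[a, b]
        tree = TreeNode.read([f"({a}:{d / 2},{b}:{d / 2});"])
        return ClonalTree(tree=tree, distances=D)

    dm = DistanceMatrix(D.to_numpy(), ids=list(D.index))
    tree = nj(dm)
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        logger.info("clamped %d negative NJ branch lengths to 0", clamped)
    root_tip = tree.find(root_name)
    tree = tree.root_at(root_tip.parent, reset=True)
    return ClonalTree(tree=tree, distances=D)


def robinson_foulds(tree_a: TreeNode, tree_b: TreeNode) -> float:
    """Unweighted Robinson-Foulds distance between two trees."""
    return float(tree_a.compare_rfd(tree_b))


# ---------------------------------------------------------------------------
# between-site differential expression
# ---------------------------------------------------------------------------

def between_site_de(expr: LogExpression, site_labels,
                    params: PipelineParams | None = None
                    ) -> dict[tuple[str, str], pd.DataFrame]:
    """Pairwise Wilcoxon DE between every pair of qualifying sites."""
    params = params or PipelineParams()
    labels = pd.Series(np.asarray(site_labels), index=expr.cell_ids)
    sites = [s for s in sorted(labels.unique())
             if (labels == s).sum() >= params.min_cells_site]
    if len(sites) < 2:
        raise ValueError("need >= 2 sites passing the per-site cell floor")
    out = {}
    for a, b in combinations(sites, 2):
        out[(a, b)] = pairwise_de(
            expr, labels.index[labels == a], labels.index[labels == b],
            params, label=f"{a}_vs_{b}")
    return out
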