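import numpy as np
import pandas as pd
import pytest

from mucinsig import lineage as lm
from mucinsig import preprocess as pp
from mucinsig import synthetic as syn


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale default cohort shared across read-only tests."""
    cfg = syn.default_config(seed=1, cells_per_sample=120)
    counts, annotation, truth = syn.simulate_cohort(cfg)
    return cfg, counts, annotation, truth


@pytest.fixture(scope="session")
def small_expr(small_cohort):
    _, counts, _, _ = small_cohort
    return pp.normalize_and_scale(counts)


@pytest.fixture(scope="session")
def reference_profile():
    """Lineage reference built from an independently seeded labeled cohort."""
    cfg = syn.batch_mixing_config(seed=901, n_cells=900)
    counts, _, truth = syn.simulate_cohort(cfg)
    expr = pp.normalize_and_scale(counts)
    return lm.build_reference_profile(
        expr, truth.cells["lineage"],
        {lin.name: list(lin.markers) for lin in cfg.lineages})


def toy_counts(matrix, gene_ids, n_meta=None, **meta):
    """Small CountMatrix helper with filled-in metadata."""
    matrix = np.asarray(matrix)
    n = matrix.shape[0]
    base = {"sample_id": "s1", "patient": "p1", "condition": "normal",
            "site": "appendix", "batch": "b1"}
    base.update(meta)
    cell_meta = pd.DataFrame({k: [v] * n if np.isscalar(v) or isinstance(v, str)
                              else list(v) for k, v in base.items()},
                             index=[f"c{i}" for i in range(n)])
    return pp.CountMatrix(matrix=matrix, cell_meta=cell_meta,
                          gene_ids=pd.Index(gene_ids))
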