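"""Generator: determinism, dosage law, planted effects, fixtures, configs."""

import numpy as np
import pandas as pd
import pytest

from mucinsig import cnv as cm
from mucinsig import preprocess as pp
from mucinsig import signatures as sg
from mucinsig import synthetic as syn


def _mean_counts_per_gene(counts, mask=None):
    X = counts.matrix.toarray().astype(float)
    if mask is not None:
        X = X[np.asarray(mask)]
    return X.mean(axis=0)


class TestDeterminism:
    def test_same_seed_bitwise_identical(self):
        cfg = syn.default_config(seed=9, cells_per_sample=40)
        c1, a1, t1 = syn.simulate_cohort(cfg)
        c2, a2, t2 = syn.simulate_cohort(syn.default_config(seed=9,
                                                            cells_per_sample=40))
        assert (c1.matrix != c2.matrix).nnz == 0
        pd.testing.assert_frame_equal(c1.cell_meta, c2.cell_meta)
        pd.testing.assert_frame_equal(a1.table, a2.table)
        pd.testing.assert_frame_equal(t1.clone_window_states,
                                      t2.clone_window_states)

    def test_different_seed_differs(self):
        c1, _, _ = syn.simulate_cohort(syn.default_config(seed=1,
                                                          cells_per_sample=30))
        c2, _, _ = syn.simulate_cohort(syn.default_config(seed=2,
                                                          cells_per_sample=30))
        assert (c1.matrix != c2.matrix).nnz > 0

    def test_protein_table_deterministic(self):
        cfg = syn.default_config(seed=4, cells_per_sample=30)
        t1, _ = syn.simulate_protein_table(cfg)
        t2, _ = syn.simulate_protein_table(cfg)
        pd.testing.assert_frame_equal(t1.table, t2.table)


class TestDosageLaw:
    """Expected expression under state s follows copies/2 with the
    documented leakage floor for complete loss."""

    @pytest.mark.parametrize("state,expected", [(1, syn.STATE_DOSAGE[1]),
                                                (2, 0.5), (3, 1.0),
                                                (4, 1.5), (5, 2.0)])
    def test_planted_state_scales_covered_genes(self, state, expected):
        seg = syn.CNVSegment("chr1", 1, 30_000_000, state)
        clone = syn.CloneSpec("cl", ("TUM",), (seg,))
        samples = (
            syn.SampleSpec("DIP", "p1", "PMP", "omentum", "b1", 1500,
                           (1.0, 0.0, 0.0)),
            syn.SampleSpec("TUM", "p2", "PMP", "omentum", "b1", 1500,
                           (1.0, 0.0, 0.0)),
        )
        cfg = syn.SimConfig(seed=5, genome=syn.DEFAULT_GENOME,
                            samples=samples, lineages=syn._lineages(),
                            cnv_clones=(clone,),
                            depth_range=(2000.0, 2000.0))
        counts, annotation, _ = syn.simulate_cohort(cfg)
        ann = annotation.table
        mid = (ann["start"] + ann["end"]) // 2
        covered = ((ann["chrom"] == "chr1") & (mid <= 30_000_000)).to_numpy()
        dip = counts.cell_meta["sample_id"] == "DIP"
        tum = counts.cell_meta["sample_id"] == "TUM"
        m_dip = _mean_counts_per_gene(counts, dip)[covered].sum()
        m_tum = _mean_counts_per_gene(counts, tum)[covered].sum()
        assert m_tum / m_dip == pytest.approx(expected, rel=0.05)

    def test_null_model_symmetry(self):
        # no clones, no DE programs, one batch: per-gene means match
        # across conditions within Monte-Carlo error
        samples = (
            syn.SampleSpec("X", "p1", "AMN", "appendix", "b1", 1500,
                           (1.0, 0.0, 0.0)),
            syn.SampleSpec("Y", "p2", "PMP", "omentum", "b1", 1500,
                           (1.0, 0.0, 0.0)),
        )
        cfg = syn.SimConfig(seed=3, genome=syn.DEFAULT_GENOME,
                            samples=samples, lineages=syn._lineages())
        counts, _, _ = syn.simulate_cohort(cfg)
        a = _mean_counts_per_gene(counts, counts.cell_meta["sample_id"] == "X")
        b = _mean_counts_per_gene(counts, counts.cell_meta["sample_id"] == "Y")
        well = (a + b) / 2 > 5
        ratio = a[well] / b[well]
        assert np.median(np.abs(ratio - 1)) < 0.02
        assert (np.abs(ratio - 1) < 0.05).mean() >= 0.95


class TestPlantedDE:
    def test_log2_effect_recovered_from_mean_ratio(self):
        cfg = syn.signature_recovery_config(seed=21,
                                            cells_per_condition=2000)
        counts, _, truth = syn.simulate_cohort(cfg)
        X = counts.matrix.toarray().astype(float)
        cp10k = 1e4 * X / X.sum(axis=1, keepdims=True)
        cond = counts.cell_meta["condition"].to_numpy()
        gi = counts.gene_ids.get_indexer(truth.programs["amn_unique"])
        ratio = (cp10k[cond == "AMN"][:, gi].mean(axis=0)
                 / cp10k[cond == "normal"][:, gi].mean(axis=0))
        est = np.log2(ratio).mean()
        assert est == pytest.approx(cfg.de_log2_effect, rel=0.10)


class TestTruthGrid:
    def test_truth_windows_match_cnv_module_grid(self, small_cohort):
        cfg, _, annotation, truth = small_cohort
        win = cm.make_windows(annotation, cfg.window_mb,
                              cfg.min_genes_per_window)
        pd.testing.assert_frame_equal(truth.windows, win)
        assert set(truth.clone_window_states.columns) == set(range(len(win)))
        assert (truth.clone_window_states.loc["diploid"] == 3).all()

    def test_every_cell_has_one_lineage_and_clone(self, small_cohort):
        _, counts, _, truth = small_cohort
        assert truth.cells.index.equals(counts.cell_meta.index)
        assert truth.cells["lineage"].notna().all()
        assert truth.cells["clone"].notna().all()


class TestConfigValidation:
    def test_overlapping_segments_rejected(self):
        clone = syn.CloneSpec("cl", ("A1",), (
            syn.CNVSegment("chr1", 1, 20_000_000, 4),
            syn.CNVSegment("chr1", 10_000_000, 30_000_000, 2)))
        cfg = syn.default_config(seed=0, cells_per_sample=10)
        cfg.cnv_clones = (clone,)
        with pytest.raises(ValueError, match="overlap"):
            cfg.validate()

    def test_program_gene_outside_universe_rejected(self):
        cfg = syn.default_config(seed=0, cells_per_sample=10)
        cfg.de_programs = dict(cfg.de_programs)
        cfg.de_programs["amn_unique"] = ["NOT_A_GENE"]
        with pytest.raises(ValueError, match="universe"):
            cfg.validate()

    def test_overlapping_programs_rejected(self):
        cfg = syn.default_config(seed=0, cells_per_sample=10)
        g = cfg.de_programs["shared_tumor"][0]
        cfg.de_programs = dict(cfg.de_programs)
        cfg.de_programs["amn_unique"] = [g]
        with pytest.raises(ValueError, match="overlap"):
            cfg.validate()

    def test_zero_cells_rejected(self):
        cfg = syn.default_config(seed=0, cells_per_sample=10)
        bad = syn.SampleSpec("Z", "p", "normal", "appendix", "b1", 0)
        cfg.samples = cfg.samples + (bad,)
        with pytest.raises(ValueError, match="n_cells"):
            cfg.validate()


class TestBulkCohort:
    def test_zero_purity_leaves_signatures_at_background(self):
        cfg = syn.signature_recovery_config(seed=2)
        cfg.bulk.purity_alpha = 1e-4   # purity ~ 0 for every sample
        cfg.bulk.purity_beta = 1e4
        sets = sg.SignatureSets(**cfg.de_programs)
        bulk, truth = syn.simulate_bulk_cohort(cfg, sets)
        sig_cols = [g for g in sets.shared_tumor]
        bg_cols = [g for g in bulk.columns
                   if g.startswith("G") and g not in set(
                       sum(sets.as_dict().values(), []))][:200]
        from scipy import stats
        # compare deviations from the per-gene cross-sample mean
        dev = bulk - bulk.mean(axis=0)
        t, p = stats.ttest_ind(dev[sig_cols].to_numpy().ravel(),
                               dev[bg_cols].to_numpy().ravel())
        assert p > 0.01

    def test_coexpression_means_identical_planted_activities(self):
        cfg = syn.signature_recovery_config(seed=2)
        cfg.bulk.noise_sd = 0.0
        sets = sg.SignatureSets(**cfg.de_programs)
        _, truth = syn.simulate_bulk_cohort(cfg, sets)
        from scipy.stats import spearmanr
        rho, _ = spearmanr(truth["goblet_activity"],
                           truth["metastasis_activity"])
        assert rho == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        cfg = syn.signature_recovery_config(seed=2)
        cfg.bulk.n_samples = 2
        sets = sg.SignatureSets(**cfg.de_programs)
        with pytest.raises(ValueError, match=">= 3"):
            syn.simulate_bulk_cohort(cfg, sets)

    def test_empty_signatures_rejected(self):
        cfg = syn.signature_recovery_config(seed=2)
        with pytest.raises(ValueError, match="empty"):
            syn.simulate_bulk_cohort(cfg, sg.SignatureSets([], [], [], []))


class TestFixtures:
    def test_round_trip_identity(self, tmp_path):
        cfg = syn.default_config(seed=7, cells_per_sample=10)
        counts, annotation, truth = syn.simulate_cohort(cfg)
        manifest = syn.write_fixtures(counts, annotation, tmp_path,
                                      gene_sets=truth.programs)
        back, ann_back, sets_back = syn.read_fixtures(tmp_path)
        assert (back.matrix != counts.matrix).nnz == 0
        pd.testing.assert_frame_equal(back.cell_meta, counts.cell_meta)
        assert list(back.gene_ids) == list(counts.gene_ids)
        pd.testing.assert_frame_equal(ann_back.table, annotation.table)
        assert sets_back == truth.programs

    def test_mtx_header_declares_dims_and_nnz(self, tmp_path):
        cfg = syn.default_config(seed=7, cells_per_sample=10)
        counts, annotation, _ = syn.simulate_cohort(cfg)
        syn.write_fixtures(counts, annotation, tmp_path)
        with open(tmp_path / "matrix.mtx") as fh:
            header = [line for line in fh if not line.startswith("%")][0]
        rows, cols, nnz = map(int, header.split())
        assert (rows, cols) == counts.matrix.shape
        assert nnz == counts.matrix.nnz

    def test_gmt_line_count_equals_set_count(self, tmp_path):
        cfg = syn.default_config(seed=7, cells_per_sample=10)
        counts, annotation, truth = syn.simulate_cohort(cfg)
        syn.write_fixtures(counts, annotation, tmp_path,
                           gene_sets=truth.programs)
        with open(tmp_path / "gene_sets.gmt") as fh:
            assert sum(1 for _ in fh) == len(truth.programs)

    def test_rewrite_is_byte_identical(self, tmp_path):
        cfg = syn.default_config(seed=7, cells_per_sample=10)
        counts, annotation, truth = syn.simulate_cohort(cfg)
        m1 = syn.write_fixtures(counts, annotation, tmp_path / "a",
                                gene_sets=truth.programs)
        m2 = syn.write_fixtures(counts, annotation, tmp_path / "b",
                                gene_sets=truth.programs)
        assert list(syn.fixture_checksums(m1).values()) == \
            list(syn.fixture_checksums(m2).values())


class TestProteinSimulation:
    def test_planted_strong_targets_survive_filter(self):
        from mucinsig.proteomics import decoy_confidence_filter
        cfg = syn.default_config(seed=13, cells_per_sample=10)
        table, truth = syn.simulate_protein_table(cfg)
        result = decoy_confidence_filter(table, factor=2.0)
        for sample, res in result.items():
            planted = set(truth[(truth["sample_id"] == sample)
                                & truth["planted"]].index)
            assert planted <= set(res["kept"])

    def test_all_null_targets_yield_near_empty_set(self):
        from mucinsig.proteomics import decoy_confidence_filter
        cfg = syn.default_config(seed=13, cells_per_sample=10)
        cfg.protein.n_strong = 0
        table, _ = syn.simulate_protein_table(cfg)
        result = decoy_confidence_filter(table, factor=2.0)
        assert sum(r["n_kept"] for r in result.values()) <= 2
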