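"""Synthetic multi-patient cohorts with planted ground truth.

The generator emulates the study design this package analyzes: a cohort of
normal appendix, AMN and PMP samples profiled by scRNA-seq across
experimental batches, with planted cell lineages (epithelial/goblet,
immune, stromal), clone-specific CNV segments, four condition-specific
differential expression programs, a correlated bulk validation cohort and
a target/decoy protein p-value table.  Every output is a deterministic
function of the config seed.

Generative model for counts: cell depth x normalized lineage profile x
condition DE factor (epithelial cells only) x CNV dosage x per-(batch,
gene) log-normal factor, drawn negative-binomially with a shared
dispersion.  CNV dosage follows log2(copies/2) with copies
{1: leakage, 2: 1, 3: 2, 4: 3, 5: 4, 6: 6}; complete loss uses a small
leakage floor (STATE_DOSAGE[1] = 0.02) so log-space operations stay finite.

The genome is a miniature 4 x 60 Mb layout so 10 Mb windows hold ~dozens
of genes at desk scale; the truth window grid is computed with the same
routine the CNV module uses, so planted and inferred states share a grid.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .cnv import GeneAnnotation, make_windows
from .preprocess import CountMatrix
from .proteomics import ProteinTable
from .signatures import SignatureSets, read_gmt, write_gmt

#: expression dosage per CNV state (copies / 2; state 1 keeps a leakage floor)
STATE_DOSAGE = {1: 0.02, 2: 0.5, 3: 1.0, 4: 1.5, 5: 2.0, 6: 3.0}

CONDITIONS = ("normal", "AMN", "PMP")

EPITHELIAL_MARKERS = ("MUC2", "TFF3", "SPINK4", "CLCA1", "SPDEF", "FCGBP",
                      "EPCAM", "KRT8")
IMMUNE_MARKERS = ("PTPRC", "CD3D", "CD3E", "CD2", "IL7R", "TRAC", "CD52")
STROMAL_MARKERS = ("COL1A1", "COL1A2", "COL3A1", "DCN", "LUM", "PDGFRA",
                   "VIM")
MITO_GENES = ("MT-ND1", "MT-CO1", "MT-CO2", "MT-CYB", "MT-ATP6")
RIBO_GENES = ("RPS2", "RPS6", "RPS18", "RPS4X", "RPL3", "RPL5", "RPL13",
              "RPL10")


# ---------------------------------------------------------------------------
# config types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromSpec:
    name: str
    length_bp: int
    gene_spacing_bp: int


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    patient: str
    condition: str
    site: str
    batch: str
    n_cells: int
    lineage_props: tuple[float, ...] | None = None   # follows config.lineages


@dataclass
class LineageSpec:
    name: str
    markers: tuple[str, ...]
    baseline: np.ndarray | None = None     # per-gene mean weights


@dataclass(frozen=True)
class CNVSegment:
    chrom: str
    start: int
    end: int
    state: int


@dataclass(frozen=True)
class CloneSpec:
    clone_id: str
    sample_ids: tuple[str, ...]
    segments: tuple[CNVSegment, ...]


@dataclass
class BulkConfig:
    n_samples: int = 63
    purity_alpha: float = 28.0
    purity_beta: float = 12.0
    coexpression: bool = True
    noise_sd: float = 0.4
    activity_sd: float = 0.4
    amplitude_log2: float = 2.0


@dataclass
class ProteinConfig:
    n_targets: int = 300
    n_decoys: int = 100
    n_strong: int = 60
    strong_neglog10_range: tuple[float, float] = (8.0, 12.0)
    sample_ids: tuple[str, ...] = ("ascites1", "ascites2", "ascites3")


@dataclass
class SimConfig:
    """Full description of one synthetic cohort (see module docstring)."""

    seed: int = 0
    genome: tuple[ChromSpec, ...] = ()
    samples: tuple[SampleSpec, ...] = ()
    lineages: tuple[LineageSpec, ...] = ()
    nb_dispersion: float = 10.0
    depth_range: tuple[float, float] = (1500.0, 3000.0)
    batch_effect_sd: float = 0.3
    cnv_clones: tuple[CloneSpec, ...] = ()
    de_programs: dict[str, list[str]] = field(default_factory=dict)
    de_log2_effect: float = 1.0
    bulk: BulkConfig = field(default_factory=BulkConfig)
    protein: ProteinConfig = field(default_factory=ProteinConfig)
    window_mb: float = 10.0
    min_genes_per_window: int = 5

    # ----- derived -----

    def gene_ids(self) -> pd.Index:
        return build_annotation(self.genome).genes

    def validate(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not self.genome:
            raise ValueError("empty genome layout")
        for s in self.samples:
            if s.n_cells <= 0:
                raise ValueError(f"sample {s.sample_id}: n_cells must be > 0")
            if s.condition not in CONDITIONS:
                raise ValueError(f"unknown condition {s.condition!r}")
        # DE programs: pairwise disjoint, inside the gene universe
        universe = set(self.gene_ids())
        names = list(self.de_programs)
        for i, a in enumerate(names):
            missing = set(self.de_programs[a]) - universe
            if missing:
                raise ValueError(
                    f"program {a}: genes outside universe: {sorted(missing)[:5]}")
            for b in names[i + 1:]:
                overlap = set(self.de_programs[a]) & set(self.de_programs[b])
                if overlap:
                    raise ValueError(
                        f"programs {a}/{b} overlap: {sorted(overlap)[:5]}")
        # clones: segments within chromosome, non-overlapping within a clone
        lengths = {c.name: c.length_bp for c in self.genome}
        claimed: dict[str, str] = {}
        for clone in self.cnv_clones:
            for sid in clone.sample_ids:
                if sid in claimed and claimed[sid] != clone.clone_id:
                    raise ValueError(f"sample {sid} assigned to two clones")
                claimed[sid] = clone.clone_id
            by_chrom: dict[str, list[CNVSegment]] = {}
            for seg in clone.segments:
                if seg.chrom not in lengths:
                    raise ValueError(f"segment on unknown chromosome {seg.chrom}")
                if not (1 <= seg.start < seg.end <= lengths[seg.chrom]):
                    raise ValueError(
                        f"segment {seg} outside chromosome bounds")
                if seg.state not in STATE_DOSAGE:
                    raise ValueError(f"invalid CNV state {seg.state}")
                by_chrom.setdefault(seg.chrom, []).append(seg)
            for segs in by_chrom.values():
                segs = sorted(segs, key=lambda s: s.start)
                for s1, s2 in zip(segs, segs[1:]):
                    if s2.start <= s1.end:
                        raise ValueError(
                            f"overlapping CNV segments in clone "
                            f"{clone.clone_id}: {s1} / {s2}")

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class SimTruth:
    """Planted ground truth accompanying a simulated cohort."""

    cells: pd.DataFrame                 # index cell id; lineage, clone
    clone_window_states: pd.DataFrame   # clones x windows (incl. 'diploid')
    windows: pd.DataFrame               # the shared window grid
    programs: dict[str, list[str]]


# ---------------------------------------------------------------------------
# gene universe / annotation
# ---------------------------------------------------------------------------

def build_annotation(genome: tuple[ChromSpec, ...]) -> GeneAnnotation:
    """Lay genes along the miniature genome and weave in named genes.

    Plain genes are named G<index>; lineage markers, mitochondrial and
    ribosomal genes replace plain genes at evenly spaced positions so that
    marker and housekeeping genes are scattered across chromosomes.
    """
    rows = []
    idx = 0
    for chrom in genome:
        n = chrom.length_bp // chrom.gene_spacing_bp
        for i in range(n):
            start = i * chrom.gene_spacing_bp + 1
            rows.append({"gene": f"G{idx:05d}", "chrom": chrom.name,
                         "start": start,
                         "end": start + chrom.gene_spacing_bp // 2})
            idx += 1
    table = pd.DataFrame(rows)
    special = list(EPITHELIAL_MARKERS + IMMUNE_MARKERS + STROMAL_MARKERS
                   + MITO_GENES + RIBO_GENES)
    if len(table) < 4 * len(special):
        raise ValueError("genome too small for the named gene set")
    positions = np.linspace(1, len(table) - 2, len(special)).astype(int)
    table.loc[positions, "gene"] = special
    return GeneAnnotation(table.set_index("gene"))


def _pick_program_genes(genes: pd.Index, n_per_program: int,
                        seed: int) -> dict[str, list[str]]:
    plain = [g for g in genes if g.startswith("G")]
    rng = np.random.default_rng([seed, 7])
    chosen = rng.choice(len(plain), size=4 * n_per_program, replace=False)
    names = ["normal_specific", "shared_tumor", "amn_unique", "pmp_unique"]
    return {name: sorted(plain[i] for i in part)
            for name, part in zip(names, np.split(chosen, 4))}


def _lineage_baselines(genes: pd.Index, lineages, seed: int,
                       programs: dict[str, list[str]],
                       marker_boost: float = 8.0,
                       cross_suppress: float = 0.05,
                       lineage_sd: float = 0.45) -> None:
    """Fill ``LineageSpec.baseline`` vectors in place.

    Base gene weights are log-normal; each lineage gets an independent
    log-normal modulation, its own markers boosted and other lineages'
    markers suppressed.  Program genes get a fixed moderate baseline so
    the planted effects act on reliably detected genes.
    """
    rng = np.random.default_rng([seed, 11])
    base = rng.lognormal(0.0, 1.0, size=len(genes))
    gi = {g: j for j, g in enumerate(genes)}
    program_genes = [g for genes_ in programs.values() for g in genes_]
    base[[gi[g] for g in program_genes]] = rng.lognormal(
        np.log(4.0), 0.25, size=len(program_genes))
    all_markers = {m for lin in lineages for m in lin.markers}
    for lin in lineages:
        w = base * rng.lognormal(0.0, lineage_sd, size=len(genes))
        own = [gi[m] for m in lin.markers if m in gi]
        other = [gi[m] for m in (all_markers - set(lin.markers)) if m in gi]
        w[own] *= marker_boost
        w[other] *= cross_suppress
        lin.baseline = w


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _condition_programs(condition: str, programs: dict[str, list[str]]
                        ) -> list[str]:
    if condition == "normal":
        keys = ("normal_specific",)
    elif condition == "AMN":
        keys = ("shared_tumor", "amn_unique")
    else:
        keys = ("shared_tumor", "pmp_unique")
    return [g for k in keys for g in programs.get(k, [])]


def _clone_dosage(clone: CloneSpec, annotation: GeneAnnotation) -> np.ndarray:
    ann = annotation.table
    mid = ((ann["start"] + ann["end"]) // 2).to_numpy()
    chrom = ann["chrom"].to_numpy()
    dosage = np.ones(len(ann))
    for seg in clone.segments:
        covered = (chrom == seg.chrom) & (mid >= seg.start) & (mid <= seg.end)
        dosage[covered] = STATE_DOSAGE[seg.state]
    return dosage


def _truth_window_states(config: SimConfig, annotation: GeneAnnotation,
                         windows: pd.DataFrame) -> pd.DataFrame:
    """Per-clone true state per window: bp-overlap majority, else neutral."""
    out = {"diploid": np.full(len(windows), 3, dtype=int)}
    for clone in config.cnv_clones:
        states = np.full(len(windows), 3, dtype=int)
        for w, row in windows.iterrows():
            cover: dict[int, float] = {}
            for seg in clone.segments:
                if seg.chrom != row["chrom"]:
                    continue
                ov = (min(seg.end, row["end"])
                      - max(seg.start, row["start"]) + 1)
                if ov > 0:
                    cover[seg.state] = cover.get(seg.state, 0.0) + ov
            if cover:
                state, bp = max(cover.items(), key=lambda kv: kv[1])
                if bp > row["length_bp"] / 2.0:
                    states[w] = state
        out[clone.clone_id] = states
    return pd.DataFrame(out).T


def simulate_cohort(config: SimConfig
                    ) -> tuple[CountMatrix, GeneAnnotation, SimTruth]:
    """Draw a full cohort from the generative model (see module docstring)."""
    config.validate()
    annotation = build_annotation(config.genome)
    genes = annotation.genes
    rng = np.random.default_rng([config.seed, 1])

    if any(lin.baseline is None for lin in config.lineages):
        _lineage_baselines(genes, config.lineages, config.seed,
                           config.de_programs)
    gi = {g: j for j, g in enumerate(genes)}

    batches = sorted({s.batch for s in config.samples})
    batch_factor = {b: rng.lognormal(0.0, config.batch_effect_sd,
                                     size=len(genes)) for b in batches}
    clone_of_sample = {sid: clone for clone in config.cnv_clones
                      for sid in clone.sample_ids}
    dosage_of_clone = {clone.clone_id: _clone_dosage(clone, annotation)
                       for clone in config.cnv_clones}

    lineage_names = [lin.name for lin in config.lineages]
    default_props = np.full(len(lineage_names), 1.0 / len(lineage_names))

    blocks, meta_rows, truth_rows = [], [], []
    cell_counter = 0
    for s in config.samples:
        props = (np.asarray(s.lineage_props, dtype=float)
                 if s.lineage_props is not None else default_props)
        props = props / props.sum()
        lin_idx = rng.choice(len(lineage_names), size=s.n_cells, p=props)
        depths = rng.uniform(*config.depth_range, size=s.n_cells)
        clone = clone_of_sample.get(s.sample_id)
        counts = np.zeros((s.n_cells, len(genes)), dtype=np.int64)
        for li, lin in enumerate(config.lineages):
            rows = np.flatnonzero(lin_idx == li)
            if not len(rows):
                continue
            p = lin.baseline.astype(np.float64).copy()
            if lin.name == "epithelial":
                up = [gi[g] for g in
                      _condition_programs(s.condition, config.de_programs)]
                p[up] *= 2.0 ** config.de_log2_effect
            p /= p.sum()
            mu = depths[rows, None] * p[None, :]
            if clone is not None and lin.name == "epithelial":
                mu = mu * dosage_of_clone[clone.clone_id][None, :]
            mu = mu * batch_factor[s.batch][None, :]
            theta = config.nb_dispersion
            pnb = theta / (theta + mu)
            counts[rows] = rng.negative_binomial(theta, pnb)
        blocks.append(sp.csr_matrix(counts))
        for i in range(s.n_cells):
            cid = f"{s.sample_id}_c{cell_counter + i:05d}"
            meta_rows.append({"cell_id": cid, "sample_id": s.sample_id,
                              "patient": s.patient, "condition": s.condition,
                              "site": s.site, "batch": s.batch})
            is_epi = lineage_names[lin_idx[i]] == "epithelial"
            truth_rows.append({
                "cell_id": cid,
                "lineage": lineage_names[lin_idx[i]],
                "clone": (clone.clone_id if clone is not None and is_epi
                          else "diploid")})
        cell_counter += s.n_cells

    matrix = sp.vstack(blocks, format="csr")
    cell_meta = pd.DataFrame(meta_rows).set_index("cell_id")
    counts_obj = CountMatrix(matrix=matrix, cell_meta=cell_meta,
                             gene_ids=genes)
    windows = make_windows(annotation, config.window_mb,
                           config.min_genes_per_window)
    truth = SimTruth(
        cells=pd.DataFrame(truth_rows).set_index("cell_id"),
        clone_window_states=_truth_window_states(config, annotation, windows),
        windows=windows,
        programs=dict(config.de_programs))
    return counts_obj, annotation, truth


# ---------------------------------------------------------------------------
# bulk cohort
# ---------------------------------------------------------------------------

def simulate_bulk_cohort(config: SimConfig, signatures: SignatureSets
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bulk expression cohort carrying the derived signatures.

    Each sample's log2 expression = stromal background + purity x (goblet
    activity on the shared-tumor genes + metastasis activity on the
    PMP-unique genes + a normal-mucosa activity, scaled by 1 - purity, on
    the normal genes) + Gaussian noise.  With the co-expression flag both
    tumor activities equal one per-sample latent factor; otherwise they are
    independent.  Returns (samples x genes table, per-sample truth).
    """
    sets = signatures.as_dict()
    if not any(sets.values()):
        raise ValueError("signatures are empty")
    bulk = config.bulk
    if bulk.n_samples < 3:
        raise ValueError("need >= 3 bulk samples")
    rng = np.random.default_rng([config.seed, 2])
    genes = config.gene_ids()
    gi = {g: j for j, g in enumerate(genes)}

    background = rng.normal(5.0, 1.0, size=len(genes))
    purity = rng.beta(bulk.purity_alpha, bulk.purity_beta,
                      size=bulk.n_samples)
    latent = rng.normal(1.0, bulk.activity_sd, size=bulk.n_samples)
    if bulk.coexpression:
        a_goblet = latent.copy()
        a_metastasis = latent.copy()
    else:
        a_goblet = rng.normal(1.0, bulk.activity_sd, size=bulk.n_samples)
        a_metastasis = rng.normal(1.0, bulk.activity_sd,
                                  size=bulk.n_samples)
    a_normal = rng.normal(1.0, bulk.activity_sd, size=bulk.n_samples)

    X = np.tile(background, (bulk.n_samples, 1))
    amp = bulk.amplitude_log2
    for name, activity, scale in (
            ("shared_tumor", a_goblet, purity),
            ("pmp_unique", a_metastasis, purity),
            ("normal_specific", a_normal, 1.0 - purity)):
        cols = [gi[g] for g in sets.get(name, []) if g in gi]
        if cols:
            X[:, cols] += (scale * activity)[:, None] * amp
    if bulk.noise_sd > 0:
        X += rng.normal(0.0, bulk.noise_sd, size=X.shape)

    index = pd.Index([f"bulk{j:03d}" for j in range(bulk.n_samples)],
                     name="sample_id")
    table = pd.DataFrame(X, index=index, columns=genes)
    truth = pd.DataFrame({"purity": purity, "goblet_activity": a_goblet,
                          "metastasis_activity": a_metastasis,
                          "normal_activity": a_normal}, index=index)
    return table, truth


# ---------------------------------------------------------------------------
# protein table
# ---------------------------------------------------------------------------

def simulate_protein_table(config: SimConfig
                           ) -> tuple[ProteinTable, pd.DataFrame]:
    """Target/decoy p-value tables per ascites sample.

    Decoy p-values (and null targets) are uniform; a planted subset of
    targets carries inflated -log10 p.  Returns (table, per-row truth with
    the planted flag).
    """
    pc = config.protein
    if pc.n_decoys < 1:
        raise ValueError("need >= 1 decoy")
    rng = np.random.default_rng([config.seed, 3])
    rows, truth_rows = [], []
    for sample in pc.sample_ids:
        strong = set(rng.choice(pc.n_targets, size=min(pc.n_strong,
                                                       pc.n_targets),
                                replace=False).tolist())
        for i in range(pc.n_targets):
            pid = f"{sample}_T{i:04d}"
            if i in strong:
                neglog = rng.uniform(*pc.strong_neglog10_range)
                p = 10.0 ** (-neglog)
            else:
                p = rng.uniform(np.nextafter(0, 1), 1.0)
            rows.append({"protein_id": pid, "p_value": p, "decoy": False,
                         "sample_id": sample})
            truth_rows.append({"protein_id": pid, "sample_id": sample,
                               "planted": i in strong})
        for i in range(pc.n_decoys):
            rows.append({"protein_id": f"{sample}_D{i:04d}",
                         "p_value": rng.uniform(np.nextafter(0, 1), 1.0),
                         "decoy": True, "sample_id": sample})
    return (ProteinTable(pd.DataFrame(rows)),
            pd.DataFrame(truth_rows).set_index("protein_id"))


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def write_fixtures(counts: CountMatrix, annotation: GeneAnnotation,
                   out_dir, gene_sets: dict[str, list[str]] | None = None
                   ) -> dict[str, str]:
    """Write MTX + TSV + GMT fixtures; returns a manifest of paths.

    Reading the files back with :func:`read_fixtures` reproduces the inputs
    exactly (integer MatrixMarket counts, tab-separated metadata and
    annotation).
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest = {}

    def _path(name):
        p = os.path.join(out_dir, name)
        manifest[name] = p
        return p

    try:
        scipy.io.mmwrite(_path("matrix.mtx"), counts.matrix.astype(np.int64),
                         field="integer")
        counts.cell_meta.index.to_series().to_csv(
            _path("barcodes.tsv"), sep="\t", index=False, header=False)
        pd.Series(counts.gene_ids).to_csv(
            _path("features.tsv"), sep="\t", index=False, header=False)
        counts.cell_meta.reset_index(names="cell_id").to_csv(
            _path("metadata.tsv"), sep="\t", index=False)
        annotation.write_tsv(_path("annotation.tsv"))
        if gene_sets is not None:
            write_gmt(gene_sets, _path("gene_sets.gmt"))
    except OSError as err:
        raise OSError(f"failed writing fixture {err.filename}: {err}") from err
    return manifest


def read_fixtures(in_dir) -> tuple[CountMatrix, GeneAnnotation,
                                   dict[str, list[str]] | None]:
    def _path(name):
        p = os.path.join(in_dir, name)
        if not os.path.exists(p) and name != "gene_sets.gmt":
            raise FileNotFoundError(f"missing fixture file: {p}")
        return p

    matrix = sp.csr_matrix(scipy.io.mmread(_path("matrix.mtx")))
    meta = pd.read_csv(_path("metadata.tsv"), sep="\t").set_index("cell_id")
    genes = pd.read_csv(_path("features.tsv"), sep="\t", header=None)[0]
    annotation = GeneAnnotation.read_tsv(_path("annotation.tsv"))
    counts = CountMatrix(matrix=matrix, cell_meta=meta,
                         gene_ids=pd.Index(genes))
    gmt_path = os.path.join(in_dir, "gene_sets.gmt")
    sets = read_gmt(gmt_path) if os.path.exists(gmt_path) else None
    return counts, annotation, sets


def fixture_checksums(manifest: dict[str, str]) -> dict[str, str]:
    """md5 of each fixture file (byte-identity checks across reruns)."""
    out = {}
    for name, path in sorted(manifest.items()):
        with open(path, "rb") as fh:
            out[name] = hashlib.md5(fh.read()).hexdigest()
    return out


# ---------------------------------------------------------------------------
# ready-made study configurations
# ---------------------------------------------------------------------------

DEFAULT_GENOME = tuple(ChromSpec(f"chr{i + 1}", 60_000_000, 100_000)
                       for i in range(4))


def _lineages() -> tuple[LineageSpec, ...]:
    return (LineageSpec("epithelial", EPITHELIAL_MARKERS),
            LineageSpec("immune", IMMUNE_MARKERS),
            LineageSpec("stromal", STROMAL_MARKERS))


def default_config(seed: int = 0, cells_per_sample: int = 250) -> SimConfig:
    """The standard desk-scale cohort: 3 normal, 3 AMN and one PMP patient
    with three metastatic sites, across two experimental batches, with
    nested CNV clones and the four planted DE programs."""
    samples = (
        SampleSpec("N1", "patN1", "normal", "appendix", "b1", cells_per_sample),
        SampleSpec("N2", "patN2", "normal", "appendix", "b2", cells_per_sample),
        SampleSpec("N3", "patN3", "normal", "appendix", "b1", cells_per_sample),
        SampleSpec("A1", "patA1", "AMN", "appendix", "b1", cells_per_sample),
        SampleSpec("A2", "patA2", "AMN", "appendix", "b2", cells_per_sample),
        SampleSpec("A3", "patA3", "AMN", "appendix", "b2", cells_per_sample),
        SampleSpec("P1_mes", "patP1", "PMP", "mesentery", "b2",
                   cells_per_sample),
        SampleSpec("P1_omen", "patP1", "PMP", "omentum", "b1",
                   cells_per_sample),
        SampleSpec("P1_ovary", "patP1", "PMP", "ovary", "b2",
                   cells_per_sample),
    )
    props = (0.6, 0.25, 0.15)
    samples = tuple(replace(s, lineage_props=props) for s in samples)
    # AMN clones: one 30 Mb gain each (FGA 12.5%); PMP sites share a 20 Mb
    # gain, the omental/ovarian pair shares a second gain, and the
    # mesenteric site carries private events (FGA ~16.7%)
    shared = CNVSegment("chr2", 1, 20_000_000, 4)
    pair_evt = CNVSegment("chr4", 1, 20_000_000, 4)
    clones = (
        CloneSpec("cloneA1", ("A1",), (CNVSegment("chr3", 1, 30_000_000, 4),)),
        CloneSpec("cloneA2", ("A2",), (CNVSegment("chr1", 30_000_001,
                                                  60_000_000, 4),)),
        CloneSpec("cloneA3", ("A3",), (CNVSegment("chr4", 30_000_001,
                                                  60_000_000, 2),)),
        CloneSpec("cloneP1mes", ("P1_mes",),
                  (shared, CNVSegment("chr1", 1, 10_000_000, 4),
                   CNVSegment("chr3", 40_000_001, 60_000_000, 2))),
        CloneSpec("cloneP1pair_omen", ("P1_omen",), (shared, pair_evt)),
        CloneSpec("cloneP1pair_ovary", ("P1_ovary",), (shared, pair_evt)),
    )
    cfg = SimConfig(seed=seed, genome=DEFAULT_GENOME, samples=samples,
                    lineages=_lineages(), cnv_clones=clones)
    cfg.de_programs = _pick_program_genes(cfg.gene_ids(), 30, seed)
    return cfg


def batch_mixing_config(seed: int = 0, n_cells: int = 3000) -> SimConfig:
    """Three lineages split over two batches; no clones, no DE programs."""
    per = n_cells // 2
    samples = (
        SampleSpec("S_b1", "pat1", "normal", "appendix", "b1", per,
                   (1 / 3, 1 / 3, 1 / 3)),
        SampleSpec("S_b2", "pat2", "normal", "appendix", "b2",
                   n_cells - per, (1 / 3, 1 / 3, 1 / 3)),
    )
    return SimConfig(seed=seed, genome=DEFAULT_GENOME, samples=samples,
                     lineages=_lineages())


def cnv_recovery_config(seed: int = 0, n_tumor_cells: int = 150,
                        n_normal_cells: int = 150) -> SimConfig:
    """One diploid normal sample plus one tumor sample with planted
    single-copy gains and losses, at ~2000-count depth."""
    samples = (
        SampleSpec("NORM", "patN", "normal", "appendix", "b1",
                   n_normal_cells, (0.6, 0.25, 0.15)),
        SampleSpec("TUM", "patT", "PMP", "omentum", "b1", n_tumor_cells,
                   (1.0, 0.0, 0.0)),
    )
    clone = CloneSpec("cloneT", ("TUM",), (
        CNVSegment("chr1", 1, 20_000_000, 4),
        CNVSegment("chr2", 20_000_001, 40_000_000, 2),
        CNVSegment("chr3", 1, 10_000_000, 2),
        CNVSegment("chr4", 40_000_001, 60_000_000, 4),
    ))
    return SimConfig(seed=seed, genome=DEFAULT_GENOME, samples=samples,
                     lineages=_lineages(), cnv_clones=(clone,),
                     depth_range=(2000.0, 2000.0))


def fga_cohort_config(seed: int = 0, n_samples: int = 20,
                      cells_per_sample: int = 40) -> SimConfig:
    """Many single-clone tumor samples with randomized window-aligned
    segments, plus a shared normal reference sample."""
    rng = np.random.default_rng([seed, 5])
    samples = [SampleSpec("NORM", "patN", "normal", "appendix", "b1",
                          120, (0.6, 0.25, 0.15))]
    clones = []
    # plant segments aligned to the realized window grid so the per-clone
    # truth states are unambiguous
    grid = make_windows(build_annotation(DEFAULT_GENOME), 10.0, 5)
    for k in range(n_samples):
        sid = f"T{k:02d}"
        condition = "AMN" if k < n_samples // 2 else "PMP"
        samples.append(SampleSpec(sid, f"pat{sid}", condition, "appendix",
                                  "b1", cells_per_sample, (1.0, 0.0, 0.0)))
        n_seg = rng.integers(1, 4)
        segs, used = [], set()
        for _ in range(n_seg):
            w0 = int(rng.integers(len(grid) - 1))
            if grid.loc[w0, "chrom"] != grid.loc[w0 + 1, "chrom"]:
                continue
            if used & {w0, w0 + 1}:
                continue
            used.update({w0, w0 + 1})
            state = int(rng.choice([2, 4, 5]))
            segs.append(CNVSegment(grid.loc[w0, "chrom"],
                                   int(grid.loc[w0, "start"]),
                                   int(grid.loc[w0 + 1, "end"]), state))
        clones.append(CloneSpec(f"clone{sid}", (sid,), tuple(segs)))
    return SimConfig(seed=seed, genome=DEFAULT_GENOME, samples=tuple(samples),
                     lineages=_lineages(), cnv_clones=tuple(clones),
                     depth_range=(2000.0, 2000.0))


def nested_clone_config(seed: int = 0, cells_per_site: int = 50) -> SimConfig:
    """Three metastatic sites with nested clone structure (root -> shared
    events -> site-pair events -> private events) plus a normal sample."""
    samples = (
        SampleSpec("NORM", "patN", "normal", "appendix", "b1", 120,
                   (0.6, 0.25, 0.15)),
        SampleSpec("siteA", "patP", "PMP", "mesentery", "b1",
                   cells_per_site, (1.0, 0.0, 0.0)),
        SampleSpec("siteB", "patP", "PMP", "omentum", "b1",
                   cells_per_site, (1.0, 0.0, 0.0)),
        SampleSpec("siteC", "patP", "PMP", "ovary", "b1",
                   cells_per_site, (1.0, 0.0, 0.0)),
    )
    trunk = CNVSegment("chr2", 1, 20_000_000, 4)
    pair1 = CNVSegment("chr4", 1, 20_000_000, 4)
    pair2 = CNVSegment("chr1", 40_000_001, 60_000_000, 4)
    clones = (
        CloneSpec("cloneA", ("siteA",),
                  (trunk, CNVSegment("chr3", 1, 10_000_000, 2))),
        CloneSpec("cloneB", ("siteB",),
                  (trunk, pair1, pair2,
                   CNVSegment("chr3", 30_000_001, 40_000_000, 4))),
        CloneSpec("cloneC", ("siteC",),
                  (trunk, pair1, pair2)),
    )
    return SimConfig(seed=seed, genome=DEFAULT_GENOME, samples=samples,
                     lineages=_lineages(), cnv_clones=clones,
                     depth_range=(2000.0, 2000.0))


def signature_recovery_config(seed: int = 0,
                              cells_per_condition: int = 200,
                              genes_per_program: int = 30) -> SimConfig:
    """Epithelial-only cells, one sample per condition, no clones: the
    planted four-program recovery experiment."""
    samples = (
        SampleSpec("N", "patN", "normal", "appendix", "b1",
                   cells_per_condition, (1.0, 0.0, 0.0)),
        SampleSpec("A", "patA", "AMN", "appendix", "b1",
                   cells_per_condition, (1.0, 0.0, 0.0)),
        SampleSpec("P", "patP", "PMP", "omentum", "b1",
                   cells_per_condition, (1.0, 0.0, 0.0)),
    )
    cfg = SimConfig(seed=seed, genome=DEFAULT_GENOME, samples=samples,
                    lineages=_lineages())
    cfg.de_programs = _pick_program_genes(cfg.gene_ids(),
                                          genes_per_program, seed)
    return cfg
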