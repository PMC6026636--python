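"""End-to-end orchestration: simulate -> index -> classify -> profile genes -> stats.

A single ``PipelineConfig`` drives every stage with one seed; stage outputs
are cached on disk keyed by a content hash of their inputs and parameters,
so reruns with an unchanged config are byte-identical and cheap. The final
``StudyReport`` aggregates every comparison into one JSON document whose
numbers all trace back to stage output files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_stats as cs
from . import gene_profiler as gp
from . import read_classifier as rc
from . import synthetic_community as sc
from .fingerprint_index import build_index, load_index, save_index, reference_hash
from .synthetic_community import ConfigurationError

logger = logging.getLogger(__name__)


class ConfigValidationError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid pipeline config:\n" + "\n".join(
            f"  - {e}" for e in errors))


@dataclass
class PipelineConfig:
    outdir: str = "pipeline_out"
    seed: int = 0
    # either a simulation block or explicit input paths
    simulation: dict | None = None
    sample_plan: dict | None = None  # sample_type -> {cohort: n}; default plan if None
    genomes: str | None = None
    tree: str | None = None
    panel: str | None = None
    reads_dir: str | None = None
    metadata: str | None = None
    clinical: str | None = None
    # classifier parameters
    k: int = 21
    max_edit: int | None = None
    min_reads: int = 5
    min_fingerprint_frac: float = 0.005
    # statistics parameters
    subsample_depth: int | None = None  # None -> per-sample-type minimum
    log2fc_threshold: float = 2.0
    alpha: float = 0.05
    diff_gene_quantity: str = "rpm"

    def classifier_params(self) -> rc.ClassifierParams:
        return rc.ClassifierParams(self.max_edit, self.min_reads,
                                   self.min_fingerprint_frac)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def validate_config(path_or_dict) -> PipelineConfig:
    """Parse and validate a pipeline config, reporting all errors at once."""
    if isinstance(path_or_dict, (str, Path)):
        raw = json.loads(Path(path_or_dict).read_text())
    else:
        raw = dict(path_or_dict)
    errors: list[str] = []
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        errors.append(f"unknown fields: {sorted(unknown)}")
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    if cfg.k < 8:
        errors.append(f"k={cfg.k}: fingerprint index requires k >= 8")
    if cfg.min_reads < 0:
        errors.append("min_reads must be non-negative")
    if not 0 <= cfg.min_fingerprint_frac <= 1:
        errors.append("min_fingerprint_frac must lie in [0, 1]")
    if not 0 < cfg.alpha < 1:
        errors.append("alpha must lie in (0, 1)")
    if cfg.subsample_depth is not None and cfg.subsample_depth <= 0:
        errors.append("subsample_depth must be positive")
    if cfg.simulation is not None:
        try:
            sim = dict(cfg.simulation)
            sim.setdefault("seed", cfg.seed)
            sc.SimulationConfig(**sim)
        except (ConfigurationError, TypeError) as exc:
            errors.append(f"simulation block: {exc}")
        if cfg.sample_plan is not None:
            for stype, cohorts in cfg.sample_plan.items():
                for cohort, n in cohorts.items():
                    if cohort not in sc.COHORTS:
                        errors.append(f"sample_plan: unknown cohort {cohort!r}")
                    if not isinstance(n, int) or n < 0:
                        errors.append(f"sample_plan[{stype}][{cohort}] must be a"
                                      " non-negative integer")
    else:
        for name in ("genomes", "tree", "panel", "reads_dir", "metadata"):
            p = getattr(cfg, name)
            if p is None:
                errors.append(f"{name} path required when no simulation block")
            elif not Path(p).exists():
                errors.append(f"{name} path does not exist: {p}")
    if errors:
        raise ConfigValidationError(errors)
    return cfg


@dataclass
class StudyReport:
    config_hash: str
    outdir: str
    n_samples: int
    clinical_tests: dict = field(default_factory=dict)
    alpha_diversity: dict = field(default_factory=dict)
    lrt: dict = field(default_factory=dict)
    ordination: dict = field(default_factory=dict)
    flagged_genes: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2,
                                         default=_jsonable) + "\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _cached(path: Path, input_hash: str) -> bool:
    side = path.with_suffix(path.suffix + ".hash")
    return path.exists() and side.exists() and side.read_text() == input_hash


def _mark(path: Path, input_hash: str) -> None:
    path.with_suffix(path.suffix + ".hash").write_text(input_hash)


# ---------------------------------------------------------------------------
# Stages

def stage_simulate(cfg: PipelineConfig, outdir: Path) -> Path:
    study = outdir / "study"
    sim = dict(cfg.simulation or {})
    sim.setdefault("seed", cfg.seed)
    sim_cfg = sc.SimulationConfig(**sim)
    h = hashlib.sha256(json.dumps([asdict(sim_cfg), cfg.sample_plan],
                                  sort_keys=True,
                                  default=_jsonable).encode()).hexdigest()[:16]
    marker = study / "metadata.tsv"
    if _cached(marker, h):
        logger.info("simulate: cached")
        return study
    sc.simulate_study(sim_cfg, study, sample_plan=cfg.sample_plan)
    _mark(marker, h)
    return study


def stage_index(cfg: PipelineConfig, genomes: dict[str, str],
                tree_path: Path, outdir: Path):
    from .fingerprint_index import PhyloTree
    index_path = outdir / "fingerprints.json"
    ref_hash = reference_hash(genomes)
    h = f"{ref_hash}:{cfg.k}"
    if _cached(index_path, h):
        logger.info("index: cached")
        return load_index(index_path, expected_reference_hash=ref_hash)
    tree = PhyloTree.read_newick(tree_path)
    index = build_index(genomes, tree, cfg.k)
    save_index(index, index_path)
    _mark(index_path, h)
    return index


def stage_classify(cfg: PipelineConfig, index, genomes, meta: pd.DataFrame,
                   reads_dir: Path, outdir: Path) -> pd.DataFrame:
    """Classify every sample; returns the samples x taxa count matrix."""
    params = cfg.classifier_params()
    prof_dir = outdir / "profiles"
    prof_dir.mkdir(parents=True, exist_ok=True)
    matrix_path = outdir / "taxa_counts.tsv"
    abundance_path = outdir / "taxa_abundance.tsv"
    h = f"{cfg.content_hash()}:classify"
    if _cached(matrix_path, h):
        logger.info("classify: cached")
        return pd.read_csv(matrix_path, sep="\t", index_col=0)
    profiles = []
    seed_index = rc.GenomeSeedIndex(genomes, index.k)
    for sid in meta["sample_id"]:
        cls = rc.classify_fastq(reads_dir / f"{sid}.fastq", index, genomes,
                                params, sid, seed_index)
        prof = rc.aggregate_sample(cls, index, params)
        prof.to_frame().to_csv(prof_dir / f"{sid}.tsv", sep="\t", index=False)
        profiles.append(prof)
    counts = rc.profiles_to_matrix(profiles, index.tree.leaf_names, "counts")
    counts.to_csv(matrix_path, sep="\t")
    rc.profiles_to_matrix(profiles, index.tree.leaf_names, "abundance").to_csv(
        abundance_path, sep="\t")
    _mark(matrix_path, h)
    return counts


def stage_profile_genes(cfg: PipelineConfig, panel: gp.GenePanel,
                        meta: pd.DataFrame, reads_dir: Path,
                        outdir: Path) -> pd.DataFrame:
    table_path = outdir / "gene_coverage.tsv"
    h = f"{cfg.content_hash()}:{panel.version_hash()}:genes"
    if _cached(table_path, h):
        logger.info("profile-genes: cached")
        return pd.read_csv(table_path, sep="\t")
    per_sample, totals = {}, {}
    for sid in meta["sample_id"]:
        path = reads_dir / f"{sid}.fastq"
        n_reads = sum(1 for _ in open(path)) // 4
        per_sample[sid] = gp.map_fastq_to_genes(path, panel, cfg.k, cfg.max_edit)
        totals[sid] = n_reads
    table = gp.build_gene_matrix(per_sample, panel, meta, totals,
                                 panel_hash=panel.version_hash())
    table.to_csv(table_path, sep="\t", index=False)
    _mark(table_path, h)
    return table


def stage_stats(cfg: PipelineConfig, counts: pd.DataFrame,
                gene_table: pd.DataFrame, meta: pd.DataFrame,
                clinical: pd.DataFrame | None, outdir: Path,
                report: StudyReport) -> None:
    meta = meta.set_index("sample_id")
    rng_seed = cfg.seed + 13

    if clinical is not None:
        binary = [c for c in clinical.columns
                  if c not in ("subject", "cohort")
                  and set(clinical[c].unique()) <= {0, 1}]
        continuous = [c for c in clinical.columns
                      if c not in ("subject", "cohort") and c not in binary]
        for cov in binary:
            tab = pd.crosstab(clinical["cohort"], clinical[cov]) \
                .reindex(index=["old", "new"], columns=[1, 0], fill_value=0)
            res = cs.fisher_exact_2x2(tab.to_numpy())
            report.clinical_tests[cov] = res.to_dict()
        for cov in continuous:
            old = clinical.loc[clinical["cohort"] == "old", cov]
            new = clinical.loc[clinical["cohort"] == "new", cov]
            report.clinical_tests[cov] = cs.two_sample_t(old, new, tails=2).to_dict()

    # alpha diversity per sample, summarised per sample type and cohort
    chao = counts.apply(lambda row: cs.chao1(row.to_numpy()), axis=1)
    alpha_tab = pd.DataFrame({"chao1": chao}).join(
        meta[["cohort", "sample_type"]])
    alpha_tab.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
    for stype, grp in alpha_tab.groupby("sample_type"):
        old = grp.loc[grp["cohort"] == "old", "chao1"]
        new = grp.loc[grp["cohort"] == "new", "chao1"]
        entry = {"mean_old": float(old.mean()), "mean_new": float(new.mean())}
        if len(old) >= 2 and len(new) >= 2:
            entry["t_test"] = cs.two_sample_t(old, new, tails=2).to_dict()
        report.alpha_diversity[stype] = entry

    # whole-community LRT per sample type, rarefied to a common depth
    for stype, sids in meta.groupby("sample_type").groups.items():
        sub = counts.loc[[s for s in sids if s in counts.index]]
        if len(sub) < 4:
            continue
        depth = cfg.subsample_depth or int(sub.sum(axis=1).min())
        rare = rc.subsample_counts(sub, depth, seed=rng_seed)
        detected = rare.columns[(rare.sum(axis=0) > 0)]
        rare = rare[detected]
        grp = meta.loc[rare.index, "cohort"]
        a = rare[grp == "old"].to_numpy()
        b = rare[grp == "new"].to_numpy()
        if len(a) >= 2 and len(b) >= 2:
            res = cs.dm_lrt(a, b)
            res.extra["subsample_depth"] = depth
            report.lrt[stype] = res.to_dict()

    # ordination + clustering + similarity over all samples
    shared = counts.loc[counts.sum(axis=1) > 0]
    rel = shared.div(shared.sum(axis=1), axis=0) * 100
    bc = cs.bray_curtis_matrix(rel)
    bc.to_csv(outdir / "bray_curtis.tsv", sep="\t")
    coords, evals = cs.pcoa(bc.to_numpy())
    coord_df = pd.DataFrame(coords[:, :min(3, coords.shape[1])],
                            index=rel.index,
                            columns=[f"PCo{i+1}" for i in
                                     range(min(3, coords.shape[1]))])
    coord_df.to_csv(outdir / "pcoa_coordinates.tsv", sep="\t")
    pd.Series(evals, name="eigenvalue").to_csv(outdir / "pcoa_eigenvalues.tsv",
                                               sep="\t")
    medoids, labels = cs.pam_cluster(bc.to_numpy(), 2)
    pd.DataFrame({"sample_id": rel.index, "pam_label": labels}).to_csv(
        outdir / "pam_clusters.tsv", sep="\t", index=False)
    cs.pearson_similarity(rel).to_csv(outdir / "pearson_similarity.tsv", sep="\t")
    if coords.shape[1] >= 2:
        cs.biplot_vectors(coords, rel).to_csv(outdir / "biplot_vectors.tsv",
                                              sep="\t")
    report.ordination = {
        "eigenvalues": [float(e) for e in evals[:5]],
        "n_negative_eigenvalues": int((evals < 0).sum()),
        "pam_medoids": [str(rel.index[m]) for m in medoids],
    }

    # differential genes per sample type (old = A, new = B)
    wide = gp.gene_matrix_wide(gene_table, cfg.diff_gene_quantity)
    gmeta = gene_table[["sample_id", "cohort", "sample_type"]].drop_duplicates() \
        .set_index("sample_id")
    flagged_frames = []
    for stype, sids in gmeta.groupby("sample_type").groups.items():
        sub = wide.loc[[s for s in sids if s in wide.index]]
        grp = gmeta.loc[sub.index, "cohort"]
        a, b = sub[grp == "old"], sub[grp == "new"]
        if len(a) < 2 or len(b) < 2:
            continue
        res = cs.diff_genes(a, b, cfg.log2fc_threshold)
        frame = cs.diff_genes_frame(res)
        frame.insert(0, "sample_type", stype)
        flagged_frames.append(frame)
        report.flagged_genes[stype] = [r.gene_id for r in res if r.flagged]
    if flagged_frames:
        pd.concat(flagged_frames).to_csv(outdir / "diff_genes.tsv", sep="\t",
                                         index=False)


def run_pipeline(config: PipelineConfig | dict | str | Path) -> StudyReport:
    """Execute every stage; returns the aggregated StudyReport.

    Stage outputs are cached under ``config.outdir`` and reused when the
    config is unchanged; a failed stage aborts with its name while partial
    outputs remain on disk for inspection.
    """
    cfg = config if isinstance(config, PipelineConfig) else validate_config(config)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        if cfg.simulation is not None:
            study = stage_simulate(cfg, outdir)
            genomes_path, tree_path = study / "genomes.fasta", study / "tree.nwk"
            panel_path, reads_dir = study / "panel.fasta", study / "reads"
            meta_path, clinical_path = study / "metadata.tsv", study / "clinical.tsv"
        else:
            genomes_path, tree_path = Path(cfg.genomes), Path(cfg.tree)
            panel_path, reads_dir = Path(cfg.panel), Path(cfg.reads_dir)
            meta_path = Path(cfg.metadata)
            clinical_path = Path(cfg.clinical) if cfg.clinical else None

        genomes = sc.read_genomes_fasta(genomes_path)
        meta = pd.read_csv(meta_path, sep="\t")
        clinical = (pd.read_csv(clinical_path, sep="\t")
                    if clinical_path and clinical_path.exists() else None)
        panel = gp.GenePanel.from_fasta(panel_path)

        stage = "index"
        index = stage_index(cfg, genomes, tree_path, outdir)
        stage = "classify"
        counts = stage_classify(cfg, index, genomes, meta, reads_dir, outdir)
        stage = "profile-genes"
        gene_table = stage_profile_genes(cfg, panel, meta, reads_dir, outdir)
        stage = "stats"
        report = StudyReport(config_hash=cfg.content_hash(), outdir=str(outdir),
                             n_samples=len(meta))
        stage_stats(cfg, counts, gene_table, meta, clinical, outdir, report)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    report.files = {
        "taxa_counts": str(outdir / "taxa_counts.tsv"),
        "gene_coverage": str(outdir / "gene_coverage.tsv"),
        "report": str(outdir / "report.json"),
    }
    report.to_json(outdir / "report.json")
    return report
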