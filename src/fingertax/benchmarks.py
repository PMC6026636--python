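"""Self-contained evaluation benchmarks for the pipeline.

Each function builds its own synthetic inputs from a seed, runs the
relevant pipeline stages, and returns a scalar quality measure:
calibration and power of the Dirichlet-Multinomial likelihood-ratio test,
taxonomic soundness of the classifier on error-free reads, end-to-end
abundance recovery error, and recovery of the designed differential-gene
set. Used by the test suite and the reproduction script.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_stats as cs
from . import gene_profiler as gp
from . import read_classifier as rc
from . import synthetic_community as sc
from .fingerprint_index import build_index


def _dm_draw(rng, pi, theta, n_samples, depth):
    alpha = np.asarray(pi) * (1 - theta) / theta
    p = rng.dirichlet(alpha, size=n_samples)
    return np.array([rng.multinomial(depth, q) for q in p])


def lrt_type1_error(reps: int = 500, n_per_group: int = 10,
                    depth: int = 10_000, alpha_level: float = 0.05,
                    seed: int = 0,
                    config: sc.SimulationConfig | None = None) -> float:
    """Null rejection rate of dm_lrt when both cohorts share one DM law.

    Conditions follow the generator defaults: 12 taxa with the rank-skewed
    mean composition and overdispersion theta.
    """
    cfg = config or sc.SimulationConfig()
    rng = np.random.default_rng(seed)
    pi, theta = np.asarray(cfg.pi_base), cfg.theta
    rejections = 0
    for _ in range(reps):
        a = _dm_draw(rng, pi, theta, n_per_group, depth)
        b = _dm_draw(rng, pi, theta, n_per_group, depth)
        rejections += cs.dm_lrt(a, b).p_value < alpha_level
    return rejections / reps


def lrt_power(reps: int = 100, n_per_group: int = 10, depth: int = 10_000,
              alpha_level: float = 0.05, seed: int = 0,
              sample_type: str = "skin",
              config: sc.SimulationConfig | None = None) -> float:
    """Rejection rate of dm_lrt at the generator's cohort effect size
    (the skin/environment composition shift)."""
    cfg = config or sc.SimulationConfig()
    rng = np.random.default_rng(seed)
    pi_old = sc.shifted_pi(cfg, "old", sample_type)
    pi_new = sc.shifted_pi(cfg, "new", sample_type)
    rejections = 0
    for _ in range(reps):
        a = _dm_draw(rng, pi_old, cfg.theta, n_per_group, depth)
        b = _dm_draw(rng, pi_new, cfg.theta, n_per_group, depth)
        rejections += cs.dm_lrt(a, b).p_value < alpha_level
    return rejections / reps


def _study(config: sc.SimulationConfig, plan: dict, outdir: Path):
    meta = sc.simulate_study(config, outdir, sample_plan=plan)
    genomes = sc.read_genomes_fasta(outdir / "genomes.fasta")
    from .fingerprint_index import PhyloTree
    tree = PhyloTree.read_newick(outdir / "tree.nwk")
    return meta, tree, genomes


def classifier_soundness(seed: int = 0, n_taxa: int = 8,
                         genome_length: int = 6000,
                         reads_per_sample: int = 1500,
                         plan: dict | None = None) -> tuple[int, int]:
    """(violations, assigned reads) over error-free fixture samples.

    A violation is an accepted genome-derived read whose assigned node's
    subtree excludes the read's true source genome.
    """
    cfg = sc.SimulationConfig(n_taxa=n_taxa, genome_length=genome_length,
                              reads_per_sample=reads_per_sample,
                              seq_error_rate=0.0, seed=seed)
    plan = plan or {"stool_2wk": {"old": 2, "new": 2},
                    "skin": {"old": 2, "new": 2}}
    violations = assigned = 0
    with tempfile.TemporaryDirectory() as tmp:
        outdir = Path(tmp)
        meta, tree, genomes = _study(cfg, plan, outdir)
        index = build_index(genomes, tree, k=21)
        seed_index = rc.GenomeSeedIndex(genomes, index.k)
        from Bio import SeqIO
        for sid in meta["sample_id"]:
            recs = list(SeqIO.parse(str(outdir / "reads" / f"{sid}.fastq"),
                                    "fastq"))
            cls = rc.classify_reads(((r.id, str(r.seq)) for r in recs),
                                    index, genomes, sample_id=sid,
                                    seed_index=seed_index)
            for r, a in zip(recs, cls.assignments):
                _, taxon, contig, _, _ = r.id.split("|")
                if contig.startswith("spike:") or a.status != "assigned":
                    continue
                assigned += 1
                if not tree.is_ancestor(a.node, taxon):
                    violations += 1
    return violations, assigned


def abundance_recovery_mae(seed: int = 0,
                           config: sc.SimulationConfig | None = None,
                           plan: dict | None = None) -> float:
    """Mean absolute abundance error (percentage points) of the full
    classifier chain on DM-simulated, spike-free samples."""
    cfg = config or sc.SimulationConfig(gene_spikes=[], seed=seed)
    plan = plan or {"stool_2wk": {"old": 2, "new": 2}}
    errors = []
    with tempfile.TemporaryDirectory() as tmp:
        outdir = Path(tmp)
        meta, tree, genomes = _study(cfg, plan, outdir)
        truth = pd.read_csv(outdir / "true_compositions.tsv", sep="\t",
                            index_col="sample_id")
        index = build_index(genomes, tree, k=21)
        seed_index = rc.GenomeSeedIndex(genomes, index.k)
        for sid in meta["sample_id"]:
            cls = rc.classify_fastq(outdir / "reads" / f"{sid}.fastq", index,
                                    genomes, sample_id=sid,
                                    seed_index=seed_index)
            prof = rc.aggregate_sample(cls, index)
            t = truth.loc[sid]
            t_pct = t / t.sum() * 100
            est = np.array([prof.leaf_abundance.get(x, 0.0) for x in t.index])
            errors.append(np.abs(est - t_pct.to_numpy()).mean())
    return float(np.mean(errors))


def expected_gene_log2fc(config: sc.SimulationConfig,
                         sample_type: str = "stool_2wk") -> dict[str, float]:
    """Design-implied log2 fold change (new vs old) of each panel gene's
    read frequency, from copy numbers, host composition and contig lengths.
    """
    copies = {"old": {}, "new": {}}
    for gid, cohort, n in config.gene_spikes:
        copies[cohort][gid] = copies[cohort].get(gid, 0) + n
    host_len = {
        c: config.genome_length + config.gene_length * sum(copies[c].values())
        for c in copies}
    host = sorted(range(config.n_taxa))[config.spike_host_taxon]
    out = {}
    eps = 1e-12
    genes = set(copies["old"]) | set(copies["new"])
    for gid in sorted(genes):
        rates = {}
        for c in ("old", "new"):
            pi_host = sc.shifted_pi(config, c, sample_type)[host]
            rates[c] = (pi_host * config.gene_length * copies[c].get(gid, 0)
                        / host_len[c])
        out[gid] = float(np.log2((rates["new"] + eps) / (rates["old"] + eps)))
    return out


def designed_gene_sets(config: sc.SimulationConfig,
                       threshold: float = 2.0) -> tuple[set, set, set]:
    """(up in new, down in new, null) gene ids implied by the spike design."""
    l2fc = expected_gene_log2fc(config)
    up = {g for g, v in l2fc.items() if v >= threshold}
    down = {g for g, v in l2fc.items() if v <= -threshold}
    null = set(l2fc) - up - down
    return up, down, null


def spiked_gene_recovery(seed: int = 0, n_per_cohort: int = 5,
                         reads_per_sample: int = 12_000,
                         config: sc.SimulationConfig | None = None) -> dict:
    """Run the gene profiler + diff_genes on one spiked synthetic cohort
    pair; report flagged sets vs the design."""
    cfg = config or sc.SimulationConfig(seed=seed,
                                        reads_per_sample=reads_per_sample)
    plan = {"stool_2wk": {"old": n_per_cohort, "new": n_per_cohort}}
    with tempfile.TemporaryDirectory() as tmp:
        outdir = Path(tmp)
        meta, _, _ = _study(cfg, plan, outdir)
        panel = gp.GenePanel.from_fasta(outdir / "panel.fasta")
        per_sample, totals = {}, {}
        for sid in meta["sample_id"]:
            path = outdir / "reads" / f"{sid}.fastq"
            per_sample[sid] = gp.map_fastq_to_genes(path, panel, k=21)
            totals[sid] = cfg.reads_per_sample
        table = gp.build_gene_matrix(per_sample, panel, meta, totals)
    wide = gp.gene_matrix_wide(table, "rpm")
    cohorts = meta.set_index("sample_id")["cohort"]
    res = cs.diff_genes(wide[cohorts.loc[wide.index] == "old"],
                        wide[cohorts.loc[wide.index] == "new"],
                        log2fc_threshold=2.0)
    up, down, null = designed_gene_sets(cfg)
    flagged_up = {r.gene_id for r in res if r.flagged and r.log2_fold_change > 0}
    flagged_down = {r.gene_id for r in res
                    if r.flagged and r.log2_fold_change < 0}
    return {
        "designed_up": up, "designed_down": down, "null": null,
        "flagged_up": flagged_up, "flagged_down": flagged_down,
        "null_flagged": (flagged_up | flagged_down) & null,
        "results": res,
    }


def null_gene_flag_rate(reps: int = 15, seed: int = 0,
                        n_per_cohort: int = 4,
                        reads_per_sample: int = 4000) -> float:
    """Fraction of (null gene, replicate) pairs flagged by diff_genes."""
    flagged = total = 0
    for r in range(reps):
        out = spiked_gene_recovery(seed=seed + 1000 * (r + 1),
                                   n_per_cohort=n_per_cohort,
                                   reads_per_sample=reads_per_sample)
        flagged += len(out["null_flagged"])
        total += len(out["null"])
    return flagged / total if total else 0.0
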