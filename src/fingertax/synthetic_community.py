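"""Synthetic two-cohort metagenomic study generator.

Produces everything the downstream pipeline consumes without any external
downloads: reference genomes evolved down a random rooted tree, an
antimicrobial-resistance / virulence gene panel, per-sample taxon
compositions drawn from a Dirichlet-Multinomial model (shared parameters
for stool, shifted parameters for skin/environment between cohorts),
single-end reads with substitution errors, and a subject-level clinical
covariate table with exact cross-tabulation margins.

Read ids carry their ground-truth source (taxon, contig, position, strand)
as a fixture convention so classifier accuracy can be scored exactly; this
is not a FASTQ standard.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .fingerprint_index import PhyloTree

NUCLEOTIDES = np.frombuffer(b"ACGT", dtype="S1")

SAMPLE_TYPES = ("stool_2wk", "stool_discharge", "skin", "environment")
COHORTS = ("old", "new")


def _default_pi(n_taxa: int) -> np.ndarray:
    """Rank-skewed mean composition: a few dominant genera, a long tail."""
    w = 1.0 / np.arange(1, n_taxa + 1)
    return w / w.sum()


def _default_effect_map(n_taxa: int) -> dict:
    """Cohort shift per sample type as multiplicative weights on pi.

    Stool compositions are shared between cohorts (no shift); skin and
    environment differ: the new-cohort community is tilted towards the
    tail taxa, giving a total-variation shift of roughly 0.2 at the
    default composition. Taxon 0 — the host of the spiked resistance and
    virulence genes — keeps weight 1 in both cohorts, so gene-level fold
    changes reflect gene content rather than the community shift.
    """
    up = [1.0] * n_taxa
    tilt = [1.0] + list(np.linspace(0.35, 2.6, n_taxa - 1))
    return {
        "stool_2wk": {"old": up, "new": up},
        "stool_discharge": {"old": up, "new": up},
        "skin": {"old": up, "new": tilt},
        "environment": {"old": up, "new": tilt},
    }


def _default_gene_spikes() -> list[tuple[str, str, int]]:
    """Copy-number placements (gene id, cohort, copies) for the panel.

    Genes AMR01..AMR03 are spiked high in the new cohort and low in the
    old one (expected read-frequency fold change comfortably above 2 log2
    units after accounting for the host contig-length difference);
    AMR04/VIR01 are present equally in both cohorts (null genes); VIR02
    is old-cohort only.
    """
    return [
        ("AMR01", "new", 8), ("AMR01", "old", 1),
        ("AMR02", "new", 16), ("AMR02", "old", 1),
        ("AMR03", "new", 12), ("AMR03", "old", 1),
        ("AMR04", "new", 4), ("AMR04", "old", 4),
        ("VIR01", "new", 3), ("VIR01", "old", 3),
        ("VIR02", "old", 6),
    ]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    pi_base and theta are the mean composition and overdispersion of the
    Dirichlet-Multinomial sampling model; effect_map maps sample type ->
    cohort -> multiplicative weights applied to pi_base (renormalised).
    gene_spikes lists (gene id, cohort, copies) contig placements.
    """

    n_taxa: int = 12
    genome_length: int = 50_000
    tree_branch_mut_rate: float = 0.05
    read_length: int = 100
    reads_per_sample: int = 50_000
    seq_error_rate: float = 0.01
    pi_base: list[float] = None
    theta: float = 0.02
    effect_map: dict = None
    gene_spikes: list = None
    gene_length: int = 1_000
    spike_host_taxon: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.pi_base is None:
            self.pi_base = list(_default_pi(self.n_taxa))
        if self.effect_map is None:
            self.effect_map = _default_effect_map(self.n_taxa)
        if self.gene_spikes is None:
            self.gene_spikes = _default_gene_spikes()
        self.validate()

    def validate(self) -> None:
        if self.n_taxa < 2:
            raise ConfigurationError("n_taxa must be >= 2")
        if self.genome_length < self.read_length:
            raise ConfigurationError("genome_length must be >= read_length")
        if self.read_length < 1 or self.reads_per_sample < 0:
            raise ConfigurationError("read_length/reads_per_sample invalid")
        for name in ("tree_branch_mut_rate", "seq_error_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"{name}={r} outside [0, 1]")
        if not 0.0 <= self.theta < 1.0:
            raise ConfigurationError(f"theta={self.theta} outside [0, 1)")
        pi = np.asarray(self.pi_base, dtype=float)
        if pi.shape != (self.n_taxa,) or (pi < 0).any():
            raise ConfigurationError("pi_base must be n_taxa non-negative values")
        if abs(pi.sum() - 1.0) > 1e-9:
            raise ConfigurationError("pi_base must sum to 1 within 1e-9")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        return cls(**json.loads(Path(path).read_text()))


class ConfigurationError(ValueError):
    """Invalid simulation or pipeline parameterisation."""


# ---------------------------------------------------------------------------
# Tree and genomes

def _random_topology(names: list[str], rng: np.random.Generator) -> str:
    """Random coalescent-style rooted binary topology as a Newick string."""
    lineages = [f"{n}" for n in names]
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        b = lineages.pop(j)
        a = lineages.pop(i)
        lineages.append(f"({a},{b})")
    return lineages[0] + ";"


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each position independently with probability `rate`.

    A substitution always changes the base (draw among the other three).
    """
    if rate <= 0:
        return seq.copy()
    out = seq.copy()
    hits = np.flatnonzero(rng.random(seq.size) < rate)
    if hits.size:
        # index of current base + random offset 1..3 mod 4 => a different base
        cur = np.searchsorted(NUCLEOTIDES, out[hits])
        out[hits] = NUCLEOTIDES[(cur + rng.integers(1, 4, hits.size)) % 4]
    return out


def simulate_tree_and_genomes(config: SimulationConfig) -> tuple[PhyloTree, dict[str, str]]:
    """Evolve one genome per leaf of a random rooted binary tree.

    A root sequence is drawn uniformly and copied down the tree, applying
    per-branch substitutions at ``tree_branch_mut_rate`` per site. Returns
    the tree and a dict of leaf name -> genome string.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = [f"T{i:02d}" for i in range(config.n_taxa)]
    tree = PhyloTree.from_newick(_random_topology(names, rng))
    root_seq = NUCLEOTIDES[rng.integers(0, 4, config.genome_length)]
    genomes: dict[str, str] = {}

    def descend(node, seq):
        for child in node.children:
            child_seq = _mutate(seq, config.tree_branch_mut_rate, rng)
            if child.is_tip():
                genomes[child.name] = child_seq.tobytes().decode()
            else:
                descend(child, child_seq)

    root = tree.root
    if root.is_tip():  # n_taxa >= 2 guarantees this never happens
        raise ConfigurationError("degenerate single-leaf tree")
    descend(root, root_seq)
    return tree, genomes


def write_genomes_fasta(genomes: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in genomes:
            fh.write(f">{name}\n")
            seq = genomes[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def read_genomes_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Gene panel

GENE_CLASSES = {
    "AMR01": ("beta-lactam", "synthetic"),
    "AMR02": ("aminoglycoside", "synthetic"),
    "AMR03": ("tetracycline", "synthetic"),
    "AMR04": ("macrolide", "synthetic"),
    "VIR01": ("virulence", "synthetic"),
    "VIR02": ("virulence", "synthetic"),
}


def simulate_gene_panel(config: SimulationConfig) -> dict[str, tuple[str, str, str]]:
    """Random gene panel: id -> (sequence, class, source).

    Sequences are independent random DNA, so they share no k-mers with the
    reference genomes except by (vanishingly rare) chance.
    """
    rng = np.random.default_rng(config.seed + 101)
    panel = {}
    for gid, (cls, src) in GENE_CLASSES.items():
        seq = NUCLEOTIDES[rng.integers(0, 4, config.gene_length)].tobytes().decode()
        panel[gid] = (seq, cls, src)
    return panel


def write_panel_fasta(panel: dict, path: str | Path) -> None:
    """Panel FASTA with the documented 'id|class|source' description line."""
    with open(path, "w") as fh:
        for gid, (seq, cls, src) in panel.items():
            fh.write(f">{gid}|{cls}|{src}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


# ---------------------------------------------------------------------------
# Compositions

def shifted_pi(config: SimulationConfig, cohort: str, sample_type: str) -> np.ndarray:
    """Mean composition after the cohort/sample-type multiplicative shift."""
    try:
        weights = np.asarray(config.effect_map[sample_type][cohort], dtype=float)
    except KeyError as exc:
        raise KeyError(f"unknown cohort/sample_type: {cohort}/{sample_type}") from exc
    pi = np.asarray(config.pi_base, dtype=float) * weights
    return pi / pi.sum()


def draw_sample_composition(
    config: SimulationConfig,
    cohort: str,
    sample_type: str,
    depth: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Dirichlet-Multinomial taxon counts for one sample.

    p ~ Dirichlet(alpha) with alpha_i = pi_i (1-theta)/theta, then
    counts ~ Multinomial(depth, p). theta = 0 degenerates to a plain
    multinomial draw from pi.
    """
    if depth < 1:
        raise ConfigurationError("depth must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pi = shifted_pi(config, cohort, sample_type)
    if config.theta == 0.0:
        p = pi
    else:
        alpha = pi * (1.0 - config.theta) / config.theta
        p = rng.dirichlet(alpha)
    return rng.multinomial(depth, p)


# ---------------------------------------------------------------------------
# Reads

def _spiked_contigs(
    config: SimulationConfig,
    genomes: dict[str, str],
    panel: dict,
    cohort: str,
) -> dict[str, list[tuple[str, str]]]:
    """Per-taxon contig lists (name, sequence) with cohort gene spikes.

    Spiked genes are appended as extra contigs (tandem copies) of the host
    taxon's genome; coverage profiling is position-agnostic so mid-sequence
    insertion would change nothing downstream.
    """
    names = sorted(genomes)
    contigs = {n: [(n, genomes[n])] for n in names}
    host = names[config.spike_host_taxon]
    for gid, spike_cohort, copies in config.gene_spikes:
        if spike_cohort != cohort or copies <= 0:
            continue
        if gid not in panel:
            raise ConfigurationError(f"gene spike references unknown gene {gid}")
        seq = panel[gid][0] * copies
        contigs[host].append((f"spike:{gid}", seq))
    return contigs


def write_reads(
    composition: np.ndarray,
    contigs: dict[str, list[tuple[str, str]]],
    config: SimulationConfig,
    path: str | Path,
    sample_id: str = "S",
    rng: np.random.Generator | None = None,
) -> None:
    """Emit single-end FASTQ reads for one sample.

    ``composition[i]`` reads are drawn from taxon i (sorted taxon order);
    within a taxon the source position is uniform over all windows of its
    contigs (genome plus any spiked gene copies). Per-base substitution
    errors at ``seq_error_rate``; strand uniform; constant Sanger quality.
    Read ids encode the true source: ``sample:n|taxon|contig|pos|strand``.
    """
    names = sorted(contigs)
    composition = np.asarray(composition)
    if composition.shape != (len(names),):
        raise StructuralError(
            f"composition length {composition.shape} != {len(names)} taxa")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.read_length
    qual = "I" * L
    n = 0
    with open(path, "w") as fh:
        for taxon, count in zip(names, composition):
            if count == 0:
                continue
            windows = []
            for cname, seq in contigs[taxon]:
                if len(seq) >= L:
                    windows.append((cname, seq, len(seq) - L + 1))
            if not windows:
                raise StructuralError(f"no contig of taxon {taxon} fits a read")
            weights = np.array([w for _, _, w in windows], dtype=float)
            picks = rng.choice(len(windows), size=int(count), p=weights / weights.sum())
            for ci in picks:
                cname, seq, nwin = windows[ci]
                pos = int(rng.integers(0, nwin))
                frag = np.frombuffer(seq[pos:pos + L].encode(), dtype="S1")
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "-":
                    frag = _revcomp_array(frag)
                frag = _mutate(frag, config.seq_error_rate, rng)
                rid = f"{sample_id}:{n}|{taxon}|{cname}|{pos}|{strand}"
                fh.write(f"@{rid}\n{frag.tobytes().decode()}\n+\n{qual}\n")
                n += 1


_COMP = bytes.maketrans(b"ACGT", b"TGCA")


def _revcomp_array(frag: np.ndarray) -> np.ndarray:
    return np.frombuffer(frag.tobytes().translate(_COMP), dtype="S1")[::-1]


class StructuralError(ValueError):
    """Inputs structurally inconsistent (shape/identity mismatches)."""


# ---------------------------------------------------------------------------
# Clinical table

#: Default margins reproduce the study design: old n=14, new n=18 with the
#: published exposure counts per cohort.
DEFAULT_CLINICAL_MARGINS = {
    "cohort_sizes": {"old": 14, "new": 18},
    "binary": {
        "antibiotic_exposure": {"old": 12, "new": 8},
        "cephalosporin_3rd_gen": {"old": 4, "new": 0},
        "exclusive_breast_milk": {"old": 11, "new": 7},
        "some_breast_milk": {"old": 11, "new": 17},
        "tpn": {"old": 12, "new": 12},
    },
    "continuous": {
        "gestational_age_weeks": {"old": 31.4, "new": 33.2, "sd": 3.0},
        "length_of_stay_days": {"old": 33.5, "new": 33.2, "sd": 12.0},
    },
}


def generate_clinical_table(
    margins: dict | None = None, seed: int = 0
) -> pd.DataFrame:
    """Subject-level clinical covariate table with exact binary margins.

    Binary covariates are assigned so every cohort x exposure cross-tab
    equals the requested counts exactly; continuous covariates are drawn
    from normals with the configured cohort means. Row order is shuffled
    deterministically by ``seed``.
    """
    margins = margins if margins is not None else DEFAULT_CLINICAL_MARGINS
    rng = np.random.default_rng(seed)
    sizes = margins["cohort_sizes"]
    rows = []
    for cohort in sizes:
        for i in range(sizes[cohort]):
            rows.append({"subject": f"{cohort}_{i:02d}", "cohort": cohort})
    df = pd.DataFrame(rows)
    for cov, counts in margins.get("binary", {}).items():
        col = np.zeros(len(df), dtype=int)
        for cohort in sizes:
            n_yes = int(counts.get(cohort, 0))
            if n_yes > sizes[cohort]:
                raise ConfigurationError(
                    f"{cov}: {n_yes} exposed exceeds cohort size {sizes[cohort]}")
            idx = np.flatnonzero((df["cohort"] == cohort).to_numpy())
            col[rng.permutation(idx)[:n_yes]] = 1
        df[cov] = col
    for cov, spec_ in margins.get("continuous", {}).items():
        sd = spec_.get("sd", 1.0)
        vals = np.empty(len(df))
        for cohort in sizes:
            mask = (df["cohort"] == cohort).to_numpy()
            vals[mask] = rng.normal(spec_[cohort], sd, mask.sum())
        df[cov] = np.round(vals, 2)
    return df.sample(frac=1.0, random_state=int(rng.integers(0, 2**31))).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Whole-study convenience

#: Desk-scale sample plan mirroring the study's sample-type stratification.
DEFAULT_SAMPLE_PLAN = {
    "stool_2wk": {"old": 9, "new": 13},
    "stool_discharge": {"old": 12, "new": 14},
    "skin": {"old": 11, "new": 10},
    "environment": {"old": 6, "new": 10},
}


def simulate_study(
    config: SimulationConfig,
    outdir: str | Path,
    sample_plan: dict | None = None,
) -> pd.DataFrame:
    """Generate the complete synthetic study under ``outdir``.

    Writes genomes.fasta, tree.nwk, panel.fasta, reads/<sample>.fastq,
    metadata.tsv, clinical.tsv and the config JSON; returns the sample
    metadata table (sample_id, cohort, sample_type, true composition file).
    """
    outdir = Path(outdir)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)
    tree, genomes = simulate_tree_and_genomes(config)
    write_genomes_fasta(genomes, outdir / "genomes.fasta")
    tree.write_newick(outdir / "tree.nwk")
    panel = simulate_gene_panel(config)
    write_panel_fasta(panel, outdir / "panel.fasta")
    config.to_json(outdir / "config.json")

    plan = sample_plan if sample_plan is not None else DEFAULT_SAMPLE_PLAN
    rng = np.random.default_rng(config.seed + 7)
    taxa = sorted(genomes)
    meta_rows, truth_rows = [], []
    for sample_type, cohorts in plan.items():
        for cohort, n_samples in cohorts.items():
            contigs = _spiked_contigs(config, genomes, panel, cohort)
            for i in range(n_samples):
                sid = f"{cohort}_{sample_type}_{i:02d}"
                comp = draw_sample_composition(
                    config, cohort, sample_type, config.reads_per_sample, rng)
                write_reads(comp, contigs, config,
                            outdir / "reads" / f"{sid}.fastq", sid, rng)
                meta_rows.append({"sample_id": sid, "cohort": cohort,
                                  "sample_type": sample_type,
                                  "subject": f"{cohort}_{i:02d}"})
                truth_rows.append({"sample_id": sid,
                                   **{t: int(c) for t, c in zip(taxa, comp)}})
    meta = pd.DataFrame(meta_rows)
    meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    pd.DataFrame(truth_rows).to_csv(outdir / "true_compositions.tsv",
                                    sep="\t", index=False)
    generate_clinical_table(seed=config.seed).to_csv(
        outdir / "clinical.tsv", sep="\t", index=False)
    return meta
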