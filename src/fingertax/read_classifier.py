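"""Per-sample read classification against the fingerprint index.

Two comparators run in sequence: an exact canonical k-mer match against the
fingerprint sets proposes a candidate tree node for each read, then a
banded edit-distance comparison of the whole read against the candidate's
leaf genomes verifies it. Accepted reads are aggregated to per-node counts,
presence calls and relative abundances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .fingerprint_index import FingerprintIndex, reverse_complement

logger = logging.getLogger(__name__)


@dataclass
class ClassifierParams:
    """Tunable policy of the per-sample phase.

    max_edit defaults to ceil(0.1 * read length) at verification time:
    tolerant of ~1% sequencing error plus reference divergence, strict
    against chance matches. Presence needs min_reads accepted reads AND
    matched distinct strict fingerprints >= min_fingerprint_frac of the
    leaf's strict-fingerprint set. Relaxed fingerprints support a node at
    relaxed_weight per hit (strict hits weigh 1.0).
    """

    max_edit: int | None = None
    min_reads: int = 5
    min_fingerprint_frac: float = 0.005
    relaxed_weight: float = 0.5

    def edit_budget(self, read_length: int) -> int:
        if self.max_edit is not None:
            return self.max_edit
        return math.ceil(0.1 * read_length)


@dataclass
class ReadAssignment:
    read_id: str
    node: str | None
    fingerprint_hits: int
    edit_distance: int | None
    status: str  # assigned | rejected | unclassified


@dataclass
class AbundanceProfile:
    """Per-sample classification result.

    ``counts`` holds accepted-read counts at every node (leaves and
    internal); ``leaf_abundance`` maps present leaves to relative abundance
    in percent (sums to 100 over present leaves); ``unredistributed`` is
    the internal-node mass that had no present descendant to receive it.
    """

    sample_id: str
    counts: dict[str, int]
    presence: dict[str, bool]
    leaf_abundance: dict[str, float]
    total_classified: int
    unredistributed: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for node, count in sorted(self.counts.items()):
            rows.append({
                "node": node,
                "count": count,
                "relative_abundance_pct": self.leaf_abundance.get(node, np.nan),
                "present": self.presence.get(node, False),
            })
        return pd.DataFrame(rows)


def read_kmer_hits(read: str, index: FingerprintIndex):
    """Yield (canonical k-mer, read offset, node, strict) for every indexed
    k-mer of the read."""
    k = index.k
    seq = read.upper()
    if len(seq) < k:
        return
    rc = reverse_complement(seq) if set(seq) <= set("ACGT") else None
    n = len(seq)
    for i in range(n - k + 1):
        kmer = seq[i:i + k]
        if rc is not None:
            rk = rc[n - k - i:n - i]
            if rk < kmer:
                kmer = rk
        elif any(b not in "ACGT" for b in kmer):
            continue
        else:
            rk = reverse_complement(kmer)
            if rk < kmer:
                kmer = rk
        hit = index.assignments.get(kmer)
        if hit is not None:
            yield kmer, i, hit[0], hit[1]


class GenomeSeedIndex:
    """Lazily built canonical k-mer -> positions map per reference genome.

    Lets the verifier align a read only against windows around its matched
    fingerprints instead of scanning whole genomes.
    """

    def __init__(self, genomes: dict[str, str], k: int):
        self.genomes = genomes
        self.k = k
        self._maps: dict[str, dict[str, list[int]]] = {}

    def positions(self, genome_name: str, kmer: str) -> list[int]:
        m = self._maps.get(genome_name)
        if m is None:
            m = {}
            seq = self.genomes[genome_name]
            k = self.k
            rc = reverse_complement(seq)
            n = len(seq)
            for i in range(n - k + 1):
                km = seq[i:i + k]
                rk = rc[n - k - i:n - i]
                m.setdefault(min(km, rk), []).append(i)
            self._maps[genome_name] = m
        return m.get(kmer, [])


def match_read(read: str, index: FingerprintIndex,
               params: ClassifierParams | None = None):
    """First comparator: propose a candidate node from fingerprint hits.

    Returns ``(node, hit_count, strict_kmers)`` or ``None`` when no indexed
    k-mer occurs in the read. The candidate is the deepest node with direct
    hits (a hit at a node also supports its ancestors); ties at equal depth
    are broken by the larger weighted hit count, and a residual tie is sent
    to the tied nodes' LCA as ambiguous.
    """
    params = params or ClassifierParams()
    tree = index.tree
    hits: dict[str, float] = {}
    raw: dict[str, int] = {}
    strict_kmers: dict[str, set[str]] = {}
    seed_offsets: dict[str, int] = {}
    k = index.k
    seq = read.upper()
    n = len(seq)
    assignments = index.assignments
    w_relaxed = params.relaxed_weight
    if n >= k and set(seq) <= set("ACGT"):
        # hot path: inline canonical window scan
        rc_seq = reverse_complement(seq)
        for i in range(n - k + 1):
            kmer = seq[i:i + k]
            rk = rc_seq[n - k - i:n - i]
            if rk < kmer:
                kmer = rk
            hit = assignments.get(kmer)
            if hit is None:
                continue
            node, strict = hit
            if strict:
                hits[node] = hits.get(node, 0.0) + 1.0
                strict_kmers.setdefault(node, set()).add(kmer)
            else:
                hits[node] = hits.get(node, 0.0) + w_relaxed
            raw[node] = raw.get(node, 0) + 1
            seed_offsets.setdefault(kmer, i)
    else:
        for kmer, offset, node, strict in read_kmer_hits(read, index):
            hits[node] = hits.get(node, 0.0) + (1.0 if strict else w_relaxed)
            raw[node] = raw.get(node, 0) + 1
            seed_offsets.setdefault(kmer, offset)
            if strict:
                strict_kmers.setdefault(node, set()).add(kmer)
    if not hits:
        return None
    max_depth = max(tree.depth(n) for n in hits)
    deepest = [n for n in hits if tree.depth(n) == max_depth]
    if len(deepest) == 1:
        cand = deepest[0]
    else:
        best = max(hits[n] for n in deepest)
        top = sorted(n for n in deepest if hits[n] == best)
        cand = top[0] if len(top) == 1 else tree.lca(
            [leaf for n in top for leaf in tree.leafset(n)])
    return cand, raw.get(cand, 0) or sum(raw.values()), strict_kmers, seed_offsets


MAX_SEED_WINDOWS = 8


def verify_read(read: str, candidate: str, genomes: dict[str, str],
                tree, max_edit: int,
                seeds: dict[str, int] | None = None,
                seed_index: GenomeSeedIndex | None = None) -> tuple[int | None, bool]:
    """Second comparator: banded edit distance of the whole read against
    windows of the candidate node's leaf genomes (both strands).

    When ``seeds`` (matched canonical k-mer -> read offset) and a
    ``seed_index`` are given, the alignment is restricted to windows
    around the matched k-mer positions (capped at MAX_SEED_WINDOWS per
    genome); otherwise the whole genome is scanned. Returns ``(best
    distance, accepted)``; distance is None when nothing comes within the
    ``max_edit`` band.
    """
    leaves = tree.leafset(candidate)
    if not leaves:
        return None, False
    best: int | None = None
    L = len(read)
    queries = (read, reverse_complement(read))
    for leaf in sorted(leaves):
        target = genomes[leaf]
        if seeds and seed_index is not None:
            windows = []
            starts: set[int] = set()
            for kmer in seeds:
                for pos in seed_index.positions(leaf, kmer):
                    start = max(0, pos - L - max_edit)
                    if start not in starts:
                        starts.add(start)
                        windows.append(
                            target[start:pos + seed_index.k + L + max_edit])
                    if len(windows) >= MAX_SEED_WINDOWS:
                        break
                if len(windows) >= MAX_SEED_WINDOWS:
                    break
        else:
            windows = [target]
        for win in windows:
            for q in queries:
                res = edlib.align(q, win, mode="HW", task="distance", k=max_edit)
                d = res["editDistance"]
                if d >= 0 and (best is None or d < best):
                    best = d
                    if best == 0:
                        return 0, True
    return best, best is not None and best <= max_edit


@dataclass
class SampleClassification:
    sample_id: str
    assignments: list[ReadAssignment]
    strict_kmers_by_node: dict[str, set[str]]


def classify_reads(reads, index: FingerprintIndex, genomes: dict[str, str],
                   params: ClassifierParams | None = None,
                   sample_id: str = "S",
                   seed_index: GenomeSeedIndex | None = None) -> SampleClassification:
    """Run both comparators over an iterable of ``(read id, sequence)``."""
    params = params or ClassifierParams()
    tree = index.tree
    if seed_index is None:
        seed_index = GenomeSeedIndex(genomes, index.k)
    assignments: list[ReadAssignment] = []
    strict_by_node: dict[str, set[str]] = {}
    for rid, seq in reads:
        if len(seq) < index.k:
            assignments.append(ReadAssignment(rid, None, 0, None, "unclassified"))
            continue
        m = match_read(seq, index, params)
        if m is None:
            assignments.append(ReadAssignment(rid, None, 0, None, "unclassified"))
            continue
        cand, nhits, strict_kmers, seeds = m
        dist, ok = verify_read(seq, cand, genomes, tree,
                               params.edit_budget(len(seq)),
                               seeds=seeds, seed_index=seed_index)
        if ok:
            assignments.append(ReadAssignment(rid, cand, nhits, dist, "assigned"))
            for node, kmers in strict_kmers.items():
                strict_by_node.setdefault(node, set()).update(kmers)
        else:
            assignments.append(ReadAssignment(rid, None, nhits, dist, "rejected"))
    return SampleClassification(sample_id, assignments, strict_by_node)


def classify_fastq(path, index: FingerprintIndex, genomes: dict[str, str],
                   params: ClassifierParams | None = None,
                   sample_id: str | None = None,
                   seed_index: GenomeSeedIndex | None = None) -> SampleClassification:
    from Bio import SeqIO
    sid = sample_id or str(path)
    reads = ((rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq"))
    return classify_reads(reads, index, genomes, params, sid, seed_index)


def aggregate_sample(classification: SampleClassification,
                     index: FingerprintIndex,
                     params: ClassifierParams | None = None) -> AbundanceProfile:
    """Fold accepted read assignments into an abundance profile.

    A leaf is present iff its accepted-read count >= min_reads and its
    distinct matched strict fingerprints cover >= min_fingerprint_frac of
    the leaf's strict-fingerprint set. Internal-node counts are then
    redistributed to present descendant leaves proportionally to their
    direct counts; mass with no present descendant stays at the node and
    is excluded from the percentages. Abundance = 100 * leaf mass / total
    mass over present leaves.
    """
    params = params or ClassifierParams()
    tree = index.tree
    counts: dict[str, int] = {}
    for a in classification.assignments:
        if a.status == "assigned":
            counts[a.node] = counts.get(a.node, 0) + 1
    total_classified = sum(counts.values())

    presence: dict[str, bool] = {}
    for leaf in tree.leaf_names:
        c = counts.get(leaf, 0)
        n_strict = index.strict_count(leaf)
        matched = len(classification.strict_kmers_by_node.get(leaf, ()))
        frac_ok = (n_strict == 0) or (matched >= params.min_fingerprint_frac * n_strict)
        presence[leaf] = c >= params.min_reads and frac_ok

    mass = {leaf: float(counts.get(leaf, 0))
            for leaf in tree.leaf_names if presence[leaf]}
    unredistributed: dict[str, float] = {}
    # deepest internal nodes first so mass cascades toward the leaves
    internal = sorted(
        (n for n in counts if not tree.is_leaf(n)),
        key=lambda n: -tree.depth(n))
    for node in internal:
        node_mass = float(counts[node]) + unredistributed.pop(node, 0.0)
        dest = [lf for lf in tree.mask_to_leaves(tree.leaf_mask(node))
                if presence.get(lf) and counts.get(lf, 0) > 0]
        if not dest:
            unredistributed[node] = node_mass
            continue
        weights = np.array([counts[lf] for lf in dest], dtype=float)
        weights /= weights.sum()
        for lf, w in zip(dest, weights):
            mass[lf] += node_mass * w

    total_mass = sum(mass.values())
    leaf_abundance = ({lf: 100.0 * m / total_mass for lf, m in mass.items()}
                      if total_mass > 0 else {})
    return AbundanceProfile(
        sample_id=classification.sample_id,
        counts=counts,
        presence=presence,
        leaf_abundance=leaf_abundance,
        total_classified=total_classified,
        unredistributed=unredistributed,
    )


def profiles_to_matrix(profiles: list[AbundanceProfile],
                       leaves: list[str] | None = None,
                       values: str = "abundance") -> pd.DataFrame:
    """Samples x taxa matrix of leaf relative abundances (%) or counts."""
    if leaves is None:
        leaves = sorted({lf for p in profiles for lf in p.leaf_abundance})
    rows = {}
    for p in profiles:
        if values == "abundance":
            rows[p.sample_id] = [p.leaf_abundance.get(lf, 0.0) for lf in leaves]
        else:
            rows[p.sample_id] = [p.counts.get(lf, 0) for lf in leaves]
    return pd.DataFrame.from_dict(rows, orient="index", columns=leaves)


def subsample_counts(table: pd.DataFrame, depth: int,
                     seed: int = 0) -> pd.DataFrame:
    """Rarefy each sample (row) to exactly ``depth`` reads without
    replacement (multivariate hypergeometric); samples whose total is
    below ``depth`` are dropped with a logged warning.
    """
    if depth <= 0:
        raise ValueError("subsampling depth must be positive")
    rng = np.random.default_rng(seed)
    kept, rows = [], []
    for sid, row in table.iterrows():
        counts = row.to_numpy(dtype=np.int64)
        total = int(counts.sum())
        if total < depth:
            logger.warning("sample %s excluded: total %d < depth %d",
                           sid, total, depth)
            continue
        if total == depth:
            rows.append(counts)
        else:
            rows.append(rng.multivariate_hypergeometric(counts, depth))
        kept.append(sid)
    return pd.DataFrame(rows, index=kept, columns=table.columns)
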