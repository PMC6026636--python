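"""Tree-anchored k-mer fingerprint database (pre-computation phase).

Every canonical k-mer present in the reference genomes is assigned to the
lowest common ancestor (LCA) of the genomes that contain it. A k-mer whose
genome set is exactly the leaf set of its node is a *strict* fingerprint —
it identifies that clade uniquely; otherwise it is kept as a *relaxed*
fingerprint at the LCA, flagged and down-weighted during read scoring.
"""

from __future__ import annotations

import hashlib
import json
from io import StringIO
from pathlib import Path

from skbio import TreeNode


class IntegrityError(RuntimeError):
    """Serialized index is corrupt or built from a different reference set."""


_COMP = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canonical_kmers(sequence: str, k: int) -> set[str]:
    """Set of canonical k-mers (lexicographic min of k-mer and its reverse
    complement) over all windows of ``sequence``; windows containing a base
    outside {A,C,G,T} are skipped. ``k`` longer than the sequence gives an
    empty set.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = sequence.upper()
    out: set[str] = set()
    valid = set("ACGT")
    # rightmost invalid position seen so far; a window starting at i is clean
    # iff every base in [i, i+k) is valid
    last_bad = -1
    for j, base in enumerate(seq):
        if base not in valid:
            last_bad = j
        i = j - k + 1
        if i >= 0 and last_bad < i:
            kmer = seq[i:j + 1]
            rc = reverse_complement(kmer)
            out.add(kmer if kmer <= rc else rc)
    return out


class PhyloTree:
    """Rooted tree over reference genomes with per-node leaf sets.

    Thin wrapper around ``skbio.TreeNode`` adding deterministic internal
    node names, cached leaf sets (as bitmasks over the sorted leaf order),
    depths, and LCA lookup for arbitrary genome sets.
    """

    def __init__(self, tree: TreeNode):
        self._tree = tree
        n_internal = 0
        for node in tree.preorder():
            if not node.is_tip() and not node.name:
                node.name = f"N{n_internal}"
                n_internal += 1
        self.leaf_names = sorted(t.name for t in tree.tips())
        self._leaf_bit = {n: 1 << i for i, n in enumerate(self.leaf_names)}
        self._nodes: dict[str, TreeNode] = {}
        self._mask: dict[str, int] = {}
        self._depth: dict[str, int] = {}
        self._parent: dict[str, str | None] = {}
        for node in tree.postorder():
            if node.name in self._nodes:
                raise ValueError(f"duplicate node name {node.name!r}")
            self._nodes[node.name] = node
            if node.is_tip():
                self._mask[node.name] = self._leaf_bit[node.name]
            else:
                self._mask[node.name] = 0
                for c in node.children:
                    self._mask[node.name] |= self._mask[c.name]
        for node in tree.preorder():
            p = node.parent
            self._parent[node.name] = p.name if p is not None else None
            self._depth[node.name] = 0 if p is None else self._depth[p.name] + 1

    # -- construction / IO --------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        return cls(TreeNode.read(StringIO(newick), format="newick"))

    @classmethod
    def read_newick(cls, path: str | Path) -> "PhyloTree":
        return cls.from_newick(Path(path).read_text())

    def write_newick(self, path: str | Path) -> None:
        self._tree.write(str(path), format="newick")

    def to_newick(self) -> str:
        buf = StringIO()
        self._tree.write(buf, format="newick")
        return buf.getvalue()

    # -- queries -------------------------------------------------------------
    @property
    def root(self) -> TreeNode:
        return self._tree

    @property
    def root_name(self) -> str:
        return self._tree.name

    def node(self, name: str) -> TreeNode:
        return self._nodes[name]

    def node_names(self):
        return list(self._nodes)

    def is_leaf(self, name: str) -> bool:
        return self._nodes[name].is_tip()

    def depth(self, name: str) -> int:
        return self._depth[name]

    def parent(self, name: str) -> str | None:
        return self._parent[name]

    def leafset(self, name: str) -> frozenset[str]:
        return frozenset(self.mask_to_leaves(self._mask[name]))

    def leaf_mask(self, name: str) -> int:
        return self._mask[name]

    def mask_to_leaves(self, mask: int) -> list[str]:
        return [n for n in self.leaf_names if self._leaf_bit[n] & mask]

    def leaves_to_mask(self, names) -> int:
        mask = 0
        for n in names:
            mask |= self._leaf_bit[n]
        return mask

    def is_ancestor(self, anc: str, name: str) -> bool:
        """True iff ``anc`` lies on the root path of ``name`` (inclusive)."""
        cur: str | None = name
        while cur is not None:
            if cur == anc:
                return True
            cur = self._parent[cur]
        return False

    def lca_mask(self, mask: int) -> str:
        """Name of the deepest node whose leaf set contains ``mask``."""
        if mask == 0:
            raise ValueError("empty genome set has no LCA")
        node = self._tree
        while True:
            nxt = None
            for c in node.children:
                if self._mask[c.name] & mask == mask:
                    nxt = c
                    break
            if nxt is None:
                return node.name
            node = nxt

    def lca(self, leaf_names) -> str:
        return self.lca_mask(self.leaves_to_mask(leaf_names))


class FingerprintIndex:
    """Canonical k-mer -> tree node map with strict/relaxed flags.

    ``assignments`` maps each k-mer to ``(node name, strict flag)``; the
    partition property (one node per k-mer) holds by construction and is
    re-checked on load. Strict fingerprints score 1.0 during read matching,
    relaxed ones ``relaxed_weight`` (default 0.5).
    """

    FORMAT = "fingertax-index-v1"

    def __init__(self, k: int, tree: PhyloTree,
                 assignments: dict[str, tuple[str, bool]],
                 provenance: dict | None = None):
        self.k = k
        self.tree = tree
        self.assignments = assignments
        self.provenance = provenance or {}
        self.node_counts = self._count_fibers()

    def _count_fibers(self) -> dict[str, dict[str, int]]:
        counts: dict[str, dict[str, int]] = {}
        for node, strict in self.assignments.values():
            c = counts.setdefault(node, {"strict": 0, "relaxed": 0})
            c["strict" if strict else "relaxed"] += 1
        return counts

    def strict_count(self, node: str) -> int:
        return self.node_counts.get(node, {}).get("strict", 0)

    def lookup(self, kmer: str) -> tuple[str, bool] | None:
        return self.assignments.get(kmer)

    def __len__(self) -> int:
        return len(self.assignments)


def reference_hash(genomes: dict[str, str]) -> str:
    h = hashlib.sha256()
    for name in sorted(genomes):
        h.update(name.encode())
        h.update(b"\0")
        h.update(genomes[name].encode())
        h.update(b"\0")
    return h.hexdigest()


def build_index(genomes: dict[str, str], tree: PhyloTree, k: int = 21) -> FingerprintIndex:
    """Assign every canonical k-mer of the reference set to the LCA of the
    genomes containing it.

    Strict if the containing-genome set equals the node's full leaf set,
    relaxed otherwise. Requires every tree leaf to have a genome.
    """
    if k < 8:
        raise ValueError("k must be >= 8 for a usable fingerprint index")
    missing = [n for n in tree.leaf_names if n not in genomes]
    if missing:
        raise ValueError(f"tree leaves without genomes: {missing}")

    kmer_mask: dict[str, int] = {}
    for name in tree.leaf_names:
        bit = tree.leaves_to_mask([name])
        for kmer in canonical_kmers(genomes[name], k):
            kmer_mask[kmer] = kmer_mask.get(kmer, 0) | bit

    lca_cache: dict[int, tuple[str, bool]] = {}
    assignments: dict[str, tuple[str, bool]] = {}
    for kmer, mask in kmer_mask.items():
        hit = lca_cache.get(mask)
        if hit is None:
            node = tree.lca_mask(mask)
            hit = (node, tree.leaf_mask(node) == mask)
            lca_cache[mask] = hit
        assignments[kmer] = hit

    provenance = {
        "reference_hash": reference_hash(genomes),
        "k": k,
        "n_genomes": len(tree.leaf_names),
        "tree": tree.to_newick().strip(),
    }
    return FingerprintIndex(k, tree, assignments, provenance)


def save_index(index: FingerprintIndex, path: str | Path) -> None:
    """Serialize to a single JSON container with an embedded checksum."""
    by_node: dict[str, dict[str, list[str]]] = {}
    for kmer, (node, strict) in index.assignments.items():
        d = by_node.setdefault(node, {"strict": [], "relaxed": []})
        d["strict" if strict else "relaxed"].append(kmer)
    for d in by_node.values():
        d["strict"].sort()
        d["relaxed"].sort()
    payload = json.dumps({
        "format": FingerprintIndex.FORMAT,
        "k": index.k,
        "provenance": index.provenance,
        "kmers_by_node": by_node,
    }, sort_keys=True)
    digest = hashlib.sha256(payload.encode()).hexdigest()
    Path(path).write_text(json.dumps({"checksum": digest, "payload": payload}))


def load_index(path: str | Path, expected_reference_hash: str | None = None) -> FingerprintIndex:
    """Load a serialized index, verifying checksum, partition property and
    (optionally) the reference-set hash recorded in the provenance block.
    """
    try:
        container = json.loads(Path(path).read_text())
        payload = container["payload"]
        checksum = container["checksum"]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise IntegrityError(f"unreadable index container: {exc}") from exc
    if hashlib.sha256(payload.encode()).hexdigest() != checksum:
        raise IntegrityError("index checksum mismatch (truncated or edited file)")
    data = json.loads(payload)
    if data.get("format") != FingerprintIndex.FORMAT:
        raise IntegrityError(f"unknown index format {data.get('format')!r}")
    prov = data["provenance"]
    if (expected_reference_hash is not None
            and prov.get("reference_hash") != expected_reference_hash):
        raise IntegrityError("index built from a different reference set")
    tree = PhyloTree.from_newick(prov["tree"])
    assignments: dict[str, tuple[str, bool]] = {}
    for node, d in data["kmers_by_node"].items():
        for kmer in d["strict"]:
            if kmer in assignments:
                raise IntegrityError(f"k-mer {kmer} assigned to two nodes")
            assignments[kmer] = (node, True)
        for kmer in d["relaxed"]:
            if kmer in assignments:
                raise IntegrityError(f"k-mer {kmer} assigned to two nodes")
            assignments[kmer] = (node, False)
    return FingerprintIndex(data["k"], tree, assignments, prov)
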