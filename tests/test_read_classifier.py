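"""Classifier checks: k-mer matching, edit-distance verification,
aggregation policy, soundness on clean reads, and rarefaction."""

import random

import numpy as np
import pandas as pd
import pytest

from fingertax.fingerprint_index import PhyloTree, build_index, reverse_complement
from fingertax.read_classifier import (
    ClassifierParams,
    GenomeSeedIndex,
    SampleClassification,
    ReadAssignment,
    aggregate_sample,
    classify_reads,
    match_read,
    subsample_counts,
    verify_read,
)


def _random_seq(n, seed):
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture(scope="module")
def shared_block_refs():
    """Four divergent genomes sharing one identical 300 bp block."""
    tree = PhyloTree.from_newick("((A,B),(C,D));")
    shared = _random_seq(300, 99)
    genomes = {n: _random_seq(1500, i) + shared + _random_seq(1500, 50 + i)
               for i, n in enumerate(tree.leaf_names)}
    index = build_index(genomes, tree, k=21)
    return tree, genomes, index


class TestMatchRead:
    def test_unique_region_read_hits_leaf(self, shared_block_refs):
        _, genomes, index = shared_block_refs
        read = genomes["A"][100:200]
        cand, hits, *_ = match_read(read, index)
        assert cand == "A" and hits > 0

    def test_random_read_matches_nothing(self, shared_block_refs):
        _, _, index = shared_block_refs
        # collision probability per window ~ 4^-21; none expected
        for seed in range(20):
            assert match_read(_random_seq(100, 1000 + seed), index) is None

    def test_shared_region_read_goes_to_root(self, shared_block_refs):
        tree, genomes, index = shared_block_refs
        read = genomes["A"][1600:1700]  # inside the shared block
        cand, *_ = match_read(read, index)
        assert cand == tree.root_name

    def test_read_shorter_than_k_unclassified(self, shared_block_refs):
        _, genomes, index = shared_block_refs
        cls = classify_reads([("r0", "ACGT")], index, genomes)
        assert cls.assignments[0].status == "unclassified"


class TestVerifyRead:
    def test_exact_substring_distance_zero(self, shared_block_refs):
        tree, genomes, _ = shared_block_refs
        read = genomes["B"][700:800]
        dist, ok = verify_read(read, "B", genomes, tree, max_edit=10)
        assert dist == 0 and ok

    def test_two_substitutions_distance_two(self, shared_block_refs):
        tree, genomes, _ = shared_block_refs
        read = list(genomes["B"][700:800])
        for pos in (10, 60):
            read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
        dist, ok = verify_read("".join(read), "B", genomes, tree, max_edit=10)
        assert dist == 2 and ok

    def test_random_reads_rejected(self, shared_block_refs):
        tree, genomes, _ = shared_block_refs
        rejected = 0
        n = 300
        for seed in range(n):
            _, ok = verify_read(_random_seq(100, 5000 + seed), "A", genomes,
                                tree, max_edit=10)
            rejected += not ok
        assert rejected == n

    def test_seeded_verification_agrees_with_full_scan(self, shared_block_refs):
        tree, genomes, index = shared_block_refs
        seed_index = GenomeSeedIndex(genomes, index.k)
        read = genomes["C"][2000:2100]
        m = match_read(read, index)
        dist_seeded, ok = verify_read(read, m[0], genomes, tree, 10,
                                      seeds=m[3], seed_index=seed_index)
        dist_full, ok_full = verify_read(read, m[0], genomes, tree, 10)
        assert (dist_seeded, ok) == (dist_full, ok_full) == (0, True)


def _make_classification(counted, strict_kmers=None):
    assignments = []
    i = 0
    for node, n in counted.items():
        for _ in range(n):
            assignments.append(ReadAssignment(f"r{i}", node, 3, 0, "assigned"))
            i += 1
    return SampleClassification("S", assignments, strict_kmers or {})


class TestAggregateSample:
    def test_single_taxon_sample_is_100pct(self, shared_block_refs):
        _, genomes, index = shared_block_refs
        cls = classify_reads(
            ((f"r{i}", genomes["A"][i:i + 100]) for i in range(0, 800, 10)),
            index, genomes)
        prof = aggregate_sample(cls, index,
                               ClassifierParams(min_fingerprint_frac=0.0))
        assert prof.leaf_abundance == pytest.approx({"A": 100.0})
        assert prof.presence["A"] and not prof.presence["B"]

    def test_min_reads_filter_renormalises(self, shared_block_refs):
        _, _, index = shared_block_refs
        cls = _make_classification({"A": 60, "B": 40, "C": 3})
        prof = aggregate_sample(cls, index, ClassifierParams(
            min_reads=5, min_fingerprint_frac=0.0))
        assert not prof.presence["C"]
        assert prof.leaf_abundance == pytest.approx({"A": 60.0, "B": 40.0})

    def test_internal_counts_redistributed_proportionally(self, shared_block_refs):
        tree, _, index = shared_block_refs
        root = tree.root_name
        cls = _make_classification({"A": 30, "B": 10, root: 20})
        prof = aggregate_sample(cls, index, ClassifierParams(
            min_reads=5, min_fingerprint_frac=0.0))
        # 20 root reads split 3:1 between A and B -> masses 45 and 15
        assert prof.leaf_abundance == pytest.approx({"A": 75.0, "B": 25.0})

    def test_unredistributable_mass_stays_at_node(self, shared_block_refs):
        tree, _, index = shared_block_refs
        cls = _make_classification({tree.root_name: 50})
        prof = aggregate_sample(cls, index, ClassifierParams(
            min_reads=5, min_fingerprint_frac=0.0))
        assert prof.leaf_abundance == {}
        assert prof.unredistributed[tree.root_name] == 50.0

    def test_empty_sample(self, shared_block_refs):
        _, _, index = shared_block_refs
        prof = aggregate_sample(SampleClassification("S", [], {}), index)
        assert prof.total_classified == 0
        assert not any(prof.presence.values())

    def test_abundances_sum_to_100(self, shared_block_refs):
        _, _, index = shared_block_refs
        cls = _make_classification({"A": 17, "B": 29, "C": 31, "D": 5})
        prof = aggregate_sample(cls, index, ClassifierParams(
            min_reads=5, min_fingerprint_frac=0.0))
        assert sum(prof.leaf_abundance.values()) == pytest.approx(100.0, abs=1e-6)


class TestSoundnessAndRecovery:
    def test_clean_reads_never_leave_ancestral_path(self, small_refs, small_index):
        # error-free reads must land on the true source's root path
        tree, genomes = small_refs
        rng = random.Random(0)
        reads = []
        for taxon in tree.leaf_names:
            for _ in range(40):
                pos = rng.randrange(len(genomes[taxon]) - 100)
                reads.append((taxon, genomes[taxon][pos:pos + 100]))
        cls = classify_reads(((t, s) for t, s in reads), small_index, genomes)
        for (truth, _), a in zip(reads, cls.assignments):
            assert a.status == "assigned"
            assert small_index.tree.is_ancestor(a.node, truth)

    def test_classified_fraction_monotone_in_max_edit(self, small_refs,
                                                      small_index):
        tree, genomes = small_refs
        rng = random.Random(1)
        reads = []
        for _ in range(150):
            taxon = rng.choice(tree.leaf_names)
            pos = rng.randrange(len(genomes[taxon]) - 100)
            read = list(genomes[taxon][pos:pos + 100])
            for _ in range(rng.randrange(0, 8)):  # up to 7 substitutions
                i = rng.randrange(100)
                read[i] = rng.choice("ACGT")
            reads.append(("r", "".join(read)))

        def frac(max_edit):
            cls = classify_reads(iter(reads), small_index, genomes,
                                 ClassifierParams(max_edit=max_edit))
            return np.mean([a.status == "assigned" for a in cls.assignments])

        fr = [frac(m) for m in (0, 2, 5, 10)]
        assert all(a <= b + 1e-12 for a, b in zip(fr, fr[1:]))

    def test_two_taxon_mixture_recovered_within_2pp(self):
        from fingertax.synthetic_community import (
            SimulationConfig, simulate_tree_and_genomes)
        cfg = SimulationConfig(n_taxa=2, genome_length=8000, seed=17,
                               seq_error_rate=0.0)
        tree, genomes = simulate_tree_and_genomes(cfg)
        index = build_index(genomes, tree, 21)
        rng = random.Random(2)
        names = sorted(genomes)
        reads = []
        for taxon, n in zip(names, (3500, 1500)):
            for _ in range(n):
                pos = rng.randrange(len(genomes[taxon]) - 100)
                reads.append(("r", genomes[taxon][pos:pos + 100]))
        cls = classify_reads(iter(reads), index, genomes)
        prof = aggregate_sample(cls, index)
        assert abs(prof.leaf_abundance[names[0]] - 70.0) < 2.0
        assert abs(prof.leaf_abundance[names[1]] - 30.0) < 2.0


class TestSubsample:
    def test_identity_at_current_depth(self):
        t = pd.DataFrame([[5, 3, 2], [1, 0, 9]], index=["s1", "s2"])
        out = subsample_counts(t, 10, seed=0)
        pd.testing.assert_frame_equal(out, t)

    def test_row_sums_equal_depth(self):
        t = pd.DataFrame([[50, 30, 20], [10, 80, 40]], index=["s1", "s2"])
        out = subsample_counts(t, 25, seed=0)
        assert (out.sum(axis=1) == 25).all()

    def test_shallow_samples_excluded(self, caplog):
        t = pd.DataFrame([[50, 30, 20], [1, 1, 1]], index=["deep", "shallow"])
        with caplog.at_level("WARNING"):
            out = subsample_counts(t, 25, seed=0)
        assert list(out.index) == ["deep"]
        assert "shallow" in caplog.text

    def test_nonpositive_depth_rejected(self):
        t = pd.DataFrame([[5, 5]])
        with pytest.raises(ValueError):
            subsample_counts(t, 0)

    def test_subsampling_is_unbiased(self):
        counts = np.array([50, 30, 20])
        t = pd.DataFrame([counts], index=["s"])
        reps = 1000
        rng_props = np.array([
            subsample_counts(t, 40, seed=s).iloc[0].to_numpy() / 40
            for s in range(reps)])
        p = counts / counts.sum()
        n_tot, depth = counts.sum(), 40
        var = p * (1 - p) / depth * (n_tot - depth) / (n_tot - 1)
        se = np.sqrt(var / reps)
        assert np.all(np.abs(rng_props.mean(axis=0) - p) < 3 * se + 1e-12)
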