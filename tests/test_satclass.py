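"""Profile training/classification, array annotation, dimhaps, signatures,
trees and the homogenization permutation test."""

import warnings

import numpy as np
import pytest

from satarch._align import revcomp
from satarch.errors import InputError, StatTestError, TrainingError
from satarch.periodicity import Monomer
from satarch.satclass import (
    AMBIGUOUS,
    MonomerAssignment,
    annotate_satellite_arrays,
    build_tree,
    call_dimhaps,
    classify_monomers,
    homogenization_test,
    kmer_signatures,
    train_profiles,
)
from satarch.synthetic import make_monomer_library, mutate_sequence
from tests.conftest import make_random_dna


def _mono(seq, start=0, name="chr1"):
    return Monomer(name, start, start + len(seq), "+", seq)


def _training_set(lib, n=20, rate=0.02, seed=0):
    rng = np.random.default_rng(seed)
    return {
        fam: [mutate_sequence(cons, rate, 0.001, rng) for _ in range(n)]
        for fam, cons in lib.families
    }


class TestProfiles:
    def test_own_consensus_beats_other_profile(self, alpha_lib):
        profiles = train_profiles(_training_set(alpha_lib))
        from satarch.satclass import _score

        for fam, cons in alpha_lib.families:
            own = _score(profiles.profiles[fam], cons)
            others = [
                _score(profiles.profiles[f], cons)
                for f in profiles.families
                if f != fam
            ]
            assert own > max(others)

    def test_profile_consensus_matches_training_source(self, alpha_lib):
        profiles = train_profiles(_training_set(alpha_lib, n=30))
        for fam, cons in alpha_lib.families:
            called = profiles.profiles[fam].consensus
            mismatches = sum(a != b for a, b in zip(called, cons))
            assert mismatches / len(cons) <= 0.02

    def test_zero_pseudocount_gives_minus_inf(self):
        mono = make_random_dna(50, seed=1)
        hard = train_profiles({"A": [mono] * 10}, pseudocount=0.0)
        smooth = train_profiles({"A": [mono] * 10}, pseudocount=0.01)
        lo_hard = hard.profiles["A"].log_odds
        lo_smooth = smooth.profiles["A"].log_odds
        assert np.isneginf(lo_hard).any()
        assert np.isfinite(lo_smooth).all()

    def test_empty_family_rejected(self):
        with pytest.raises(TrainingError):
            train_profiles({"A": []})

    def test_length_heterogeneity_rejected(self):
        with pytest.raises(TrainingError):
            train_profiles(
                {"A": [make_random_dna(100, seed=1), make_random_dna(150, seed=2)]}
            )

    def test_low_confidence_flag(self, alpha_lib):
        small = {f: m[:3] for f, m in _training_set(alpha_lib).items()}
        profiles = train_profiles(small)
        assert profiles.low_confidence() == {"S3", "S4"}


class TestClassification:
    def test_consensus_assigned_to_own_family(self, alpha_lib):
        profiles = train_profiles(_training_set(alpha_lib))
        a = classify_monomers([_mono(alpha_lib.consensus("S3"))], profiles)[0]
        assert (a.family, a.strand) == ("S3", "+")
        assert a.margin > 0

    def test_reverse_complement_gets_minus_strand(self, alpha_lib):
        profiles = train_profiles(_training_set(alpha_lib))
        rc = revcomp(alpha_lib.consensus("S3"))
        a = classify_monomers([_mono(rc)], profiles)[0]
        assert (a.family, a.strand) == ("S3", "-")

    def test_nearer_family_wins(self, alpha_lib):
        # monomer at 10% divergence from S3 and therefore ~25% from S4
        rng = np.random.default_rng(4)
        profiles = train_profiles(_training_set(alpha_lib))
        from satarch.satclass import score_monomer

        query = mutate_sequence(alpha_lib.consensus("S3"), 0.10, 0.0, rng)
        a = classify_monomers([_mono(query)], profiles)[0]
        assert a.family == "S3"
        # exhaustive score table agrees with the assignment
        table = score_monomer(profiles, query)
        best = max(table, key=table.get)
        assert best[0] == "S3"

    def test_low_margin_becomes_ambiguous(self, alpha_lib):
        profiles = train_profiles(_training_set(alpha_lib))
        a = classify_monomers(
            [_mono(alpha_lib.consensus("S3"))], profiles, min_margin=10**6
        )[0]
        assert a.family == AMBIGUOUS

    def test_order_invariance(self, alpha_lib):
        rng = np.random.default_rng(6)
        monomers = [
            _mono(mutate_sequence(alpha_lib.consensus(f), 0.05, 0.0, rng), start=i)
            for i, f in enumerate(["S3", "S4"] * 10)
        ]
        training = _training_set(alpha_lib)
        fwd = classify_monomers(monomers, train_profiles(training))
        reversed_profiles = train_profiles(dict(reversed(list(training.items()))))
        shuffled = list(reversed(monomers))
        bwd = classify_monomers(shuffled, reversed_profiles)
        by_start_fwd = {a.monomer.start: (a.family, a.strand) for a in fwd}
        by_start_bwd = {a.monomer.start: (a.family, a.strand) for a in bwd}
        assert by_start_fwd == by_start_bwd

    def test_empty_profiles_rejected(self):
        from satarch.satclass import ProfileSet

        with pytest.raises(InputError):
            classify_monomers([_mono("ACGT")], ProfileSet())


def _assignment(start, family, name="chr1", length=170):
    m = Monomer(name, start, start + length, "+", "A" * length)
    return MonomerAssignment(m, family, 100.0, 10.0, "+")


class TestArrayAnnotation:
    def test_single_run_merged(self):
        assignments = [_assignment(i * 170, "SF1-1") for i in range(100)]
        arrays = annotate_satellite_arrays(assignments, min_array_monomers=10)
        assert len(arrays) == 1
        assert arrays[0].n_monomers == 100
        assert arrays[0].layer == "active"

    def test_flanked_active_array_layering(self):
        # inactive flanks of an older subfamily around the active array
        assignments = (
            [_assignment(i * 170, "SF1-5") for i in range(50)]
            + [_assignment((50 + i) * 170, "SF1-1") for i in range(200)]
            + [_assignment((250 + i) * 170, "SF1-5") for i in range(50)]
        )
        arrays = annotate_satellite_arrays(
            assignments,
            min_array_monomers=10,
            centromere_windows={"chr1": (0, 300 * 170)},
        )
        assert [a.family for a in arrays] == ["SF1-5", "SF1-1", "SF1-5"]
        assert [a.layer for a in arrays] == ["inactive", "active", "inactive"]
        assert sum(a.layer == "active" for a in arrays) == 1

    def test_short_run_dropped(self):
        assignments = [_assignment(i * 170, "SF1-1") for i in range(5)]
        assert annotate_satellite_arrays(assignments, min_array_monomers=10) == []

    def test_gap_splits_arrays(self):
        left = [_assignment(i * 170, "SF1-1") for i in range(20)]
        right = [_assignment(100000 + i * 170, "SF1-1") for i in range(30)]
        arrays = annotate_satellite_arrays(
            left + right, min_array_monomers=10, max_gap=1000
        )
        assert len(arrays) == 2
        assert {a.n_monomers for a in arrays} == {20, 30}

    def test_unsorted_input_rejected(self):
        assignments = [_assignment(170, "A"), _assignment(0, "A")]
        with pytest.raises(InputError):
            annotate_satellite_arrays(assignments)


class TestDimhaps:
    def test_identical_dimers_single_cluster(self):
        dimer = make_random_dna(340, seed=9)
        arrays = {("chr1", f"a{i}"): dimer for i in range(3)}
        haps = call_dimhaps(arrays)
        assert len(haps) == 1
        assert haps[0].specificity == 1.0
        assert len(haps[0].member_arrays) == 3

    def test_divergent_pair_below_linkage_splits(self):
        rng = np.random.default_rng(10)
        dimer = make_random_dna(340, seed=10)
        other = mutate_sequence(dimer, 0.05, 0.0, rng)  # ~95% identity
        haps = call_dimhaps(
            {("chr1", "a"): dimer, ("chr2", "b"): other}, link_identity=0.99
        )
        assert len(haps) == 2

    def test_planted_two_clade_recovery(self):
        rng = np.random.default_rng(12)
        root_a = make_random_dna(340, seed=12)
        root_b = mutate_sequence(root_a, 0.20, 0.0, rng)
        arrays = {}
        for i in range(7):  # clade A: >=99.2% mutual identity
            arrays[(f"chr{i}", "a")] = mutate_sequence(root_a, 0.003, 0.0, rng)
        for i in range(3):
            arrays[(f"chr{7 + i}", "b")] = mutate_sequence(root_b, 0.003, 0.0, rng)
        haps = call_dimhaps(arrays, link_identity=0.99)
        assert len(haps) == 2
        sizes = sorted(len(h.member_arrays) for h in haps)
        assert sizes == [3, 7]

    def test_empty_input(self):
        assert call_dimhaps({}) == []


class TestKmerSignatures:
    def test_unrelated_arrays_disjoint_nonempty(self):
        a = make_random_dna(300, seed=1) * 5
        b = make_random_dna(300, seed=2) * 5
        sigs = kmer_signatures({"chr1": a, "chr2": b}, k=21, min_copies=2)
        assert all(sig.kmers for sig in sigs)
        assert not (sigs[0].kmers & sigs[1].kmers)

    def test_identical_arrays_empty(self):
        a = make_random_dna(300, seed=3) * 5
        sigs = kmer_signatures({"chr1": a, "chr2": a}, k=21, min_copies=2)
        assert all(not sig.kmers for sig in sigs)

    def test_min_copies_above_counts_empty(self):
        a = make_random_dna(300, seed=1) * 5
        b = make_random_dna(300, seed=2) * 5
        sigs = kmer_signatures({"chr1": a, "chr2": b}, k=21, min_copies=100)
        assert all(not sig.kmers for sig in sigs)

    def test_k_exceeding_shortest_rejected(self):
        with pytest.raises(InputError):
            kmer_signatures({"chr1": "ACGT" * 100, "chr2": "ACGTA"}, k=21)

    def test_canonical_counting_strand_symmetry(self):
        a = make_random_dna(300, seed=5) * 4
        b = make_random_dna(300, seed=6) * 4
        fwd = kmer_signatures({"c1": a, "c2": b}, k=21, min_copies=2)
        rev = kmer_signatures({"c1": revcomp(a), "c2": b}, k=21, min_copies=2)
        assert fwd[0].kmers == rev[0].kmers


def _evolve(parent: str, n_sub: int, rng) -> str:
    """Mutate exactly n_sub distinct positions (additive distances)."""
    pos = rng.choice(len(parent), size=n_sub, replace=False)
    out = list(parent)
    for p in pos:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestTrees:
    def test_additive_four_taxon_topology(self):
        # ((a,b),(c,d)) with long internal branch; disjoint mutation sets
        # keep pairwise distances additive
        rng = np.random.default_rng(20)
        root = make_random_dna(2000, seed=20)
        left = _evolve(root, 200, rng)
        right = _evolve(root, 200, rng)
        seqs = [
            ("a", _evolve(left, 20, rng)),
            ("b", _evolve(left, 20, rng)),
            ("c", _evolve(right, 20, rng)),
            ("d", _evolve(right, 20, rng)),
        ]
        tree = build_tree(seqs)
        # the split {a,b} | {c,d} must be present
        subsets = {frozenset(t.name for t in n.tips()) for n in tree.non_tips()}
        assert frozenset({"a", "b"}) in subsets or frozenset({"c", "d"}) in subsets

    def test_identical_sequences_zero_branch_lengths(self):
        s = make_random_dna(500, seed=21)
        tree = build_tree([("a", s), ("b", s), ("c", s)])
        for node in tree.traverse():
            if node.length is not None:
                assert node.length == pytest.approx(0.0, abs=1e-9)

    def test_two_clade_bipartition_recovered(self):
        rng = np.random.default_rng(22)
        root = make_random_dna(1000, seed=22)
        clade1 = _evolve(root, 200, rng)
        clade2 = _evolve(root, 200, rng)
        seqs = [(f"a{i}", _evolve(clade1, 10, rng)) for i in range(10)] + [
            (f"b{i}", _evolve(clade2, 10, rng)) for i in range(10)
        ]
        tree = build_tree(seqs)
        want = frozenset(f"a{i}" for i in range(10))
        other = frozenset(f"b{i}" for i in range(10))
        subsets = {frozenset(t.name for t in n.tips()) for n in tree.non_tips()}
        assert want in subsets or other in subsets

    def test_too_few_sequences_rejected(self):
        with pytest.raises(InputError):
            build_tree([("a", "ACGT"), ("b", "ACGT")])


class TestHomogenization:
    def _clustered_tree(self):
        rng = np.random.default_rng(30)
        root = make_random_dna(800, seed=30)
        c1 = _evolve(root, 160, rng)
        c2 = _evolve(root, 160, rng)
        seqs = [(f"a{i}", _evolve(c1, 8, rng)) for i in range(10)] + [
            (f"b{i}", _evolve(c2, 8, rng)) for i in range(10)
        ]
        tree = build_tree(seqs)
        labels = {n: ("chr1" if n.startswith("a") else "chr2") for n, _ in seqs}
        return tree, labels

    def test_clustered_labels_significant(self):
        tree, labels = self._clustered_tree()
        stat, p = homogenization_test(tree, labels, n_permutations=999, seed=1)
        assert stat >= 0.9
        assert p <= 0.01

    def test_shuffled_labels_not_significant(self):
        tree, labels = self._clustered_tree()
        rng = np.random.default_rng(5)
        names = list(labels)
        values = rng.permutation(list(labels.values()))
        shuffled = dict(zip(names, values))
        _, p = homogenization_test(tree, shuffled, n_permutations=999, seed=2)
        assert p > 0.01

    def test_single_chromosome_rejected(self):
        tree, labels = self._clustered_tree()
        with pytest.raises(StatTestError):
            homogenization_test(tree, {n: "chr1" for n in labels})

    def test_tiny_tree_warns(self):
        s = make_random_dna(300, seed=33)
        rng = np.random.default_rng(33)
        tree = build_tree(
            [("a", _evolve(s, 30, rng)), ("b", _evolve(s, 30, rng)), ("c", _evolve(s, 30, rng))]
        )
        labels = {"a": "chr1", "b": "chr2", "c": "chr1"}
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            stat, p = homogenization_test(tree, labels, n_permutations=100, seed=3)
        assert any("degenerate" in str(w.message) for w in caught)
        assert 0 < p <= 1
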