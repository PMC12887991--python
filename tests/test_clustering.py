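"""Identity, greedy clustering, Jaccard distances, UPGMA trees."""

import numpy as np
import pytest
from skbio import DistanceMatrix

from conftest import make_db
from oracles import oracle_best_score, oracle_greedy_clusters, oracle_identity
from panatlas.clustering import (
    build_upgma_tree,
    classify_clusters,
    cluster_proteoforms,
    compare_to_known,
    jaccard_digest_matrix,
    pairwise_identity,
    upset_membership,
)
from panatlas.records import ClusterClass

AA = list("ACDEFGHIKLMNPQRSTVWY")


def _random_seq(rng, length):
    return "".join(rng.choice(AA, length))


def _mutate(rng, seq, rate):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = str(rng.choice(AA))
    return "".join(out)


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("MKWVTR", "MKWVTR") == 1.0

    def test_three_of_four_over_shorter(self):
        assert pairwise_identity("AAAA", "AAAT") == 0.75

    def test_substring_normalized_by_shorter(self):
        assert pairwise_identity("ACDEF", "ACDEFGHIKLMNP") == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "A")

    def test_matches_dp_oracle_on_random_pairs(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            a = _random_seq(rng, int(rng.integers(5, 31)))
            if rng.random() < 0.5:
                b = _mutate(rng, a, 0.2)
            else:
                b = _random_seq(rng, int(rng.integers(5, 31)))
            assert pairwise_identity(a, b) == pytest.approx(oracle_identity(a, b))


class TestClusterProteoforms:
    def test_planted_pair_clusters_together(self):
        rng = np.random.default_rng(40)
        s1 = _random_seq(rng, 100)
        s2 = _mutate(rng, s1, 0.05)
        s3 = _random_seq(rng, 100)
        db = make_db([("P1", s1, "A"), ("P2", s2, "B"), ("P3", s3, "C")])
        clusters = cluster_proteoforms(db, 0.7)
        memberships = sorted(sorted(c.member_groups) for c in clusters)
        assert memberships == [[0, 1], [2]]

    def test_threshold_one_recovers_sequence_groups(self):
        rng = np.random.default_rng(41)
        seqs = [_random_seq(rng, 50) for _ in range(5)]
        db = make_db([(f"P{i}", s, "A") for i, s in enumerate(seqs)])
        clusters = cluster_proteoforms(db, 1.0)
        assert len(clusters) == db.n_targets
        assert all(len(c.member_groups) == 1 for c in clusters)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(42)
        seqs = {}
        base = [_random_seq(rng, int(rng.integers(40, 80))) for _ in range(10)]
        gid = 0
        for b in base:
            seqs[gid] = b
            gid += 1
            for _ in range(int(rng.integers(0, 3))):
                seqs[gid] = _mutate(rng, b, 0.05)
                gid += 1
        while len(seqs) < 30:
            seqs[gid] = _random_seq(rng, int(rng.integers(40, 80)))
            gid += 1
        db = make_db([(f"P{g:02d}", s, "A") for g, s in sorted(seqs.items())])
        clusters = cluster_proteoforms(db, 0.7)
        expected = oracle_greedy_clusters(
            dict(enumerate(db.records[g].sequence for g in range(db.n_targets))),
            pairwise_identity, 0.7)
        assert abs(len(clusters) - len(expected)) <= 1
        got_sets = sorted(sorted(c.member_groups) for c in clusters)
        exp_sets = sorted(sorted(m) for m in expected)
        assert got_sets == exp_sets

    def test_kmer_prefilter_does_not_change_result(self):
        rng = np.random.default_rng(43)
        seqs = [_random_seq(rng, 60) for _ in range(12)]
        seqs += [_mutate(rng, seqs[0], 0.05), _mutate(rng, seqs[1], 0.1)]
        db1 = make_db([(f"P{i:02d}", s, "A") for i, s in enumerate(seqs)])
        db2 = make_db([(f"P{i:02d}", s, "A") for i, s in enumerate(seqs)])
        plain = cluster_proteoforms(db1, 0.7, kmer_prefilter=False)
        fast = cluster_proteoforms(db2, 0.7, kmer_prefilter=True)
        assert [sorted(c.member_groups) for c in plain] == \
               [sorted(c.member_groups) for c in fast]

    def test_lower_threshold_never_more_clusters(self):
        rng = np.random.default_rng(44)
        seqs = [_random_seq(rng, 50) for _ in range(8)]
        seqs += [_mutate(rng, s, 0.15) for s in seqs[:4]]
        db = make_db([(f"P{i:02d}", s, "A") for i, s in enumerate(seqs)])
        previous = None
        for threshold in (1.0, 0.9, 0.7, 0.5, 0.3):
            db_copy = make_db([(f"P{i:02d}", s, "A") for i, s in enumerate(seqs)])
            n = len(cluster_proteoforms(db_copy, threshold))
            if previous is not None:
                assert n <= previous
            previous = n

    def test_alignment_scoring_matches_dp(self):
        # the aligner configuration itself: optimal scores equal the oracle's
        from panatlas.clustering import _ALIGNER
        rng = np.random.default_rng(45)
        for _ in range(10):
            a = _random_seq(rng, int(rng.integers(10, 30)))
            b = _random_seq(rng, int(rng.integers(10, 30)))
            assert _ALIGNER.align(a, b).score == pytest.approx(oracle_best_score(a, b))


class TestClassifyClusters:
    def _clusters(self, entries, threshold=0.7):
        db = make_db(entries)
        clusters = cluster_proteoforms(db, threshold)
        return db, clusters

    def test_core_accessory_orphan(self):
        rng = np.random.default_rng(50)
        fam1 = _random_seq(rng, 80)   # in A, B, C -> core
        fam2 = _random_seq(rng, 80)   # in A, B -> accessory
        fam3 = _random_seq(rng, 80)   # in C -> orphan
        entries = [("A1", fam1, "A"), ("B1", _mutate(rng, fam1, 0.03), "B"),
                   ("C1", _mutate(rng, fam1, 0.03), "C"),
                   ("A2", fam2, "A"), ("B2", _mutate(rng, fam2, 0.03), "B"),
                   ("C3", fam3, "C")]
        db, clusters = self._clusters(entries)
        classify_clusters(clusters, {"A", "B", "C"}, db)
        by_class = {c.cluster_class for c in clusters}
        assert by_class == {ClusterClass.CORE, ClusterClass.ACCESSORY,
                            ClusterClass.ORPHAN}

    def test_classes_partition_strain_clusters(self):
        rng = np.random.default_rng(51)
        entries = []
        for i in range(12):
            strain = ["A", "B", "C"][i % 3]
            entries.append((f"P{i:02d}", _random_seq(rng, 60), strain))
        db, clusters = self._clusters(entries)
        classify_clusters(clusters, {"A", "B", "C"}, db)
        n_strain = sum(1 for c in clusters
                       if c.cluster_class is not ClusterClass.NON_STRAIN)
        counts = {cls: sum(1 for c in clusters if c.cluster_class is cls)
                  for cls in (ClusterClass.CORE, ClusterClass.ACCESSORY,
                              ClusterClass.ORPHAN)}
        assert sum(counts.values()) == n_strain == len(clusters)


class TestJaccardMatrix:
    PROTEOME_A = ["MKAAAAAAKWVTTTTTR", "CCCDDDEEEKFFFGGGR"]

    def test_identical_proteomes_distance_zero(self, config):
        dm = jaccard_digest_matrix(
            {"A": self.PROTEOME_A, "B": list(self.PROTEOME_A)}, config)
        assert dm["A", "B"] == 0.0

    def test_disjoint_distance_one(self, config):
        dm = jaccard_digest_matrix(
            {"A": ["MKAAAAAAKWVTTTTTR"], "B": ["CCCDDDEEEKFFFGGGR"]}, config)
        assert dm["A", "B"] == 1.0

    def test_half_overlap(self, config):
        # peptide sets {a,b,c} vs {b,c,d}: J = 2/4
        proto_a = ["AAAAAAAKWWWWWWWKCCCCCCCK"]
        proto_b = ["WWWWWWWKCCCCCCCKDDDDDDDK"]
        dm = jaccard_digest_matrix({"A": proto_a, "B": proto_b}, config)
        assert dm["A", "B"] == pytest.approx(0.5)

    def test_empty_peptide_set_errors(self, config):
        with pytest.raises(ValueError, match="empty peptide set"):
            jaccard_digest_matrix({"A": ["MK"], "B": self.PROTEOME_A}, config)

    def test_restriction_to_observed_never_decreases_similarity(self, config):
        # removing strain-private peptides can only pull the sets together
        proto_a = ["AAAAAAAKWWWWWWWKCCCCCCC"]
        proto_b = ["WWWWWWWKCCCCCCCKDDDDDDD"]
        full = jaccard_digest_matrix({"A": proto_a, "B": proto_b}, config)
        observed = {"WWWWWWWK", "CCCCCCC", "CCCCCCCK"}  # shared peptides only
        restricted = jaccard_digest_matrix({"A": proto_a, "B": proto_b}, config,
                                           observed_peptides=observed)
        assert restricted["A", "B"] <= full["A", "B"]


class TestUpgma:
    def test_two_leaves_split_at_half_distance(self):
        dm = DistanceMatrix([[0.0, 1.0], [1.0, 0.0]], ids=["A", "B"])
        tree = build_upgma_tree(dm)
        assert sorted(t.name for t in tree.tips()) == ["A", "B"]
        assert [t.length for t in tree.tips()] == [0.5, 0.5]

    def test_three_leaves_hand_executed(self):
        # d(A,B)=0.2, d(A,C)=d(B,C)=0.6: A,B join at height 0.1; C at 0.3
        dm = DistanceMatrix(
            [[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]],
            ids=["A", "B", "C"])
        tree = build_upgma_tree(dm)
        depths = {t.name: t.accumulate_to_ancestor(tree) for t in tree.tips()}
        assert depths == pytest.approx({"A": 0.3, "B": 0.3, "C": 0.3})
        ab_parent = tree.find("A").parent
        assert {t.name for t in ab_parent.tips()} == {"A", "B"}
        assert tree.find("A").length == pytest.approx(0.1)
        assert tree.find("C").length == pytest.approx(0.3)

    def test_zero_matrix_gives_star_with_zero_branches(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("ABCD"))
        tree = build_upgma_tree(dm)
        assert len(tree.children) == 4  # star: all tips hang off the root
        assert all(t.length == 0.0 for t in tree.tips())

    def test_single_leaf_errors(self):
        with pytest.raises(ValueError):
            build_upgma_tree(DistanceMatrix([[0.0]], ids=["A"]))

    def test_ultrametric_on_random_matrices(self):
        rng = np.random.default_rng(60)
        for _ in range(10):
            n = int(rng.integers(3, 9))
            x = rng.random((n, 2))
            d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
            dm = DistanceMatrix(d, ids=[f"L{i}" for i in range(n)])
            tree = build_upgma_tree(dm)
            depths = [t.accumulate_to_ancestor(tree) for t in tree.tips()]
            assert max(depths) - min(depths) < 1e-9


class TestCompareToKnown:
    def test_identical_is_previously_observed(self):
        rng = np.random.default_rng(70)
        known = _random_seq(rng, 60)
        new, seen = compare_to_known([known], [known], 0.7)
        assert new == [] and seen == [known]

    def test_unrelated_is_new(self):
        rng = np.random.default_rng(71)
        canon = _random_seq(rng, 60)
        knowns = [_random_seq(rng, 60) for _ in range(3)]
        new, seen = compare_to_known([canon], knowns, 0.7)
        assert new == [canon]

    def test_planted_relatives_partition_exactly(self):
        rng = np.random.default_rng(72)
        knowns = [_random_seq(rng, 80) for _ in range(10)]
        relatives = [_mutate(rng, k, 0.2) for k in knowns]   # ~80% identity
        novel = [_random_seq(rng, 80) for _ in range(10)]
        new, seen = compare_to_known(relatives + novel, knowns, 0.7)
        assert sorted(seen) == sorted(relatives)
        assert sorted(new) == sorted(novel)

    def test_empty_lists_error(self):
        with pytest.raises(ValueError):
            compare_to_known([], ["ACDEF"], 0.7)


class TestUpsetMembership:
    def test_rows_partition_and_order(self):
        rng = np.random.default_rng(80)
        entries = []
        # 3 families in {A,B}, 1 in {C}
        for i in range(3):
            fam = _random_seq(rng, 60)
            entries += [(f"A{i}", fam, "A"), (f"B{i}", _mutate(rng, fam, 0.03), "B")]
        entries.append(("C0", _random_seq(rng, 60), "C"))
        db = make_db(entries)
        clusters = cluster_proteoforms(db, 0.7)
        classify_clusters(clusters, {"A", "B", "C"}, db)
        table = upset_membership(clusters)
        assert table.n_clusters.sum() == len(clusters)
        assert list(table.n_clusters) == sorted(table.n_clusters, reverse=True)
        top = table.iloc[0]
        assert top.strains == "A;B" and top.n_clusters == 3
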