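"""Gene clustering and presence/absence profile outlier detection."""

import itertools

import numpy as np
import pytest

from submarker.core import GenomeRecord, SubmarkerError
from submarker.pangenome import (PangenomeMatrix, build_pangenome,
                                 detect_mislabeled)
from submarker.simulate import SimConfig, simulate_references


def _mutate(seq, positions):
    rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
    s = list(seq)
    for p in positions:
        s[p] = rot[s[p]]
    return "".join(s)


RNG = np.random.default_rng(99)


def _seq(n):
    return "".join(RNG.choice(list("ACGT"), size=n))


class TestBuildPangenome:
    def test_identical_gene_sets_give_all_ones(self):
        genes = [("x", _seq(300)), ("y", _seq(250)), ("z", _seq(200))]
        g1 = GenomeRecord("g1", "cladeA", genes)
        g2 = GenomeRecord("g2", "cladeB", list(genes))
        m = build_pangenome([g1, g2])
        assert len(m.clusters) == 3
        assert m.presence.all()

    def test_shared_gene_at_99pct_identity_merges_at_095(self):
        base = _seq(400)
        variant = _mutate(base, range(0, 400, 100))  # 4 subs = 99% identity
        g1 = GenomeRecord("g1", "cladeA", [("x", base)])
        g2 = GenomeRecord("g2", "cladeB", [("x", variant)])
        m95 = build_pangenome([g1, g2], identity_threshold=0.95)
        assert len(m95.clusters) == 1 and m95.presence.all()
        m999 = build_pangenome([g1, g2], identity_threshold=0.999)
        assert len(m999.clusters) == 2

    def test_recovers_planted_cluster_structure(self, small_refs):
        genomes, truth = small_refs
        m = build_pangenome(genomes)
        assert len(m.clusters) == len(truth.clusters)
        # genome order matches; cluster discovery order does not, so
        # compare the multiset of per-cluster presence rows
        assert m.genomes == list(truth.genome_content)
        got = sorted(map(tuple, m.presence.astype(int).tolist()))
        want = sorted(map(tuple, truth.presence_frame().to_numpy().tolist()))
        assert got == want

    def test_genome_order_does_not_change_presence(self, small_refs):
        genomes, _ = small_refs
        subset = genomes[:4] + genomes[-4:]
        m1 = build_pangenome(subset)
        m2 = build_pangenome(subset[::-1])
        f1 = m1.to_frame().sort_index(axis=1)
        f2 = m2.to_frame().sort_index(axis=1)
        assert sorted(map(tuple, f1.to_numpy().tolist())) == \
            sorted(map(tuple, f2.to_numpy().tolist()))

    def test_empty_gene_list_is_an_error_naming_the_genome(self):
        g1 = GenomeRecord("ok", "cladeA", [("x", "ACGT" * 50)])
        g2 = GenomeRecord("empty_one", "cladeB", [])
        with pytest.raises(ValueError, match="empty_one"):
            build_pangenome([g1, g2])

    @pytest.mark.parametrize("kwargs", [dict(identity_threshold=0.0),
                                        dict(identity_threshold=1.5),
                                        dict(coverage_threshold=-0.1)])
    def test_threshold_validation(self, kwargs):
        g = [GenomeRecord(f"g{i}", "cladeA", [("x", "ACGT" * 30)]) for i in range(2)]
        with pytest.raises(ValueError):
            build_pangenome(g, **kwargs)


def _matrix(presence, labels):
    presence = np.asarray(presence, dtype=bool)
    genomes = list(labels)
    return PangenomeMatrix(
        clusters=[(f"c{i}", "A" * 20) for i in range(presence.shape[0])],
        genomes=genomes, presence=presence, labels=dict(labels))


def _brute_force_two_partition(matrix):
    """Minimum total within-group Jaccard distance over all 2-partitions."""
    from scipy.spatial.distance import pdist, squareform

    sq = squareform(pdist(matrix.presence.T.astype(bool), metric="jaccard"))
    n = len(matrix.genomes)
    best, best_cost = None, np.inf
    for r in range(1, n // 2 + 1):
        for combo in itertools.combinations(range(n), r):
            g1 = set(combo)
            g2 = set(range(n)) - g1
            cost = sum(sq[i, j] for a in (g1, g2)
                       for i, j in itertools.combinations(sorted(a), 2))
            if cost < best_cost - 1e-12:
                best_cost, best = cost, frozenset(map(frozenset, (g1, g2)))
    return best


class TestDetectMislabeled:
    def test_planted_swaps_are_flagged_exactly(self):
        cfg = SimConfig(seed=5, core_gene_count=120, specific_gene_count=40,
                        gene_length_mean=400.0, n_mislabeled=2)
        _, truth = simulate_references(cfg)
        report = detect_mislabeled(truth.to_matrix())
        assert sorted(report.flagged) == sorted(truth.mislabeled)
        assert set(report.cluster_assignment.values()) == {1, 2}

    def test_clean_labels_give_no_flags(self, small_refs):
        _, truth = small_refs
        report = detect_mislabeled(truth.to_matrix())
        assert report.flagged == []

    def test_flag_stability_under_exclusion(self):
        cfg = SimConfig(seed=17, core_gene_count=120, specific_gene_count=40,
                        gene_length_mean=400.0, n_mislabeled=1)
        _, truth = simulate_references(cfg)
        m = truth.to_matrix()
        first = detect_mislabeled(m)
        assert first.flagged == truth.mislabeled
        second = detect_mislabeled(m.drop_genomes(first.flagged))
        assert second.flagged == []

    def test_matches_exhaustive_two_partition_on_small_inputs(self):
        cfg = SimConfig(seed=23, n_genomes_a=5, n_genomes_b=6,
                        core_gene_count=40, specific_gene_count=15,
                        gene_length_mean=400.0, n_mislabeled=1)
        _, truth = simulate_references(cfg)
        m = truth.to_matrix()
        report = detect_mislabeled(m)
        got = frozenset(
            frozenset(i for i, g in enumerate(m.genomes)
                      if report.cluster_assignment[g] == c)
            for c in (1, 2))
        assert got == _brute_force_two_partition(m)
        assert report.flagged == truth.mislabeled

    def test_identical_profiles_are_an_error(self):
        m = _matrix(np.ones((4, 4)), {"g1": "cladeA", "g2": "cladeA",
                                      "g3": "cladeB", "g4": "cladeB"})
        with pytest.raises(SubmarkerError, match="no cluster structure"):
            detect_mislabeled(m)

    def test_majority_tie_flags_the_whole_group(self):
        # group 1: one A + one B (tie); group 2: one A + one B (tie)
        presence = np.array([[1, 1, 0, 0], [1, 1, 0, 0],
                             [0, 0, 1, 1], [0, 0, 1, 1]])
        m = _matrix(presence, {"g1": "cladeA", "g2": "cladeB",
                               "g3": "cladeA", "g4": "cladeB"})
        report = detect_mislabeled(m)
        assert sorted(report.flagged) == ["g1", "g2", "g3", "g4"]

    def test_unknown_genomes_are_never_flagged(self):
        presence = np.array([[1, 1, 1, 0, 0], [1, 1, 1, 0, 0],
                             [0, 0, 0, 1, 1], [0, 0, 0, 1, 1]])
        m = _matrix(presence, {"g1": "cladeA", "g2": "cladeA", "g3": "unknown",
                               "g4": "cladeB", "g5": "cladeB"})
        report = detect_mislabeled(m)
        assert report.flagged == []
        assert "g3" in report.cluster_assignment

    def test_silhouette_scores_are_high_for_clean_structure(self, small_refs):
        _, truth = small_refs
        report = detect_mislabeled(truth.to_matrix())
        assert min(report.silhouette_like_score.values()) > 0.5
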