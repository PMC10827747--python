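"""Marker selection rule, specificity filter and database assembly."""

import numpy as np
import pytest

from submarker import benchmarks as bm
from submarker.core import SubmarkerError
from submarker.markers import (CandidateMarker, build_marker_db,
                               filter_specificity, min_presence_count,
                               select_candidates)
from submarker.pangenome import PangenomeMatrix

RNG = np.random.default_rng(1234)


def _seq(n):
    return "".join(RNG.choice(list("ACGT"), size=n))


def _matrix(rows, n_a=14, n_b=30, labels_extra=None):
    """rows: list of (presence_in_A: int, presence_in_B: int)."""
    genomes = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    labels = {g: ("cladeA" if g.startswith("A") else "cladeB") for g in genomes}
    if labels_extra:
        labels.update(labels_extra)
    presence = np.zeros((len(rows), len(genomes)), dtype=bool)
    for r, (ka, kb) in enumerate(rows):
        presence[r, :ka] = True
        presence[r, n_a:n_a + kb] = True
    clusters = [(f"c{r}", _seq(120)) for r in range(len(rows))]
    return PangenomeMatrix(clusters=clusters, genomes=genomes,
                           presence=presence, labels=labels)


class TestSelectionRule:
    def test_worked_example_13_of_14(self):
        """A gene in 13 of 14 clade-A genomes and no clade-B genome is a
        clade-A candidate; one stray clade-B carrier kills it; 12 of 14
        misses the 90% bar."""
        m = _matrix([(13, 0), (14, 1), (12, 0)])
        got = {(c.cluster_id, c.clade) for c in select_candidates(m)}
        assert got == {("c0", "cladeA")}

    def test_min_presence_count_threshold_arithmetic(self):
        assert min_presence_count(14, 0.90) == 13
        assert min_presence_count(30, 0.90) == 27
        assert min_presence_count(10, 0.90) == 9
        with pytest.raises(ValueError):
            min_presence_count(10, 0.0)

    def test_candidate_carries_presence_fraction(self):
        m = _matrix([(13, 0)])
        (cand,) = select_candidates(m)
        assert cand.presence_fraction_target == pytest.approx(13 / 14)
        assert cand.presence_count_offtarget == 0

    def test_symmetric_for_clade_b(self):
        m = _matrix([(0, 28)])
        (cand,) = select_candidates(m)
        assert cand.clade == "cladeB"

    def test_unknown_and_excluded_genomes_are_ignored(self):
        # carried by 13/14 A genomes and one genome we then exclude
        m = _matrix([(13, 1)], labels_extra={"B29": "unknown"})
        assert select_candidates(m) == []  # B0 still carries it
        m2 = _matrix([(13, 1)])
        got = select_candidates(m2, excluded_genomes={"B0"})
        assert [c.cluster_id for c in got] == ["c0"]

    def test_matches_exhaustive_oracle_on_random_matrices(self):
        res = bm.marker_selection_oracle_agreement(n_matrices=60, seed=3)
        assert res["agreement_pct"] == 100.0

    def test_raising_threshold_never_adds_candidates(self):
        rng = np.random.default_rng(8)
        rows = [(int(rng.integers(0, 15)), int(rng.integers(0, 31)))
                for _ in range(30)]
        m = _matrix(rows)
        prev = None
        for thr in (0.5, 0.7, 0.9, 1.0):
            cur = {c.cluster_id for c in select_candidates(m, presence_threshold=thr)}
            if prev is not None:
                assert cur <= prev
            prev = cur


class TestSpecificityFilter:
    def _candidate(self, seq):
        return CandidateMarker("cand", "cladeA", 1.0, 0, seq)

    @staticmethod
    def _mutate(seq, rate, rng):
        rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
        return "".join(rot[c] if rng.random() < rate else c for c in seq)

    def test_high_identity_wide_coverage_hit_is_removed(self):
        rng = np.random.default_rng(0)
        cand = self._candidate(_seq(500))
        decoy = self._mutate(cand.sequence[:300], 0.04, rng)  # ~96% id, 60% cov
        kept, (v,) = filter_specificity([cand], [("d1", decoy)])
        assert kept == [] and not v.passed
        assert v.best_hit[0] == "d1"
        assert v.best_hit[1] > 0.90 and v.best_hit[2] > 0.50

    def test_narrow_coverage_hit_is_retained(self):
        rng = np.random.default_rng(1)
        cand = self._candidate(_seq(500))
        decoy = self._mutate(cand.sequence[:200], 0.04, rng)  # 40% cov
        kept, (v,) = filter_specificity([cand], [("d1", decoy)])
        assert kept == [cand] and v.passed
        assert v.best_hit is not None and v.best_hit[2] <= 0.50

    def test_no_seed_hits_means_retained_with_no_best_hit(self):
        cand = self._candidate(_seq(400))
        kept, (v,) = filter_specificity([cand], [("d1", _seq(400))])
        assert kept == [cand] and v.passed and v.best_hit is None

    def test_candidate_shorter_than_seed_uses_full_dp(self):
        cand = self._candidate("ACGTACGTAC")  # 10 bp < k
        kept, (v,) = filter_specificity([cand], [("d1", "TTT" + cand.sequence + "GGG")])
        assert kept == [] and not v.passed
        assert v.best_hit[1] == pytest.approx(1.0)

    def test_enlarging_decoy_set_never_rescues_a_marker(self, small_refs):
        _, truth = small_refs
        cands = bm.mk.select_candidates(truth.to_matrix())
        half = truth.decoys[: len(truth.decoys) // 2]
        kept_half, _ = filter_specificity(cands, half)
        kept_full, _ = filter_specificity(cands, truth.decoys)
        assert {c.cluster_id for c in kept_full} <= {c.cluster_id for c in kept_half}

    def test_empty_decoy_set_is_an_error(self):
        with pytest.raises(ValueError):
            filter_specificity([self._candidate(_seq(100))], [])

    def test_planted_homologs_define_removals_exactly(self, small_refs):
        _, truth = small_refs
        cands = bm.mk.select_candidates(truth.to_matrix())
        _, verdicts = filter_specificity(cands, truth.decoys)
        homolog_fams = set(truth.decoy_homolog_of.values())
        removed = {v.marker_id for v in verdicts if not v.passed}
        assert removed == {c.cluster_id for c in cands
                          if c.cluster_id in homolog_fams}

    def test_no_core_family_is_ever_selected(self, small_refs):
        _, truth = small_refs
        cands = bm.mk.select_candidates(truth.to_matrix())
        assert not any(c.cluster_id.startswith("core") for c in cands)
        spec = {c.cluster_id for c in cands}
        assert spec == truth.marker_truth["cladeA"] | truth.marker_truth["cladeB"]


class TestBuildMarkerDb:
    def test_ids_are_deterministic_by_descending_length(self):
        cands = [CandidateMarker("x", "cladeA", 1.0, 0, _seq(100)),
                 CandidateMarker("y", "cladeA", 1.0, 0, _seq(300)),
                 CandidateMarker("z", "cladeB", 0.95, 0, _seq(200))]
        db = build_marker_db(cands)
        assert [m.marker_id for m in db] == ["cladeA_0000", "cladeA_0001", "cladeB_0000"]
        assert db.get("cladeA_0000").length == 300
        assert db.get("cladeB_0000").source_cluster == "z"

    def test_duplicate_sequence_across_clades_is_a_hard_error(self):
        s = _seq(150)
        cands = [CandidateMarker("x", "cladeA", 1.0, 0, s),
                 CandidateMarker("y", "cladeB", 1.0, 0, s)]
        with pytest.raises(SubmarkerError, match="specificity"):
            build_marker_db(cands)

    def test_single_clade_database_warns_but_builds(self):
        cands = [CandidateMarker("x", "cladeA", 1.0, 0, _seq(100))]
        with pytest.warns(UserWarning, match="unquantifiable"):
            db = build_marker_db(cands)
        assert len(db) == 1
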