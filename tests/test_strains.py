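"""Consensus calling, SNP distances and neighbor joining."""

import io as _io
import re

import numpy as np
import pytest

from submarker import benchmarks as bm
from submarker.core import (Marker, MarkerDatabase, MarkerHit, Read, ReadSet,
                            SubmarkerError)
from submarker.quantify import MappingResult, map_reads
from submarker.simulate import SimConfig, mutate_genome, simulate_reads, simulate_references
from submarker.strains import (DistanceMatrix, StrainAlignment, attach_reads,
                               build_consensus, nj_tree, pairwise_distances)

RNG = np.random.default_rng(321)


def _seq(n):
    return "".join(RNG.choice(list("ACGT"), size=n))


def _aln(rows, ids=None):
    arr = np.array([list(r.encode()) for r in rows], dtype=np.uint8)
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return StrainAlignment(samples=ids, marker_ids=["m"],
                           marker_offsets=np.array([0, arr.shape[1]]),
                           consensus=arr, depth=np.ones_like(arr, dtype=np.int32))


@pytest.fixture(scope="module")
def strain_setup():
    cfg = SimConfig(seed=808, core_gene_count=40, specific_gene_count=20,
                    gene_length_mean=400.0, gene_length_sd=50.0,
                    read_count=6000, error_rate=0.0, dropout=0.0)
    genomes, truth = simulate_references(cfg)
    from submarker import markers as mk

    cands = mk.select_candidates(truth.to_matrix())
    kept, verd = mk.filter_specificity(cands, truth.decoys)
    db = MarkerDatabase(markers=mk.build_marker_db(kept, verd).by_clade("cladeA"))
    base = next(g for g in genomes if g.label == "cladeA")
    return cfg, db, base


def _map_sample(genome, db, cfg, sid, seed):
    rs, _ = simulate_reads([genome], {"cladeA": 1.0}, cfg, sample_id=sid, seed=seed)
    mapping = map_reads(rs, db)
    attach_reads(mapping, rs)
    return mapping


class TestConsensus:
    def test_error_free_reads_reproduce_the_genome(self, strain_setup):
        cfg, db, base = strain_setup
        aln = build_consensus([_map_sample(base, db, cfg, "s1", 11)], db)
        assert aln.samples == ["s1"]
        row = aln.row("s1")
        genes = dict(base.genes)
        for mid, (lo, hi) in zip(aln.marker_ids,
                                 zip(aln.marker_offsets, aln.marker_offsets[1:])):
            marker = db.get(mid)
            called = [(i, c) for i, c in enumerate(row[lo:hi]) if c != "N"]
            src = genes[marker.source_cluster]
            assert called, f"marker {mid} fully uncalled"
            assert all(src[i] == c for i, c in called)

    def test_planted_snps_appear_exactly(self, strain_setup):
        cfg, db, base = strain_setup
        marker_genes = [m.source_cluster for m in db]
        variant, snps = mutate_genome(base, 20, seed=99, gene_ids=marker_genes)
        aln = build_consensus([_map_sample(base, db, cfg, "orig", 21),
                               _map_sample(variant, db, cfg, "var", 22)], db)
        assert sorted(aln.samples) == ["orig", "var"]
        r0 = np.frombuffer(aln.row("orig").encode(), dtype=np.uint8)
        r1 = np.frombuffer(aln.row("var").encode(), dtype=np.uint8)
        both = (r0 != ord("N")) & (r1 != ord("N"))
        got = set(np.nonzero(both & (r0 != r1))[0].tolist())
        want = set()
        offsets = {m.marker_id: int(o) for m, o in zip(db, aln.marker_offsets)}
        by_gene = {m.source_cluster: m.marker_id for m in db}
        for gene, positions in snps.items():
            for p in positions:
                want.add(offsets[by_gene[gene]] + p)
        # every consensus difference is a planted SNP; callable planted
        # SNPs are all recovered
        assert got <= want
        assert len(got) >= 0.9 * len(want)

    def test_even_allele_split_yields_n(self):
        db = MarkerDatabase(markers=[Marker("m", "cladeA", "ACGTACGTACGT" * 10)])
        seq = db.get("m").sequence
        alt = "G" if seq[5] != "G" else "T"
        reads = [Read(f"a{i}", seq[:60]) for i in range(3)]
        reads += [Read(f"b{i}", seq[:5] + alt + seq[6:60]) for i in range(3)]
        rs = ReadSet("s", reads)
        mapping = MappingResult("s", n_reads=6)
        for r in reads:
            mapping.hits.append(MarkerHit(r.read_id, "m", 1.0, 60, 0, 0))
        attach_reads(mapping, rs)
        aln = build_consensus([mapping], db, min_depth=3, majority=0.8,
                              min_marker_count=1, min_callable_fraction=0.0)
        assert aln.row("s")[5] == "N"
        assert aln.row("s")[10] == seq[10]

    def test_lowering_min_depth_never_adds_n_calls(self, strain_setup):
        cfg, db, base = strain_setup
        mapping = _map_sample(base, db, cfg, "s1", 31)
        n_counts = []
        for depth in (1, 3, 6):
            aln = build_consensus([mapping], db, min_depth=depth,
                                  min_marker_count=1, min_callable_fraction=0.0)
            n_counts.append(aln.row("s1").count("N"))
        assert n_counts[0] <= n_counts[1] <= n_counts[2]

    def test_no_passing_sample_warns_and_returns_empty(self, strain_setup):
        cfg, db, base = strain_setup
        mapping = MappingResult("s", n_reads=0)
        attach_reads(mapping, ReadSet("s", []))
        with pytest.warns(UserWarning, match="no sample"):
            aln = build_consensus([mapping], db)
        assert aln.samples == []


class TestDistances:
    def test_identical_rows_have_zero_distance(self):
        dm = pairwise_distances(_aln(["ACGTAC", "ACGTAC"]))
        assert dm[("s0", "s1")] == 0.0
        assert dm.values.diagonal().sum() == 0.0

    def test_five_mismatches_in_hundred_sites(self):
        a = _seq(100)
        b = a[:95] + "".join({"A": "C", "C": "G", "G": "T", "T": "A"}[c] for c in a[95:])
        dm = pairwise_distances(_aln([a, b]))
        assert dm[("s0", "s1")] == pytest.approx(0.05)

    def test_n_sites_are_excluded_pairwise(self):
        dm = pairwise_distances(_aln(["ACGTNN", "ANGTAC"]))
        # comparable sites: positions 0,2,3 -> 0 mismatches
        assert dm[("s0", "s1")] == 0.0

    def test_zero_comparable_sites_is_missing_not_zero(self):
        dm = pairwise_distances(_aln(["NNNAAA", "CCCNNN"]))
        assert np.isnan(dm[("s0", "s1")])
        with pytest.raises(SubmarkerError, match="missing"):
            nj_tree(DistanceMatrix(ids=["a", "b", "c"],
                                   values=np.array([[0, np.nan, 1],
                                                    [np.nan, 0, 1], [1, 1, 0.0]])))

    def test_sample_order_invariance(self, strain_setup):
        cfg, db, base = strain_setup
        maps = [_map_sample(base, db, cfg, f"s{i}", 40 + i) for i in range(3)]
        d1 = pairwise_distances(build_consensus(maps, db))
        d2 = pairwise_distances(build_consensus(maps[::-1], db))
        for i in d1.ids:
            for j in d1.ids:
                assert d1[(i, j)] == d2[(i, j)]


def _branch_lengths(newick):
    return [float(x) for x in re.findall(r":([0-9.eE+-]+)", newick)]


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(ids=["a", "b", "c"],
                            values=np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]]))
        nwk = nj_tree(dm)
        lengths = dict(zip(re.findall(r"([a-c]):", nwk), _branch_lengths(nwk)))
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_recovers_additive_five_taxon_topology(self):
        rng = np.random.default_rng(13)
        dm, G = bm.random_additive_matrix(5, rng)
        nwk = nj_tree(dm)
        assert bm._rf_distance(nwk, bm._tree_from_graph(G, dm.ids)) == 0.0

    def test_agrees_with_skbio_nj_topology(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(29)
        for _ in range(5):
            dm, _ = bm.random_additive_matrix(int(rng.integers(4, 8)), rng)
            ours = nj_tree(dm)
            theirs = skbio_nj(SkbioDM(dm.values, ids=dm.ids))
            assert bm._rf_distance(ours, str(theirs)) == 0.0

    def test_branch_lengths_never_negative_even_on_noisy_input(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            dm, _ = bm.random_additive_matrix(6, rng)
            noisy = dm.values + rng.uniform(0, 0.3, dm.values.shape)
            noisy = (noisy + noisy.T) / 2
            np.fill_diagonal(noisy, 0.0)
            nwk = nj_tree(DistanceMatrix(ids=dm.ids, values=noisy))
            assert min(_branch_lengths(nwk)) >= 0.0

    def test_fewer_than_three_samples_is_an_error(self):
        dm = DistanceMatrix(ids=["a", "b"], values=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            nj_tree(dm)

    def test_planted_strain_clusters_are_separated(self):
        res = bm.strain_cluster_separation(n_seeds=3, seed=2)
        assert res["bipartition_separation_pct"] == 100.0
        assert res["within_less_than_between_pct"] == 100.0
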