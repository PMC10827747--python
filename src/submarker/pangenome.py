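"""Pangenome construction and mis-annotated-reference detection.

``build_pangenome`` clusters the gene sequences of a set of reference
genomes into gene families (greedy, length-sorted, identity-based) and
records which genome carries which family — the presence/absence matrix
that everything downstream consumes.

``detect_mislabeled`` clusters the genomes themselves by the Jaccard
similarity of their presence/absence profiles.  With two subspecies the
profiles fall into two clear groups; a genome whose declared subspecies
disagrees with the majority label of its group is flagged as a suspected
mis-annotation.  Flagged genomes are only reported — excluding them is
the caller's explicit decision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from . import _align
from .core import UNKNOWN_LABEL, GenomeRecord, SubmarkerError

logger = logging.getLogger(__name__)

__all__ = ["PangenomeMatrix", "OutlierReport", "build_pangenome", "detect_mislabeled"]


@dataclass
class PangenomeMatrix:
    """Gene-family presence/absence across genomes.

    ``clusters`` holds ``(cluster_id, representative_sequence)`` in
    creation order; ``presence`` is a boolean [cluster x genome] array.
    """

    clusters: list[tuple[str, str]]
    genomes: list[str]
    presence: np.ndarray
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.clusters), len(self.genomes)):
            raise ValueError(
                f"presence shape {self.presence.shape} != "
                f"({len(self.clusters)}, {len(self.genomes)})"
            )

    @property
    def cluster_ids(self) -> list[str]:
        return [c for c, _ in self.clusters]

    def label_of(self, genome_id: str) -> str:
        return self.labels.get(genome_id, UNKNOWN_LABEL)

    def genome_profile(self, genome_id: str) -> np.ndarray:
        return self.presence[:, self.genomes.index(genome_id)]

    def drop_genomes(self, genome_ids) -> "PangenomeMatrix":
        """A copy without the given genomes; families left with no
        carrier are removed."""
        drop = set(genome_ids)
        keep = [j for j, g in enumerate(self.genomes) if g not in drop]
        pres = self.presence[:, keep]
        rows = pres.any(axis=1)
        return PangenomeMatrix(
            clusters=[c for c, r in zip(self.clusters, rows) if r],
            genomes=[self.genomes[j] for j in keep],
            presence=pres[rows],
            labels={g: l for g, l in self.labels.items() if g not in drop},
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.presence.astype(int), index=self.cluster_ids,
                            columns=self.genomes)


@dataclass
class OutlierReport:
    """Result of presence/absence profile clustering at k=2."""

    cluster_assignment: dict[str, int]
    flagged: list[str]
    silhouette_like_score: dict[str, float]
    majority_labels: dict[int, Optional[str]]


def build_pangenome(
    genomes: Sequence[GenomeRecord],
    identity_threshold: float = 0.95,
    coverage_threshold: float = 0.80,
    k: int = 15,
    rep_stride: int = 5,
) -> PangenomeMatrix:
    """Greedy length-sorted clustering of all genes into families.

    Genes are processed in order of decreasing length (ties broken by
    sequence, so genome input order never matters).  Each gene joins the
    first existing cluster whose representative it matches at
    ``>= identity_threshold`` over ``>= coverage_threshold`` of the
    shorter sequence, else it founds a new cluster with itself as
    representative.  Candidate representatives are found by shared
    ``k``-mers (representatives indexed every ``rep_stride`` positions);
    identity is an edit-distance identity with the shorter sequence
    aligned end-to-end inside the longer, which spans the shorter
    sequence fully, so an accepted merge always covers it.
    """
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    for thr, name in ((identity_threshold, "identity_threshold"),
                      (coverage_threshold, "coverage_threshold")):
        if not (0.0 < thr <= 1.0):
            raise ValueError(f"{name} must be in (0, 1], got {thr}")
    for g in genomes:
        if not g.genes:
            raise ValueError(f"genome {g.genome_id} has an empty gene list")

    seen = set()
    for g in genomes:
        if g.genome_id in seen:
            raise SubmarkerError(f"duplicate genome_id {g.genome_id!r}")
        seen.add(g.genome_id)

    entries = [
        (len(seq), seq, g.genome_id, gene_id)
        for g in genomes
        for gene_id, seq in g.genes
    ]
    entries.sort(key=lambda e: (-e[0], e[1], e[2], e[3]))

    index = _align.KmerIndex(k=k, stride=rep_stride)
    genome_pos = {g.genome_id: j for j, g in enumerate(genomes)}
    assignments: list[list[int]] = []  # cluster -> genome column hits
    reps: list[tuple[str, str]] = []

    for length, seq, genome_id, gene_id in entries:
        codes = _align.encode(seq)
        if length >= k:
            candidates = index.seed_refs(codes)
        else:  # too short to seed: fall back to scanning every representative
            candidates = list(range(len(reps)))
        target = -1
        for ci in candidates:
            rep_codes = index.seqs[ci]
            short, long_ = (codes, rep_codes) if length <= rep_codes.shape[0] else (rep_codes, codes)
            if _align.identity_infix(short, long_) >= identity_threshold:
                target = ci
                break
        if target < 0:
            target = index.add(f"cl{len(reps):05d}", codes)
            reps.append((index.names[target], seq))
            assignments.append([])
        assignments[target].append(genome_pos[genome_id])

    presence = np.zeros((len(reps), len(genomes)), dtype=bool)
    for ci, cols in enumerate(assignments):
        presence[ci, cols] = True

    labels = {g.genome_id: g.label for g in genomes}
    logger.info("pangenome: %d genes -> %d clusters over %d genomes",
                len(entries), len(reps), len(genomes))
    return PangenomeMatrix(clusters=reps, genomes=list(labels), presence=presence,
                           labels=labels)


def _jaccard_condensed(matrix: PangenomeMatrix) -> np.ndarray:
    profiles = matrix.presence.T.astype(bool)
    return pdist(profiles, metric="jaccard")


def detect_mislabeled(matrix: PangenomeMatrix) -> OutlierReport:
    """Partition genomes into two groups by their gene-content profiles
    and flag label/group disagreements.

    Average-linkage hierarchical clustering on Jaccard distance between
    presence/absence profiles, cut at k=2.  The majority (non-unknown)
    label of each group defines its subspecies; any labeled genome in
    the wrong group is flagged.  A tie in the majority count flags every
    labeled genome of that group — ambiguity surfaces rather than hides.
    """
    labeled_counts: dict[str, int] = {}
    for g in matrix.genomes:
        lab = matrix.label_of(g)
        if lab != UNKNOWN_LABEL:
            labeled_counts[lab] = labeled_counts.get(lab, 0) + 1
    if len(labeled_counts) < 2 or min(labeled_counts.values()) < 2:
        raise ValueError("need at least 2 labeled genomes per subspecies")

    dist = _jaccard_condensed(matrix)
    if np.allclose(dist, 0.0):
        raise SubmarkerError("no cluster structure: all presence profiles identical")
    Z = linkage(dist, method="average")
    groups = fcluster(Z, t=2, criterion="maxclust")
    assignment = {g: int(c) for g, c in zip(matrix.genomes, groups)}

    majority: dict[int, Optional[str]] = {}
    for c in (1, 2):
        counts: dict[str, int] = {}
        for g in matrix.genomes:
            if assignment[g] == c and matrix.label_of(g) != UNKNOWN_LABEL:
                lab = matrix.label_of(g)
                counts[lab] = counts.get(lab, 0) + 1
        if not counts:
            majority[c] = None
            continue
        best = max(counts.values())
        winners = [l for l, n in counts.items() if n == best]
        majority[c] = winners[0] if len(winners) == 1 else None  # None == tie

    flagged = []
    for g in matrix.genomes:
        lab = matrix.label_of(g)
        if lab == UNKNOWN_LABEL:
            continue
        maj = majority[assignment[g]]
        if maj is None or lab != maj:
            flagged.append(g)

    sq = squareform(dist)
    sil: dict[str, float] = {}
    gidx = {g: i for i, g in enumerate(matrix.genomes)}
    for g in matrix.genomes:
        own = [gidx[h] for h in matrix.genomes if assignment[h] == assignment[g] and h != g]
        other = [gidx[h] for h in matrix.genomes if assignment[h] != assignment[g]]
        a = float(np.mean(sq[gidx[g], own])) if own else 0.0
        b = float(np.mean(sq[gidx[g], other])) if other else 0.0
        denom = max(a, b)
        sil[g] = (b - a) / denom if denom > 0 else 0.0

    return OutlierReport(cluster_assignment=assignment, flagged=flagged,
                         silhouette_like_score=sil, majority_labels=majority)
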