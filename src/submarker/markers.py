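"""Subspecies marker selection and cross-species specificity filtering.

A gene family is a candidate marker for a clade when it is present in at
least 90% of that clade's reference genomes and in not a single genome
of the sister clade.  Candidates are then screened against a decoy
collection of off-target-species genes: any candidate whose best local
alignment to a decoy exceeds 90% identity over more than 50% of the
candidate's length is discarded as non-specific (the desk-scale
equivalent of a BLAST search against a comprehensive nucleotide
database).  Survivors become the marker database used for
quantification.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from . import _align
from .core import UNKNOWN_LABEL, Marker, MarkerDatabase, SubmarkerError
from .pangenome import PangenomeMatrix

logger = logging.getLogger(__name__)

__all__ = ["CandidateMarker", "SpecificityVerdict", "min_presence_count",
           "select_candidates", "filter_specificity", "build_marker_db"]


@dataclass(frozen=True)
class CandidateMarker:
    cluster_id: str
    clade: str
    presence_fraction_target: float
    presence_count_offtarget: int
    sequence: str


@dataclass(frozen=True)
class SpecificityVerdict:
    marker_id: str
    best_hit: Optional[tuple[str, float, float]]  # (decoy_id, identity, query_coverage)
    passed: bool


def min_presence_count(n_genomes: int, presence_threshold: float = 0.90) -> int:
    """Minimum qualifying presence count under the >=threshold rule:
    ``ceil(threshold * n)`` — 13 for 14 genomes at 90%."""
    if not (0.0 < presence_threshold <= 1.0):
        raise ValueError(f"presence_threshold must be in (0, 1], got {presence_threshold}")
    return math.ceil(presence_threshold * n_genomes)


def select_candidates(
    matrix: PangenomeMatrix,
    presence_threshold: float = 0.90,
    excluded_genomes: Iterable[str] = (),
) -> list[CandidateMarker]:
    """Apply the presence rule per gene family.

    A family is a clade-A candidate iff it is present in at least
    ``ceil(presence_threshold * n_A)`` clade-A genomes and in zero
    clade-B genomes (and symmetrically).  Genomes labeled unknown and
    genomes in ``excluded_genomes`` are ignored entirely.
    """
    excluded = set(excluded_genomes)
    by_clade: dict[str, list[int]] = {}
    for j, g in enumerate(matrix.genomes):
        lab = matrix.label_of(g)
        if g in excluded or lab == UNKNOWN_LABEL:
            continue
        by_clade.setdefault(lab, []).append(j)
    if len(by_clade) != 2:
        raise ValueError(
            f"expected exactly 2 labeled subspecies after exclusions, got {sorted(by_clade)}"
        )
    (clade_x, cols_x), (clade_y, cols_y) = sorted(by_clade.items())
    if not cols_x or not cols_y:
        raise ValueError("each subspecies needs >=1 genome after exclusions")

    need = {clade_x: min_presence_count(len(cols_x), presence_threshold),
            clade_y: min_presence_count(len(cols_y), presence_threshold)}

    out: list[CandidateMarker] = []
    for (cid, seq), row in zip(matrix.clusters, matrix.presence):
        nx = int(row[cols_x].sum())
        ny = int(row[cols_y].sum())
        if nx >= need[clade_x] and ny == 0:
            out.append(CandidateMarker(cid, clade_x, nx / len(cols_x), ny, seq))
        elif ny >= need[clade_y] and nx == 0:
            out.append(CandidateMarker(cid, clade_y, ny / len(cols_y), nx, seq))
    return out


def filter_specificity(
    candidates: Sequence[CandidateMarker],
    decoy_genes: Sequence[tuple[str, str]],
    identity_cutoff: float = 0.90,
    coverage_cutoff: float = 0.50,
    k: int = 15,
    scoring: Optional[dict] = None,
) -> tuple[list[CandidateMarker], list[SpecificityVerdict]]:
    """Screen candidates against a decoy gene collection.

    Decoys sharing a ``k``-mer with a candidate are aligned locally
    (match +1, mismatch -1, gap open -2, extend -1 by default); the
    candidate is removed iff some hit has identity strictly above
    ``identity_cutoff`` AND covers strictly more than ``coverage_cutoff``
    of the candidate's length.  Identity is identities / alignment
    columns and coverage is the aligned query span / candidate length
    (BLAST's pident / qcovs semantics).  Candidates shorter than ``k``
    are aligned against every decoy by full dynamic programming rather
    than skipped.
    """
    if not decoy_genes:
        raise ValueError("decoy gene set is empty")
    index = _align.KmerIndex(k=k, stride=1)
    for did, dseq in decoy_genes:
        index.add(did, dseq)

    kept: list[CandidateMarker] = []
    verdicts: list[SpecificityVerdict] = []
    for cand in candidates:
        codes = _align.encode(cand.sequence)
        if len(cand.sequence) >= k:
            cand_refs = index.seed_refs(codes)
            targets = [decoy_genes[i] for i in cand_refs]
        else:
            targets = list(decoy_genes)

        best_any: Optional[_align.LocalHit] = None
        best_failing: Optional[_align.LocalHit] = None
        for tgt in targets:
            hit = _align.best_local_alignment(cand.sequence, [tgt], scoring=scoring)
            if hit is None:
                continue
            if best_any is None or hit.score > best_any.score:
                best_any = hit
            if hit.identity > identity_cutoff and hit.query_coverage > coverage_cutoff:
                if best_failing is None or hit.score > best_failing.score:
                    best_failing = hit

        if best_failing is not None:
            verdicts.append(SpecificityVerdict(
                cand.cluster_id,
                (best_failing.target_id, best_failing.identity, best_failing.query_coverage),
                passed=False,
            ))
            logger.info(
                "specificity: removing %s (best decoy hit %s, identity=%.3f, coverage=%.3f)",
                cand.cluster_id, best_failing.target_id,
                best_failing.identity, best_failing.query_coverage,
            )
        else:
            bh = (best_any.target_id, best_any.identity, best_any.query_coverage) \
                if best_any is not None else None
            verdicts.append(SpecificityVerdict(cand.cluster_id, bh, passed=True))
            kept.append(cand)
    return kept, verdicts


def build_marker_db(
    markers: Sequence[CandidateMarker],
    verdicts: Optional[Sequence[SpecificityVerdict]] = None,
) -> MarkerDatabase:
    """Assemble the final database with deterministic marker ids:
    ``<clade>_<index>`` with the index zero-padded and assigned by
    descending length (ties by sequence) within each clade."""
    by_clade: dict[str, list[CandidateMarker]] = {}
    for c in markers:
        by_clade.setdefault(c.clade, []).append(c)
    if len(by_clade) < 2:
        missing = "both clades" if not by_clade else "one clade"
        warnings.warn(
            f"marker database covers {len(by_clade)} clade(s); {missing} "
            "unrepresented and unquantifiable", stacklevel=2)

    seq_to_clade: dict[str, str] = {}
    for c in markers:
        prev = seq_to_clade.get(c.sequence)
        if prev is not None and prev != c.clade:
            raise SubmarkerError(
                f"identical marker sequence assigned to clades {prev!r} and "
                f"{c.clade!r} (cluster {c.cluster_id}): specificity violated"
            )
        seq_to_clade[c.sequence] = c.clade

    vmap = {v.marker_id: v for v in verdicts or []}
    out: list[Marker] = []
    for clade in sorted(by_clade):
        ranked = sorted(by_clade[clade], key=lambda c: (-len(c.sequence), c.sequence))
        pad = max(4, len(str(len(ranked))))
        for i, c in enumerate(ranked):
            v = vmap.get(c.cluster_id)
            if v is None or v.best_hit is None:
                verdict = "pass"
            else:
                did, ident, cov = v.best_hit
                status = "pass" if v.passed else "fail"
                verdict = f"{status}:best={did},id={ident:.4f},cov={cov:.4f}"
            out.append(Marker(
                marker_id=f"{clade}_{i:0{pad}d}",
                clade=clade,
                sequence=c.sequence,
                source_cluster=c.cluster_id,
                presence_fraction=c.presence_fraction_target,
                decoy_verdict=verdict,
            ))
    return MarkerDatabase(markers=out)
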