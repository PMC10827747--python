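"""Strain-level analysis on marker genes.

For each sample a consensus sequence is called over every marker by
majority pileup of the mapped reads; samples with enough well-covered
markers are placed in a concatenated alignment, pairwise SNP distances
are computed over positions called in both samples, and a
neighbor-joining tree summarises strain relatedness.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _align
from .core import MarkerDatabase, MarkerHit, ReadSet, SubmarkerError
from .quantify import MappingResult

logger = logging.getLogger(__name__)

__all__ = ["StrainAlignment", "DistanceMatrix", "build_consensus",
           "attach_reads", "pairwise_distances", "nj_tree"]

_N = ord("N")
_GAP = ord("-")


@dataclass
class StrainAlignment:
    """Per-sample consensus over the concatenated marker genes.

    ``consensus`` is a (sample x position) byte matrix over
    ``{A,C,G,T,N,-}``; coordinates follow the database marker order
    (``marker_offsets`` gives each marker's start).  ``markers_used``
    maps sample -> markers with a retained consensus.
    """

    samples: list[str]
    marker_ids: list[str]
    marker_offsets: np.ndarray
    consensus: np.ndarray
    depth: np.ndarray
    markers_used: dict[str, list[str]] = field(default_factory=dict)

    def row(self, sample_id: str) -> str:
        return self.consensus[self.samples.index(sample_id)].tobytes().decode("ascii")


@dataclass
class DistanceMatrix:
    """Symmetric normalized SNP distances; NaN marks pairs with no
    comparable sites."""

    ids: list[str]
    values: np.ndarray

    def __getitem__(self, pair) -> float:
        i, j = pair
        return float(self.values[self.ids.index(i), self.ids.index(j)])

    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def build_consensus(
    mapped_samples: Sequence[MappingResult],
    db: MarkerDatabase,
    min_depth: int = 3,
    majority: float = 0.8,
    min_marker_count: Optional[int] = None,
    min_callable_fraction: float = 0.5,
) -> StrainAlignment:
    """Majority-pileup consensus per sample over all markers.

    A position is called when depth >= ``min_depth`` and the top allele
    frequency >= ``majority``; otherwise N.  A marker is dropped for a
    sample (its stretch set to N) when fewer than
    ``min_callable_fraction`` of its positions are callable.  A sample
    is kept only if it retains at least ``min_marker_count`` markers —
    default 50, scaled down to half the database size when the database
    has fewer than 50 markers.

    Only unambiguously assigned hits contribute to pileups; the species
    pool carries no subspecies strain signal.
    """
    if min_marker_count is None:
        min_marker_count = 50 if len(db) >= 50 else max(1, len(db) // 2)

    marker_ids = [m.marker_id for m in db]
    midx = {m: i for i, m in enumerate(marker_ids)}
    lengths = np.array([m.length for m in db], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    width = int(offsets[-1])

    kept_rows: list[np.ndarray] = []
    kept_depth: list[np.ndarray] = []
    kept_samples: list[str] = []
    markers_used: dict[str, list[str]] = {}

    for mapping in mapped_samples:
        counts = np.zeros((4, width), dtype=np.int32)
        reads_by_id = getattr(mapping, "_read_lookup", None)
        if reads_by_id is None:
            raise ValueError(
                "MappingResult lacks read sequences; call attach_reads() "
                "or build it via map_reads_with_sequences"
            )
        for h in mapping.hits:
            seq = reads_by_id[h.read_id]
            seg = _align.encode(seq)[h.read_start:h.read_start + h.aligned_bases]
            start = offsets[midx[h.marker_id]] + h.marker_start
            ok = seg < 4
            np.add.at(counts, (seg[ok], np.arange(start, start + seg.size)[ok]), 1)

        depth = counts.sum(axis=0)
        top = counts.max(axis=0)
        call = (depth >= min_depth) & (depth > 0) & (top >= majority * depth)
        row = np.full(width, _N, dtype=np.uint8)
        allele = counts.argmax(axis=0)
        row[call] = _align._CODE_TO_BASE[allele[call]]

        used: list[str] = []
        for mid, mi in midx.items():
            lo, hi = int(offsets[mi]), int(offsets[mi + 1])
            frac = call[lo:hi].mean() if hi > lo else 0.0
            if frac < min_callable_fraction:
                row[lo:hi] = _N
            else:
                used.append(mid)
        if len(used) >= min_marker_count:
            kept_samples.append(mapping.sample_id)
            kept_rows.append(row)
            kept_depth.append(depth)
            markers_used[mapping.sample_id] = used

    if not kept_samples:
        warnings.warn("no sample passed the marker-count rule; alignment is empty",
                      stacklevel=2)
    consensus = np.vstack(kept_rows) if kept_rows else np.empty((0, width), dtype=np.uint8)
    depth_mat = np.vstack(kept_depth) if kept_depth else np.empty((0, width), dtype=np.int32)
    return StrainAlignment(samples=kept_samples, marker_ids=marker_ids,
                           marker_offsets=offsets, consensus=consensus,
                           depth=depth_mat, markers_used=markers_used)


def attach_reads(mapping: MappingResult, reads: ReadSet) -> MappingResult:
    """Store read sequences on a mapping result so consensus building
    can recover the aligned bases."""
    mapping._read_lookup = {r.read_id: r.sequence for r in reads}  # type: ignore[attr-defined]
    return mapping


def pairwise_distances(aln: StrainAlignment) -> DistanceMatrix:
    """Normalized SNP distance: mismatches / sites where both samples
    have a non-N, non-gap call.  Pairs with zero comparable sites get
    NaN (missing), never 0."""
    if len(aln.samples) < 2:
        raise ValueError("need at least 2 samples")
    C = aln.consensus
    valid = (C != _N) & (C != _GAP)
    n = len(aln.samples)
    out = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                out[i, j] = out[j, i] = np.nan
            else:
                d = int((C[i][both] != C[j][both]).sum()) / m
                out[i, j] = out[j, i] = d
    return DistanceMatrix(ids=list(aln.samples), values=out)


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically
    smallest pair of subtree names.  Negative branch lengths are clamped
    to zero with the deficit transferred to the sibling edge.  Returns
    an unrooted newick string (trifurcating root).
    """
    if np.isnan(dm.values).any():
        raise SubmarkerError(
            "distance matrix has missing entries; drop samples without "
            "comparable sites before building a tree"
        )
    n = len(dm.ids)
    if n < 3:
        raise ValueError("need at least 3 samples for a tree")

    D = dm.values.astype(float).copy()
    names = list(dm.ids)        # lexicographic key per active node
    newick = [f"{_escape(x)}" for x in dm.ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        pairs = [
            (min(names[active[a]], names[active[b]]),
             max(names[active[a]], names[active[b]]), a, b)
            for a, b in zip(*np.nonzero(np.isclose(Q, qmin, rtol=0, atol=1e-12)))
            if a < b
        ]
        _, _, a, b = min(pairs)
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)

        # distances from the new node to every other active node
        newD = np.zeros(D.shape[0])
        for c in active:
            if c in (i, j):
                continue
            newD[c] = 0.5 * (D[i, c] + D[j, c] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newD
        D[:-1, -1] = newD
        u = D.shape[0] - 1
        newick.append(f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g})")
        names.append(min(names[i], names[j]))
        active = [c for c in active if c not in (i, j)] + [u]

    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    li, lj, lk = (max(0.0, x) for x in (li, lj, lk))
    order = sorted(range(3), key=lambda t: names[active[t]])
    parts = [(newick[active[t]], (li, lj, lk)[t]) for t in order]
    inner = ",".join(f"{s}:{L:.10g}" for s, L in parts)
    return f"({inner});"


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += -li
        li = 0.0
    if lj < 0:
        li += -lj
        lj = 0.0
    return li, max(0.0, lj)


def _escape(name: str) -> str:
    if any(c in name for c in "(),:; \t"):
        return "'" + name.replace("'", "''") + "'"
    return name
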