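"""Read mapping against the marker database and clade abundance
estimation.

Mapping is ungapped and seed-based: reads sharing an exact k-mer with a
marker are placed on the implied diagonal and scored by per-base
identity over the overlap.  Each read is assigned to at most one marker
(best identity).  A read whose best hits to the two clades are
indistinguishable (identity difference < 0.01) carries species-level but
not subspecies-level information and is routed to a species pool; an
exact-identity tie between two distinct markers of the winning clade
makes the read ambiguous and it is discarded.

Abundances are depth-based: per-marker depth = aligned bases / marker
length, aggregated per clade with a truncated mean (robust to individual
outlier markers), and converted to percentages over the four reserved
entries {clade A, clade B, unclassified, other}, where "unclassified"
is species-level signal attributable to neither clade and "other" is
the unmapped read mass.  A clade is called detected when its relative
abundance reaches the detection floor (default 0.5%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _align
from .core import (OTHER, UNCLASSIFIED, AbundanceProfile, MarkerDatabase,
                   MarkerHit, ReadSet)

__all__ = ["MappingResult", "map_reads", "estimate_abundance", "is_detected",
           "truncated_mean"]


@dataclass
class MappingResult:
    """Outcome of mapping one sample against the marker database."""

    sample_id: str
    hits: list[MarkerHit] = field(default_factory=list)
    ambiguous: list[MarkerHit] = field(default_factory=list)  # species pool
    n_reads: int = 0
    n_discarded_ties: int = 0

    @property
    def n_mapped(self) -> int:
        return len(self.hits) + len(self.ambiguous)


class _MarkerRef:
    """Concatenated marker sequences + full k-mer table for seeding."""

    def __init__(self, db: MarkerDatabase, k: int):
        self.k = k
        self.marker_ids = [m.marker_id for m in db]
        self.clade_names = db.clades
        clade_idx = {c: i for i, c in enumerate(self.clade_names)}
        self.marker_clade = np.array([clade_idx[m.clade] for m in db], dtype=np.int64)
        codes = [_align.encode(m.sequence) for m in db]
        self.lengths = np.array([c.shape[0] for c in codes], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(self.lengths)])
        self.concat = np.concatenate(codes) if codes else np.empty(0, dtype=np.uint8)

        pos_all, val_all = [], []
        for mi, c in enumerate(codes):
            pos, vals = _align.kmer_codes(c, k)
            pos_all.append(pos + self.offsets[mi])
            val_all.append(vals)
        vals = np.concatenate(val_all) if val_all else np.empty(0, dtype=np.int64)
        pos = np.concatenate(pos_all) if pos_all else np.empty(0, dtype=np.int64)
        order = np.argsort(vals, kind="stable")
        self.kmer_vals = vals[order]
        self.kmer_pos = pos[order]

    def marker_of(self, gpos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.offsets, gpos, side="right") - 1


def _reads_matrix(reads: Sequence, length: int) -> np.ndarray:
    joined = "".join(r.sequence for r in reads)
    return _align.encode(joined).reshape(len(reads), length)


def map_reads(
    reads: ReadSet,
    db: MarkerDatabase,
    min_identity: float = 0.95,
    min_aligned: int = 40,
    k: int = 15,
    ambiguity_delta: float = 0.01,
    seed_stride: int = 11,
) -> MappingResult:
    """Place each read on its best marker.

    Reads are processed in batches of equal length (each batch fully
    vectorized).  Reads shorter than ``k`` cannot seed and are counted
    unmapped.
    """
    if len(db) == 0:
        raise ValueError("marker database is empty")
    ref = _MarkerRef(db, k)
    result = MappingResult(sample_id=reads.sample_id, n_reads=len(reads))

    by_len: dict[int, list[int]] = {}
    for i, r in enumerate(reads):
        by_len.setdefault(len(r.sequence), []).append(i)

    for L, idxs in sorted(by_len.items()):
        if L < k:
            continue
        batch = [reads.reads[i] for i in idxs]
        mat = _reads_matrix(batch, L)
        _map_batch(mat, batch, ref, min_identity, min_aligned,
                   ambiguity_delta, seed_stride, result)
    return result


def _map_batch(mat, batch, ref: _MarkerRef, min_identity, min_aligned,
               ambiguity_delta, seed_stride, result: MappingResult) -> None:
    n, L = mat.shape
    k = ref.k
    sample_pos = np.arange(0, L - k + 1, max(1, seed_stride))

    # --- seed: read k-mers at sampled offsets -> (read, diagonal) votes
    read_idx_list, diag_list = [], []
    weights = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    for p in sample_pos.tolist():
        win = mat[:, p:p + k].astype(np.int64)
        ok = (mat[:, p:p + k] < 4).all(axis=1)
        vals = win @ weights
        lo = np.searchsorted(ref.kmer_vals, vals, side="left")
        hi = np.searchsorted(ref.kmer_vals, vals, side="right")
        cnt = np.where(ok, hi - lo, 0)
        have = np.nonzero(cnt)[0]
        if have.size == 0:
            continue
        rep = cnt[have]
        flat = np.concatenate([np.arange(lo[i], hi[i]) for i in have.tolist()])
        read_idx_list.append(np.repeat(have, rep))
        diag_list.append(ref.kmer_pos[flat] - p)

    if not read_idx_list:
        return
    read_idx = np.concatenate(read_idx_list)
    diag = np.concatenate(diag_list)

    # unique candidate (read, diagonal) pairs
    key = read_idx * (int(ref.offsets[-1]) + 2 * L) + (diag + L)
    _, uidx = np.unique(key, return_index=True)
    read_idx, diag = read_idx[uidx], diag[uidx]

    # --- score: per-base identity over the read/marker overlap
    mi = ref.marker_of(np.maximum(diag, 0))
    m_lo = ref.offsets[mi]
    m_hi = ref.offsets[mi + 1]
    a0 = np.maximum(diag, m_lo)
    a1 = np.minimum(diag + L, m_hi)
    span = (a1 - a0).astype(np.int64)
    valid = span >= max(min_aligned, 1)
    read_idx, diag, mi, a0, a1, span = (x[valid] for x in (read_idx, diag, mi, a0, a1, span))
    if read_idx.size == 0:
        return

    ident = np.empty(read_idx.size, dtype=np.float64)
    full = span == L
    if full.any():
        rows = read_idx[full]
        starts = a0[full]
        gathered = ref.concat[starts[:, None] + np.arange(L)]
        ident[full] = (gathered == mat[rows]).mean(axis=1)
    part = np.nonzero(~full)[0]
    for j in part.tolist():
        rs = int(a0[j] - diag[j])
        seg = mat[read_idx[j], rs:rs + span[j]]
        ident[j] = float((ref.concat[a0[j]:a1[j]] == seg).mean())

    ok = ident >= min_identity
    read_idx, diag, mi, a0, span, ident = (x[ok] for x in (read_idx, diag, mi, a0, span, ident))
    if read_idx.size == 0:
        return
    clade = ref.marker_clade[mi]

    # --- reduce: best candidate per (read, clade); detect same-clade ties
    order = np.lexsort((diag, mi, -ident, clade, read_idx))
    r_s, c_s = read_idx[order], clade[order]
    i_s, m_s = ident[order], mi[order]
    group = r_s * (len(ref.clade_names) + 1) + c_s
    first = np.ones(order.size, dtype=bool)
    first[1:] = group[1:] != group[:-1]
    # exact-identity tie with a different marker directly after a group head
    tie = np.zeros(order.size, dtype=bool)
    if order.size > 1:
        tie[:-1] = (first[:-1] & ~first[1:]
                    & (i_s[:-1] == i_s[1:]) & (m_s[:-1] != m_s[1:]))

    n_clades = len(ref.clade_names)
    best_ident = np.full((n, n_clades), -1.0)
    best_row = np.full((n, n_clades), -1, dtype=np.int64)
    tied = np.zeros((n, n_clades), dtype=bool)
    heads = np.nonzero(first)[0]
    best_ident[r_s[heads], c_s[heads]] = i_s[heads]
    best_row[r_s[heads], c_s[heads]] = order[heads]
    th = heads[tie[heads]]
    tied[r_s[th], c_s[th]] = True

    has = best_ident >= 0
    any_has = has.any(axis=1)
    winner = np.argmax(best_ident, axis=1)
    if n_clades >= 2:
        part = np.sort(best_ident, axis=1)
        both = has.sum(axis=1) >= 2
        ambig = any_has & both & (part[:, -1] - part[:, -2] < ambiguity_delta)
    else:
        ambig = np.zeros(n, dtype=bool)
    assign = any_has & ~ambig
    winner_tied = tied[np.arange(n), winner]
    result.n_discarded_ties += int((assign & winner_tied).sum())
    assign &= ~winner_tied

    for r in np.nonzero(ambig)[0].tolist():
        row = best_row[r, winner[r]]
        result.ambiguous.append(_make_hit(batch, ref, row, read_idx, diag, mi,
                                          a0, span, ident))
    for r in np.nonzero(assign)[0].tolist():
        row = best_row[r, winner[r]]
        result.hits.append(_make_hit(batch, ref, row, read_idx, diag, mi,
                                     a0, span, ident))


def _make_hit(batch, ref, row, read_idx, diag, mi, a0, span, ident):
    j = int(row)
    m = int(mi[j])
    return MarkerHit(
        read_id=batch[int(read_idx[j])].read_id,
        marker_id=ref.marker_ids[m],
        identity=float(ident[j]),
        aligned_bases=int(span[j]),
        marker_start=int(a0[j] - ref.offsets[m]),
        read_start=int(a0[j] - diag[j]),
    )


def truncated_mean(values: Sequence[float], trim: float = 0.10) -> float:
    """Robust mean of per-marker depths: with >=10 values drop the top
    and bottom ``trim`` fraction (at least one each); with 3-9 values
    drop the single min and max; with fewer, plain mean."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        return 0.0
    if n < 3:
        return float(v.mean())
    cut = max(1, int(trim * n)) if n >= 10 else 1
    return float(v[cut:n - cut].mean())


def estimate_abundance(
    mapping: MappingResult,
    db: MarkerDatabase,
    read_count_total: Optional[int] = None,
    detection_threshold: float = 0.5,
    trim: float = 0.10,
) -> AbundanceProfile:
    """Convert marker hits into a relative-abundance profile.

    Per-marker depth is aligned bases / marker length.  Each clade's
    score is the truncated mean of its markers' depths.  The species
    score is the truncated mean over *all* markers of assigned depth
    plus the species pool spread uniformly over the database;
    ``unclassified = max(0, species - sum(clades))`` therefore captures
    species-level mass not attributable to either clade.  Scores are
    scaled by the mapped read fraction and normalized so the profile
    sums to 100, with "other" carrying the unmapped remainder.
    """
    total = read_count_total if read_count_total is not None else mapping.n_reads
    marker_ids = [m.marker_id for m in db]
    midx = {m: i for i, m in enumerate(marker_ids)}
    lengths = np.array([m.length for m in db], dtype=float)

    assigned = np.zeros(len(db))
    for h in mapping.hits:
        assigned[midx[h.marker_id]] += h.aligned_bases
    ambig_bases = float(sum(h.aligned_bases for h in mapping.ambiguous))

    depths = assigned / lengths
    clade_scores: dict[str, float] = {}
    for clade in db.clades:
        rows = [midx[m.marker_id] for m in db.by_clade(clade)]
        clade_scores[clade] = truncated_mean(depths[rows], trim) if rows else 0.0

    species_depths = depths + ambig_bases / lengths.sum()
    species_score = truncated_mean(species_depths, trim)
    unclassified = max(0.0, species_score - sum(clade_scores.values()))

    scores = dict(clade_scores)
    scores[UNCLASSIFIED] = unclassified
    s_tot = sum(scores.values())
    mapped_frac = mapping.n_mapped / total if total > 0 else 0.0

    entries = {c: 0.0 for c in scores}
    if s_tot > 0:
        for c in scores:
            entries[c] = 100.0 * mapped_frac * scores[c] / s_tot
    entries[OTHER] = max(0.0, 100.0 - sum(entries.values()))

    return AbundanceProfile(sample_id=mapping.sample_id, entries=entries,
                            detection_threshold=detection_threshold)


def is_detected(profile: AbundanceProfile, clade: str, threshold: float = 0.5) -> bool:
    """Detection rule: a clade counts as present when its relative
    abundance is at or above the floor (default 0.5%)."""
    return profile[clade] >= threshold
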