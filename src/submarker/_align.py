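"""Shared sequence-comparison primitives: 2-bit k-mer encoding, k-mer
seed indexes, edit-distance identity (edlib) and scored local alignment
(Bio.Align).  No domain logic lives here."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import edlib
import numpy as np
from Bio import Align

_BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_CODE[_b] = _i
_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)

#: code used for N / anything non-ACGT after encoding
AMBIG = 255


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A=0 C=1 G=2 T=3, else 255)."""
    return _BASE_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    out = np.full(codes.shape, ord("N"), dtype=np.uint8)
    ok = codes < 4
    out[ok] = _CODE_TO_BASE[codes[ok]]
    return out.tobytes().decode("ascii")


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All k-mers of an encoded sequence as 2k-bit integers.

    Returns ``(positions, kmer_ints)``; windows containing an ambiguous
    base are dropped.  Requires ``k <= 31``.
    """
    n = codes.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    valid = codes < 4
    win = np.lib.stride_tricks.sliding_window_view(codes.astype(np.int64), k)
    weights = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    vals = win @ weights
    ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    pos = np.nonzero(ok)[0]
    return pos, vals[ok]


class KmerIndex:
    """Exact k-mer lookup over a collection of reference sequences.

    ``stride`` subsamples reference k-mer start positions (1 = every
    position); queries always enumerate their own k-mers densely enough
    to hit a strided reference k-mer of any co-linear match.
    """

    def __init__(self, k: int = 15, stride: int = 1):
        self.k = k
        self.stride = stride
        self._table: dict[int, list[tuple[int, int]]] = {}
        self.names: list[str] = []
        self.seqs: list[np.ndarray] = []

    def add(self, name: str, seq: str | np.ndarray) -> int:
        codes = seq if isinstance(seq, np.ndarray) else encode(seq)
        idx = len(self.names)
        self.names.append(name)
        self.seqs.append(codes)
        pos, vals = kmer_codes(codes, self.k)
        if self.stride > 1:
            keep = (pos % self.stride) == 0
            pos, vals = pos[keep], vals[keep]
        tab = self._table
        for p, v in zip(pos.tolist(), vals.tolist()):
            tab.setdefault(v, []).append((idx, p))
        return idx

    def __len__(self) -> int:
        return len(self.names)

    def lookup(self, kmer: int) -> list[tuple[int, int]]:
        return self._table.get(kmer, [])

    def seed_refs(self, codes: np.ndarray, max_hits_per_kmer: int = 64) -> list[int]:
        """Reference indexes sharing >=1 k-mer with the query, in
        ascending reference order (k-mers enumerated densely)."""
        _, vals = kmer_codes(codes, self.k)
        hits: set[int] = set()
        for v in vals.tolist():
            entries = self._table.get(v)
            if entries:
                for ref, _ in entries[:max_hits_per_kmer]:
                    hits.add(ref)
        return sorted(hits)


def identity_infix(query: str | np.ndarray, target: str | np.ndarray) -> float:
    """Identity of ``query`` aligned end-to-end inside ``target``
    (edlib infix mode): 1 - edit_distance / len(query).

    ``query`` must be the shorter sequence.  Clamped at 0.
    """
    q = decode(query) if isinstance(query, np.ndarray) else query
    t = decode(target) if isinstance(target, np.ndarray) else target
    d = edlib.align(q, t, mode="HW", task="distance")["editDistance"]
    return max(0.0, 1.0 - d / len(q))


@dataclass(frozen=True)
class LocalHit:
    """Best scored local alignment of a query against one target."""

    target_id: str
    score: float
    identity: float          # identities / aligned columns (gaps included)
    query_coverage: float    # aligned query span / query length
    n_columns: int


_DEFAULT_SCORING = dict(match_score=1, mismatch_score=-1,
                        open_gap_score=-2, extend_gap_score=-1)


def best_local_alignment(
    query: str,
    targets: Sequence[tuple[str, str]],
    scoring: Optional[dict] = None,
) -> Optional[LocalHit]:
    """Highest-scoring local alignment of ``query`` against each of
    ``targets`` (id, sequence); returns the best hit or None for empty
    targets / no positive-scoring alignment."""
    if not targets:
        return None
    aligner = Align.PairwiseAligner(mode="local", **(scoring or _DEFAULT_SCORING))
    best: Optional[LocalHit] = None
    for tid, tseq in targets:
        try:
            aln = aligner.align(query, tseq)[0]
        except (IndexError, ValueError):
            continue
        if aln.score <= 0:
            continue
        counts = aln.counts()
        ncols = counts.identities + counts.mismatches + counts.internal_gaps
        if ncols == 0:
            continue
        ident = counts.identities / ncols
        qblocks = aln.aligned[0]
        qspan = int(qblocks[-1][1] - qblocks[0][0]) if len(qblocks) else 0
        cov = qspan / len(query)
        hit = LocalHit(tid, float(aln.score), ident, cov, int(ncols))
        if best is None or hit.score > best.score:
            best = hit
    return best
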