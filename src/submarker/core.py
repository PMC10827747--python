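"""Core domain types shared across the toolkit.

The pipeline works on two sister subspecies of one bacterial species
(the motivating case is *Bifidobacterium longum* subsp. *infantis* vs
subsp. *longum*).  Throughout the package the two clades are referred to
by arbitrary string names carried on the data objects; nothing is
hard-coded to a particular organism.

All sequence coordinates are 0-based, half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "UNKNOWN_LABEL",
    "UNCLASSIFIED",
    "OTHER",
    "SubmarkerError",
    "DuplicateIdError",
    "FormatError",
    "GenomeRecord",
    "Read",
    "ReadSet",
    "Marker",
    "MarkerDatabase",
    "MarkerHit",
    "AbundanceProfile",
]

#: label for genomes without a subspecies assignment
UNKNOWN_LABEL = "unknown"
#: reserved profile entry: species-level signal attributable to neither clade
UNCLASSIFIED = "unclassified"
#: reserved profile entry: read mass not mapping to the marker database
OTHER = "other"

_VALID_BASES = frozenset("ACGTN")


class SubmarkerError(Exception):
    """Base class for errors raised by this package."""


class DuplicateIdError(SubmarkerError):
    """A primary identifier (genome, gene, marker, read) occurred twice."""


class FormatError(SubmarkerError):
    """An on-disk representation could not be parsed."""


def _check_dna(seq: str, what: str) -> None:
    if not seq:
        raise ValueError(f"{what}: empty sequence")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"{what}: invalid characters {sorted(bad)}")


@dataclass
class GenomeRecord:
    """One annotated reference genome: its identifier, subspecies label
    and the gene sequences called on it.

    ``label`` is either one of the two clade names in play or
    :data:`UNKNOWN_LABEL`.
    """

    genome_id: str
    label: str
    genes: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gene_id, seq in self.genes:
            if gene_id in seen:
                raise DuplicateIdError(
                    f"genome {self.genome_id}: duplicate gene id {gene_id!r}"
                )
            seen.add(gene_id)
            _check_dna(seq, f"genome {self.genome_id}, gene {gene_id}")

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.genes]

    def total_length(self) -> int:
        return sum(len(s) for _, s in self.genes)


@dataclass(frozen=True)
class Read:
    read_id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.read_id}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass
class ReadSet:
    """A set of shotgun reads from one metagenome sample."""

    sample_id: str
    reads: list[Read] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)


@dataclass(frozen=True)
class Marker:
    """A final subspecies marker gene.

    ``presence_fraction`` is the fraction of the source clade's reference
    genomes carrying the gene cluster; ``decoy_verdict`` summarises the
    cross-species specificity check (e.g. ``"pass"`` or
    ``"pass:best=<id>,id=0.72,cov=0.31"``).
    """

    marker_id: str
    clade: str
    sequence: str
    source_cluster: str = ""
    presence_fraction: float = float("nan")
    decoy_verdict: str = "pass"

    def __post_init__(self) -> None:
        _check_dna(self.sequence, f"marker {self.marker_id}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __eq__(self, other) -> bool:  # NaN-tolerant equality for round trips
        if not isinstance(other, Marker):
            return NotImplemented
        pf_eq = (
            self.presence_fraction == other.presence_fraction
            or (math.isnan(self.presence_fraction) and math.isnan(other.presence_fraction))
        )
        return (
            self.marker_id == other.marker_id
            and self.clade == other.clade
            and self.sequence == other.sequence
            and self.source_cluster == other.source_cluster
            and pf_eq
            and self.decoy_verdict == other.decoy_verdict
        )

    __hash__ = None  # type: ignore[assignment]


@dataclass
class MarkerDatabase:
    """The final marker set used for quantification.

    Exactly two clades are expected in normal operation; a single-clade
    database is legal (that clade alone is quantifiable) and produces a
    warning at build time.
    """

    markers: list[Marker] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.markers:
            if m.marker_id in seen:
                raise DuplicateIdError(f"duplicate marker id {m.marker_id!r}")
            seen.add(m.marker_id)

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MarkerDatabase):
            return NotImplemented
        return self.markers == other.markers

    @property
    def clades(self) -> list[str]:
        out: list[str] = []
        for m in self.markers:
            if m.clade not in out:
                out.append(m.clade)
        return out

    def by_clade(self, clade: str) -> list[Marker]:
        return [m for m in self.markers if m.clade == clade]

    def get(self, marker_id: str) -> Marker:
        for m in self.markers:
            if m.marker_id == marker_id:
                return m
        raise KeyError(marker_id)

    def total_length(self) -> int:
        return sum(m.length for m in self.markers)


@dataclass(frozen=True)
class MarkerHit:
    """Best placement of one read on one marker.

    The alignment is ungapped (substitution-only mapping): the read
    segment ``[read_start, read_start + aligned_bases)`` lies on the
    marker at ``[marker_start, marker_start + aligned_bases)``.
    """

    read_id: str
    marker_id: str
    identity: float
    aligned_bases: int
    marker_start: int = 0
    read_start: int = 0


@dataclass
class AbundanceProfile:
    """Per-clade relative abundances (percent) for one sample.

    Entries always include the two clade names plus the reserved keys
    :data:`UNCLASSIFIED` (species-level signal attributable to neither
    clade) and :data:`OTHER` (read mass that did not map to the marker
    database).  Entries sum to 100.
    """

    sample_id: str
    entries: dict[str, float] = field(default_factory=dict)
    detection_threshold: float = 0.5

    def __getitem__(self, clade: str) -> float:
        return self.entries[clade]

    @property
    def clade_names(self) -> list[str]:
        return [c for c in self.entries if c not in (UNCLASSIFIED, OTHER)]

    def total(self) -> float:
        return float(sum(self.entries.values()))

    def subspecies_shares(self) -> dict[str, float]:
        """Composition within the target species: entries other than
        :data:`OTHER`, renormalized to sum to 1.  All-zero species signal
        yields zeros."""
        keys = [c for c in self.entries if c != OTHER]
        tot = sum(self.entries[c] for c in keys)
        if tot <= 0:
            return {c: 0.0 for c in keys}
        return {c: self.entries[c] / tot for c in keys}
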