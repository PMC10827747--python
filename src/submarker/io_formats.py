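"""Readers and writers for every on-disk representation.

Formats: multi-FASTA of gene sequences per genome plus a two-column
labels TSV; marker databases as FASTA with structured headers
(``>marker_id|clade=<name>|len=<int>``) and a provenance sidecar TSV;
reads as FASTA/FASTQ (gzip transparent); abundance profiles and Ct
tables as TSV; trees as newick.  FASTA parsing tolerates wrapped lines
and CRLF; sequences are upper-cased, ``N`` is kept and any other IUPAC
ambiguity code is mapped to ``N`` with a logged count.  No science in
this module.
"""

from __future__ import annotations

import csv
import gzip
import logging
import math
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO

from Bio import SeqIO

from .concordance import CtTable
from .core import (OTHER, UNCLASSIFIED, UNKNOWN_LABEL, AbundanceProfile,
                   DuplicateIdError, FormatError, GenomeRecord, Marker,
                   MarkerDatabase, Read, ReadSet)

logger = logging.getLogger(__name__)

__all__ = [
    "read_genome_dir", "write_genome_dir",
    "read_marker_db", "write_marker_db",
    "read_reads", "write_reads",
    "read_abundance", "write_abundance",
    "read_ct_table", "write_ct_table",
    "read_matrix", "write_matrix",
    "read_tree", "write_tree",
]

_FASTA_EXTS = (".fasta", ".fa", ".fna")
_ALLOWED = set("ACGTN")


def _open_text(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _clean_seq(raw: str, context: str) -> str:
    seq = raw.upper().replace("\r", "").replace("\n", "")
    bad = sum(1 for c in seq if c not in _ALLOWED)
    if bad:
        logger.info("%s: %d ambiguity characters mapped to N", context, bad)
        seq = "".join(c if c in _ALLOWED else "N" for c in seq)
    return seq


def _genome_stem(path: Path) -> str:
    name = path.name
    if name.endswith(".gz"):
        name = name[:-3]
    for ext in _FASTA_EXTS:
        if name.endswith(ext):
            return name[: -len(ext)]
    return Path(name).stem


def read_genome_dir(path: str | Path, labels_path: Optional[str | Path] = None,
                    ) -> list[GenomeRecord]:
    """Load every gene FASTA in a directory as one genome each.

    The file stem is the genome id; the labels file (two-column TSV:
    genome_id, label) assigns subspecies — genomes absent from it get
    :data:`~submarker.core.UNKNOWN_LABEL`, and a label naming a missing
    genome is a warning, never a fabricated record.
    """
    path = Path(path)
    files = sorted(
        p for p in path.iterdir()
        if p.is_file() and _genome_stem(p) != p.name  # recognised extension
        and any(str(p).endswith(e) or str(p).endswith(e + ".gz") for e in _FASTA_EXTS)
    )
    if not files:
        raise FileNotFoundError(f"no FASTA files in {path}")

    labels: dict[str, str] = {}
    if labels_path is not None:
        with _open_text(Path(labels_path)) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\r\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise FormatError(f"{labels_path}:{ln}: expected 2 columns")
                labels[parts[0]] = parts[1]

    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for fp in files:
        gid = _genome_stem(fp)
        if gid in seen:
            raise DuplicateIdError(f"duplicate genome_id {gid!r} in {path}")
        seen.add(gid)
        genes: list[tuple[str, str]] = []
        with _open_text(fp) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                genes.append((rec.id, _clean_seq(str(rec.seq), f"{fp.name}:{rec.id}")))
        if not genes:
            raise FormatError(f"empty FASTA: {fp}")
        records.append(GenomeRecord(genome_id=gid,
                                    label=labels.get(gid, UNKNOWN_LABEL),
                                    genes=genes))

    missing = set(labels) - seen
    for gid in sorted(missing):
        warnings.warn(f"labels file names genome {gid!r} with no FASTA; ignored",
                      stacklevel=2)
    return records


def write_genome_dir(genomes: Sequence[GenomeRecord], path: str | Path,
                     labels_name: str = "labels.tsv") -> Path:
    """Write one FASTA per genome plus the labels TSV; returns the
    labels path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for g in genomes:
        with open(path / f"{g.genome_id}.fasta", "w") as fh:
            for gene_id, seq in g.genes:
                fh.write(f">{gene_id}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
    labels_path = path / labels_name
    with open(labels_path, "w") as fh:
        for g in genomes:
            fh.write(f"{g.genome_id}\t{g.label}\n")
    return labels_path


def write_marker_db(db: MarkerDatabase, path: str | Path) -> Path:
    """Marker FASTA with structured headers plus a ``.tsv`` provenance
    sidecar (same path with extension swapped)."""
    if len(db) == 0:
        raise ValueError("marker database is empty")
    path = Path(path)
    with open(path, "w") as fh:
        for m in db:
            fh.write(f">{m.marker_id}|clade={m.clade}|len={m.length}\n")
            for i in range(0, len(m.sequence), 80):
                fh.write(m.sequence[i:i + 80] + "\n")
    side = path.with_suffix(".tsv")
    with open(side, "w") as fh:
        fh.write("marker_id\tsource_cluster\tpresence_fraction\tdecoy_verdict\n")
        for m in db:
            pf = "" if math.isnan(m.presence_fraction) else repr(m.presence_fraction)
            fh.write(f"{m.marker_id}\t{m.source_cluster}\t{pf}\t{m.decoy_verdict}\n")
    return path


def read_marker_db(path: str | Path) -> MarkerDatabase:
    path = Path(path)
    headers: dict[str, tuple[str, int]] = {}
    order: list[str] = []
    seqs: dict[str, str] = {}

    with _open_text(path) as fh:
        current = None
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if line.startswith(">"):
                fields = line[1:].split("|")
                if len(fields) != 3:
                    raise FormatError(f"{path}:{ln}: header needs id|clade=|len=")
                mid = fields[0]
                if not fields[1].startswith("clade="):
                    raise FormatError(f"{path}:{ln}: missing clade= tag")
                if not fields[2].startswith("len="):
                    raise FormatError(f"{path}:{ln}: missing len= tag")
                try:
                    length = int(fields[2][4:])
                except ValueError:
                    raise FormatError(f"{path}:{ln}: len= is not an integer") from None
                if mid in headers:
                    raise DuplicateIdError(f"{path}:{ln}: duplicate marker id {mid!r}")
                headers[mid] = (fields[1][6:], length)
                order.append(mid)
                seqs[mid] = ""
                current = mid
            elif line:
                if current is None:
                    raise FormatError(f"{path}:{ln}: sequence before any header")
                seqs[current] += line.strip().upper()

    side = path.with_suffix(".tsv")
    prov: dict[str, tuple[str, float, str]] = {}
    if side.exists():
        with open(side) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                pf = float(row["presence_fraction"]) if row["presence_fraction"] else float("nan")
                prov[row["marker_id"]] = (row["source_cluster"], pf, row["decoy_verdict"])

    markers = []
    for mid in order:
        clade, length = headers[mid]
        seq = _clean_seq(seqs[mid], f"{path}:{mid}")
        if len(seq) != length:
            raise FormatError(
                f"{path}: marker {mid}: header len={length} but sequence is {len(seq)}")
        src, pf, verdict = prov.get(mid, ("", float("nan"), "pass"))
        markers.append(Marker(marker_id=mid, clade=clade, sequence=seq,
                              source_cluster=src, presence_fraction=pf,
                              decoy_verdict=verdict))
    return MarkerDatabase(markers=markers)


def read_reads(path: str | Path, sample_id: Optional[str] = None) -> ReadSet:
    """FASTA or FASTQ (by extension; .gz transparent)."""
    path = Path(path)
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    fmt = "fastq" if name.endswith((".fastq", ".fq")) else "fasta"
    sid = sample_id if sample_id is not None else Path(name).stem
    reads: list[Read] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            if rec.id in seen:
                raise DuplicateIdError(f"{path}: duplicate read id {rec.id!r}")
            seen.add(rec.id)
            qual = None
            if fmt == "fastq":
                qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            reads.append(Read(read_id=rec.id,
                              sequence=_clean_seq(str(rec.seq), f"{path}:{rec.id}"),
                              quality=qual))
    return ReadSet(sample_id=sid, reads=reads)


def write_reads(readset: ReadSet, path: str | Path) -> Path:
    """FASTQ when any read has qualities (missing ones padded with 'I'),
    FASTA otherwise; chosen by extension."""
    path = Path(path)
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    fmt = "fastq" if name.endswith((".fastq", ".fq")) else "fasta"
    with _open_text(path, "wt") as fh:
        for r in readset:
            if fmt == "fastq":
                q = r.quality if r.quality is not None else "I" * len(r.sequence)
                fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{q}\n")
            else:
                fh.write(f">{r.read_id}\n{r.sequence}\n")
    return path


def write_abundance(profile: AbundanceProfile, path: str | Path) -> Path:
    """TSV: ``#clade<TAB>relative_abundance`` header, 0-100 scale; the
    sample id rides in a leading comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"##sample={profile.sample_id}\n")
        fh.write(f"##detection_threshold={profile.detection_threshold:.6g}\n")
        fh.write("#clade\trelative_abundance\n")
        for clade, val in profile.entries.items():
            fh.write(f"{clade}\t{val:.10g}\n")
    return path


def read_abundance(path: str | Path) -> AbundanceProfile:
    path = Path(path)
    sample_id = path.stem
    threshold = 0.5
    entries: dict[str, float] = {}
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            if line.startswith("##sample="):
                sample_id = line.split("=", 1)[1]
            elif line.startswith("##detection_threshold="):
                threshold = float(line.split("=", 1)[1])
            elif line.startswith("#"):
                continue
            else:
                parts = line.split("\t")
                if len(parts) != 2:
                    raise FormatError(f"{path}:{ln}: expected 2 columns")
                if parts[0] in entries:
                    raise DuplicateIdError(f"{path}:{ln}: duplicate clade {parts[0]!r}")
                entries[parts[0]] = float(parts[1])
    return AbundanceProfile(sample_id=sample_id, entries=entries,
                            detection_threshold=threshold)


def read_ct_table(path: str | Path) -> CtTable:
    """TSV with columns sample_id, target, ct, replicate."""
    rows: list[tuple[str, str, float, int]] = []
    with _open_text(Path(path)) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        needed = {"sample_id", "target", "ct", "replicate"}
        if reader.fieldnames is None or not needed <= set(reader.fieldnames):
            raise FormatError(f"{path}: expected columns {sorted(needed)}")
        for row in reader:
            rows.append((row["sample_id"], row["target"],
                         float(row["ct"]), int(row["replicate"])))
    return CtTable(rows=rows)


def write_ct_table(table: CtTable, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample_id\ttarget\tct\treplicate\n")
        for s, t, ct, rep in table.rows:
            fh.write(f"{s}\t{t}\t{ct:.10g}\t{rep}\n")
    return path


def write_matrix(matrix, path: str | Path) -> Path:
    """Presence/absence TSV (clusters x genomes; a ``#labels`` comment
    row carries subspecies labels) plus a representative-sequence FASTA
    sidecar (extension swapped to ``.fasta``)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#cluster_id\t" + "\t".join(matrix.genomes) + "\n")
        fh.write("#labels\t" + "\t".join(matrix.label_of(g) for g in matrix.genomes) + "\n")
        for (cid, _), row in zip(matrix.clusters, matrix.presence):
            fh.write(cid + "\t" + "\t".join("1" if v else "0" for v in row) + "\n")
    side = path.with_suffix(".fasta")
    with open(side, "w") as fh:
        for cid, seq in matrix.clusters:
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    return path


def read_matrix(path: str | Path):
    import numpy as np

    from .pangenome import PangenomeMatrix

    path = Path(path)
    genomes: list[str] = []
    labels: dict[str, str] = {}
    rows: list[list[bool]] = []
    cluster_ids: list[str] = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if line.startswith("#cluster_id"):
                genomes = parts[1:]
            elif line.startswith("#labels"):
                labels = dict(zip(genomes, parts[1:]))
            elif line.startswith("#"):
                continue
            else:
                if cluster_ids and parts[0] in cluster_ids:
                    raise DuplicateIdError(f"{path}:{ln}: duplicate cluster {parts[0]!r}")
                cluster_ids.append(parts[0])
                rows.append([v == "1" for v in parts[1:]])
    seqs: dict[str, str] = {}
    side = path.with_suffix(".fasta")
    if side.exists():
        with _open_text(side) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                seqs[rec.id] = _clean_seq(str(rec.seq), f"{side}:{rec.id}")
    clusters = [(cid, seqs.get(cid, "")) for cid in cluster_ids]
    return PangenomeMatrix(clusters=clusters, genomes=genomes,
                           presence=np.array(rows, dtype=bool), labels=labels)


def write_tree(newick: str, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(newick.rstrip() + "\n")
    return path


def read_tree(path: str | Path) -> str:
    text = Path(path).read_text().strip()
    if not text.endswith(";"):
        raise FormatError(f"{path}: not a newick tree (no trailing ';')")
    return text
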