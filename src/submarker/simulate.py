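"""Synthetic two-subspecies benchmark generator.

Emulates the reference-genome situation the marker-discovery method is
designed for: a species split into two subspecies (clade A and clade B)
whose genomes share a large core of orthologous genes (slightly diverged
between the clades) plus a set of subspecies-specific genes that are
present in (almost) every genome of their own clade and absent from the
other.  Optional extras exercise the harder parts of the pipeline:

* *mislabeled genomes* — genomes carrying one clade's gene content but
  the other clade's label, emulating mis-annotated references;
* *decoy homologs* — off-target-species gene variants of some specific
  genes at high identity, exercising the cross-species specificity
  filter;
* *strain variants* — copies of a genome with planted SNPs, for
  consensus/phylogeny tests;
* *read mixtures* — substitution-error shotgun reads drawn from the
  genomes at planted clade proportions.

Everything is driven by one integer seed; identical config + seed gives
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from . import _align
from .core import OTHER, UNKNOWN_LABEL, GenomeRecord, Read, ReadSet

__all__ = ["SimConfig", "GroundTruth", "ReadPool", "simulate_references",
           "simulate_reads", "mutate_genome"]

CLADE_A = "cladeA"
CLADE_B = "cladeB"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Defaults mirror the reference-genome regime the method targets:
    14 + 30 genomes, ~2,000 shared core genes, ~200 specific genes per
    subspecies, mean gene length 1,000 bp, ~2% core divergence between
    the subspecies and a 7% presence-dropout of specific genes (so a
    typical specific gene is seen in ~13 of 14 clade-A genomes).
    """

    seed: int
    n_genomes_a: int = 14
    n_genomes_b: int = 30
    core_gene_count: int = 2000
    specific_gene_count: int = 200
    gene_length_mean: float = 1000.0
    gene_length_sd: float = 200.0
    min_gene_length: int = 300
    core_divergence: float = 0.02
    dropout: float = 0.07
    n_mislabeled: int = 0
    decoy_homolog_rate: float = 0.25
    decoy_divergence: float = 0.05
    decoy_random_count: int = 50
    strain_snp_count: int = 20
    read_length: int = 150
    error_rate: float = 0.01
    read_count: int = 200_000
    clade_a: str = CLADE_A
    clade_b: str = CLADE_B

    def __post_init__(self) -> None:
        for name in ("core_divergence", "dropout", "decoy_homolog_rate",
                     "decoy_divergence", "error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_mislabeled > self.n_genomes_a:
            raise ValueError("more mislabeled genomes than clade-A genomes")
        if self.min_gene_length < 2 * self.read_length:
            # reads must fit inside genes with room for a uniform start
            object.__setattr__(self, "min_gene_length",
                               max(self.min_gene_length, 2 * self.read_length))


@dataclass
class GroundTruth:
    """What the simulator actually planted; the oracle for every test."""

    clusters: list[str] = field(default_factory=list)
    genome_content: dict[str, set[str]] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)
    true_labels: dict[str, str] = field(default_factory=dict)
    mislabeled: list[str] = field(default_factory=list)
    marker_truth: dict[str, set[str]] = field(default_factory=dict)
    family_sequences: dict[str, dict[str, str]] = field(default_factory=dict)
    decoys: list[tuple[str, str]] = field(default_factory=list)
    decoy_homolog_of: dict[str, str] = field(default_factory=dict)
    mixture: dict[str, float] = field(default_factory=dict)
    read_clades: Optional[np.ndarray] = None
    snp_positions: dict[str, list[int]] = field(default_factory=dict)

    def presence_frame(self):
        """Presence/absence as a pandas DataFrame (clusters x genomes)."""
        import pandas as pd

        genomes = list(self.genome_content)
        data = np.zeros((len(self.clusters), len(genomes)), dtype=int)
        cidx = {c: i for i, c in enumerate(self.clusters)}
        for j, g in enumerate(genomes):
            for fam in self.genome_content[g]:
                data[cidx[fam], j] = 1
        return pd.DataFrame(data, index=self.clusters, columns=genomes)

    def to_matrix(self):
        """The planted pangenome as a :class:`~submarker.pangenome.PangenomeMatrix`
        (bypasses sequence clustering; representatives are clade-A family
        sequences where present, clade-B otherwise)."""
        from .pangenome import PangenomeMatrix

        genomes = list(self.genome_content)
        presence = self.presence_frame().to_numpy().astype(bool)
        reps = []
        for fam in self.clusters:
            variants = self.family_sequences.get(fam, {})
            seq = variants.get(CLADE_A) or variants.get(CLADE_B) or ""
            reps.append((fam, seq))
        return PangenomeMatrix(clusters=reps, genomes=genomes,
                               presence=presence, labels=dict(self.labels))


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _mutate(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    out = codes.copy()
    mask = rng.random(codes.shape[0]) < rate
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
    return out


def _gene_lengths(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    raw = rng.normal(cfg.gene_length_mean, cfg.gene_length_sd, size=n)
    return np.maximum(cfg.min_gene_length, np.round(raw)).astype(int)


def simulate_references(cfg: SimConfig) -> tuple[list[GenomeRecord], GroundTruth]:
    """Generate reference genomes, decoy genes and full ground truth.

    Core gene families are shared by every genome, with clade-specific
    variants diverged ``core_divergence`` from each other (half the
    divergence applied on each branch).  Specific families are private
    to one clade and dropped out of individual genomes at rate
    ``dropout``.  The first ``n_mislabeled`` clade-A genome slots carry
    clade-B content (content follows the true clade; the emitted label
    does not).
    """
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth()

    core_fams = [f"core{i:05d}" for i in range(cfg.core_gene_count)]
    spec_a = [f"specA{i:04d}" for i in range(cfg.specific_gene_count)]
    spec_b = [f"specB{i:04d}" for i in range(cfg.specific_gene_count)]

    # family sequences
    core_len = _gene_lengths(rng, cfg, cfg.core_gene_count)
    half = cfg.core_divergence / 2.0
    for fam, L in zip(core_fams, core_len):
        anc = _random_seq(rng, int(L))
        truth.family_sequences[fam] = {
            CLADE_A: _align.decode(_mutate(rng, anc, half)),
            CLADE_B: _align.decode(_mutate(rng, anc, half)),
        }
    for fams, clade in ((spec_a, CLADE_A), (spec_b, CLADE_B)):
        lens = _gene_lengths(rng, cfg, len(fams))
        for fam, L in zip(fams, lens):
            truth.family_sequences[fam] = {clade: _align.decode(_random_seq(rng, int(L)))}

    # genome content: mislabeled genomes occupy the first clade-A slots
    def make_genome(gid: str, true_clade: str, label: str) -> GenomeRecord:
        spec = spec_a if true_clade == CLADE_A else spec_b
        keep = rng.random(len(spec)) >= cfg.dropout
        fams = list(core_fams) + [f for f, k in zip(spec, keep) if k]
        genes = [(fam, truth.family_sequences[fam][true_clade]) for fam in fams]
        truth.genome_content[gid] = set(fams)
        truth.labels[gid] = label
        truth.true_labels[gid] = true_clade
        if label != true_clade:
            truth.mislabeled.append(gid)
        return GenomeRecord(genome_id=gid, label=label, genes=genes)

    genomes: list[GenomeRecord] = []
    for i in range(cfg.n_genomes_a):
        true_clade = CLADE_B if i < cfg.n_mislabeled else CLADE_A
        genomes.append(make_genome(f"A{i:03d}", true_clade, cfg.clade_a))
    for i in range(cfg.n_genomes_b):
        genomes.append(make_genome(f"B{i:03d}", CLADE_B, cfg.clade_b))

    present = set().union(*truth.genome_content.values())
    truth.clusters = [f for f in core_fams + spec_a + spec_b if f in present]

    # true marker sets: specific families at >=90% presence among the
    # *correctly* labeled genomes of their clade (mislabeled excluded)
    for clade, fams in ((CLADE_A, spec_a), (CLADE_B, spec_b)):
        gids = [g for g, lab in truth.true_labels.items()
                if lab == clade and truth.labels[g] == lab]
        need = math.ceil(0.9 * len(gids)) if gids else 0
        truth.marker_truth[clade] = {
            f for f in fams
            if sum(f in truth.genome_content[g] for g in gids) >= need > 0
        }

    # decoys: homologs of a fraction of specific families, plus unrelated genes
    n_hom = 0
    for fam in spec_a + spec_b:
        if rng.random() < cfg.decoy_homolog_rate:
            clade = CLADE_A if fam.startswith("specA") else CLADE_B
            src = _align.encode(truth.family_sequences[fam][clade])
            did = f"decoy_hom{n_hom:04d}"
            truth.decoys.append((did, _align.decode(_mutate(rng, src, cfg.decoy_divergence))))
            truth.decoy_homolog_of[did] = fam
            n_hom += 1
    rand_lens = _gene_lengths(rng, cfg, cfg.decoy_random_count)
    for i, L in enumerate(rand_lens):
        truth.decoys.append((f"decoy_rand{i:04d}", _align.decode(_random_seq(rng, int(L)))))

    return genomes, truth


class ReadPool:
    """Concatenated clade genomes with the valid read-start positions
    (reads never cross gene boundaries).  Build once per genome set and
    reuse across samples via the ``pools`` argument of
    :func:`simulate_reads`."""

    def __init__(self, genomes: Sequence[GenomeRecord], read_length: int):
        lens = np.array([len(seq) for g in genomes for _, seq in g.genes],
                        dtype=np.int64)
        joined = "".join(seq for g in genomes for _, seq in g.genes)
        self.concat = _align.encode(joined)
        total = int(lens.sum())
        valid = np.ones(total, dtype=bool)
        if read_length > 1 and lens.size:
            ends = np.cumsum(lens)
            tail = np.arange(-(read_length - 1), 0, dtype=np.int64)
            bad = (ends[:, None] + tail[None, :]).ravel()
            bad = bad[(bad >= 0) & (bad < total)]
            valid[bad] = False
            # genes shorter than the read length yield no reads at all
            short = lens < read_length
            if short.any():
                starts_off = ends - lens
                for s, e in zip(starts_off[short].tolist(), ends[short].tolist()):
                    valid[s:e] = False
        self.starts = np.nonzero(valid)[0]

    def draw(self, rng: np.random.Generator, n: int, read_length: int) -> np.ndarray:
        if self.starts.size == 0:
            raise ValueError("no gene long enough to yield reads")
        s = rng.choice(self.starts, size=n, replace=True)
        return self.concat[s[:, None] + np.arange(read_length)]


def simulate_reads(
    genomes: Sequence[GenomeRecord],
    mixture: Mapping[str, float],
    cfg: SimConfig,
    sample_id: str = "sample",
    seed: Optional[int] = None,
    pools: Optional[dict[str, "ReadPool"]] = None,
) -> tuple[ReadSet, GroundTruth]:
    """Draw a shotgun sample at planted clade proportions.

    ``mixture`` maps clade label -> fraction of reads (must sum to 1);
    the reserved key ``"other"`` draws reads from random background
    sequence.  Reads take uniform start positions within genes of a
    uniformly length-weighted genome of the clade and carry i.i.d.
    substitution errors at ``cfg.error_rate``.
    """
    tot = sum(mixture.values())
    if abs(tot - 1.0) > 1e-9:
        raise ValueError(f"mixture fractions sum to {tot}, expected 1")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    clades = list(mixture)
    counts = rng.multinomial(cfg.read_count, [mixture[c] for c in clades])
    L = cfg.read_length

    blocks: list[np.ndarray] = []
    read_clades: list[str] = []
    for clade, n in zip(clades, counts):
        if n == 0:
            continue
        if clade == OTHER:
            block = rng.integers(0, 4, size=(n, L), dtype=np.uint8)
        else:
            if pools is not None and clade in pools:
                pool = pools[clade]
            else:
                members = [g for g in genomes if g.label == clade]
                if not members:
                    raise ValueError(f"no genome labeled {clade!r}")
                pool = ReadPool(members, L)
            block = pool.draw(rng, n, L)
        blocks.append(block)
        read_clades.extend([clade] * n)

    mat = np.concatenate(blocks) if blocks else np.empty((0, L), dtype=np.uint8)
    if cfg.error_rate > 0 and mat.size:
        mask = rng.random(mat.shape) < cfg.error_rate
        n_err = int(mask.sum())
        mat[mask] = (mat[mask] + rng.integers(1, 4, size=n_err, dtype=np.uint8)) % 4

    flat = _align._CODE_TO_BASE[mat].tobytes().decode("ascii") if mat.size else ""
    reads = [
        Read(read_id=f"{sample_id}_r{i:07d}", sequence=flat[i * L:(i + 1) * L])
        for i in range(mat.shape[0])
    ]
    truth = GroundTruth(mixture=dict(mixture),
                        read_clades=np.array(read_clades, dtype=object))
    return ReadSet(sample_id=sample_id, reads=reads), truth


def mutate_genome(
    genome: GenomeRecord,
    n_snps: int,
    seed: int,
    gene_ids: Optional[Sequence[str]] = None,
    suffix: str = "_v",
) -> tuple[GenomeRecord, dict[str, list[int]]]:
    """Plant ``n_snps`` substitutions into a genome (a strain variant).

    SNP positions are drawn without replacement, uniformly over the
    concatenated length of ``gene_ids`` (default: all genes).  Returns
    the variant genome and the planted positions per gene.
    """
    rng = np.random.default_rng(seed)
    targets = list(gene_ids) if gene_ids is not None else [g for g, _ in genome.genes]
    target_set = set(targets)
    seqs = {g: s for g, s in genome.genes}
    lens = [len(seqs[g]) for g in targets]
    total = int(np.sum(lens))
    if n_snps > total:
        raise ValueError(f"{n_snps} SNPs requested over {total} bases")
    flat_pos = np.sort(rng.choice(total, size=n_snps, replace=False))
    bounds = np.cumsum([0] + lens)

    snps: dict[str, list[int]] = {}
    new_seqs = dict(seqs)
    for p in flat_pos.tolist():
        gi = int(np.searchsorted(bounds, p, side="right") - 1)
        gene = targets[gi]
        pos = p - int(bounds[gi])
        codes = _align.encode(new_seqs[gene])
        codes[pos] = (codes[pos] + rng.integers(1, 4)) % 4
        new_seqs[gene] = _align.decode(codes)
        snps.setdefault(gene, []).append(pos)

    variant = GenomeRecord(
        genome_id=genome.genome_id + suffix,
        label=genome.label,
        genes=[(g, new_seqs[g]) for g, _ in genome.genes],
    )
    return variant, snps
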