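# Methods

This note records the models, defaults and design choices behind each
stage of the pipeline, what the synthetic benchmark does and does not
emulate, and the known limitations.

## Pangenome construction

Gene families are built by greedy, length-sorted clustering: genes are
sorted by decreasing length (ties broken by sequence, so the result is
invariant to genome input order) and each gene joins the first existing
cluster whose representative it matches, else founds a new cluster.
Candidate representatives are found via shared 15-mers (representatives
indexed at stride 5); the match test aligns the shorter of
gene/representative end-to-end inside the longer with a bounded
edit-distance alignment and computes identity = 1 − edits/len(shorter).
Because the shorter sequence is aligned end-to-end, an accepted merge
always spans it fully, so the coverage requirement (default 80% of the
shorter sequence) is satisfied by construction under this aligner; the
parameter is retained for alternative scorers and to document intent.
Defaults (identity 0.95, coverage 0.80) are conventional pangenome
settings; both are exposed on the CLI.  Genes shorter than the seed
k-mer are compared against every representative rather than skipped.

Consequence of the greedy rule: two clade-variants of the same ancestral
gene merge into one family whenever their divergence is below 1 −
identity threshold (the simulator's 2% core divergence merges cleanly at
the 0.95 default), while subspecies-specific genes — unrelated sequences
— never merge.

## Mis-annotation detection

Genome presence/absence profiles are clustered with average-linkage
hierarchical clustering on Jaccard distance, cut at k = 2.  The
distance/linkage pair is a deliberate choice — one defensible
instantiation of "cluster the profiles"; on cleanly
separated profiles the k = 2 cut coincides with the minimum
total-within-group-distance 2-partition (verified against exhaustive
enumeration on ≤12 genomes in the tests).  A genome is flagged when its
declared label disagrees with the majority (non-unknown) label of its
group; a majority tie flags every labeled genome of the group, on the
principle that ambiguity should surface rather than hide.  Flagged
genomes are reported only — exclusion is the caller's explicit step
(`--exclude` / `excluded_genomes`), mirroring how suspect references
should be handled in practice.  A per-genome silhouette-like score
((b − a)/max(a, b) on Jaccard distances) quantifies how cleanly each
genome sits in its group.

## Marker selection and specificity

The presence rule is count ≥ ⌈threshold·n⌉ of the clade's genomes and
exactly zero of the sister clade's.  Ceiling is used for non-integer
products: at the 0.90 default and n = 14 the minimum qualifying count is
13, the canonical worked case.  Genomes labeled `unknown` are ignored
entirely (they could belong to either subspecies).

The cross-species filter aligns each candidate locally (match +1,
mismatch −1, gap open −2, gap extend −1; all config-exposed) against
every decoy sharing a 15-mer with it, and removes the candidate iff some
hit has identity strictly above 0.90 **and** covers strictly more than
0.50 of the candidate's length.  Identity is identities/alignment
columns and coverage is aligned-query-span/candidate-length — i.e.
BLAST's `pident` and `qcovs` semantics, which is our reading of the
ambiguous ">90% alignment and over 50% coverage" convention.  The decoy
collection is a user-supplied FASTA standing in for a comprehensive
nucleotide database: the artifact must be testable at desk scale, and
the interface accepts any off-target gene set.  Candidates shorter than
the seed k-mer are aligned against every decoy by full dynamic
programming, never silently skipped.  Every removal is logged with its
best hit.

Marker ids are deterministic (`<clade>_<index>`, descending length), and
byte-identical sequences assigned to both clades are a hard error —
such a gene contradicts specificity by construction.

## Quantification

Mapping is ungapped and seed-based: read k-mers (k = 15, sampled every
11 positions) vote for (marker, diagonal) placements; each candidate
placement is scored by per-base identity over the read/marker overlap.
Defaults: identity ≥ 0.95 (subspecies-level stringency) over ≥ 40
aligned bases.  Assignment rules:

* best identity wins, one marker per read;
* best hits to **both** clades within Δ identity < 0.01 → the read is
  species-informative only and feeds the species pool (this is the
  mechanism that generates the `unclassified` bucket);
* an exact-identity tie between two distinct markers of the winning
  clade → the read is discarded as ambiguous.

Abundance: per-marker depth = aligned bases/marker length.  A clade's
score is the truncated mean of its markers' depths — with ≥10 markers
the top and bottom 10% are discarded, with 3–9 the single min and max,
below that a plain mean.  The truncation mirrors the robust-averaging
philosophy of marker-based profilers and guards against individual
markers with aberrant depth (repeats, shared fragments).  The species
score is the truncated mean over *all* markers of assigned depth plus
the species pool spread uniformly across the database;
`unclassified = max(0, species − Σ clades)` is then exactly the
species-level mass not attributable to either clade.  Scores are scaled
by the mapped read fraction and normalized to sum to 100 with `other`
carrying unmapped mass.  Normalization is across the four reserved
entries only — this tool profiles one species' subspecies, not the
community; community-wide renormalization is the caller's composition
step.  `AbundanceProfile.subspecies_shares()` gives the within-species
composition (entries excluding `other`, renormalized to 1), which is
the quantity comparable across samples with different community
backgrounds and the one used in the concordance analysis.

Detection floor: a clade is treated as present when its relative
abundance is ≥ 0.5% (inclusive boundary).

## Strain analysis

Consensus is a per-position majority pileup on each marker (no
re-alignment is needed because mapping is ungapped): a position is
called when depth ≥ 3 and top-allele frequency ≥ 0.8, else `N`; a
marker with < 50% callable positions is dropped for that sample; a
sample is kept when ≥ 50 markers survive, scaled down to half the
database when the database itself has fewer than 50 markers.  The
depth/majority defaults are our choices (exposed on the CLI); the
50-marker rule matches standard strain-profiling practice.  Only
unambiguously assigned reads contribute — species-pool reads carry no
subspecies strain signal.

Distances are mismatches / jointly-called sites, excluding `N` and gap
pairwise; a pair with zero comparable sites is *missing*, never zero.
The tree is neighbor joining with deterministic tie-breaking
(lexicographically smallest subtree-name pair at equal Q) and negative
branch lengths clamped to zero with the deficit moved to the sibling
edge.  NJ is exact on additive matrices, which the tests exploit:
matrices built from random trees by path-length construction must be
recovered at Robinson-Foulds distance zero, and the topology is
cross-checked against an independent NJ implementation.

## ΔΔCt concordance

The two-target form is used: replicate Cts are averaged per target
within a sample, fold = E^−(Ct_A − Ct_B) with E = 2 by default, shares =
(fold/(1+fold), 1/(1+fold)).  This within-sample two-target reading is
the only form that yields a subspecies ratio directly; primer
efficiency correction (E = 1 + efficiency) is available but off by
default since efficiencies are typically validated rather than
corrected for.  Agreement is ordinary least squares of qPCR shares on
computational shares with a two-sided t-test on the slope; either
within-species shares or community-relative abundances can be fed in —
the function is agnostic to which composition the caller chooses.

## Synthetic benchmark

`simulate` emulates the reference situation the method targets: two
subspecies sharing ~2,000 core gene families (diverged ~2% between the
clades, half applied on each branch from a common ancestor) plus ~200
subspecies-specific families each, across 14 + 30 genomes of mean gene
length 1,000 bp.  Specific genes drop out of individual genomes at rate
0.07, putting a typical specific family in ~13 of 14 clade-A genomes —
the regime the presence rule is designed for.  Mis-annotated genomes
carry one clade's content under the other clade's label.  Decoy
homologs are planted for 25% of specific families at 5% divergence
(safely above the 90%-identity removal bar at the default gene length).
Reads are substitution-only (1% error, 150 bp, uniform starts within
genes); indels are deliberately absent so the ungapped mapper is exact —
an acknowledged simplification.

What the simulator does **not** emulate: real community background
(off-target organisms exist only as decoy genes and random `other`
reads), indel and chimera errors, GC/coverage bias, gene gain/loss
within a clade beyond i.i.d. dropout, and homologous recombination.
Passing benchmarks therefore demonstrate the algorithmic correctness of
every stage against planted truth, not field performance on real
metagenomes, where database completeness and off-target homology are
the binding constraints.

## Benchmark problem sizes

The property suites fix these scales (chosen once, as the package's own
benchmark design): marker-selection oracle agreement on 200 random
matrices (≤20 clusters × ≤10 genomes); mis-annotation detection over 50
seeds at 14 + 30 genomes with 200 core + 60 specific families of mean
length 500 bp (profile structure, not sequence content, drives this
stage, so a reduced gene budget tests the same decision); specificity
filtering over 20 seeds at 50 specific families; mixture recovery at
the full default reference scale over the grid {0, 10, 25, 50, 75, 90,
100}% with 200,000 reads/sample × 10 seeds; NJ recovery on 50 random
5–8-taxon additive matrices; strain-cluster separation over 20 seeds
with two clusters of three samples (30 shared + 5 private SNPs on the
clade-A markers, reads at ~15× marker depth); concordance over 20
samples at 200,000 reads against pseudo-Ct values derived from the
planted ratios with 0.1-cycle noise.

## Numerical and degenerate-input conventions

All coordinates are 0-based, half-open.  FASTA parsing tolerates
wrapped lines and CRLF; lowercase is upper-cased; `N` is kept and other
IUPAC ambiguity codes map to `N` with a logged count.  Profiles sum to
100 within 1e-6 for every input; a sample with zero mapped reads yields
`other` = 100.  Zero-variance predictors in the agreement regression,
missing qPCR targets, empty decoy sets, genomes with empty gene lists
and all-identical presence profiles are hard errors rather than silent
degenerate output.  All randomness flows from explicit integer seeds;
simulator output is byte-identical for identical config + seed.

## Known limitations

Binary subspecies only (>2 subspecies per run is out of scope; rarely
observed sister subspecies will be absorbed into `unclassified` or
misassigned).  The mapper has no indel model, which is adequate for the
marker-length scale and short reads but would undercall strains with
indel variation.  The specificity filter is only as good as the decoy
collection supplied.  Whether an external pangenome tool's gene-family
definitions would produce identical candidate sets cannot be settled
without fixing that tool's exact version and parameters; the clustering
here is a self-contained, deterministic replacement.
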