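# Methods

`sporopan` re-implements, as a tested reusable pipeline, the comparative-genomics
workflow used to characterize the 29 cocci-shaped *Sporosarcina* strains:
all-vs-all protein similarity, threshold-based ortholog clustering into
core / pan / strain-specific genes, ordered core-gene concatenation, AAI/ANI
matrices with 95%-AAI species delimitation, accessory presence/absence
distances, distance trees, and a reference-gene presence screen. A synthetic
proteome-family generator with machine-readable planted truth stands in for
the sequenced genomes, so every recovery claim the package makes is checkable
against a known answer.

## Pairwise alignment and similarity statistics

All comparisons are optimal Smith–Waterman local alignments under affine gap
penalties, computed with Biopython's C `PairwiseAligner`. Protein scoring
defaults to BLOSUM62 with gap open −11 / extend −1 and Karlin–Altschul
parameters λ = 0.267, K = 0.041 (the canonical gapped-BLOSUM62 set);
nucleotide scoring defaults to +1/−2 with gap open −5 / extend −2. The gap
convention is Biopython's: a gap of length L costs `open + (L−1)·extend`.
The test suite checks score equality against an independent, hand-written
Gotoh dynamic program on hundreds of random pairs.

From an alignment we derive the statistics every cutoff is expressed in:

* **PI** (percent identity) = 100 × identities / alignment columns
  (gaps included in the denominator, matching `pident` semantics);
* **PC** (percent query coverage) = 100 × aligned query span / query length
  (`qcovs` semantics);
* bit score = (λ·S − ln K)/ln 2 and E-value = `query_len · db_residues ·
  2^(−bit)`, with `db_residues` the residue total over all proteomes
  (mirroring one search database holding every genome).

Among co-optimal tracebacks the aligner's deterministic first alignment is
reported; scores are unaffected by this choice and reruns are byte-identical.
Empty (score-0) alignments are represented by an explicit sentinel, never by
fabricated statistics.

The all-vs-all search generates candidate pairs from an inverted exact-k-mer
index, which is equivalent to the pairwise shared-k-mer prefilter and avoids
quadratic enumeration. The prefilter default is k = 4. For ≥ 90% identity
over ≥ 90% of a ≥ 25-residue query, a shared 4-mer is guaranteed by
pigeonhole, so the prefilter is lossless at the stringent (core) cutoffs;
at the relaxed pan cutoffs (30% PI / 70% PC) a qualifying pair can in rare
cases share no 4-mer (spread-out identities), so the prefilter is a
documented approximation there. Study-scale runs (29 strains × 250 genes)
use k = 6, which keeps the run on one CPU in about a minute; at the
simulated divergences the probability that a true ortholog pair shares no
6-mer is negligible for average-length genes, and the generator certifies
the planted structure against exactly this candidate rule (below).

## Ortholog clustering and pan/core analysis

Hits are filtered by a threshold set — PI ≥ `pi_min`, PC ≥ `pc_min`,
optionally E ≤ `evalue_max` — applied inclusively; an undirected edge is kept
when either direction's hit qualifies (a both-directions mode exists).
Clusters are single-linkage connected components; genes without a qualifying
edge become singletons; every gene lies in exactly one cluster. Two
canonical runs are exposed:

* **core run**: PI ≥ 90, PC ≥ 90, E ≤ 1e−4 (an alternate relaxed stringency
  of PI ≥ 75 is preconfigured);
* **pan run**: PI ≥ 30, PC ≥ 70, no E-value cutoff.

A *core cluster* has at least one member in every genome; the *pan-genome
size* is the total cluster count including singletons; a *strain-specific*
cluster has all members from one genome. Paralogs may share a cluster; the
concatenation representative is the longest member (ties broken by gene id),
and concatenates place one representative per core cluster in ascending
cluster-id order — the same order for every genome — for optional external
alignment and tree building. The E-value cutoff written as "> 1e−4" in the
source material is interpreted as a maximum (E ≤ 1e−4); a stringency floor
would be meaningless.

Chaining is the known cost of single linkage: one borderline hit can bridge
two families. The clade-delimitation audit (below) and the generator's
certification both address where this matters.

## AAI, ANI, and clade delimitation

**AAI** between two proteomes is the unweighted mean PI over reciprocal
best-hit (RBH) pairs: best hits are taken per query by bit score (ties by
subject id) in both directions, retained when both pass PI ≥ 30 and
PC ≥ 70, and paired reciprocally. The matrix is symmetric by construction
with a 100 diagonal; a pair with no RBH support is *missing* (NaN), never 0,
and counts as below any cutoff downstream. The RBH filter values are the
package's own documented defaults — the original web calculator's defaults
are not published — and are recorded in every run report.

**ANI** follows the fragment convention: the query genome is chopped into
consecutive 1020-bp windows, each window and its reverse complement are
aligned locally to the subject, windows whose best hit passes 30% identity /
70% coverage are retained, and ANI is their mean identity averaged over both
directions. Tails shorter than a third of the window length are skipped.

**Clade (candidate species) delimitation** thresholds the AAI matrix at 95%
(the conspecificity range proposed for AAI is 95–96%) and takes
single-linkage components, ordered by smallest member label. An explicit
`is_clean` audit reports whether every within-clade pair is above and every
between-clade pair below the cutoff — i.e. whether the partition is
linkage-independent; when false, the partition is flagged rather than
silently trusted.

## Distance trees and partition comparison

Three distance views feed the same Saitou–Nei neighbor-joining machinery
(scikit-bio's implementation; negative branch lengths clamped to zero;
Newick output):

* **core-gene distance** = 100 − length-weighted mean PI over pairwise
  alignments of core-cluster representatives (weights = mean representative
  length per cluster);
* **accessory distance** = Jaccard distance between presence/absence
  profiles;
* **100 − AAI**, with missing AAI mapped to the maximum distance.

NJ is exact on additive matrices, which the tests verify to 1e−9.

A tree induces a partition of its leaves by single-linkage grouping at a
patristic (tip-to-tip path) distance cutoff. The species workflow uses each
analysis's natural scale: 100 − 95 = 5 identity points for the core-gene and
AAI trees, and the scale midpoint 0.5 for Jaccard distances. Partitions are
compared with the Rand index (fraction of label pairs on which two
partitions agree), computed via scikit-learn and checked against explicit
pair enumeration.

**Choice of accessory profile.** The species workflow derives the
presence/absence matrix from the *stringent* (core-threshold) cluster set,
not the pan-level one. At the stringent cutoff, gene families split at the
species boundary, so the binary profile carries both gene-content and
family-divergence signal. This matters for the simulated families: their
accessory genes are strain-private by design, so pan-level profiles are
clade-uninformative by construction (every strain owns all core clusters
plus its own singletons, making all pairwise Jaccard distances equal), while
stringent-level profiles separate clades sharply. On real data, where
accessory genes are shared within clades, both profiles are informative.

## The synthetic family generator

`simulate_family` plants: an ancestral core proteome (`core_size` genes,
lengths uniform on [min, 2·mean − min] — bounded, mean-preserving, no heavy
tail); per clade, a clade root derived by independent per-site substitution
with probability `q_between`; per strain, core-gene copies derived from the
clade root at `q_within`, plus `strain_specific_per_strain` genes drawn
fresh from the Robinson–Robinson background amino-acid frequencies. A
substituted site always receives a different residue, so expected identity
to the parent is exactly 100·(1−q); pairwise expectations are
100·(1−q_within)² within a clade and 100·[(1−q_within)(1−q_between)]²
between clades (independent layers on both lineages; back-substitution is a
second-order correction at the default rates). An optional indel mode
(geometric lengths) exists but carries no analytic guarantees.

Defaults mirror the 29-strain study structure: 8 clades of sizes
(3, 1, 3, 5, 2, 5, 5, 5) — the published clade memberships, with the one
unenumerated clade taking the remaining five strains — a 200-gene core, 50
strain-specific genes per strain, q_within = 0.01, q_between = 0.12, and
gene lengths of mean 120 / min 60 residues, a deliberately reduced gene
length that keeps a full 29-strain, 7 250-gene analysis on one CPU at about
a minute while leaving every statistic of interest unchanged.

**Certified planted truth.** Independently drawn random proteins are not
automatically a valid clustering oracle at the pan cutoffs, for two reasons
observed at study scale: (i) two families can *merge* through a long weak
chance window (~30–35% identity across most of a short gene — invisible to
any ancestor-level screen based on the optimal alignment, which may be a
short perfect match elsewhere); and (ii) a short family can *split* when
mutation erases every shared 6-mer between clades, so the prefiltered search
never aligns the pair. The generator therefore certifies each family against
the pipeline's own candidate rule (shared-6-mer index, then optimal local
alignment against the pan thresholds): a new family is redrawn if any of its
strain copies yields a qualifying hit against an accepted family, or if its
own copy graph is not connected. Strain-specific genes are rejection-sampled
to share no 6-mer with any other gene, which makes them singletons under any
downstream thresholds. The no-split certificate transfers to smaller k and
to prefilter-off searches (they only add candidate pairs); the no-merge
certificate is guaranteed for k = 6-prefiltered searches, and prefilter-off
pan counts may differ by the occasional chance merge.

What the generator does *not* emulate: indel-driven length variation (off by
default), codon-level evolution, recombination, horizontal transfer,
clade-shared accessory genes, and paralogy. Passing recovery tests therefore
demonstrate that the pipeline's statistics and thresholds behave exactly as
designed under the substitution-only model — not that real proteomes meet
those assumptions.

## Numerical and degenerate-input conventions

Intervals are 0-based half-open throughout. Matrix files carry 4 decimals
and round-trip to 1e−4. Thresholds are inclusive. Missing identity values
propagate as NaN and compare as below-cutoff. Genome-table summaries round
to the printed precision of such tables (Mb to 2 decimals, CDS/tRNA to
integers, IS counts to 1 decimal); the prophage column is raw text (its
printed footnote is internally inconsistent) and is never summarized.
Proteomes with duplicate gene ids, empty FASTA files, empty reference sets,
non-square matrices, and sub-3-taxon trees are rejected with named errors.
Run reports serialize the resolved configuration and input checksums and are
byte-identical across reruns; all randomness flows from a single integer
seed.

## Problem sizes used by the shipped checks

The acceptance checks run the full pipeline at the study-mirroring scale
(29 strains × 250 genes, five seeds in the test suite, one seed in
`scripts/acceptance.py`) and the desk-scale oracle comparisons on hundreds
of random instances. ANI checks use multi-kilobase synthetic genomes (3.6–5.1
kb), large enough for ten 1020-bp fragments per pair.

## Known limitations

* Single best local alignment per gene pair: no multiple HSPs, no HSP
  tiling, no composition-based statistics — counts on real data will differ
  from a BLAST-based pipeline in proportion to how often these matter.
* Single-linkage chaining can bridge families through one borderline hit;
  the `is_clean` audit flags the analogous risk for clades, but cluster-level
  chaining on real data is undetected by construction.
* The k-mer prefilter is exact only at stringent cutoffs; pan-level searches
  with the default k = 4 are a very close, but not exact, approximation of
  an unfiltered search.
* AAI depends on the RBH filter values; published matrices computed with
  other defaults may differ by a few tenths of a point.
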