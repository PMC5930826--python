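"""Pairwise local alignment and the similarity statistics built on it.

This is the package's internal replacement for a BLASTp/BLASTn search stage:
optimal Smith-Waterman local alignment under affine gap penalties, and the
derived statistics the clustering cutoffs are expressed in —

* PI, percent identity: ``100 * identities / alignment_length`` where
  ``alignment_length`` counts alignment columns including gaps;
* PC, percent query coverage: ``100 * aligned_query_span / query_length``;
* bit score ``(lambda * S - ln K) / ln 2`` and E-value
  ``query_len * db_residues * 2**(-bit)`` under Karlin-Altschul statistics.

The gap convention is Biopython's: a gap of length L costs
``gap_open + (L - 1) * gap_extend``. Alignment itself is delegated to
Biopython's C ``PairwiseAligner``; an all-vs-all search over proteomes is
driven by an inverted k-mer index so that gene pairs sharing no exact k-mer
are never aligned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import GenomeProteome, SequenceRecord


class AlignmentError(ValueError):
    """Raised for invalid alignment inputs."""


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and Karlin-Altschul parameters.

    Defaults correspond to gapped BLOSUM62 (gap open -11 / extend -1,
    lambda = 0.267, K = 0.041), the canonical protein search parameter set.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = -11
    gap_extend: int = -1
    lam: float = 0.267
    k_param: float = 0.041
    alphabet: str = "protein"
    match: int = 1    # used only for dna schemes
    mismatch: int = -2

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError("require gap_open <= gap_extend < 0")
        if self.lam <= 0 or self.k_param <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")

    @classmethod
    def protein_default(cls) -> "ScoringScheme":
        return cls()

    @classmethod
    def nucleotide_default(cls) -> "ScoringScheme":
        """Megablast-like scoring: +1/-2, gap open -5 extend -2.

        lambda/K are the ungapped values for +1/-2 scoring (1.28, 0.46).
        """
        return cls(
            matrix_name="NUC.1-2",
            gap_open=-5,
            gap_extend=-2,
            lam=1.28,
            k_param=0.46,
            alphabet="dna",
            match=1,
            mismatch=-2,
        )


@dataclass(frozen=True)
class LocalAlignment:
    """An optimal local alignment; spans are 0-based half-open."""

    query_id: str
    subject_id: str
    score: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    alignment_length: int
    identities: int

    def __post_init__(self) -> None:
        if not 0 <= self.identities <= self.alignment_length:
            raise AlignmentError("identities out of range")
        if self.score < 0:
            raise AlignmentError("local alignment score must be >= 0")

    @property
    def is_empty(self) -> bool:
        return self.alignment_length == 0


@dataclass(frozen=True)
class PairwiseHit:
    """One query-vs-subject similarity record: the similarity-graph edge."""

    query_id: str
    subject_id: str
    query_genome: str
    subject_genome: str
    percent_identity: float
    percent_query_coverage: float
    bit_score: float
    evalue: float
    alignment_length: int = 0
    identities: int = 0
    query_span: tuple[int, int] = (0, 0)
    subject_span: tuple[int, int] = (0, 0)


@lru_cache(maxsize=8)
def _aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if scheme.alphabet == "protein":
        aligner.substitution_matrix = substitution_matrices.load(scheme.matrix_name)
    else:
        aligner.match_score = scheme.match
        aligner.mismatch_score = scheme.mismatch
    aligner.open_gap_score = scheme.gap_open
    aligner.extend_gap_score = scheme.gap_extend
    return aligner


def _empty_alignment(query_id: str, subject_id: str) -> LocalAlignment:
    return LocalAlignment(
        query_id=query_id,
        subject_id=subject_id,
        score=0.0,
        query_span=(0, 0),
        subject_span=(0, 0),
        alignment_length=0,
        identities=0,
    )


def local_align(
    query: SequenceRecord, subject: SequenceRecord, scheme: ScoringScheme
) -> LocalAlignment:
    """Optimal Smith-Waterman local alignment of two sequences.

    Returns an empty-alignment sentinel (score 0, zero-length spans) when no
    positive-scoring local alignment exists.
    """
    if query.alphabet != scheme.alphabet or subject.alphabet != scheme.alphabet:
        raise AlignmentError(
            f"alphabet mismatch: {query.alphabet}/{subject.alphabet} sequences "
            f"vs {scheme.alphabet} scheme"
        )
    if len(query) == 0 or len(subject) == 0:
        raise AlignmentError("cannot align an empty sequence")
    aligner = _aligner(scheme)
    score = aligner.score(query.sequence, subject.sequence)
    if score <= 0:
        return _empty_alignment(query.id, subject.id)
    aln = aligner.align(query.sequence, subject.sequence)[0]
    counts = aln.counts()
    qs, qe = int(aln.coordinates[0][0]), int(aln.coordinates[0][-1])
    ss, se = int(aln.coordinates[1][0]), int(aln.coordinates[1][-1])
    return LocalAlignment(
        query_id=query.id,
        subject_id=subject.id,
        score=float(score),
        query_span=(qs, qe),
        subject_span=(ss, se),
        alignment_length=counts.identities + counts.mismatches + counts.gaps,
        identities=counts.identities,
    )


def hit_from_alignment(
    aln: LocalAlignment,
    query_len: int,
    db_residues: int,
    scheme: ScoringScheme,
    query_genome: str = "",
    subject_genome: str = "",
) -> PairwiseHit:
    """Derive PI / PC / bit score / E-value from a local alignment."""
    if aln.alignment_length == 0:
        raise AlignmentError("empty alignment has no identity")
    if db_residues <= 0:
        raise AlignmentError("db_residues must be positive")
    span_len = aln.query_span[1] - aln.query_span[0]
    if query_len < span_len:
        raise AlignmentError("query_len shorter than the aligned query span")
    bit = (scheme.lam * aln.score - math.log(scheme.k_param)) / math.log(2.0)
    evalue = query_len * db_residues * 2.0 ** (-bit)
    return PairwiseHit(
        query_id=aln.query_id,
        subject_id=aln.subject_id,
        query_genome=query_genome,
        subject_genome=subject_genome,
        percent_identity=100.0 * aln.identities / aln.alignment_length,
        percent_query_coverage=100.0 * span_len / query_len,
        bit_score=bit,
        evalue=evalue,
        alignment_length=aln.alignment_length,
        identities=aln.identities,
        query_span=aln.query_span,
        subject_span=aln.subject_span,
    )


def kmer_set(sequence: str, k: int) -> frozenset[str]:
    return frozenset(sequence[i : i + k] for i in range(len(sequence) - k + 1))


def kmer_prefilter(a: SequenceRecord, b: SequenceRecord, k: int = 4) -> bool:
    """True iff the two sequences share at least one exact k-mer."""
    if k < 2:
        raise ValueError("k must be >= 2")
    short, long_ = (a.sequence, b.sequence)
    if len(short) > len(long_):
        short, long_ = long_, short
    kmers = kmer_set(short, k)
    return any(long_[i : i + k] in kmers for i in range(len(long_) - k + 1))


def search_all_vs_all(
    proteomes: Sequence[GenomeProteome],
    scheme: ScoringScheme | None = None,
    prefilter: bool = True,
    k: int = 4,
) -> list[PairwiseHit]:
    """Best-local-alignment hits for every cross-genome gene pair.

    For each unordered cross-genome gene pair that shares at least one exact
    k-mer (or every pair when ``prefilter`` is off), the optimal local
    alignment is computed once and reported in both directions (PI is
    symmetric; PC and E-value depend on the query). Pairs whose alignment is
    empty produce no hit. ``db_residues`` is the total residue count over all
    proteomes, mirroring a single search database holding every genome.

    Output is sorted by (query genome, query id, subject genome, subject id).
    """
    if len(proteomes) < 2:
        raise ValueError("need >= 2 proteomes")
    scheme = scheme or ScoringScheme.protein_default()
    genes: list[tuple[int, str, SequenceRecord]] = []  # (genome index, gid, record)
    seen: set[tuple[str, str]] = set()
    for gi, prot in enumerate(proteomes):
        for rec in prot.records:
            key = (prot.genome_id, rec.id)
            if key in seen:
                raise ValueError(f"duplicate global gene id {key}")
            seen.add(key)
            genes.append((gi, prot.genome_id, rec))
    db_residues = sum(p.total_residues for p in proteomes)

    if prefilter:
        index: dict[str, list[int]] = {}
        for idx, (_, _, rec) in enumerate(genes):
            for kmer in kmer_set(rec.sequence, k):
                index.setdefault(kmer, []).append(idx)
        candidate_pairs: set[tuple[int, int]] = set()
        for members in index.values():
            if len(members) < 2:
                continue
            for i, a in enumerate(members):
                ga = genes[a][0]
                for b in members[i + 1 :]:
                    if genes[b][0] != ga:
                        candidate_pairs.add((a, b))
        pairs = candidate_pairs
    else:
        pairs = {
            (i, j)
            for i in range(len(genes))
            for j in range(i + 1, len(genes))
            if genes[i][0] != genes[j][0]
        }

    hits: list[PairwiseHit] = []
    for i, j in pairs:
        _, genome_i, rec_i = genes[i]
        _, genome_j, rec_j = genes[j]
        aln = local_align(rec_i, rec_j, scheme)
        if aln.is_empty:
            continue
        hits.append(
            hit_from_alignment(
                aln, len(rec_i), db_residues, scheme,
                query_genome=genome_i, subject_genome=genome_j,
            )
        )
        flipped = LocalAlignment(
            query_id=rec_j.id,
            subject_id=rec_i.id,
            score=aln.score,
            query_span=aln.subject_span,
            subject_span=aln.query_span,
            alignment_length=aln.alignment_length,
            identities=aln.identities,
        )
        hits.append(
            hit_from_alignment(
                flipped, len(rec_j), db_residues, scheme,
                query_genome=genome_j, subject_genome=genome_i,
            )
        )
    hits.sort(key=lambda h: (h.query_genome, h.query_id, h.subject_genome, h.subject_id))
    return hits


_HIT_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "alignment_length",
    "identities", "query_start", "query_end", "subject_start", "subject_end",
    "evalue", "bit_score", "percent_query_coverage",
]


def write_hits(hits: Iterable[PairwiseHit], path: str | Path) -> Path:
    """Export hits as 12-column tab-separated text (tabular-BLAST superset)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(_HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id, h.subject_id,
                        f"{h.percent_identity:.3f}", str(h.alignment_length),
                        str(h.identities),
                        str(h.query_span[0]), str(h.query_span[1]),
                        str(h.subject_span[0]), str(h.subject_span[1]),
                        f"{h.evalue:.3g}", f"{h.bit_score:.2f}",
                        f"{h.percent_query_coverage:.3f}",
                    ]
                )
                + "\n"
            )
    return path
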