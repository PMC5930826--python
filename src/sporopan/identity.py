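"""Average amino-acid identity (AAI), fragment-based average nucleotide
identity (ANI), and clade (candidate-species) delimitation.

AAI between two proteomes is the unweighted mean percent identity over
reciprocal-best-hit (RBH) gene pairs, where a best hit must pass PI >= 30 and
PC >= 70 in both directions. AAI >= 95-96% between genomes indicates
conspecificity, and clades are delimited as single-linkage components of the
strain graph thresholded at that cutoff, with an explicit audit of whether
the partition is clean (every within-clade pair above, every between-clade
pair below).

ANI follows the fragment convention: the query genome is chopped into
consecutive 1020-bp windows, each window (and its reverse complement) is
locally aligned to the subject, windows whose best hit passes 30% identity /
70% coverage are retained, and ANI is their mean identity, averaged over both
directions for symmetry.

A pair with no supporting RBH pairs or retained fragments has no signal; the
value is NaN, never 0, and is treated as below any cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .align_engine import (
    PairwiseHit,
    ScoringScheme,
    local_align,
    search_all_vs_all,
)
from .io_formats import GenomeProteome, SequenceRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IdentityMatrix:
    """Symmetric strain-by-strain percent-identity matrix (AAI or ANI).

    Missing (no-signal) pairs are NaN. ``n_pairs_used`` counts the supporting
    RBH pairs or retained fragments per cell.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    kind: str  # "AAI" or "ANI"
    n_pairs_used: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(v), 100.0):
            raise ValueError(f"{self.kind} diagonal must be 100")
        finite = np.isfinite(v)
        if not np.array_equal(v[finite], v.T[finite.T]):
            raise ValueError("matrix must be symmetric")
        if np.any((v[finite] < 0) | (v[finite] > 100)):
            raise ValueError("identities must lie in [0, 100]")

    def value(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.values[ia, ib])


@dataclass(frozen=True)
class CladePartition:
    """Strain clades delimited at an identity cutoff.

    ``is_clean`` is True iff every within-clade pair is >= cutoff and every
    between-clade pair is < cutoff — i.e. the partition does not depend on
    the linkage rule.
    """

    cutoff: float
    clades: tuple[frozenset[str], ...]
    is_clean: bool

    def as_mapping(self) -> dict[str, int]:
        return {label: i for i, clade in enumerate(self.clades) for label in clade}

    @property
    def n_clades(self) -> int:
        return len(self.clades)


def _best_hits_by_genome_pair(
    hits: Iterable[PairwiseHit], pi_min: float, pc_min: float
) -> dict[tuple[str, str], dict[str, PairwiseHit]]:
    """query gene -> best qualifying hit, grouped by (query, subject) genome."""
    best: dict[tuple[str, str], dict[str, PairwiseHit]] = {}
    for h in hits:
        if h.percent_identity < pi_min or h.percent_query_coverage < pc_min:
            continue
        bucket = best.setdefault((h.query_genome, h.subject_genome), {})
        cur = bucket.get(h.query_id)
        if (
            cur is None
            or h.bit_score > cur.bit_score
            or (h.bit_score == cur.bit_score and h.subject_id < cur.subject_id)
        ):
            bucket[h.query_id] = h
    return best


def aai_from_hits(
    hits: Iterable[PairwiseHit],
    genome_ids: Sequence[str],
    rbh_pi_min: float = 30.0,
    rbh_pc_min: float = 70.0,
) -> IdentityMatrix:
    """AAI matrix over genomes from a precomputed all-vs-all hit list."""
    labels = tuple(genome_ids)
    n = len(labels)
    values = np.full((n, n), np.nan)
    counts = np.zeros((n, n), dtype=int)
    np.fill_diagonal(values, 100.0)
    best = _best_hits_by_genome_pair(hits, rbh_pi_min, rbh_pc_min)
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            b = labels[j]
            fwd = best.get((a, b), {})
            rev = best.get((b, a), {})
            identities = []
            for qid, hit in fwd.items():
                back = rev.get(hit.subject_id)
                if back is not None and back.subject_id == qid:
                    identities.append(hit.percent_identity)
            if identities:
                values[i, j] = values[j, i] = float(np.mean(identities))
                counts[i, j] = counts[j, i] = len(identities)
    return IdentityMatrix(labels=labels, values=values, kind="AAI", n_pairs_used=counts)


def compute_aai(
    a: GenomeProteome,
    b: GenomeProteome,
    scheme: ScoringScheme | None = None,
    rbh_pi_min: float = 30.0,
    rbh_pc_min: float = 70.0,
    prefilter: bool = True,
    k: int = 4,
) -> tuple[float, int]:
    """AAI between two proteomes: mean RBH percent identity.

    Returns ``(aai, n_rbh)``; ``aai`` is NaN (the no-signal marker) when no
    reciprocal best-hit pair passes the filters.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("proteomes must be non-empty")
    hits = search_all_vs_all([a, b], scheme=scheme, prefilter=prefilter, k=k)
    m = aai_from_hits(hits, [a.genome_id, b.genome_id], rbh_pi_min, rbh_pc_min)
    return m.values[0, 1], int(m.n_pairs_used[0, 1])


def _fragments(records: Sequence[SequenceRecord], fragment_len: int) -> list[str]:
    frags = []
    for rec in records:
        seq = rec.sequence
        for start in range(0, len(seq), fragment_len):
            frag = seq[start : start + fragment_len]
            if len(frag) >= fragment_len // 3:  # skip tiny contig tails
                frags.append(frag)
    return frags


def _ani_one_direction(
    query: Sequence[SequenceRecord],
    subject: Sequence[SequenceRecord],
    scheme: ScoringScheme,
    fragment_len: int,
    pi_min: float,
    pc_min: float,
) -> tuple[list[float], int]:
    identities = []
    for fi, frag in enumerate(_fragments(query, fragment_len)):
        frag_rec = SequenceRecord(id=f"frag{fi}", sequence=frag, alphabet="dna")
        rc_rec = SequenceRecord(
            id=f"frag{fi}rc", sequence=reverse_complement(frag), alphabet="dna"
        )
        best = None
        for subj in subject:
            for candidate in (frag_rec, rc_rec):
                aln = local_align(candidate, subj, scheme)
                if aln.is_empty:
                    continue
                if best is None or aln.score > best.score:
                    best = aln
        if best is None:
            continue
        pi = 100.0 * best.identities / best.alignment_length
        pc = 100.0 * (best.query_span[1] - best.query_span[0]) / len(frag)
        if pi >= pi_min and pc >= pc_min:
            identities.append(pi)
    return identities, len(identities)


def compute_ani(
    a: Sequence[SequenceRecord],
    b: Sequence[SequenceRecord],
    scheme: ScoringScheme | None = None,
    fragment_len: int = 1020,
    pi_min: float = 30.0,
    pc_min: float = 70.0,
) -> tuple[float, int]:
    """Fragment-based ANI between two nucleotide genomes.

    Both strands are searched (each fragment and its reverse complement), and
    the two directional means are averaged. Returns ``(ani, n_fragments)``;
    NaN with 0 fragments when nothing is retained.
    """
    if not a or not b:
        raise ValueError("genomes must be non-empty")
    scheme = scheme or ScoringScheme.nucleotide_default()
    ids_ab, n_ab = _ani_one_direction(a, b, scheme, fragment_len, pi_min, pc_min)
    ids_ba, n_ba = _ani_one_direction(b, a, scheme, fragment_len, pi_min, pc_min)
    n_used = n_ab + n_ba
    if n_used == 0:
        return math.nan, 0
    means = [np.mean(x) for x in (ids_ab, ids_ba) if x]
    return float(np.mean(means)), n_used


def delimit_clades(m: IdentityMatrix, cutoff: float = 95.0) -> CladePartition:
    """Partition strains into clades at an identity cutoff.

    Clades are single-linkage connected components of the graph with an edge
    wherever identity >= cutoff (missing values count as below cutoff),
    ordered by smallest member label. ``is_clean`` audits whether the result
    is linkage-independent.
    """
    graph = nx.Graph()
    graph.add_nodes_from(m.labels)
    n = len(m.labels)
    for i in range(n):
        for j in range(i + 1, n):
            v = m.values[i, j]
            if np.isfinite(v) and v >= cutoff:
                graph.add_edge(m.labels[i], m.labels[j])
    comps = sorted((sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0])
    clades = tuple(frozenset(c) for c in comps)
    membership = {lab: k for k, c in enumerate(comps) for lab in c}
    clean = True
    for i in range(n):
        for j in range(i + 1, n):
            v = m.values[i, j]
            same = membership[m.labels[i]] == membership[m.labels[j]]
            above = bool(np.isfinite(v) and v >= cutoff)
            if same != above:
                clean = False
    return CladePartition(cutoff=cutoff, clades=clades, is_clean=clean)
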