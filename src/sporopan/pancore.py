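"""Ortholog clustering and core / pan / strain-specific genome analysis.

Hits from the all-vs-all search are filtered by a threshold set (percent
identity, percent query coverage, optional E-value ceiling), the surviving
edges are clustered by single-linkage connected components, and clusters are
classified:

* core cluster — at least one member in every genome;
* strain-specific cluster — all members from a single genome;
* pan-genome size — the total number of clusters, singletons included.

Two canonical threshold sets are exported: ``CORE_THRESHOLDS`` (PI >= 90,
PC >= 90, E <= 1e-4) for the stringent core-genome run and ``PAN_THRESHOLDS``
(PI >= 30, PC >= 70) for the pan-genome run. Thresholds are applied
inclusively, and an edge qualifies when either direction's hit passes (a
"both directions" mode is available).

Genes are addressed by global id ``(genome_id, gene_id)`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .align_engine import PairwiseHit, ScoringScheme, kmer_prefilter, local_align
from .io_formats import GenomeProteome, SequenceRecord

GeneId = tuple[str, str]  # (genome_id, gene_id)


@dataclass(frozen=True)
class ThresholdSet:
    """Similarity cutoffs defining a clustering run."""

    pi_min: float
    pc_min: float
    evalue_max: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.pi_min <= 100 and 0 <= self.pc_min <= 100):
            raise ValueError("pi_min and pc_min must lie in [0, 100]")

    def passes(self, hit: PairwiseHit) -> bool:
        if hit.percent_identity < self.pi_min:
            return False
        if hit.percent_query_coverage < self.pc_min:
            return False
        if self.evalue_max is not None and hit.evalue > self.evalue_max:
            return False
        return True


CORE_THRESHOLDS = ThresholdSet(pi_min=90.0, pc_min=90.0, evalue_max=1e-4)
PAN_THRESHOLDS = ThresholdSet(pi_min=30.0, pc_min=70.0, evalue_max=None)
#: Alternate, relaxed core stringency discussed alongside the 90% run.
ALT_CORE_THRESHOLDS = ThresholdSet(pi_min=75.0, pc_min=90.0, evalue_max=1e-4)


@dataclass(frozen=True)
class GeneCluster:
    """One orthologous gene cluster; paralogs from one genome are allowed."""

    cluster_id: int
    members: Mapping[str, tuple[str, ...]]  # genome_id -> gene ids

    @property
    def n_genomes(self) -> int:
        return len(self.members)

    @property
    def size(self) -> int:
        return sum(len(v) for v in self.members.values())

    def gene_ids(self) -> list[GeneId]:
        return [(g, gid) for g, gids in self.members.items() for gid in gids]


@dataclass(frozen=True)
class ClusterSet:
    """A partition of every input gene into orthologous clusters."""

    clusters: tuple[GeneCluster, ...]
    n_genomes_total: int
    thresholds: ThresholdSet

    def __len__(self) -> int:
        return len(self.clusters)


@dataclass(frozen=True)
class PanCoreSummary:
    core_count: int
    pan_count: int
    strain_specific: Mapping[str, int]

    def as_dict(self) -> dict:
        return {
            "core_count": self.core_count,
            "pan_count": self.pan_count,
            "strain_specific": dict(self.strain_specific),
        }


def build_similarity_graph(
    hits: Iterable[PairwiseHit],
    thresholds: ThresholdSet,
    both_directions: bool = False,
) -> list[tuple[GeneId, GeneId]]:
    """Undirected qualifying edges between genes.

    An edge is kept when at least one direction's hit passes the thresholds
    (or both directions, with ``both_directions=True``). Self-edges are
    excluded.
    """
    passing: set[tuple[GeneId, GeneId]] = set()
    seen_pairs: set[tuple[GeneId, GeneId]] = set()
    directed_pass: set[tuple[GeneId, GeneId]] = set()
    for hit in hits:
        q = (hit.query_genome, hit.query_id)
        s = (hit.subject_genome, hit.subject_id)
        if q == s:
            continue
        key = (min(q, s), max(q, s))
        seen_pairs.add(key)
        if thresholds.passes(hit):
            directed_pass.add((q, s))
    for a, b in seen_pairs:
        fwd = (a, b) in directed_pass
        rev = (b, a) in directed_pass
        if (fwd and rev) if both_directions else (fwd or rev):
            passing.add((a, b))
    return sorted(passing)


def cluster_orthologs(
    edges: Iterable[tuple[GeneId, GeneId]],
    all_genes: Iterable[GeneId],
    thresholds: ThresholdSet,
) -> ClusterSet:
    """Single-linkage connected components over the similarity graph.

    Genes with no qualifying edge become singleton clusters. Cluster ids are
    assigned in ascending order of each component's smallest member gene id.
    """
    all_genes = list(all_genes)
    gene_set = set(all_genes)
    if len(gene_set) != len(all_genes):
        raise ValueError("duplicate gene ids in all_genes")
    graph = nx.Graph()
    graph.add_nodes_from(all_genes)
    for a, b in edges:
        if a not in gene_set or b not in gene_set:
            unknown = a if a not in gene_set else b
            raise ValueError(f"edge references unknown gene {unknown}")
        graph.add_edge(a, b)
    components = sorted(
        (sorted(comp) for comp in nx.connected_components(graph)),
        key=lambda comp: comp[0],
    )
    genomes = sorted({g for g, _ in all_genes})
    clusters = []
    for cid, comp in enumerate(components):
        members: dict[str, list[str]] = {}
        for genome_id, gene_id in comp:
            members.setdefault(genome_id, []).append(gene_id)
        clusters.append(
            GeneCluster(
                cluster_id=cid,
                members={g: tuple(sorted(v)) for g, v in sorted(members.items())},
            )
        )
    return ClusterSet(
        clusters=tuple(clusters),
        n_genomes_total=len(genomes),
        thresholds=thresholds,
    )


def summarize_pancore(cs: ClusterSet) -> PanCoreSummary:
    """Core / pan / strain-specific counts for a cluster set."""
    genomes = sorted({g for c in cs.clusters for g in c.members})
    core = sum(1 for c in cs.clusters if c.n_genomes == cs.n_genomes_total)
    specific = {g: 0 for g in genomes}
    for c in cs.clusters:
        if c.n_genomes == 1:
            (genome_id,) = c.members.keys()
            specific[genome_id] += 1
    return PanCoreSummary(
        core_count=core, pan_count=len(cs.clusters), strain_specific=specific
    )


def core_clusters(cs: ClusterSet) -> list[GeneCluster]:
    return [c for c in cs.clusters if c.n_genomes == cs.n_genomes_total]


def _representative(
    cluster: GeneCluster, genome_id: str, lookup: Mapping[GeneId, SequenceRecord]
) -> SequenceRecord:
    # Longest member wins; ties broken lexicographically by gene id.
    candidates = [lookup[(genome_id, gid)] for gid in cluster.members[genome_id]]
    return min(candidates, key=lambda r: (-len(r), r.id))


def _gene_lookup(
    proteomes: Sequence[GenomeProteome],
) -> dict[GeneId, SequenceRecord]:
    return {
        (p.genome_id, r.id): r for p in proteomes for r in p.records
    }


def concatenate_core(
    cs: ClusterSet, proteomes: Sequence[GenomeProteome]
) -> dict[str, SequenceRecord]:
    """Per-genome concatenation of core-cluster representatives.

    One representative (longest member, ties by gene id) per core cluster per
    genome, concatenated in ascending cluster-id order — the same gene order
    for every genome, suitable for external alignment and tree building.
    """
    cores = core_clusters(cs)
    if not cores:
        raise ValueError("no core clusters to concatenate")
    lookup = _gene_lookup(proteomes)
    out: dict[str, SequenceRecord] = {}
    for prot in proteomes:
        parts = []
        for cluster in sorted(cores, key=lambda c: c.cluster_id):
            if prot.genome_id not in cluster.members:
                raise RuntimeError(
                    f"genome {prot.genome_id!r} missing from core cluster "
                    f"{cluster.cluster_id}"
                )
            parts.append(_representative(cluster, prot.genome_id, lookup).sequence)
        out[prot.genome_id] = SequenceRecord(
            id=prot.genome_id,
            sequence="".join(parts),
            description=f"concatenated core genome ({len(cores)} clusters)",
        )
    return out


def presence_absence_matrix(cs: ClusterSet) -> pd.DataFrame:
    """Binary genomes x clusters matrix; entry 1 iff the genome has a member."""
    genomes = sorted({g for c in cs.clusters for g in c.members})
    cluster_ids = [c.cluster_id for c in sorted(cs.clusters, key=lambda c: c.cluster_id)]
    data = np.zeros((len(genomes), len(cluster_ids)), dtype=int)
    row = {g: i for i, g in enumerate(genomes)}
    for j, c in enumerate(sorted(cs.clusters, key=lambda c: c.cluster_id)):
        for g in c.members:
            data[row[g], j] = 1
    return pd.DataFrame(data, index=genomes, columns=cluster_ids)


def gene_presence_screen(
    reference: Sequence[SequenceRecord],
    proteome: GenomeProteome,
    scheme: ScoringScheme | None = None,
    identity_min: float = 20.0,
    prefilter: bool = True,
    k: int = 4,
) -> pd.DataFrame:
    """Screen a reference protein set (e.g. spore-related genes) for presence.

    For each reference gene the best-scoring local alignment against the
    proteome is found; the gene is flagged present when its best-hit percent
    identity is >= ``identity_min`` (default 20, the relaxed floor used for
    spore-gene detection). Returns a frame indexed by reference gene id with
    columns best_pi, best_pc, best_subject, present.
    """
    if not reference:
        raise ValueError("reference set is empty")
    scheme = scheme or ScoringScheme.protein_default()
    rows = []
    for ref in sorted(reference, key=lambda r: r.id):
        best = None
        for rec in proteome.records:
            if prefilter and not kmer_prefilter(ref, rec, k=k):
                continue
            aln = local_align(ref, rec, scheme)
            if aln.is_empty:
                continue
            if best is None or aln.score > best.score:
                best = aln
        if best is None:
            rows.append((ref.id, np.nan, np.nan, "", False))
        else:
            pi = 100.0 * best.identities / best.alignment_length
            pc = 100.0 * (best.query_span[1] - best.query_span[0]) / len(ref)
            rows.append((ref.id, pi, pc, best.subject_id, pi >= identity_min))
    return pd.DataFrame(
        rows, columns=["reference_id", "best_pi", "best_pc", "best_subject", "present"]
    ).set_index("reference_id")


def write_cluster_table(cs: ClusterSet, path: str | Path) -> Path:
    """Tab-separated (cluster_id, genome_id, gene_id) listing."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("cluster_id\tgenome_id\tgene_id\n")
        for c in sorted(cs.clusters, key=lambda c: c.cluster_id):
            for genome_id, gene_id in c.gene_ids():
                fh.write(f"{c.cluster_id}\t{genome_id}\t{gene_id}\n")
    return path
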