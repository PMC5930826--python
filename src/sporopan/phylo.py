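"""Distance matrices and neighbor-joining trees.

Three distance views of the strain set feed the same tree machinery:

* core-gene distance — ``100 - (length-weighted mean percent identity)`` over
  pairwise alignments of core-cluster representatives;
* accessory distance — Jaccard distance between presence/absence profiles;
* ``100 - AAI``.

Trees are built with Saitou-Nei neighbor joining (exact on additive
matrices; negative branch lengths clamped to zero) and serialized as Newick.
A tree induces a partition of its leaves by single-linkage grouping at a
patristic-distance cutoff, and partitions are compared with the Rand index.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj
from sklearn.metrics import rand_score

from .align_engine import ScoringScheme, local_align
from .io_formats import GenomeProteome
from .identity import CladePartition, IdentityMatrix
from .pancore import ClusterSet, core_clusters, _gene_lookup, _representative

Partition = Mapping[str, int] | CladePartition | Sequence[frozenset[str]]


def core_distance_matrix(
    cs: ClusterSet,
    proteomes: Sequence[GenomeProteome],
    scheme: ScoringScheme | None = None,
) -> DistanceMatrix:
    """Pairwise core-genome distances.

    For each strain pair, every core cluster contributes the percent identity
    of the local alignment of its two representatives, weighted by the mean
    representative length; the distance is ``100 - weighted mean PI``.
    """
    cores = core_clusters(cs)
    if not cores:
        raise ValueError("no core genome: cluster set has no core clusters")
    scheme = scheme or ScoringScheme.protein_default()
    lookup = _gene_lookup(proteomes)
    labels = [p.genome_id for p in proteomes]
    reps = {
        (c.cluster_id, p.genome_id): _representative(c, p.genome_id, lookup)
        for c in cores
        for p in proteomes
    }
    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num = 0.0
            den = 0.0
            for c in cores:
                ra = reps[(c.cluster_id, labels[i])]
                rb = reps[(c.cluster_id, labels[j])]
                aln = local_align(ra, rb, scheme)
                pi = (
                    0.0
                    if aln.is_empty
                    else 100.0 * aln.identities / aln.alignment_length
                )
                w = (len(ra) + len(rb)) / 2.0
                num += w * pi
                den += w
            dist[i, j] = dist[j, i] = 100.0 - num / den
    return DistanceMatrix(dist, ids=labels)


def jaccard_distance_matrix(pa: pd.DataFrame) -> DistanceMatrix:
    """Jaccard distances between binary presence/absence profiles."""
    values = pa.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("presence/absence matrix must be binary")
    if (values.sum(axis=1) == 0).any():
        empty = list(pa.index[values.sum(axis=1) == 0])
        raise ValueError(f"genome(s) with all-zero profiles: {empty}")
    n = values.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = np.sum((values[i] == 1) & (values[j] == 1))
            union = np.sum((values[i] == 1) | (values[j] == 1))
            dist[i, j] = dist[j, i] = 1.0 - inter / union
    return DistanceMatrix(dist, ids=[str(x) for x in pa.index])


def aai_distance_matrix(m: IdentityMatrix) -> DistanceMatrix:
    """``100 - AAI`` distances; missing AAI becomes the maximum distance 100."""
    values = np.where(np.isfinite(m.values), 100.0 - m.values, 100.0)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(values, ids=list(m.labels))


def nj_tree(d: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; negative branch lengths clamped to 0."""
    if len(d.ids) < 3:
        raise ValueError("neighbor joining needs >= 3 labels")
    return nj(d, neg_as_zero=True)


def to_newick(tree: TreeNode) -> str:
    return str(tree).strip()


def tree_partition(tree: TreeNode, cutoff: float) -> dict[str, int]:
    """Partition a tree's leaves by patristic distance.

    Two leaves fall in the same block when they are connected by a chain of
    leaves with pairwise tip-to-tip path distance <= cutoff (single linkage).
    Blocks are numbered by smallest member label.
    """
    dm = tree.tip_tip_distances()
    labels = list(dm.ids)
    parent = {lab: lab for lab in labels}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            if dm[a, labels[j]] <= cutoff:
                parent[find(a)] = find(labels[j])
    blocks: dict[str, list[str]] = {}
    for lab in labels:
        blocks.setdefault(find(lab), []).append(lab)
    ordered = sorted((sorted(v) for v in blocks.values()), key=lambda b: b[0])
    return {lab: k for k, block in enumerate(ordered) for lab in block}


def _as_mapping(p: Partition) -> dict[str, int]:
    if isinstance(p, CladePartition):
        return p.as_mapping()
    if isinstance(p, Mapping):
        return dict(p)
    return {lab: i for i, block in enumerate(p) for lab in block}


def compare_partitions(p1: Partition, p2: Partition) -> float:
    """Rand index: the fraction of label pairs on which two partitions agree."""
    m1, m2 = _as_mapping(p1), _as_mapping(p2)
    if set(m1) != set(m2):
        raise ValueError("partitions cover different label sets")
    labels = sorted(m1)
    if len(labels) < 2:
        return 1.0
    return float(rand_score([m1[x] for x in labels], [m2[x] for x in labels]))
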