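"""End-to-end analysis drivers wiring the modules into the two workflows.

``run_pancore`` — all-vs-all search, ortholog clustering at one threshold
set, core/pan/strain-specific summary, core concatenates, presence/absence
matrix.

``run_species`` — the species-delimitation workflow: AAI matrix with clade
partition at the 95% cutoff, plus three neighbor-joining trees (core-gene
distance, accessory Jaccard distance, 100-AAI) and the partitions they
induce, with a concordance report.

The accessory profile is taken from the stringent (core-threshold) cluster
set rather than the pan-level one: at the stringent identity cutoff gene
families split at the species boundary, so presence/absence carries both
gene-content and family-divergence signal. (With the synthetic generator's
strain-private accessory genes, pan-level profiles are clade-uninformative
by construction; see docs/methods.md.)

Every run produces a machine-readable report (resolved parameters, input
checksums, headline counts) that is byte-identical across reruns on
identical inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .align_engine import ScoringScheme, search_all_vs_all, write_hits
from .identity import aai_from_hits, delimit_clades, CladePartition, IdentityMatrix
from .io_formats import GenomeProteome, write_fasta, write_matrix
from .pancore import (
    CORE_THRESHOLDS,
    PAN_THRESHOLDS,
    ClusterSet,
    PanCoreSummary,
    ThresholdSet,
    build_similarity_graph,
    cluster_orthologs,
    concatenate_core,
    core_clusters,
    presence_absence_matrix,
    summarize_pancore,
    write_cluster_table,
)
from .phylo import (
    aai_distance_matrix,
    compare_partitions,
    core_distance_matrix,
    jaccard_distance_matrix,
    nj_tree,
    to_newick,
    tree_partition,
)


@dataclass(frozen=True)
class RunConfig:
    """Resolved parameters of a pipeline run (fully serialized in reports)."""

    core_thresholds: ThresholdSet = CORE_THRESHOLDS
    pan_thresholds: ThresholdSet = PAN_THRESHOLDS
    rbh_pi_min: float = 30.0
    rbh_pc_min: float = 70.0
    clade_cutoff: float = 95.0
    accessory_cutoff: float = 0.5  # Jaccard patristic cutoff for the accessory tree
    prefilter: bool = True
    prefilter_k: int = 4
    both_directions: bool = False
    seed: int = 0

    def as_dict(self) -> dict:
        d = asdict(self)
        return d


def _input_checksums(proteomes: Sequence[GenomeProteome]) -> dict[str, str]:
    out = {}
    for p in proteomes:
        h = hashlib.sha256()
        for r in p.records:
            h.update(r.id.encode())
            h.update(r.sequence.encode())
        out[p.genome_id] = h.hexdigest()
    return out


def _report(config: RunConfig, proteomes, extra: dict) -> dict:
    return {
        "package": "sporopan",
        "version": __version__,
        "parameters": config.as_dict(),
        "inputs": _input_checksums(proteomes),
        **extra,
    }


@dataclass
class PanCoreResult:
    cluster_set: ClusterSet
    summary: PanCoreSummary
    report: dict


def run_pancore(
    proteomes: Sequence[GenomeProteome],
    thresholds: ThresholdSet | None = None,
    config: RunConfig | None = None,
    scheme: ScoringScheme | None = None,
    outdir: str | Path | None = None,
) -> PanCoreResult:
    """Cluster genes at one threshold set and summarize core/pan content."""
    if len(proteomes) < 2:
        raise ValueError("need >= 2 genomes")
    config = config or RunConfig()
    thresholds = thresholds or config.core_thresholds
    scheme = scheme or ScoringScheme.protein_default()
    hits = search_all_vs_all(
        proteomes, scheme, prefilter=config.prefilter, k=config.prefilter_k
    )
    all_genes = [(p.genome_id, r.id) for p in proteomes for r in p.records]
    edges = build_similarity_graph(hits, thresholds, config.both_directions)
    cs = cluster_orthologs(edges, all_genes, thresholds)
    summary = summarize_pancore(cs)
    report = _report(
        config,
        proteomes,
        {
            "thresholds": asdict(thresholds),
            "n_genomes": len(proteomes),
            "n_genes": len(all_genes),
            "n_hits": len(hits),
            "summary": summary.as_dict(),
        },
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_hits(hits, outdir / "hits.tsv")
        write_cluster_table(cs, outdir / "clusters.tsv")
        pa = presence_absence_matrix(cs)
        pa.to_csv(outdir / "presence_absence.tsv", sep="\t")
        if core_clusters(cs):
            concat = concatenate_core(cs, proteomes)
            write_fasta(
                [concat[p.genome_id] for p in proteomes],
                outdir / "core_concatenates.faa",
            )
        with open(outdir / "pancore_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return PanCoreResult(cluster_set=cs, summary=summary, report=report)


@dataclass
class SpeciesResult:
    aai: IdentityMatrix
    aai_partition: CladePartition
    trees: dict[str, str]  # analysis name -> newick
    tree_partitions: dict[str, dict[str, int]]
    concordant: bool
    pan_summary: PanCoreSummary
    report: dict


def run_species(
    proteomes: Sequence[GenomeProteome],
    config: RunConfig | None = None,
    scheme: ScoringScheme | None = None,
    outdir: str | Path | None = None,
) -> SpeciesResult:
    """AAI clade delimitation plus core / accessory / AAI distance trees."""
    if len(proteomes) < 3:
        raise ValueError("need >= 3 genomes for tree building")
    config = config or RunConfig()
    scheme = scheme or ScoringScheme.protein_default()
    labels = [p.genome_id for p in proteomes]
    all_genes = [(p.genome_id, r.id) for p in proteomes for r in p.records]

    hits = search_all_vs_all(
        proteomes, scheme, prefilter=config.prefilter, k=config.prefilter_k
    )

    # Pan-level clustering: the cluster universe, core clusters for the tree.
    pan_edges = build_similarity_graph(hits, config.pan_thresholds, config.both_directions)
    pan_cs = cluster_orthologs(pan_edges, all_genes, config.pan_thresholds)
    pan_summary = summarize_pancore(pan_cs)

    # Stringent clustering: species-resolved families for the accessory profile.
    core_edges = build_similarity_graph(hits, config.core_thresholds, config.both_directions)
    core_cs = cluster_orthologs(core_edges, all_genes, config.core_thresholds)

    aai = aai_from_hits(hits, labels, config.rbh_pi_min, config.rbh_pc_min)
    aai_partition = delimit_clades(aai, config.clade_cutoff)

    dist_cutoff = 100.0 - config.clade_cutoff
    trees: dict[str, str] = {}
    partitions: dict[str, dict[str, int]] = {}

    core_dm = core_distance_matrix(pan_cs, proteomes, scheme)
    t = nj_tree(core_dm)
    trees["core"] = to_newick(t)
    partitions["core"] = tree_partition(t, dist_cutoff)

    pa = presence_absence_matrix(core_cs)
    acc_dm = jaccard_distance_matrix(pa)
    t = nj_tree(acc_dm)
    trees["accessory"] = to_newick(t)
    partitions["accessory"] = tree_partition(t, config.accessory_cutoff)

    aai_dm = aai_distance_matrix(aai)
    t = nj_tree(aai_dm)
    trees["aai"] = to_newick(t)
    partitions["aai"] = tree_partition(t, dist_cutoff)

    ref = partitions["core"]
    concordant = all(
        compare_partitions(ref, partitions[name]) == 1.0
        for name in ("accessory", "aai")
    )
    missing_pairs = int(np.sum(~np.isfinite(aai.values)))
    report = _report(
        config,
        proteomes,
        {
            "n_genomes": len(proteomes),
            "pan_summary": pan_summary.as_dict(),
            "aai_n_clades": aai_partition.n_clades,
            "aai_is_clean": aai_partition.is_clean,
            "aai_missing_pairs": missing_pairs,
            "partitions_concordant": concordant,
        },
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_matrix(labels, aai.values, outdir / "aai_matrix.tsv")
        with open(outdir / "clades.tsv", "w") as fh:
            fh.write("strain\tclade_id\n")
            for strain, clade in sorted(aai_partition.as_mapping().items()):
                fh.write(f"{strain}\t{clade}\n")
        for name, newick in trees.items():
            (outdir / f"{name}_tree.nwk").write_text(newick + "\n")
        with open(outdir / "species_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return SpeciesResult(
        aai=aai,
        aai_partition=aai_partition,
        trees=trees,
        tree_partitions=partitions,
        concordant=concordant,
        pan_summary=pan_summary,
        report=report,
    )
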