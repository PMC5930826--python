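import itertools
import random

import numpy as np
import pytest

from oracle import transitive_closure_partition
from sporopan.align_engine import PairwiseHit, search_all_vs_all
from sporopan.io_formats import GenomeProteome, SequenceRecord
from sporopan.pancore import (
    CORE_THRESHOLDS,
    PAN_THRESHOLDS,
    ThresholdSet,
    build_similarity_graph,
    cluster_orthologs,
    concatenate_core,
    gene_presence_screen,
    presence_absence_matrix,
    summarize_pancore,
)


def make_hit(q, s, pi=95.0, pc=95.0, ev=1e-10):
    (qg, qi), (sg, si) = q, s
    return PairwiseHit(
        query_id=qi, subject_id=si, query_genome=qg, subject_genome=sg,
        percent_identity=pi, percent_query_coverage=pc, bit_score=100.0, evalue=ev,
    )


def cluster_from_members(members):
    """Build a ClusterSet-like fixture through the public constructor path."""
    genes = [g for block in members for g in block]
    edges = [
        (block[0], g) for block in members for g in block[1:]
    ]
    n_genomes = len({g for g, _ in genes})
    return cluster_orthologs(edges, genes, CORE_THRESHOLDS)


class TestSimilarityGraph:
    def test_passing_hit_kept(self):
        hits = [make_hit(("A", "a1"), ("B", "b1"))]
        assert build_similarity_graph(hits, CORE_THRESHOLDS) == [
            (("A", "a1"), ("B", "b1"))
        ]

    def test_boundary_below_pi_dropped_at_exact_kept(self):
        below = [make_hit(("A", "a1"), ("B", "b1"), pi=89.9)]
        exact = [make_hit(("A", "a1"), ("B", "b1"), pi=90.0)]
        assert build_similarity_graph(below, CORE_THRESHOLDS) == []
        assert len(build_similarity_graph(exact, CORE_THRESHOLDS)) == 1

    def test_either_direction_union_vs_both_directions(self):
        fwd_only = [
            make_hit(("A", "a1"), ("B", "b1"), pi=95),
            make_hit(("B", "b1"), ("A", "a1"), pi=50),
        ]
        assert len(build_similarity_graph(fwd_only, CORE_THRESHOLDS)) == 1
        assert build_similarity_graph(fwd_only, CORE_THRESHOLDS, both_directions=True) == []

    def test_random_tables_match_bruteforce_filter(self):
        rng = random.Random(4)
        genes = [(f"g{i%4}", f"p{i}") for i in range(12)]
        for _ in range(30):
            hits = []
            for _ in range(40):
                q, s = rng.sample(genes, 2)
                if q[0] == s[0]:
                    continue
                hits.append(
                    make_hit(q, s, pi=rng.uniform(0, 100), pc=rng.uniform(0, 100),
                             ev=10 ** rng.uniform(-20, 0))
                )
            got = set(build_similarity_graph(hits, CORE_THRESHOLDS))
            want = set()
            for h in hits:
                if (
                    h.percent_identity >= 90
                    and h.percent_query_coverage >= 90
                    and h.evalue <= 1e-4
                ):
                    q = (h.query_genome, h.query_id)
                    s = (h.subject_genome, h.subject_id)
                    want.add((min(q, s), max(q, s)))
            assert got == want


class TestClustering:
    def test_shared_gene_across_three_genomes(self):
        genes = [("A", "x"), ("B", "x"), ("C", "x")]
        edges = list(itertools.combinations(genes, 2))
        cs = cluster_orthologs(edges, genes, CORE_THRESHOLDS)
        assert len(cs) == 1 and cs.clusters[0].n_genomes == 3

    def test_no_edges_all_singletons(self):
        genes = [("A", f"p{i}") for i in range(5)]
        cs = cluster_orthologs([], genes, CORE_THRESHOLDS)
        assert len(cs) == 5
        assert all(c.size == 1 for c in cs.clusters)

    def test_unknown_gene_in_edge_rejected(self):
        with pytest.raises(ValueError, match="unknown gene"):
            cluster_orthologs([(("A", "x"), ("B", "y"))], [("A", "x")], CORE_THRESHOLDS)

    def test_components_match_transitive_closure_oracle(self):
        rng = random.Random(12)
        for _ in range(25):
            n = rng.randint(5, 50)
            genes = [(f"g{i % 5}", f"p{i}") for i in range(n)]
            edges = []
            for _ in range(rng.randint(0, 2 * n)):
                a, b = rng.sample(genes, 2)
                edges.append((a, b))
            cs = cluster_orthologs(edges, genes, PAN_THRESHOLDS)
            got = {frozenset(c.gene_ids()) for c in cs.clusters}
            want = set(transitive_closure_partition(genes, edges))
            assert got == want

    def test_partition_property(self):
        rng = random.Random(13)
        genes = [(f"g{i % 3}", f"p{i}") for i in range(30)]
        edges = [tuple(rng.sample(genes, 2)) for _ in range(25)]
        cs = cluster_orthologs(edges, genes, PAN_THRESHOLDS)
        all_members = [g for c in cs.clusters for g in c.gene_ids()]
        assert sorted(all_members) == sorted(genes)

    def test_cluster_ids_ordered_by_smallest_member(self):
        genes = [("A", "a"), ("A", "b"), ("B", "z")]
        cs = cluster_orthologs([(("A", "b"), ("B", "z"))], genes, CORE_THRESHOLDS)
        firsts = [min(c.gene_ids()) for c in cs.clusters]
        assert firsts == sorted(firsts)


class TestSummaries:
    def test_core_pan_specific_by_definition(self):
        cs = cluster_from_members(
            [[("A", "x"), ("B", "x"), ("C", "x")], [("A", "y")], [("B", "y")]]
        )
        s = summarize_pancore(cs)
        assert s.core_count == 1 and s.pan_count == 3
        assert s.strain_specific == {"A": 1, "B": 1, "C": 0}

    def test_singletons_from_one_genome_give_no_core(self):
        cs = cluster_from_members([[("A", "x")], [("A", "y")], [("B", "z")]])
        s = summarize_pancore(cs)
        assert s.core_count == 0 and s.pan_count == 3
        assert s.strain_specific == {"A": 2, "B": 1}

    def test_threshold_monotonicity_on_simulated_hits(self, small_family):
        _, proteomes, _ = small_family
        hits = search_all_vs_all(proteomes, prefilter=True, k=4)
        genes = [(p.genome_id, r.id) for p in proteomes for r in p.records]
        summaries = []
        for pi_min in (90, 60, 30):
            thr = ThresholdSet(pi_min=pi_min, pc_min=70)
            cs = cluster_orthologs(build_similarity_graph(hits, thr), genes, thr)
            summaries.append(summarize_pancore(cs))
        for tight, loose in zip(summaries, summaries[1:]):
            assert loose.core_count >= tight.core_count
            assert loose.pan_count <= tight.pan_count

    def test_genome_monotonicity(self, small_family):
        _, proteomes, _ = small_family

        def run(prots):
            hits = search_all_vs_all(prots, prefilter=True, k=4)
            genes = [(p.genome_id, r.id) for p in prots for r in p.records]
            thr = PAN_THRESHOLDS
            return summarize_pancore(
                cluster_orthologs(build_similarity_graph(hits, thr), genes, thr)
            )

        s3 = run(proteomes[:3])
        s4 = run(proteomes)
        assert s4.core_count <= s3.core_count
        assert s4.pan_count >= s3.pan_count

    def test_strain_specific_clusters_have_one_genome(self, small_family):
        _, proteomes, _ = small_family
        hits = search_all_vs_all(proteomes, prefilter=True, k=4)
        genes = [(p.genome_id, r.id) for p in proteomes for r in p.records]
        cs = cluster_orthologs(
            build_similarity_graph(hits, PAN_THRESHOLDS), genes, PAN_THRESHOLDS
        )
        specific_total = sum(summarize_pancore(cs).strain_specific.values())
        singleton_genome_clusters = sum(1 for c in cs.clusters if c.n_genomes == 1)
        assert specific_total == singleton_genome_clusters


class TestConcatenation:
    def _proteomes(self):
        a = GenomeProteome("A", (
            SequenceRecord(id="a1", sequence="M" * 10),
            SequenceRecord(id="a2", sequence="K" * 20),
        ))
        b = GenomeProteome("B", (
            SequenceRecord(id="b1", sequence="M" * 12),
            SequenceRecord(id="b2", sequence="K" * 20),
        ))
        return a, b

    def test_order_and_lengths(self):
        a, b = self._proteomes()
        cs = cluster_from_members(
            [[("A", "a1"), ("B", "b1")], [("A", "a2"), ("B", "b2")]]
        )
        concat = concatenate_core(cs, [a, b])
        assert len(concat["A"].sequence) == 30
        assert len(concat["B"].sequence) == 32
        assert concat["A"].sequence.startswith("M" * 10)
        assert concat["B"].sequence.startswith("M" * 12)

    def test_single_core_cluster_equals_representative(self):
        a, b = self._proteomes()
        cs = cluster_from_members([[("A", "a1"), ("B", "b1")]])
        concat = concatenate_core(cs, [a, b])
        assert concat["A"].sequence == "M" * 10

    def test_zero_divergence_family_gives_identical_concatenates(self):
        from sporopan.synthetic_data import FamilySpec, simulate_family
        spec = FamilySpec(
            n_clades=2, strains_per_clade=(2, 2), core_size=10,
            strain_specific_per_strain=0, gene_length=(60, 40),
            q_between=0.0, q_within=0.0, seed=5,
        )
        proteomes, _ = simulate_family(spec)
        hits = search_all_vs_all(proteomes, prefilter=True, k=4)
        genes = [(p.genome_id, r.id) for p in proteomes for r in p.records]
        cs = cluster_orthologs(
            build_similarity_graph(hits, CORE_THRESHOLDS), genes, CORE_THRESHOLDS
        )
        concat = concatenate_core(cs, proteomes)
        seqs = {c.sequence for c in concat.values()}
        assert len(seqs) == 1

    def test_no_core_clusters_is_error(self):
        a, b = self._proteomes()
        cs = cluster_from_members([[("A", "a1")], [("B", "b1")]])
        with pytest.raises(ValueError, match="no core"):
            concatenate_core(cs, [a, b])


class TestPresenceAbsence:
    def test_columns_rows_and_sums(self):
        cs = cluster_from_members(
            [[("A", "x"), ("B", "x"), ("C", "x")], [("A", "y")], [("B", "y")]]
        )
        pa = presence_absence_matrix(cs)
        assert pa.shape == (3, 3)
        core_col = pa[0]
        assert core_col.tolist() == [1, 1, 1]
        assert pa.to_numpy().sum() == 5
        # strain-specific columns have exactly one presence
        assert sorted(pa[c].sum() for c in pa.columns) == [1, 1, 3]


class TestPresenceScreen:
    def test_identical_gene_present_with_full_identity(self, toy_proteomes):
        a, _ = toy_proteomes
        ref = [SequenceRecord(id="ref1", sequence=a.records[0].sequence)]
        rep = gene_presence_screen(ref, a)
        assert bool(rep.loc["ref1", "present"])
        assert rep.loc["ref1", "best_pi"] == pytest.approx(100.0)

    def test_unmatched_reference_absent(self, toy_proteomes):
        a, _ = toy_proteomes
        ref = [SequenceRecord(id="refx", sequence="W" * 30)]
        rep = gene_presence_screen(ref, a)
        assert not bool(rep.loc["refx", "present"])
        assert np.isnan(rep.loc["refx", "best_pi"])

    def test_flags_match_prefilter_off_recomputation(self, small_family):
        _, proteomes, _ = small_family
        rng = random.Random(21)
        refs = [proteomes[1].records[i] for i in (0, 3, 5)]
        refs = [SequenceRecord(id=f"ref{i}", sequence=r.sequence) for i, r in enumerate(refs)]
        on = gene_presence_screen(refs, proteomes[0], prefilter=True, k=4)
        off = gene_presence_screen(refs, proteomes[0], prefilter=False)
        assert on["present"].tolist() == off["present"].tolist()

    def test_empty_reference_rejected(self, toy_proteomes):
        with pytest.raises(ValueError):
            gene_presence_screen([], toy_proteomes[0])
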