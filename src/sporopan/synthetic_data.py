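"""Simulated proteome families with planted clade structure.

The generator is the statistical stand-in for a set of sequenced strains: a
shared ancestral core proteome, clade roots derived from the ancestor by
per-site substitution at probability ``q_between``, strains derived from
their clade root at ``q_within``, and per-strain unique genes drawn fresh
from the background amino-acid distribution. Defaults mirror the structure
of the 29 cocci-shaped *Sporosarcina* strains: 8 clades with sizes
(3, 1, 3, 5, 2, 5, 5, 5), a 200-gene core, 50 strain-specific genes per
strain, ~1% within-clade and ~12% between-clade per-site divergence.

Under the substitution-only model the expected pairwise identity is analytic:
``100 * (1 - q_within)**2`` within a clade and
``100 * ((1 - q_within) * (1 - q_between))**2`` between clades (independent
substitution layers on both lineages; back-substitutions are a second-order
correction at these rates).

Planted counts are made exact by construction: strain-specific genes are
rejection-sampled to share no 6-mer with any other gene, and whole core
families are redrawn whenever any realized strain copy produces a
pan-threshold-qualifying local alignment against another family (random
proteins occasionally carry long weak chance similarities, so independent
draws alone cannot guarantee the planted partition of genes into clusters).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .io_formats import GenomeProteome, SequenceRecord, write_fasta
from .align_engine import kmer_set

#: Robinson-Robinson background amino-acid frequencies (normalized in code).
BACKGROUND_AA_FREQS = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}

_AA = np.array(sorted(BACKGROUND_AA_FREQS))
_FREQS = np.array([BACKGROUND_AA_FREQS[a] for a in _AA])
_FREQS = _FREQS / _FREQS.sum()
_AA_INDEX = {a: i for i, a in enumerate(_AA)}

_SPECIFIC_SCREEN_K = 6


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one simulated proteome family."""

    n_clades: int = 8
    strains_per_clade: tuple[int, ...] = (3, 1, 3, 5, 2, 5, 5, 5)
    core_size: int = 200
    strain_specific_per_strain: int = 50
    gene_length: tuple[int, int] = (120, 60)  # (mean, min) residues
    q_between: float = 0.12
    q_within: float = 0.01
    indels: bool = False
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clades < 1:
            raise ValueError("need at least one clade")
        if len(self.strains_per_clade) != self.n_clades:
            raise ValueError("strains_per_clade length must equal n_clades")
        if any(s < 1 for s in self.strains_per_clade):
            raise ValueError("every clade needs at least one strain")
        if self.core_size < 0 or self.strain_specific_per_strain < 0:
            raise ValueError("gene counts must be >= 0")
        if not 0 <= self.q_within <= self.q_between <= 1:
            raise ValueError("require 0 <= q_within <= q_between <= 1")
        mean, minimum = self.gene_length
        if not 1 <= minimum <= mean:
            raise ValueError("gene_length requires 1 <= min <= mean")

    @property
    def n_strains(self) -> int:
        return sum(self.strains_per_clade)


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted structure of a simulated family: the recovery-test oracle."""

    partition: dict[str, int]  # strain -> clade index
    planted_core: int
    planted_strain_specific: dict[str, int]
    expected_within_identity: float
    expected_between_identity: float

    def as_dict(self) -> dict:
        return asdict(self)


def random_protein(length: int, rng: np.random.Generator, gene_id: str = "g") -> SequenceRecord:
    """A random protein drawn from the background amino-acid frequencies."""
    if length < 1:
        raise ValueError("length must be >= 1")
    seq = "".join(rng.choice(_AA, size=length, p=_FREQS))
    return SequenceRecord(id=gene_id, sequence=seq, alphabet="protein")


def mutate_sequence(
    s: SequenceRecord, q: float, rng: np.random.Generator
) -> SequenceRecord:
    """Independently substitute each site with probability ``q``.

    A substituted site receives a *different* residue drawn from the
    background distribution renormalized without the current one, so the
    expected identity to the parent is ``100 * (1 - q)``.
    """
    if not 0 <= q <= 1:
        raise ValueError("q must lie in [0, 1]")
    seq = list(s.sequence)
    mask = rng.random(len(seq)) < q
    for i in np.flatnonzero(mask):
        cur = _AA_INDEX.get(seq[i])
        if cur is None:  # X or other non-background letter
            seq[i] = str(rng.choice(_AA, p=_FREQS))
            continue
        probs = _FREQS.copy()
        probs[cur] = 0.0
        probs /= probs.sum()
        seq[i] = str(rng.choice(_AA, p=probs))
    return SequenceRecord(
        id=s.id, sequence="".join(seq), description=s.description, alphabet="protein"
    )


def _apply_indels(
    s: SequenceRecord, rate: float, rng: np.random.Generator
) -> SequenceRecord:
    """Optional indel mode: geometric-length insertions/deletions at ``rate``."""
    out: list[str] = []
    i = 0
    seq = s.sequence
    while i < len(seq):
        r = rng.random()
        if r < rate / 2 and len(seq) > 1:  # deletion
            i += 1 + rng.geometric(0.5) - 1
        elif r < rate:  # insertion
            ins = rng.geometric(0.5)
            out.append("".join(rng.choice(_AA, size=ins, p=_FREQS)))
            out.append(seq[i])
            i += 1
        else:
            out.append(seq[i])
            i += 1
    if not out:
        out = [seq[0]]
    return SequenceRecord(id=s.id, sequence="".join(out), alphabet="protein")


def _gene_lengths(spec: FamilySpec, n: int, rng: np.random.Generator) -> np.ndarray:
    mean, minimum = spec.gene_length
    # Uniform in [min, 2*mean - min]: bounded and mean-preserving.
    return rng.integers(minimum, 2 * mean - minimum + 1, size=n)


def _family_copies(
    spec: FamilySpec, gene_id: str, rng: np.random.Generator
) -> list[SequenceRecord]:
    """One gene family: ancestor -> clade roots -> one copy per strain."""
    L = int(_gene_lengths(spec, 1, rng)[0])
    ancestor = random_protein(L, rng, gene_id=gene_id)
    copies: list[SequenceRecord] = []
    for clade, size in enumerate(spec.strains_per_clade):
        root = mutate_sequence(ancestor, spec.q_between, rng)
        for _ in range(size):
            copy = mutate_sequence(root, spec.q_within, rng)
            if spec.indels and spec.indel_rate > 0:
                copy = _apply_indels(copy, spec.indel_rate, rng)
            copies.append(copy)
    return copies


class _MergeGuard:
    """Certifies that planted families are realized exactly as clusters.

    Two failure modes would silently falsify the planted truth: independently
    drawn families can chain together through long weak chance windows
    (>= 30% identity over most of a short gene), and a short family's
    cross-clade copies can lose every shared 6-mer (or drop below the pan
    cutoffs), splitting the cluster. The guard replays the pipeline's own
    candidate generation — a shared-6-mer index followed by optimal local
    alignment against the pan thresholds — and the generator redraws any
    family that merges with an accepted one or fails to stay connected.
    The no-merge certificate holds for searches run with the same (k=6)
    prefilter; connectivity also holds for smaller k or no prefilter, which
    only add candidate pairs. See docs/methods.md.
    """

    def __init__(self, pi_min: float = 30.0, pc_min: float = 70.0) -> None:
        from .align_engine import ScoringScheme, local_align

        self._local_align = local_align
        self._scheme = ScoringScheme.protein_default()
        self.pi_min = pi_min
        self.pc_min = pc_min
        self._records: list[SequenceRecord] = []
        self._index: dict[str, list[int]] = {}

    def collides(self, copies: list[SequenceRecord]) -> bool:
        for copy in copies:
            candidates: set[int] = set()
            for kmer in kmer_set(copy.sequence, _SPECIFIC_SCREEN_K):
                candidates.update(self._index.get(kmer, ()))
            for idx in candidates:
                other = self._records[idx]
                aln = self._local_align(copy, other, self._scheme)
                if aln.is_empty:
                    continue
                pi = 100.0 * aln.identities / aln.alignment_length
                pc_q = 100.0 * (aln.query_span[1] - aln.query_span[0]) / len(copy)
                pc_s = 100.0 * (aln.subject_span[1] - aln.subject_span[0]) / len(other)
                if pi >= self.pi_min and max(pc_q, pc_s) >= self.pc_min:
                    return True
        return False

    def _qualifies(self, a: SequenceRecord, b: SequenceRecord) -> bool:
        aln = self._local_align(a, b, self._scheme)
        if aln.is_empty:
            return False
        pi = 100.0 * aln.identities / aln.alignment_length
        pc_a = 100.0 * (aln.query_span[1] - aln.query_span[0]) / len(a)
        pc_b = 100.0 * (aln.subject_span[1] - aln.subject_span[0]) / len(b)
        return pi >= self.pi_min and max(pc_a, pc_b) >= self.pc_min

    def connected(self, copies: list[SequenceRecord]) -> bool:
        """True iff the family's copies form one cluster under the pipeline rule.

        A short family can lose every cross-clade shared 6-mer to mutation
        (or drop below the pan cutoffs), splitting the planted cluster; the
        generator redraws such families. Checked with union-find over
        candidate (shared-6-mer) pairs, aligning only until connected.
        """
        n = len(copies)
        if n <= 1:
            return True
        kmers = [kmer_set(c.sequence, _SPECIFIC_SCREEN_K) for c in copies]
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        n_comp = n
        # neighbours first: adjacent strains usually connect immediately
        order = [(i, i + 1) for i in range(n - 1)]
        order += [(i, j) for i in range(n) for j in range(i + 2, n)]
        for i, j in order:
            ri, rj = find(i), find(j)
            if ri == rj:
                continue
            if not (kmers[i] & kmers[j]):
                continue
            if self._qualifies(copies[i], copies[j]):
                parent[ri] = rj
                n_comp -= 1
                if n_comp == 1:
                    return True
        return n_comp == 1

    def accept(self, copies: list[SequenceRecord]) -> None:
        for copy in copies:
            idx = len(self._records)
            self._records.append(copy)
            for kmer in kmer_set(copy.sequence, _SPECIFIC_SCREEN_K):
                self._index.setdefault(kmer, []).append(idx)


def simulate_family(spec: FamilySpec) -> tuple[list[GenomeProteome], SyntheticTruth]:
    """Simulate a proteome family and return it with its planted truth.

    Fully deterministic for a fixed spec (including its seed). The planted
    counts are exact by construction for clustering runs driven by the
    shared-6-mer prefilter: core families are redrawn until no cross-family
    gene pair yields a qualifying pan-level hit, and strain-specific genes
    are rejection-sampled to share no 6-mer with any other gene.
    """
    rng = np.random.default_rng(spec.seed)

    strain_names: list[str] = []
    partition: dict[str, int] = {}
    for clade, size in enumerate(spec.strains_per_clade):
        for _ in range(size):
            name = f"S{len(strain_names) + 1:02d}"
            strain_names.append(name)
            partition[name] = clade

    guard = _MergeGuard()
    core_by_strain: dict[str, list[SequenceRecord]] = {n: [] for n in strain_names}
    all_kmers: set[str] = set()
    for fam in range(spec.core_size):
        while True:
            copies = _family_copies(spec, f"core{fam:04d}", rng)
            if guard.connected(copies) and not guard.collides(copies):
                break
        guard.accept(copies)
        for name, copy in zip(strain_names, copies):
            core_by_strain[name].append(copy)
            all_kmers |= kmer_set(copy.sequence, _SPECIFIC_SCREEN_K)

    proteomes: list[GenomeProteome] = []
    planted_specific: dict[str, int] = {}
    for name in strain_names:
        records = list(core_by_strain[name])
        n_specific = spec.strain_specific_per_strain
        made = 0
        while made < n_specific:
            L = int(_gene_lengths(spec, 1, rng)[0])
            cand = random_protein(L, rng, gene_id=f"uniq{made:04d}")
            kmers = kmer_set(cand.sequence, _SPECIFIC_SCREEN_K)
            if kmers & all_kmers:
                continue
            all_kmers |= kmers
            records.append(cand)
            made += 1
        planted_specific[name] = n_specific
        proteomes.append(GenomeProteome(genome_id=name, records=tuple(records)))

    within = 100.0 * (1.0 - spec.q_within) ** 2
    between = 100.0 * ((1.0 - spec.q_within) * (1.0 - spec.q_between)) ** 2
    truth = SyntheticTruth(
        partition=partition,
        planted_core=spec.core_size,
        planted_strain_specific=planted_specific,
        expected_within_identity=within,
        expected_between_identity=between,
    )
    return proteomes, truth


def write_family(
    proteomes: list[GenomeProteome], truth: SyntheticTruth, outdir: str | Path
) -> Path:
    """Write one FASTA per strain plus the truth as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for prot in proteomes:
        write_fasta(prot.records, outdir / f"{prot.genome_id}.faa")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.as_dict(), fh, indent=2, sort_keys=True)
    return outdir
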