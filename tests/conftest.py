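import random

import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from sporopan.align_engine import ScoringScheme
from sporopan.io_formats import GenomeProteome, SequenceRecord
from sporopan.synthetic_data import FamilySpec, simulate_family

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_protein_str(rng: random.Random, lo: int = 10, hi: int = 40) -> str:
    return "".join(rng.choice(AA20) for _ in range(rng.randint(lo, hi)))


@pytest.fixture(scope="session")
def protein_scheme() -> ScoringScheme:
    return ScoringScheme.protein_default()


@pytest.fixture(scope="session")
def small_family():
    """A 2-clade, 4-strain family small enough for exhaustive checking."""
    spec = FamilySpec(
        n_clades=2,
        strains_per_clade=(2, 2),
        core_size=12,
        strain_specific_per_strain=4,
        gene_length=(90, 50),
        q_between=0.12,
        q_within=0.01,
        seed=11,
    )
    proteomes, truth = simulate_family(spec)
    return spec, proteomes, truth


@pytest.fixture
def toy_proteomes():
    """Two tiny hand-written proteomes with an identical shared gene."""
    shared = "MKVLAWETTQRGNDFHIKPLMSAVYWCHE"
    a = GenomeProteome(
        genome_id="gA",
        records=(
            SequenceRecord(id="a1", sequence=shared),
            SequenceRecord(id="a2", sequence="MWWCHHKKPPLRSTNDAAEE"),
        ),
    )
    b = GenomeProteome(
        genome_id="gB",
        records=(
            SequenceRecord(id="b1", sequence=shared),
            SequenceRecord(id="b2", sequence="CCNNDDWWHHMMYYFFRRSS"),
        ),
    )
    return a, b
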