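import pytest

from mitoprofile.seq_io import load_feature_template
from mitoprofile.simulate import GenomeSpec, MutationSpec, generate_genome, simulate_haplotypes


@pytest.fixture(scope="session")
def template():
    return load_feature_template()


@pytest.fixture(scope="session")
def synthetic_genome():
    """Default synthetic mitogenome (bundled layout, all plants), seed 1."""
    return generate_genome(GenomeSpec(seed=1))


@pytest.fixture(scope="session")
def synthetic_alignment(synthetic_genome):
    genome, _ = synthetic_genome
    return simulate_haplotypes(genome, MutationSpec(seed=1))


@pytest.fixture(scope="session")
def plain_spec():
    """A bare 2 kb genome spec: no features, no plants (fast simulations)."""

    def make(seed: int, length: int = 2000) -> GenomeSpec:
        return GenomeSpec(
            length=length,
            feature_template=[],
            planted_elements=[],
            plant_cr_motifs=False,
            seed=seed,
        )

    return make
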