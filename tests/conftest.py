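import warnings

import pytest

from kinomeprio.feature_build import build_feature_matrix
from kinomeprio.synthetic_kinome import (
    SimConfig,
    generate_kinome,
    generate_labeled_mutations,
)

# scikit-learn convergence chatter from small-sample fits is irrelevant noise
warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
warnings.filterwarnings("ignore", message=".*did not converge.*")


@pytest.fixture(scope="session")
def small_cfg():
    """A reduced synthetic kinome: quick to generate, still class-separable."""
    return SimConfig(
        n_groups=2, families_per_group=2, genes_per_family=3,
        seqs_per_family_alignment=12, seqs_per_group_alignment=14,
        seqs_per_all_alignment=16, domain_length=120,
        n_positives=40, n_negatives=60, seed=7,
    )


@pytest.fixture(scope="session")
def small_kinome(small_cfg):
    return generate_kinome(small_cfg)


@pytest.fixture(scope="session")
def small_resources(small_kinome):
    return small_kinome.resources()


@pytest.fixture(scope="session")
def small_mutations(small_cfg, small_kinome):
    return generate_labeled_mutations(small_cfg, small_kinome)


@pytest.fixture(scope="session")
def small_matrix(small_mutations, small_resources):
    return build_feature_matrix(small_mutations, small_resources)
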