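import numpy as np
import pytest

from mcpdiv.synthetic_data import CommunitySpec, default_study_specs, generate_study


@pytest.fixture(scope="session")
def small_study():
    """Small two-biome study reused by clustering/diversity/pipeline tests."""
    specs = default_study_specs(reads_per_sample=250, n_dominant=8, seed=11)
    return generate_study(specs, seed=11, n_shared_rare=6, shared_rare_reads=10)


@pytest.fixture(scope="session")
def small_study_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("study")
    specs = default_study_specs(reads_per_sample=250, n_dominant=8, seed=11)
    generate_study(specs, seed=11, n_shared_rare=6, shared_rare_reads=10, out_dir=out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def flat_spec():
    """Mild-skew, no-pinned-singleton community for exact recovery checks."""
    return CommunitySpec(
        sample="S",
        n_haplotypes=10,
        lognormal_sigma=0.5,
        singleton_fraction=0.0,
        low_quality_fraction=0.0,
        reads_per_sample=500,
        seed=5,
    )
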