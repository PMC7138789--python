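import numpy as np
import pytest

from microrep import ProfileKind, ProfileMatrix, SyntheticSpec, generate_synthetic


@pytest.fixture(scope="session")
def small_marker():
    """Small marker cohort with clear planted signal."""
    spec = SyntheticSpec(
        n_samples=120, n_features=200, latent_dim=4, effect_size=3.0,
        kind=ProfileKind.MARKER, seed=42,
    )
    return generate_synthetic(spec)


@pytest.fixture(scope="session")
def small_abundance():
    spec = SyntheticSpec(
        n_samples=100, n_features=150, latent_dim=4, effect_size=2.0,
        kind=ProfileKind.ABUNDANCE, seed=7,
    )
    return generate_synthetic(spec)


@pytest.fixture(scope="session")
def rank_k_matrix():
    """Exactly rank-4 real matrix for linear-autoencoder recovery checks."""
    rng = np.random.default_rng(3)
    return rng.normal(size=(150, 4)) @ rng.normal(size=(4, 60))


@pytest.fixture
def tiny_profile_file(tmp_path):
    path = tmp_path / "tiny.csv"
    path.write_text(
        "sample_id,f1,f2\n"
        "s1,0,1\n"
        "s2,1,1\n"
        "s3,0,0\n"
    )
    return path
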