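import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_profiles(rng):
    """30 random binary gene profiles over 40 species (no planted structure)."""
    mat = rng.integers(0, 2, size=(30, 40)).astype("int8")
    return pd.DataFrame(
        mat,
        index=[f"g{i:02d}" for i in range(30)],
        columns=[f"s{j:02d}" for j in range(40)],
    )


@pytest.fixture
def planted_profiles():
    """Small planted-module profile with its truth."""
    from atpmod.simulate import atp_profile_spec, simulate_profiles

    spec = atp_profile_spec(n_species=400, flip_noise=0.05, seed=7)
    return simulate_profiles(spec)


@pytest.fixture
def small_genome_sim():
    from atpmod.simulate import GenomeSimSpec, simulate_genomes

    spec = GenomeSimSpec(n_genomes=120, seed=11)
    return simulate_genomes(spec)
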