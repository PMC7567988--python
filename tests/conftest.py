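import numpy as np
import pytest
from hypothesis import settings

from metapred import FixtureSpec, SSProfile, generate_dataset

# reproducible property tests: derive examples from the test body, not a RNG
settings.register_profile("deterministic", derandomize=True, max_examples=100)
settings.load_profile("deterministic")


def make_profile(probs, identifier="test", residues=None):
    probs = np.asarray(probs, dtype=float)
    if residues is None:
        residues = ["X"] * probs.shape[0]
    return SSProfile(
        identifier=identifier,
        residues=residues,
        probs=probs,
        source_program="synthetic",
    )


def random_simplex_profile(rng, length, identifier="random"):
    return make_profile(rng.dirichlet(np.ones(3), size=length), identifier=identifier)


@pytest.fixture(scope="session")
def separable_dataset():
    """The default synthetic study conditions: 50 metamorphic + 50
    monomorphic profiles, background DI ~1.1, one 20-residue segment at
    DI 2.8 per metamorphic sequence."""
    return generate_dataset(FixtureSpec(seed=7))
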