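import numpy as np
import pytest

from nannotraits import gen_ground_truth_bundle, reconstruct_communities
from nannotraits.synthetic import make_ground_truth


@pytest.fixture(scope="session")
def truth():
    return make_ground_truth("U1553-like")


@pytest.fixture(scope="session")
def bundle():
    """One fixed-seed synthetic input bundle shared across the suite."""
    return gen_ground_truth_bundle("U1553-like", seed=1)


@pytest.fixture(scope="session")
def reconstruction(bundle):
    recons, dists = reconstruct_communities(
        bundle.coccospheres,
        bundle.lith_samples,
        bundle.assemblages,
        bundle.registry,
        bundle.age_model,
    )
    return recons, dists


@pytest.fixture
def rng():
    return np.random.default_rng(42)
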