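import numpy as np
import pytest

from gutspulse.estimators import GutsModel
from gutspulse.synthetic import make_benchmark


@pytest.fixture(scope="session")
def toy_bundle():
    """Single-substance toy data bundle with known ground truth."""
    return make_benchmark("toy", seed=42)


@pytest.fixture(scope="session")
def toy_fit(toy_bundle):
    """A small variational fit of the generating variant to the toy bundle."""
    est = GutsModel(
        variant="guts_rna_pulse",
        sharing="specific",
        engine="variational",
        n_starts=2,
        draws=400,
        seed=7,
        scaling=toy_bundle.truth.scaling,
        maxiter=250,
    )
    est.fit(toy_bundle.observations)
    return est


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
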