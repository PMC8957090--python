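import tempfile

import numpy as np
import pytest
from hypothesis import configuration
from hypothesis import HealthCheck, settings

# keep hypothesis' scratch storage (example DB, constants cache) out of the repo
configuration.set_hypothesis_home_dir(tempfile.mkdtemp(prefix="hypothesis-"))

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    database=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def random_panel(rng, n_haps, n_snps, span=50_000):
    """Random segregating binary haplotype panel with sorted unique positions."""
    from selsig.containers import HaplotypePanel

    while True:
        H = rng.integers(0, 2, size=(n_haps, n_snps)).astype(np.uint8)
        counts = H.sum(axis=0)
        if np.all((counts > 0) & (counts < n_haps)):
            break
    pos = np.sort(rng.choice(np.arange(1, span + 1), size=n_snps, replace=False))
    return HaplotypePanel(H, pos, phased=True)
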