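import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from plda import MutationCatalog, SignatureSet, make_surrogate_signatures

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_catalog() -> MutationCatalog:
    """3 samples over 2 tumor types with small hand-chosen counts."""
    rng = np.random.default_rng(7)
    counts = np.zeros((3, 96), dtype=np.int64)
    counts[0, :6] = [5, 3, 0, 2, 0, 1]
    counts[1, 90:] = [1, 0, 4, 0, 2, 3]
    counts[2, 40:44] = [2, 2, 2, 2]
    del rng
    return MutationCatalog.from_samples(
        ["s1", "s2", "s3"], ["Liver-HCC", "Liver-HCC", "Skin-Melanoma"], counts
    )


@pytest.fixture(scope="session")
def surrogate5() -> SignatureSet:
    """Five well-separated sparse signatures (pairwise cosine distance >= 0.6)."""
    return make_surrogate_signatures(5, 0.6, seed=11)


@pytest.fixture(scope="session")
def disjoint_signatures() -> SignatureSet:
    """Two signatures with disjoint support: uniform over types 0-47 and 48-95."""
    probs = np.zeros((2, 96))
    probs[0, :48] = 1 / 48
    probs[1, 48:] = 1 / 48
    return SignatureSet(names=("left", "right"), probs=probs)
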