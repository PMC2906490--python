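import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20100617)


@pytest.fixture
def toy_fasta(tmp_path):
    """A tiny valid 3-sequence alignment on disk."""
    path = tmp_path / "toy.fasta"
    path.write_text(">a\nACDE\n>b\nAC-E\n>c\nACQE\n")
    return path


@pytest.fixture
def random_alignment():
    """Seeded 20 x 6 alignment over the full alphabet for oracle tests."""
    from coevomi import Alignment

    r = np.random.default_rng(7)
    codes = r.integers(0, 22, size=(20, 6), dtype=np.uint8)
    return Alignment(ids=[f"s{i}" for i in range(20)], codes=codes)
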