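import numpy as np
import pytest

from rankbank.otu_io import OtuTable


@pytest.fixture
def toy_table() -> OtuTable:
    return OtuTable(
        sample_ids=["S1", "S2"],
        otu_ids=["Otu0001", "Otu0002", "Otu0003"],
        counts=np.array([[5, 0, 1], [0, 2, 2]]),
    )


@pytest.fixture
def shared_text() -> str:
    return (
        "label\tGroup\tnumOtus\tOtu0001\tOtu0002\tOtu0003\n"
        "0.03\tS1\t3\t5\t0\t1\n"
        "0.03\tS2\t3\t0\t2\t2\n"
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_table(rng: np.random.Generator, n_samples: int = 6, n_otus: int = 20,
                 depth: int = 500) -> OtuTable:
    """Random multinomial count table (helper for property-ish tests)."""
    counts = np.vstack(
        [rng.multinomial(depth, rng.dirichlet(np.ones(n_otus)))
         for _ in range(n_samples)]
    )
    counts[:, 0] += 1  # guard against zero-sum rows
    return OtuTable(
        sample_ids=[f"S{i}" for i in range(n_samples)],
        otu_ids=[f"Otu{j:04d}" for j in range(n_otus)],
        counts=counts,
    )
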