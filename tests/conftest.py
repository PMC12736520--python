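import numpy as np
import pytest

from delimetrics.core_io import Alignment, DistanceMatrix, Taxonomy


@pytest.fixture
def tiny_alignment() -> Alignment:
    return Alignment(
        ("a1", "a2", "b1", "b2"),
        (
            "ACGTACGTAC",
            "ACGTACGTAT",
            "ACGTTTTTAC",
            "ACGTTTTTAT",
        ),
    )


@pytest.fixture
def two_species_taxonomy() -> Taxonomy:
    return Taxonomy({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})


def random_distance_matrix(n: int, rng: np.random.Generator) -> DistanceMatrix:
    """A random symmetric hollow matrix (not necessarily metric)."""
    vals = rng.uniform(0.01, 1.0, size=(n, n))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(tuple(f"s{i}" for i in range(n)), vals)
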