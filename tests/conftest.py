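import numpy as np
import pytest

from cldmerge import CLD, MergedMatrix, reference_scores


@pytest.fixture
def chain_clds():
    """A single a->b->c chain diagram with positive links."""
    return CLD("c1", links=[("a", "b", 1), ("b", "c", 1)])


@pytest.fixture
def chain_matrix():
    """Merged matrix of the chain a->b->c with unit counts."""
    cells = np.array([[0, 1, 0], [0, 0, 1], [0, 0, 0]])
    return MergedMatrix(index=("a", "b", "c"), cells=cells, n_clds=1)


@pytest.fixture(scope="session")
def ref_scores():
    """The bundled published 23-variable ranking as DematelScores."""
    return reference_scores()


def random_direct_matrix(rng, n_max=12, density=0.35, max_count=5, rho_max=0.85):
    """Random non-negative integer influence matrix with a comfortably
    sub-critical spectral radius after max-normalisation (so a 200-term
    power series converges far below the comparison tolerance)."""
    while True:
        n = int(rng.integers(2, n_max + 1))
        cells = rng.integers(0, max_count + 1, size=(n, n)) * (
            rng.random((n, n)) < density)
        np.fill_diagonal(cells, 0)
        if not cells.any():
            continue
        s = max(cells.sum(axis=1).max(), cells.sum(axis=0).max())
        rho = np.abs(np.linalg.eigvals(cells / s)).max()
        if rho <= rho_max:
            return cells.astype(float)
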