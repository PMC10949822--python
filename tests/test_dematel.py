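import numpy as np
import pytest

from cldmerge import (CLD, DirectInfluenceMatrix, MergedMatrix, dematel_scores,
                      merge, scatter_export, strip_polarity)
from cldmerge.dematel import DematelError

from conftest import random_direct_matrix


def _series_total_relation(D, terms=200):
    """Independent oracle: truncated Neumann series sum_{k=1..terms} D^k."""
    T = np.zeros_like(D)
    P = np.eye(D.shape[0])
    for _ in range(terms):
        P = P @ D
        T += P
    return T


class TestStripPolarity:
    def test_absolute_values_and_signs_retained(self):
        merged = merge([CLD(f"c{i}", links=[("a", "b", -1), ("b", "c", 1)])
                        for i in range(3)])
        direct = strip_polarity(merged)
        assert direct.cells[direct.index.index("a"), direct.index.index("b")] == 3
        assert (direct.cells >= 0).all()
        assert np.array_equal(direct.signs, np.sign(merged.cells))

    def test_all_positive_matrix_unchanged(self):
        merged = merge([CLD("c", links=[("a", "b", 1)])])
        assert np.array_equal(strip_polarity(merged).cells, np.abs(merged.cells))

    def test_mixed_signs_random_matrix(self):
        rng = np.random.default_rng(3)
        cells = rng.integers(-5, 6, size=(9, 9))
        np.fill_diagonal(cells, 0)
        merged = MergedMatrix(index=tuple(f"v{i}" for i in range(9)),
                              cells=cells, n_clds=5)
        assert np.array_equal(strip_polarity(merged).cells, np.abs(cells))


class TestDematelScores:
    def test_chain_closed_form(self, chain_matrix):
        """a->b->c with unit counts: D nilpotent, T = D + D^2 exactly."""
        scores = dematel_scores(strip_polarity(chain_matrix))
        assert np.allclose(scores.R, [2, 1, 0])
        assert np.allclose(scores.C, [0, 1, 2])
        assert np.allclose(scores.prominence, [2, 2, 2])
        assert np.allclose(scores.relation, [2, 0, -2])

    def test_single_edge_influencer_and_receiver(self):
        merged = merge([CLD("c", links=[("a", "b", 1)])])
        scores = dematel_scores(strip_polarity(merged))
        frame = scores.frame.set_index("variable")
        assert frame.loc["a", "relation"] == pytest.approx(1.0)
        assert frame.loc["b", "relation"] == pytest.approx(-1.0)
        assert np.allclose(frame["prominence"], 1.0)

    def test_symmetric_matrix_zero_relation(self):
        rng = np.random.default_rng(5)
        A = rng.integers(0, 4, size=(7, 7)).astype(float)
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        d = DirectInfluenceMatrix(index=tuple(f"v{i}" for i in range(7)), cells=A)
        scores = dematel_scores(d)
        assert np.allclose(scores.relation, 0.0, atol=1e-10)

    def test_all_zero_matrix_rejected(self):
        d = DirectInfluenceMatrix(index=("a", "b"), cells=np.zeros((2, 2)))
        with pytest.raises(DematelError, match="all-zero"):
            dematel_scores(d)

    def test_prominence_dominates_relation(self):
        rng = np.random.default_rng(11)
        cells = random_direct_matrix(rng)
        d = DirectInfluenceMatrix(index=tuple(map(str, range(len(cells)))),
                                  cells=cells)
        scores = dematel_scores(d)
        assert (scores.prominence >= np.abs(scores.relation) - 1e-12).all()

    def test_scale_invariance(self):
        rng = np.random.default_rng(13)
        cells = random_direct_matrix(rng)
        labels = tuple(map(str, range(len(cells))))
        base = dematel_scores(DirectInfluenceMatrix(index=labels, cells=cells))
        scaled = dematel_scores(DirectInfluenceMatrix(index=labels,
                                                      cells=cells * 17.3))
        assert np.allclose(base.R, scaled.R) and np.allclose(base.C, scaled.C)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(17)
        cells = random_direct_matrix(rng, n_max=8)
        n = len(cells)
        labels = tuple(f"v{i}" for i in range(n))
        perm = rng.permutation(n)
        base = dematel_scores(DirectInfluenceMatrix(index=labels, cells=cells))
        permuted = dematel_scores(DirectInfluenceMatrix(
            index=tuple(labels[i] for i in perm),
            cells=cells[np.ix_(perm, perm)]))
        assert np.allclose(base.R[perm], permuted.R)
        assert np.allclose(base.C[perm], permuted.C)

    def test_row_normalisation_variant_runs(self, chain_matrix):
        scores = dematel_scores(strip_polarity(chain_matrix), normalisation="row")
        assert np.allclose(scores.relation.sum(), 0.0, atol=1e-12)

    def test_near_singular_damps_with_warning(self):
        # a 2-cycle with equal weights drives the spectral radius to 1
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        d = DirectInfluenceMatrix(index=("a", "b"), cells=A)
        with pytest.warns(UserWarning, match="damping"):
            scores = dematel_scores(d)
        assert np.isfinite(scores.R).all()


class TestScatterExport:
    def test_chain_rows_sorted(self, chain_matrix):
        scores = dematel_scores(strip_polarity(chain_matrix))
        table = scatter_export(scores)
        assert list(table["variable"]) == ["a", "b", "c"]
        assert np.allclose(table["relation"], [2, 0, -2])

    def test_reference_tie_broken_by_relation(self, ref_scores):
        table = scatter_export(ref_scores)
        fin = table.index[table["variable"] == "Financial security"][0]
        edu = table.index[table["variable"] == "Education and training"][0]
        assert fin < edu  # equal prominence 1.99; 0.97 relation sorts first

    def test_rank_matches_published_order(self, ref_scores):
        ranked = ref_scores.ranked()
        assert list(ranked["variable"][:2]) == ["Mental health",
                                                "Social connection & support"]
        assert list(ranked["rank"]) == list(range(1, 24))
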