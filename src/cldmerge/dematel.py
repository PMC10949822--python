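"""DEMATEL ranking of merged-diagram variables.

DEMATEL (Decision-Making Trial and Evaluation Laboratory) converts a
non-negative direct-influence matrix A into a total-relation matrix that
accumulates direct and all indirect influence:

    D = A / s,        s = max(max row sum, max column sum)
    T = D (I - D)^-1  (equivalently the Neumann series sum_{k>=1} D^k)

Row sums R of T measure influence a variable dispatches, column sums C
influence it receives.  Prominence R + C ("net importance") ranks
variables by overall involvement; relation R - C is positive for net
influencers (causes) and negative for net receivers (effects).

The method needs all influence values non-negative, so link polarity is
stripped (absolute merged counts) before the analysis and restored from
the signed merged matrix afterwards.

A word on naming: here R always denotes dispatched influence (row sums)
and C received influence (column sums), so a positive R - C marks a net
influencer.  Published prose sometimes attaches the letters the other way
round; the semantics used here are the ones that make "highest R - C" and
"highest net influencer" coincide.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CLDError
from .merging import MergedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DematelError",
    "DirectInfluenceMatrix",
    "DematelScores",
    "strip_polarity",
    "dematel_scores",
    "scatter_export",
]


class DematelError(CLDError):
    """Raised for degenerate inputs (all-zero matrix, negative cells)."""


@dataclass
class DirectInfluenceMatrix:
    """Non-negative influence strengths with the signed source retained.

    ``cells`` are absolute merged counts; ``signs`` (optional) remembers the
    polarity of each link so it can be restored after the unsigned analysis.
    """

    index: tuple[str, ...]
    cells: np.ndarray = field(repr=False)
    signs: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=float)
        n = len(self.index)
        if self.cells.shape != (n, n):
            raise ValueError("cells must be square and match the index")
        if (self.cells < 0).any():
            raise DematelError("direct-influence cells must be non-negative")
        if np.diagonal(self.cells).any():
            raise DematelError("direct-influence diagonal must be zero")


def strip_polarity(m: MergedMatrix) -> DirectInfluenceMatrix:
    """Drop link polarity (absolute counts) ahead of the DEMATEL analysis."""
    return DirectInfluenceMatrix(index=m.index, cells=np.abs(m.cells),
                                 signs=np.sign(m.cells))


@dataclass
class DematelScores:
    """Per-variable DEMATEL scores and ranking.

    ``frame`` columns: R (dispatched), C (received), prominence (R + C),
    relation (R - C), rank (1 = most prominent; ties broken by relation
    descending, then label).  ``frequency`` optionally carries the number
    of constituent diagrams each variable appeared in.
    """

    index: tuple[str, ...]
    R: np.ndarray = field(repr=False)
    C: np.ndarray = field(repr=False)
    total_relation: np.ndarray | None = field(default=None, repr=False)
    frequency: dict[str, int] | None = None

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if not (len(self.index) == len(self.R) == len(self.C)):
            raise ValueError("index, R and C must have equal length")

    @property
    def prominence(self) -> np.ndarray:
        return self.R + self.C

    @property
    def relation(self) -> np.ndarray:
        return self.R - self.C

    @property
    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "variable": list(self.index),
            "R": self.R,
            "C": self.C,
            "prominence": self.prominence,
            "relation": self.relation,
        })
        order = df.sort_values(
            by=["prominence", "relation", "variable"],
            ascending=[False, False, True],
            key=lambda col: col.str.casefold() if col.name == "variable" else col,
        ).index
        df["rank"] = pd.Series(range(1, len(df) + 1), index=order)
        return df

    def ranked(self) -> pd.DataFrame:
        return self.frame.sort_values("rank").reset_index(drop=True)

    def prominence_of(self, label: str) -> float:
        return float(self.frame.set_index("variable").loc[label, "prominence"])

    @classmethod
    def from_prominence_relation(cls, variables, prominence, relation,
                                 frequency=None) -> "DematelScores":
        """Reconstruct scores from published (prominence, relation) pairs.

        R = (prominence + relation) / 2 and C = (prominence - relation) / 2;
        used to load reference rankings that print only R + C and R - C.
        """
        prominence = np.asarray(prominence, dtype=float)
        relation = np.asarray(relation, dtype=float)
        return cls(index=tuple(variables),
                   R=(prominence + relation) / 2.0,
                   C=(prominence - relation) / 2.0,
                   frequency=dict(frequency) if frequency is not None else None)


def dematel_scores(d: DirectInfluenceMatrix, *, normalisation: str = "max",
                   damping_eps: float = 1e-6,
                   condition_limit: float = 1e12) -> DematelScores:
    """Compute total-relation scores for a direct-influence matrix.

    Parameters
    ----------
    d : DirectInfluenceMatrix
        Non-negative, zero-diagonal, at least one nonzero cell.
    normalisation : {"max", "row"}
        ``"max"`` divides by max(max row sum, max column sum) — the dominant
        convention, guaranteeing spectral radius <= 1.  ``"row"`` divides by
        the max row sum only, provided for comparison.
    damping_eps : float
        When I - D is singular or too ill-conditioned (strongly cyclic
        merged diagrams can push the spectral radius to 1), D is rescaled
        by (1 - damping_eps) and a warning is emitted rather than failing.
    """
    A = d.cells
    if not A.any():
        raise DematelError("all-zero direct-influence matrix: nothing to rank")
    if normalisation == "max":
        s = float(max(A.sum(axis=1).max(), A.sum(axis=0).max()))
    elif normalisation == "row":
        s = float(A.sum(axis=1).max())
    else:
        raise ValueError(f"unknown normalisation {normalisation!r}")
    D = A / s

    n = D.shape[0]
    eye = np.eye(n)
    M = eye - D
    cond = np.inf
    try:
        cond = np.linalg.cond(M)
    except np.linalg.LinAlgError:  # pragma: no cover - cond rarely raises
        pass
    needs_damping = not np.isfinite(cond) or cond > condition_limit
    if needs_damping:
        warnings.warn(
            f"I - D is singular or ill-conditioned (cond ~ {cond:.3g}); "
            f"damping D by (1 - {damping_eps:g})", stacklevel=2)
        D = D * (1.0 - damping_eps)
        M = eye - D

    # T = D (I - D)^-1; solve M^T X^T = D^T instead of forming the inverse
    T = np.linalg.solve(M.T, D.T).T
    R = T.sum(axis=1)
    C = T.sum(axis=0)
    return DematelScores(index=d.index, R=R, C=C, total_relation=T)


def scatter_export(scores: DematelScores) -> pd.DataFrame:
    """Table of (variable, prominence, relation) for the cut-point scatter plot.

    Sorted by prominence descending, ties broken by relation descending then
    label, matching the ranking order.
    """
    df = scores.ranked()
    return df[["variable", "prominence", "relation"]].reset_index(drop=True)
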