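"""Bundled datasets.

``reference_ranking`` is the 23-variable summary ranking from a published
13-community collation of causal loop diagrams about children and young
people's health and wellbeing: per variable its DEMATEL prominence (R + C)
and relation (R - C), both printed to two decimals, and the number of
constituent community diagrams it appeared in.  The constituent diagrams
themselves are not public, so this table is the regression fixture for the
paring and sensitivity machinery.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core import canonical_key
from .dematel import DematelScores

__all__ = ["load_reference_ranking", "reference_scores"]


def load_reference_ranking() -> pd.DataFrame:
    """The published 23-variable ranking.

    Columns: ``rank, variable, prominence, relation, frequency``.
    """
    with resources.files("cldmerge.data").joinpath("reference_ranking.csv").open() as fh:
        return pd.read_csv(fh)


def reference_scores() -> DematelScores:
    """The same table as a :class:`~cldmerge.dematel.DematelScores` object.

    R and C are reconstructed from the printed prominence/relation pairs;
    frequency rides along keyed by canonical variable name.
    """
    df = load_reference_ranking()
    return DematelScores.from_prominence_relation(
        variables=df["variable"],
        prominence=df["prominence"],
        relation=df["relation"],
        frequency={canonical_key(v): int(f)
                   for v, f in zip(df["variable"], df["frequency"])},
    )
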