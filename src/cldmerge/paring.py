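"""Pare the merged diagram down to a summary CLD.

Two cut points reduce the merged diagram, in a fixed order:

1. variable cut — keep variables whose DEMATEL prominence (R + C) is at
   or above a threshold chosen by inspecting the prominence/relation
   scatter plot (``suggest_cut`` automates the "largest gap" heuristic,
   advisory only);
2. edge cut — within the induced subgraph, drop links that appeared in
   fewer than ``edge_min_count`` constituent diagrams (default 2), i.e.
   links no second community corroborated.

Polarity, stripped for DEMATEL, is restored from the signed merged matrix,
and a sensitivity analysis perturbs the variable cut multiplicatively
(by default +/-5, 10, 15%) to show how stable the retained set is.
Threshold comparisons are inclusive (prominence >= cut).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import CLD, CLDError, canonical_key
from .dematel import DematelScores
from .merging import MergedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ParingError",
    "ParingConfig",
    "SummaryLink",
    "SummaryCLD",
    "SensitivityResult",
    "apply_variable_cut",
    "suggest_cut",
    "sensitivity",
    "apply_edge_cut",
    "restore_polarity",
    "frequency",
    "frequencies",
    "pare",
]

DEFAULT_DELTAS = (-0.15, -0.10, -0.05, 0.05, 0.10, 0.15)


class ParingError(CLDError):
    pass


@dataclass(frozen=True)
class ParingConfig:
    """Thresholds driving the reduction.

    variable_cut: prominence threshold (inclusive), must be positive.
    edge_min_count: minimum |merged count| for a link to survive (>= 1).
    sensitivity_deltas: multiplicative perturbations of the variable cut.
    """

    variable_cut: float = 1.0
    edge_min_count: int = 2
    sensitivity_deltas: tuple[float, ...] = DEFAULT_DELTAS

    def __post_init__(self):
        if self.variable_cut <= 0:
            raise ParingError("variable_cut must be positive")
        if self.edge_min_count < 1:
            raise ParingError("edge_min_count must be >= 1")
        if any(not -1 < d < 1 for d in self.sensitivity_deltas):
            raise ParingError("sensitivity deltas must lie in (-1, 1)")


@dataclass(frozen=True)
class SummaryLink:
    source: str
    target: str
    count: int                 # number of constituent diagrams (magnitude)
    polarity: int | None = None  # +1 / -1 once restored, None before

    @property
    def key(self) -> tuple[str, str]:
        return (canonical_key(self.source), canonical_key(self.target))


@dataclass
class SummaryCLD:
    """The pared diagram plus the provenance of its thresholds.

    Variables isolated by the edge cut stay in the variable list (flagged
    via :attr:`isolated_variables`) — the summary describes which variables
    matter, not only which are still wired together.
    """

    variables: tuple[str, ...]
    links: tuple[SummaryLink, ...]
    scores: DematelScores | None = None
    frequencies: dict[str, int] | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def isolated_variables(self) -> tuple[str, ...]:
        touched = {k for link in self.links for k in link.key}
        return tuple(v for v in self.variables if canonical_key(v) not in touched)

    @property
    def link_keys(self) -> frozenset[tuple[str, str]]:
        return frozenset(link.key for link in self.links)

    def to_cld(self, cld_id: str = "summary") -> CLD:
        cld = CLD(cld_id, variables=self.variables)
        for link in self.links:
            if link.polarity is None:
                raise ParingError(
                    f"link {link.source!r} -> {link.target!r} has no polarity; "
                    f"run restore_polarity first")
            cld.add_link(link.source, link.target, link.polarity)
        return cld

    def to_merged_matrix(self, n_clds: int) -> MergedMatrix:
        """Signed count matrix over the summary variables (for re-paring)."""
        index = tuple(sorted(self.variables, key=str.casefold))
        pos = {canonical_key(v): i for i, v in enumerate(index)}
        cells = np.zeros((len(index), len(index)), dtype=int)
        for link in self.links:
            sign = link.polarity if link.polarity is not None else 1
            cells[pos[link.key[0]], pos[link.key[1]]] = sign * link.count
        return MergedMatrix(index=index, cells=cells, n_clds=n_clds)

    def ranking_frame(self) -> pd.DataFrame:
        """Ranking table: rank, variable, prominence, relation, frequency."""
        if self.scores is None:
            raise ParingError("summary carries no DEMATEL scores")
        df = self.scores.ranked()
        retained = {canonical_key(v) for v in self.variables}
        df = df[df["variable"].map(canonical_key).isin(retained)].copy()
        df["rank"] = range(1, len(df) + 1)
        freqs = self.frequencies or {}
        df["frequency"] = df["variable"].map(
            lambda v: freqs.get(canonical_key(v), pd.NA))
        return df[["rank", "variable", "prominence", "relation", "frequency"]]


def apply_variable_cut(scores: DematelScores, cut: float) -> tuple[str, ...]:
    """Variables with prominence >= cut, in ranking order."""
    df = scores.ranked()
    retained = df.loc[df["prominence"] >= cut, "variable"]
    if retained.empty:
        raise ParingError(
            f"variable cut {cut} retains no variables (max prominence "
            f"{df['prominence'].max():.4g}); lower the cut")
    return tuple(retained)


def suggest_cut(scores: DematelScores) -> float:
    """Advisory prominence threshold separating two clusters of variables.

    Automates the scatter-plot inspection that places a cut at the "clear
    boundary" between a prominent core and the long tail.  The suggestion
    is the midpoint of the largest *relative* gap between consecutive
    sorted prominence values (equivalently, the largest gap on a log
    scale).  Prominence distributions are heavy-tailed, so the biggest
    absolute gap usually sits between the top one or two variables rather
    than at the core/tail boundary; the relative gap is scale-free and
    finds the boundary between clusters that differ by an order of
    magnitude.  Variables with exactly zero prominence (fully isolated)
    are ignored when locating the gap.  The operative cut always comes
    from configuration — this is a starting point for inspection, not a
    decision.  Degenerate inputs (all prominences equal) return that
    common value with a warning.
    """
    if len(scores.index) < 3:
        raise ParingError("need at least 3 variables to suggest a cut")
    values = np.sort(scores.prominence)[::-1]
    values = values[values > 0]
    if len(values) == 0:
        raise ParingError("all prominence values are zero; nothing to cut")
    if len(values) < 2 or values[0] == values[-1]:
        logger.warning("all prominence values equal; no boundary to cut at")
        return float(values[0])
    ratios = values[:-1] / values[1:]
    k = int(np.argmax(ratios))
    return float((values[k] + values[k + 1]) / 2.0)


@dataclass
class SensitivityResult:
    """Per-delta stability of the retained set around the chosen cut.

    Each record holds the perturbed threshold cut*(1+delta), the variables
    newly excluded relative to the baseline retained set, and those newly
    included.  At delta 0 both change-sets are empty by construction.
    """

    cut: float
    records: list[dict] = field(default_factory=list)

    def for_delta(self, delta: float) -> dict:
        for rec in self.records:
            if abs(rec["delta"] - delta) < 1e-12:
                return rec
        raise KeyError(delta)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"delta": r["delta"], "threshold": r["threshold"],
             "excluded": "; ".join(r["excluded"]),
             "included": "; ".join(r["included"])}
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=["delta", "threshold", "excluded", "included"])


def sensitivity(scores: DematelScores, cut: float,
                deltas=DEFAULT_DELTAS) -> SensitivityResult:
    """Report how the retained set changes as the cut moves by each delta."""
    if any(not -1 < d < 1 for d in deltas):
        raise ParingError("sensitivity deltas must lie in (-1, 1)")
    baseline = set(apply_variable_cut(scores, cut))
    result = SensitivityResult(cut=cut)
    df = scores.ranked()
    for delta in sorted(deltas):
        threshold = cut * (1.0 + delta)
        retained = set(df.loc[df["prominence"] >= threshold, "variable"])
        excluded = [v for v in df["variable"] if v in baseline - retained]
        included = [v for v in df["variable"] if v in retained - baseline]
        result.records.append({
            "delta": delta, "threshold": threshold,
            "excluded": excluded, "included": included,
        })
    return result


def apply_edge_cut(m: MergedMatrix, retained, edge_min_count: int = 2) -> SummaryCLD:
    """Induce the subgraph on ``retained`` and drop uncorroborated links.

    A link survives when |merged count| >= edge_min_count, i.e. it appeared
    in at least that many constituent diagrams.  Polarity is not yet
    attached; see :func:`restore_polarity`.  An empty summary is permitted
    (with a warning) — it signals thresholds that are too aggressive.
    """
    retained = tuple(retained)
    index_keys = {canonical_key(u) for u in m.index}
    missing = [v for v in retained if canonical_key(v) not in index_keys]
    if missing:
        raise ParingError(f"retained variable(s) {missing!r} not in merged index")
    positions = [m.position(v) for v in retained]
    sub = m.cells[np.ix_(positions, positions)]
    links = []
    for a, b in zip(*np.nonzero(np.abs(sub) >= edge_min_count)):
        links.append(SummaryLink(source=retained[a], target=retained[b],
                                 count=int(abs(sub[a, b]))))
    if not links:
        logger.warning("edge cut at %d left no links among %d retained variables",
                       edge_min_count, len(retained))
    return SummaryCLD(
        variables=retained, links=tuple(links),
        provenance={"edge_min_count": edge_min_count, "n_clds": m.n_clds},
    )


def restore_polarity(s: SummaryCLD, m: MergedMatrix) -> SummaryCLD:
    """Reattach polarity from the signed merged matrix.

    Every summary link must exist in the merged matrix; the polarity is the
    sign of its cell, which by the conflict-free merge invariant equals the
    polarity every contributing community drew.
    """
    links = []
    for link in s.links:
        value = m.cell(link.source, link.target)
        if value == 0:
            raise ParingError(
                f"summary link {link.source!r} -> {link.target!r} has a zero "
                f"merged cell: summary and merged matrix disagree")
        links.append(replace(link, polarity=1 if value > 0 else -1,
                             count=abs(value)))
    return replace(s, links=tuple(links))


def frequency(clds, variable: str) -> int:
    """Number of constituent diagrams whose node set contains ``variable``."""
    return sum(1 for cld in clds if variable in cld)


def frequencies(clds) -> dict[str, int]:
    """Frequency for every variable across the diagrams, keyed canonically."""
    counts: dict[str, int] = {}
    for cld in clds:
        for key in cld.variable_keys:
            counts[key] = counts.get(key, 0) + 1
    return counts


def pare(m: MergedMatrix, scores: DematelScores, config: ParingConfig,
         clds=None) -> SummaryCLD:
    """Full paring: variable cut, edge cut, polarity restoration.

    When the constituent ``clds`` are given the summary also carries each
    retained variable's frequency of occurrence.
    """
    retained = apply_variable_cut(scores, config.variable_cut)
    summary = apply_edge_cut(m, retained, config.edge_min_count)
    summary = restore_polarity(summary, m)
    summary.scores = scores
    summary.provenance.update({"variable_cut": config.variable_cut})
    if clds is not None:
        freq = frequencies(clds)
        summary.frequencies = {canonical_key(v): freq.get(canonical_key(v), 0)
                               for v in retained}
    elif scores.frequency is not None:
        summary.frequencies = {canonical_key(k): v
                               for k, v in scores.frequency.items()}
    return summary
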