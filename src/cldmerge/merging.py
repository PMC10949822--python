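"""Merge canonicalised CLDs into one integer-weighted signed matrix.

Every unique variable appears once; the cell for an ordered pair holds the
signed count of constituent diagrams containing that link (a positive link
present in two diagrams gives +2, a negative link in three gives -3).
Conflicting links — the same ordered pair drawn with both polarities in
different communities — are detected before merging and abort it by
default, since the study protocol resolves such conflicts with the map
builders before any merge.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CLD, CLDError, canonical_key, normalize_label

logger = logging.getLogger(__name__)

__all__ = [
    "ConflictReport",
    "MergeConflictError",
    "MergedMatrix",
    "detect_conflicts",
    "merge",
    "merged_link_count",
]


@dataclass
class ConflictReport:
    """Ordered pairs that appear with both polarities across diagrams.

    ``pairs`` maps nothing implicitly: each entry is
    ``(source, target, {cld_id: polarity})`` ordered by source then target.
    The report is empty iff the merge is well-defined.
    """

    pairs: list[tuple[str, str, dict[str, int]]] = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


class MergeConflictError(CLDError):
    def __init__(self, report: ConflictReport):
        pairs = [(s, t) for s, t, _ in report.pairs]
        super().__init__(
            f"merge refused: {len(report)} link(s) with conflicting polarity "
            f"across diagrams: {pairs}"
        )
        self.report = report


def detect_conflicts(clds: list[CLD]) -> ConflictReport:
    """List every ordered pair appearing with both polarities across diagrams."""
    observed: dict[tuple[str, str], dict[str, int]] = {}
    display: dict[str, str] = {}
    for cld in clds:
        for link in cld.links:
            observed.setdefault(link.key, {})[cld.cld_id] = link.polarity
            display.setdefault(link.key[0], link.source)
            display.setdefault(link.key[1], link.target)
    report = ConflictReport()
    for (skey, tkey) in sorted(observed):
        polarities = observed[(skey, tkey)]
        if len(set(polarities.values())) > 1:
            report.pairs.append((display[skey], display[tkey], dict(polarities)))
    return report


@dataclass
class MergedMatrix:
    """Signed link-count matrix over the union of all diagram variables.

    ``cells[i, j]`` is (shared polarity) x (number of constituent diagrams
    containing the link index[i] -> index[j]); the index is the union of
    variable names sorted case-insensitively so output files are
    deterministic.
    """

    index: tuple[str, ...]
    cells: np.ndarray = field(repr=False)
    n_clds: int = 1

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=int)
        n = len(self.index)
        if self.cells.shape != (n, n):
            raise ValueError("cells must be square and match the index")
        if np.diagonal(self.cells).any():
            raise ValueError("merged matrix diagonal must be zero")
        self._pos = {canonical_key(v): i for i, v in enumerate(self.index)}

    def cell(self, source: str, target: str) -> int:
        return int(self.cells[self._pos[canonical_key(source)],
                              self._pos[canonical_key(target)]])

    def position(self, label: str) -> int:
        return self._pos[canonical_key(label)]

    @property
    def n_links(self) -> int:
        return int(np.count_nonzero(self.cells))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.index, columns=self.index)

    def to_edge_list(self) -> pd.DataFrame:
        """Long form: ``source,target,count,polarity`` with count = |cell|."""
        rows = []
        for i, j in zip(*np.nonzero(self.cells)):
            value = int(self.cells[i, j])
            rows.append((self.index[i], self.index[j], abs(value),
                         1 if value > 0 else -1))
        return pd.DataFrame(rows, columns=["source", "target", "count", "polarity"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path, n_clds: int | None = None) -> "MergedMatrix":
        frame = pd.read_csv(path, index_col=0)
        cells = frame.to_numpy(dtype=int)
        if n_clds is None:
            n_clds = max(1, int(np.abs(cells).max(initial=1)))
        return cls(index=tuple(normalize_label(v) for v in frame.index),
                   cells=cells, n_clds=n_clds)


def merge(clds: list[CLD], resolve: str = "abort") -> MergedMatrix:
    """Merge canonicalised diagrams into one :class:`MergedMatrix`.

    ``resolve="abort"`` (default, canonical) refuses to merge while any
    cross-diagram polarity conflict exists.  ``resolve="majority"`` is an
    escape hatch: each conflicted pair keeps its majority polarity with the
    minority diagrams excluded, and an exact tie drops the link entirely;
    both outcomes are logged loudly.
    """
    if not clds:
        raise ValueError("no diagrams to merge")
    conflicts = detect_conflicts(clds)
    if conflicts and resolve == "abort":
        raise MergeConflictError(conflicts)
    if resolve not in ("abort", "majority"):
        raise ValueError(f"unknown conflict resolution {resolve!r}")

    display: dict[str, str] = {}
    for cld in clds:
        for label in cld.variables:
            display.setdefault(canonical_key(label), label)
    index = tuple(display[k] for k in sorted(display))
    pos = {k: i for i, k in enumerate(sorted(display))}

    pos_counts = np.zeros((len(index), len(index)), dtype=int)
    neg_counts = np.zeros_like(pos_counts)
    for cld in clds:
        for link in cld.links:
            i, j = pos[link.key[0]], pos[link.key[1]]
            if link.polarity > 0:
                pos_counts[i, j] += 1
            else:
                neg_counts[i, j] += 1

    cells = pos_counts - neg_counts
    if conflicts:  # majority resolution
        for source, target, polarities in conflicts.pairs:
            i, j = pos[canonical_key(source)], pos[canonical_key(target)]
            n_pos, n_neg = pos_counts[i, j], neg_counts[i, j]
            if n_pos == n_neg:
                cells[i, j] = 0
                logger.warning(
                    "conflict %s -> %s tied (%d vs %d): link excluded from merge",
                    source, target, n_pos, n_neg)
            else:
                sign = 1 if n_pos > n_neg else -1
                cells[i, j] = sign * max(n_pos, n_neg)
                logger.warning(
                    "conflict %s -> %s resolved by majority to polarity %+d "
                    "(%d vs %d); minority diagrams excluded",
                    source, target, sign, n_pos, n_neg)

    merged = MergedMatrix(index=index, cells=cells, n_clds=len(clds))
    logger.info("merged %d diagrams: %d unique variables, %d unique links",
                len(clds), len(index), merged.n_links)
    return merged


def merged_link_count(m: MergedMatrix) -> int:
    """Number of unique directed links (nonzero cells) in the merged diagram."""
    return m.n_links
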