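"""Core domain types for causal loop diagrams (CLDs).

A CLD is a signed directed graph: nodes are dynamic variables, arrows are
hypothesised causal links, and each link carries a polarity — +1 when the
two variables move in the same direction, -1 when they move in opposite
directions.  Variable identity is case-insensitive after whitespace
normalisation, because community-entered names are inconsistently cased;
the original (whitespace-collapsed) casing is retained for display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CLDError",
    "ValidationError",
    "PolarityConflictError",
    "normalize_label",
    "canonical_key",
    "CausalLink",
    "CLD",
    "AdjacencyMatrix",
]


class CLDError(Exception):
    """Base class for all domain errors raised by this package."""


class ValidationError(CLDError):
    """An input violated a structural invariant (bad polarity, self-loop, ...)."""


class PolarityConflictError(CLDError):
    """The same ordered variable pair carries both polarities.

    Attributes
    ----------
    pairs : list of (source, target)
        The conflicting ordered pairs (display labels).
    """

    def __init__(self, message: str, pairs=()):
        super().__init__(message)
        self.pairs = list(pairs)


def normalize_label(label: str) -> str:
    """Collapse internal whitespace and strip the ends; keep original casing."""
    return " ".join(str(label).split())


def canonical_key(label: str) -> str:
    """Case-insensitive identity key of a variable name."""
    return normalize_label(label).casefold()


@dataclass(frozen=True)
class CausalLink:
    """A polarised causal arrow between two variables.

    ``source`` and ``target`` are display labels (whitespace-normalised);
    identity comparisons elsewhere use :func:`canonical_key`.  Polarity is
    strictly +1 or -1 — a zero would mean "no link" and is rejected.
    """

    source: str
    target: str
    polarity: int

    def __post_init__(self):
        object.__setattr__(self, "source", normalize_label(self.source))
        object.__setattr__(self, "target", normalize_label(self.target))
        if not self.source or not self.target:
            raise ValidationError("link endpoints must be non-empty labels")
        if self.polarity not in (1, -1):
            raise ValidationError(
                f"polarity must be +1 or -1, got {self.polarity!r} "
                f"for link {self.source!r} -> {self.target!r}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (canonical_key(self.source), canonical_key(self.target))


class CLD:
    """One community's causal loop diagram.

    Holds an ordered set of variables (insertion order preserved for
    round-tripping) and at most one polarised link per ordered pair.
    Duplicate links with equal polarity are dropped with a warning;
    contradictory polarities raise :class:`PolarityConflictError`.

    Parameters
    ----------
    cld_id : str
        Identifier of the community diagram.
    variables : iterable of str, optional
        Initial variables (possibly isolated).
    links : iterable of (source, target, polarity) or CausalLink, optional
    allow_self_loops : bool
        Self-referencing links are rejected by default; they almost always
        indicate a data-entry error in community diagrams.
    """

    def __init__(self, cld_id: str, variables=(), links=(), *, allow_self_loops: bool = False):
        self.cld_id = str(cld_id)
        self.allow_self_loops = allow_self_loops
        self._vars: dict[str, str] = {}  # canonical key -> display label
        self._links: dict[tuple[str, str], CausalLink] = {}
        for v in variables:
            self.add_variable(v)
        for link in links:
            if isinstance(link, CausalLink):
                self.add_link(link.source, link.target, link.polarity)
            else:
                self.add_link(*link)

    # -- construction ------------------------------------------------------
    def add_variable(self, label: str) -> str:
        """Register a variable; returns its display label (first spelling wins)."""
        label = normalize_label(label)
        if not label:
            raise ValidationError("variable label must be non-empty")
        key = canonical_key(label)
        if key not in self._vars:
            self._vars[key] = label
        return self._vars[key]

    def add_link(self, source: str, target: str, polarity: int) -> CausalLink:
        link = CausalLink(source, target, int(polarity))
        skey, tkey = link.key
        if skey == tkey and not self.allow_self_loops:
            raise ValidationError(
                f"self-loop {link.source!r} -> {link.target!r} rejected in CLD "
                f"{self.cld_id!r} (pass allow_self_loops=True to permit)"
            )
        self.add_variable(link.source)
        self.add_variable(link.target)
        existing = self._links.get((skey, tkey))
        if existing is not None:
            if existing.polarity == link.polarity:
                logger.warning(
                    "CLD %s: duplicate link %s -> %s (polarity %+d) ignored",
                    self.cld_id, link.source, link.target, link.polarity,
                )
                return existing
            raise PolarityConflictError(
                f"CLD {self.cld_id!r}: link {link.source!r} -> {link.target!r} "
                f"appears with both polarities",
                pairs=[(existing.source, existing.target)],
            )
        self._links[(skey, tkey)] = link
        return link

    # -- accessors ---------------------------------------------------------
    @property
    def variables(self) -> tuple[str, ...]:
        """Display labels in insertion order."""
        return tuple(self._vars.values())

    @property
    def variable_keys(self) -> frozenset[str]:
        return frozenset(self._vars)

    @property
    def links(self) -> tuple[CausalLink, ...]:
        return tuple(self._links.values())

    def __len__(self) -> int:
        return len(self._vars)

    def __contains__(self, label: str) -> bool:
        return canonical_key(label) in self._vars

    def display_label(self, label: str) -> str:
        return self._vars[canonical_key(label)]

    def polarity_of(self, source: str, target: str) -> int | None:
        link = self._links.get((canonical_key(source), canonical_key(target)))
        return None if link is None else link.polarity

    def __eq__(self, other) -> bool:
        if not isinstance(other, CLD):
            return NotImplemented
        return (
            set(self._vars) == set(other._vars)
            and {k: v.polarity for k, v in self._links.items()}
            == {k: v.polarity for k, v in other._links.items()}
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"CLD({self.cld_id!r}, {len(self)} variables, {len(self._links)} links)"

    # -- conversion --------------------------------------------------------
    def to_adjacency(self, index=None) -> "AdjacencyMatrix":
        """Represent the diagram as a signed adjacency matrix.

        ``index`` may list extra variables (for alignment across diagrams)
        but must contain every variable of this CLD.
        """
        if index is None:
            index = self.variables
        index = tuple(normalize_label(v) for v in index)
        positions = {canonical_key(v): i for i, v in enumerate(index)}
        missing = [v for k, v in self._vars.items() if k not in positions]
        if missing:
            raise ValidationError(
                f"index is missing variable(s) {missing!r} of CLD {self.cld_id!r}"
            )
        cells = np.zeros((len(index), len(index)), dtype=int)
        for (skey, tkey), link in self._links.items():
            cells[positions[skey], positions[tkey]] = link.polarity
        return AdjacencyMatrix(index=index, cells=cells)


@dataclass
class AdjacencyMatrix:
    """Square signed matrix view of one CLD: cells in {-1, 0, +1}, zero diagonal."""

    index: tuple[str, ...]
    cells: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.index = tuple(normalize_label(v) for v in self.index)
        self.cells = np.asarray(self.cells, dtype=int)
        n = len(self.index)
        if self.cells.shape != (n, n):
            raise ValidationError(
                f"cells shape {self.cells.shape} does not match index length {n}"
            )
        if not np.isin(self.cells, (-1, 0, 1)).all():
            raise ValidationError("adjacency cells must lie in {-1, 0, +1}")
        if np.diagonal(self.cells).any():
            raise ValidationError("adjacency diagonal must be all zero")

    def to_cld(self, cld_id: str) -> CLD:
        """Inverse of :meth:`CLD.to_adjacency` (exact round-trip)."""
        cld = CLD(cld_id, variables=self.index)
        for i, j in zip(*np.nonzero(self.cells)):
            cld.add_link(self.index[i], self.index[j], int(self.cells[i, j]))
        return cld

    @property
    def n_links(self) -> int:
        return int(np.count_nonzero(self.cells))
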