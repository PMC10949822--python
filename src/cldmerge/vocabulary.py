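"""Variable-name canonicalisation across community diagrams.

Different communities name the same construct differently ("eating healthy
food", "consumption of healthy food", ...).  The mapping from raw names to
canonical combined names is human judgment reached by reviewer consensus;
this module only *applies* a curated two-column synonym table, audits what
was fused, and offers advisory string-similarity suggestions.  It never
merges names automatically.
"""

from __future__ import annotations

import csv
import difflib
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

from .core import CLD, CLDError, canonical_key, normalize_label

__all__ = [
    "VocabularyError",
    "VocabularyMap",
    "CombinationReport",
    "apply_vocabulary",
    "suggest_synonyms",
    "vocabulary_coverage",
]


class VocabularyError(CLDError):
    """Invalid vocabulary table or a fusion that produced a polarity conflict."""


class VocabularyMap:
    """Functional mapping raw label -> canonical label (no chains allowed).

    A canonical label may not itself appear as a raw label mapping somewhere
    else: the table must be flat, so applying it twice equals applying it
    once.  Lookups are case-insensitive and whitespace-normalised.
    """

    def __init__(self, entries: dict[str, str] | None = None,
                 notes: dict[str, str] | None = None):
        self._entries: dict[str, str] = {}   # raw key -> canonical display
        self._raw_display: dict[str, str] = {}
        self.notes: dict[str, str] = {}
        for raw, canonical in (entries or {}).items():
            self.add(raw, canonical, (notes or {}).get(raw))
        self.validate()

    def add(self, raw: str, canonical: str, note: str | None = None) -> None:
        raw_d, canon_d = normalize_label(raw), normalize_label(canonical)
        raw_key = canonical_key(raw_d)
        existing = self._entries.get(raw_key)
        if existing is not None and canonical_key(existing) != canonical_key(canon_d):
            raise VocabularyError(
                f"raw name {raw_d!r} maps to both {existing!r} and {canon_d!r}"
            )
        self._entries[raw_key] = canon_d
        self._raw_display[raw_key] = raw_d
        if note:
            self.notes[raw_key] = note

    def validate(self) -> None:
        for raw_key, canon in self._entries.items():
            canon_key = canonical_key(canon)
            if canon_key == raw_key:
                continue
            onward = self._entries.get(canon_key)
            if onward is not None and canonical_key(onward) != canon_key:
                raise VocabularyError(
                    f"chained mapping: {self._raw_display[raw_key]!r} -> {canon!r} "
                    f"-> {onward!r}; flatten the table"
                )

    def canonical(self, label: str) -> str:
        """Canonical display label for ``label`` (labels not in the table pass through)."""
        return self._entries.get(canonical_key(label), normalize_label(label))

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, label: str) -> bool:
        return canonical_key(label) in self._entries

    def items(self):
        for raw_key, canon in self._entries.items():
            yield self._raw_display[raw_key], canon

    @classmethod
    def from_csv(cls, path) -> "VocabularyMap":
        """Load a ``raw_name,canonical_name[,note]`` table."""
        vocab = cls()
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or [h.strip().lower() for h in header[:2]] != [
                    "raw_name", "canonical_name"]:
                raise VocabularyError(
                    f"{path}:1: expected header 'raw_name,canonical_name[,note]'"
                )
            for row in reader:
                if not row or not any(c.strip() for c in row):
                    continue
                note = row[2].strip() if len(row) > 2 else None
                vocab.add(row[0], row[1], note)
        vocab.validate()
        return vocab

    def to_csv(self, path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["raw_name", "canonical_name", "note"])
            for raw_key, canon in self._entries.items():
                writer.writerow([self._raw_display[raw_key], canon,
                                 self.notes.get(raw_key, "")])
        return path


@dataclass
class CombinationReport:
    """Audit trail of what canonicalisation changed in one diagram.

    Each action is a ``(cld_id, action, detail)`` triple; actions are
    ``rename`` (label replaced), ``fuse`` (two or more variables became one
    node) and ``collapse`` (parallel links with agreeing polarity merged).
    """

    actions: list[tuple[str, str, str]] = field(default_factory=list)

    def record(self, cld_id: str, action: str, detail: str) -> None:
        self.actions.append((cld_id, action, detail))

    def __len__(self) -> int:
        return len(self.actions)

    def to_csv(self, path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["cld_id", "action", "detail"])
            writer.writerows(self.actions)
        return path


def apply_vocabulary(cld: CLD, vocab: VocabularyMap) -> tuple[CLD, CombinationReport]:
    """Rename every variable of ``cld`` to its canonical name.

    Variables whose canonical names coincide are fused into one node and
    their links re-targeted.  Parallel links produced by fusion collapse
    when their polarities agree; opposing polarities are a hard error —
    the conflict must be resolved in the vocabulary or the source diagram,
    mirroring how map builders resolve conflicts before merging.
    """
    report = CombinationReport()
    out = CLD(cld.cld_id, allow_self_loops=cld.allow_self_loops)

    canonical_of: dict[str, str] = {}
    fused: dict[str, list[str]] = {}
    for label in cld.variables:
        canon = vocab.canonical(label)
        canonical_of[canonical_key(label)] = canon
        fused.setdefault(canonical_key(canon), []).append(label)
        if canonical_key(canon) != canonical_key(label):
            report.record(cld.cld_id, "rename", f"{label} -> {canon}")
        out.add_variable(canon)
    for canon_key, originals in fused.items():
        if len(originals) > 1:
            report.record(cld.cld_id, "fuse",
                          f"{' + '.join(originals)} -> {out.display_label(canon_key)}")

    seen: dict[tuple[str, str], int] = {}
    conflicts = []
    for link in cld.links:
        src = canonical_of[canonical_key(link.source)]
        tgt = canonical_of[canonical_key(link.target)]
        pair = (canonical_key(src), canonical_key(tgt))
        if pair in seen:
            if seen[pair] != link.polarity:
                conflicts.append((src, tgt))
            else:
                report.record(cld.cld_id, "collapse",
                              f"parallel link {src} -> {tgt} (polarity {link.polarity:+d})")
            continue
        seen[pair] = link.polarity
        if pair[0] == pair[1] and not cld.allow_self_loops:
            conflicts.append((src, tgt))
            continue
        out.add_link(src, tgt, link.polarity)
    if conflicts:
        raise VocabularyError(
            f"CLD {cld.cld_id!r}: canonicalisation produced conflicting or "
            f"degenerate parallel links for pairs {sorted(set(conflicts))}; "
            f"resolve in the vocabulary or the source diagram"
        )
    return out, report


def suggest_synonyms(labels, similarity_floor: float = 0.8):
    """Advisory candidate synonym pairs, ranked by string similarity.

    Similarity is :class:`difflib.SequenceMatcher` ratio on casefolded,
    whitespace-collapsed labels.  Suggestions are never applied
    automatically — they exist to assist the human review step.

    Returns a list of ``(label_a, label_b, similarity)`` sorted by
    descending similarity (ties broken alphabetically).
    """
    labels = sorted({str(l) for l in labels}, key=str.casefold)
    if len(labels) < 2:
        raise ValueError("need at least two labels to suggest synonyms")
    out = []
    for a, b in combinations(labels, 2):
        ratio = difflib.SequenceMatcher(None, canonical_key(a), canonical_key(b)).ratio()
        if ratio >= similarity_floor:
            out.append((a, b, ratio))
    out.sort(key=lambda t: (-t[2], t[0].casefold(), t[1].casefold()))
    return out


def vocabulary_coverage(clds, vocab: VocabularyMap) -> int:
    """Number of unique canonical variables across all diagrams."""
    keys: set[str] = set()
    for cld in clds:
        canonical, _ = apply_vocabulary(cld, vocab)
        keys |= canonical.variable_keys
    return len(keys)
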