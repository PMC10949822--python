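"""Readers and writers for the CLD interchange formats.

Three input formats are supported for a single diagram:

* edge-list CSV, header ``cld_id,source,target,polarity`` with polarity
  tokens ``+1 / -1 / + / - / 1``;
* adjacency CSV, variable labels in the first row and column, cells in
  {-1, 0, 1} with a zero diagonal;
* JSON, following the schema shipped at ``data/cld_schema.json``:
  ``{"cld_id": str, "variables": [str, ...],
  "links": [{"source": str, "target": str, "polarity": int}, ...]}``.

Summary diagrams are written as GraphML (edge attributes ``count`` and
``polarity``), DOT (negative links dashed) or edge-list CSV
(``source,target,count,polarity``); GraphML and CSV can be read back.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import networkx as nx

from .core import CLD, PolarityConflictError, ValidationError, normalize_label

__all__ = ["read_cld", "read_clds", "write_cld", "write_summary", "read_summary"]

_POLARITY_TOKENS = {"+1": 1, "1": 1, "+": 1, "-1": -1, "-": -1, "−1": -1}


def _parse_polarity(token: str, path, line_no: int) -> int:
    token = str(token).strip()
    try:
        return _POLARITY_TOKENS[token]
    except KeyError:
        raise ValidationError(
            f"{path}:{line_no}: polarity {token!r} is not one of +1/-1/+/-"
        ) from None


def _sniff_csv_format(header: list[str]) -> str:
    first = [h.strip().lower() for h in header]
    if first[:4] == ["cld_id", "source", "target", "polarity"]:
        return "edgelist"
    return "adjacency"


def read_cld(path, fmt: str | None = None, *, cld_id: str | None = None,
             allow_self_loops: bool = False) -> CLD:
    """Read one CLD from ``path``.

    ``fmt`` is one of ``"edgelist"``, ``"adjacency"``, ``"json"``; when
    omitted it is inferred from the file suffix and, for CSV, the header.
    An edge-list file containing several ``cld_id`` values is an error here
    (use :func:`read_clds`).
    """
    path = Path(path)
    if fmt is None:
        if path.suffix.lower() == ".json":
            fmt = "json"
        else:
            with open(path, newline="") as fh:
                header = next(csv.reader(fh), [])
            fmt = _sniff_csv_format(header)

    if fmt == "json":
        return _read_json(path, allow_self_loops)
    if fmt == "edgelist":
        clds = read_clds(path, allow_self_loops=allow_self_loops)
        if len(clds) != 1:
            raise ValidationError(
                f"{path}: expected one diagram, found cld_ids "
                f"{sorted(c.cld_id for c in clds)}"
            )
        return clds[0]
    if fmt == "adjacency":
        return _read_adjacency(path, cld_id or path.stem, allow_self_loops)
    raise ValueError(f"unknown format {fmt!r}")


def read_clds(path, *, allow_self_loops: bool = False) -> list[CLD]:
    """Read every diagram from an edge-list CSV (grouped by ``cld_id``)."""
    path = Path(path)
    clds: dict[str, CLD] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or _sniff_csv_format(header) != "edgelist":
            raise ValidationError(
                f"{path}:1: expected header 'cld_id,source,target,polarity'"
            )
        conflicts = []
        for line_no, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            if len(row) < 4:
                raise ValidationError(
                    f"{path}:{line_no}: expected 4 columns, got {len(row)}"
                )
            cld_id, source, target = (c.strip() for c in row[:3])
            polarity = _parse_polarity(row[3], path, line_no)
            cld = clds.setdefault(cld_id, CLD(cld_id, allow_self_loops=allow_self_loops))
            try:
                cld.add_link(source, target, polarity)
            except PolarityConflictError as exc:
                conflicts.extend(exc.pairs)
        if conflicts:
            raise PolarityConflictError(
                f"{path}: conflicting polarities within one diagram for pairs "
                f"{sorted(set(conflicts))}",
                pairs=sorted(set(conflicts)),
            )
    return list(clds.values())


def _read_adjacency(path: Path, cld_id: str, allow_self_loops: bool) -> CLD:
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh) if any(c.strip() for c in row)]
    if not rows:
        raise ValidationError(f"{path}: empty adjacency file")
    labels = [normalize_label(c) for c in rows[0][1:]]
    n = len(labels)
    if len(rows) - 1 != n:
        raise ValidationError(
            f"{path}: adjacency matrix has {len(rows) - 1} rows for {n} columns"
        )
    cld = CLD(cld_id, variables=labels, allow_self_loops=allow_self_loops)
    for line_no, row in enumerate(rows[1:], start=2):
        row_label = normalize_label(row[0])
        if len(row[1:]) != n:
            raise ValidationError(f"{path}:{line_no}: expected {n} cells")
        for j, cell in enumerate(row[1:]):
            token = cell.strip()
            try:
                value = int(token)
            except ValueError:
                raise ValidationError(
                    f"{path}:{line_no}: cell {token!r} is not an integer"
                ) from None
            if value not in (-1, 0, 1):
                raise ValidationError(
                    f"{path}:{line_no}: adjacency cell {value} outside {{-1,0,1}}"
                )
            if value:
                cld.add_link(row_label, labels[j], value)
    return cld


def _read_json(path: Path, allow_self_loops: bool) -> CLD:
    with open(path) as fh:
        data = json.load(fh)
    try:
        cld = CLD(data["cld_id"], variables=data.get("variables", ()),
                  allow_self_loops=allow_self_loops)
        for link in data.get("links", ()):
            cld.add_link(link["source"], link["target"], int(link["polarity"]))
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"{path}: malformed CLD JSON ({exc})") from exc
    return cld


def write_cld(cld: CLD, path, fmt: str | None = None) -> Path:
    """Write one CLD as edge-list CSV or JSON (suffix decides when fmt omitted)."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "edgelist"
    if fmt == "json":
        payload = {
            "cld_id": cld.cld_id,
            "variables": list(cld.variables),
            "links": [
                {"source": l.source, "target": l.target, "polarity": l.polarity}
                for l in cld.links
            ],
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif fmt == "edgelist":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["cld_id", "source", "target", "polarity"])
            for link in cld.links:
                writer.writerow([cld.cld_id, link.source, link.target, f"{link.polarity:+d}"])
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


# -- summary diagrams ------------------------------------------------------

def write_summary(summary, path, fmt: str | None = None) -> Path:
    """Write a pared summary diagram.

    Formats: ``graphml`` (edge attributes ``count``, ``polarity``), ``dot``
    (negative links rendered dashed, per the convention that solid arrows
    are positive causal relationships), ``edgelist`` CSV with header
    ``source,target,count,polarity``.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".graphml": "graphml", ".dot": "dot", ".gv": "dot"}.get(
            path.suffix.lower(), "edgelist")

    if fmt == "graphml":
        graph = nx.DiGraph()
        for label in summary.variables:
            graph.add_node(label)
        for link in summary.links:
            graph.add_edge(link.source, link.target,
                           count=int(link.count), polarity=int(link.polarity))
        nx.write_graphml(graph, path)
    elif fmt == "dot":
        lines = ["digraph summary {"]
        for label in summary.variables:
            lines.append(f'    "{label}";')
        for link in summary.links:
            style = "solid" if link.polarity > 0 else "dashed"
            lines.append(
                f'    "{link.source}" -> "{link.target}" '
                f'[style={style}, label="{link.count}"];'
            )
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "edgelist":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target", "count", "polarity"])
            for link in summary.links:
                writer.writerow([link.source, link.target, link.count,
                                 f"{link.polarity:+d}"])
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_summary(path, fmt: str | None = None):
    """Read a summary diagram back (GraphML or edge-list CSV).

    Returns a :class:`~cldmerge.paring.SummaryCLD` carrying variables, links,
    counts and polarities; scores/frequencies are not stored in these files.
    """
    from .paring import SummaryCLD, SummaryLink

    path = Path(path)
    if fmt is None:
        fmt = "graphml" if path.suffix.lower() == ".graphml" else "edgelist"
    if fmt == "graphml":
        graph = nx.read_graphml(path)
        variables = tuple(normalize_label(n) for n in graph.nodes)
        links = tuple(
            SummaryLink(source=u, target=v,
                        count=int(data["count"]), polarity=int(data["polarity"]))
            for u, v, data in graph.edges(data=True)
        )
    elif fmt == "edgelist":
        links = []
        seen: dict[str, None] = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            for line_no, row in enumerate(reader, start=2):
                polarity = _parse_polarity(row["polarity"], path, line_no)
                link = SummaryLink(source=normalize_label(row["source"]),
                                   target=normalize_label(row["target"]),
                                   count=int(row["count"]), polarity=polarity)
                links.append(link)
                seen.setdefault(link.source)
                seen.setdefault(link.target)
        variables, links = tuple(seen), tuple(links)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return SummaryCLD(variables=variables, links=links)
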