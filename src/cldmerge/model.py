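"""High-level model interface: collate many community CLDs into a summary.

``CLDCollation`` is constructed from data (a list of community diagrams
and an optional synonym vocabulary); ``fit`` runs the three-step
procedure — canonicalise names, merge into a signed count matrix, pare via
DEMATEL — and returns a ``CollationResults`` carrying the merged matrix,
per-variable scores, the sensitivity diagnostics and the pared summary
diagram, with a ``summary()`` table in the style of the published
rankings.

Example
-------
>>> from cldmerge import CLDCollation, generate_ensemble
>>> clds, truth, vocab = generate_ensemble(seed=7)
>>> res = CLDCollation(clds, vocabulary=vocab).fit()
>>> print(res.summary())        # doctest: +SKIP
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as cld_io
from .core import CLD
from .dematel import DematelScores, dematel_scores, scatter_export, strip_polarity
from .merging import MergedMatrix, detect_conflicts, merge
from .paring import (ParingConfig, SensitivityResult, SummaryCLD, pare,
                     sensitivity, suggest_cut)
from .vocabulary import CombinationReport, VocabularyMap, apply_vocabulary

__all__ = ["CLDCollation", "CollationResults"]


class CLDCollation:
    """Collation of community causal loop diagrams.

    Parameters
    ----------
    clds : list of CLD
        The community diagrams (raw names allowed; the vocabulary is
        applied during fitting).
    vocabulary : VocabularyMap, optional
        Reviewer-curated raw -> canonical name table.  Omitted means names
        are taken as already canonical.
    """

    def __init__(self, clds: list[CLD], vocabulary: VocabularyMap | None = None):
        if not clds:
            raise ValueError("need at least one diagram")
        self.clds = list(clds)
        self.vocabulary = vocabulary or VocabularyMap()

    @classmethod
    def from_paths(cls, paths, vocabulary_path=None) -> "CLDCollation":
        """Build from edge-list/adjacency/JSON files (one or more diagrams each)."""
        clds: list[CLD] = []
        for path in paths:
            path = Path(path)
            if path.suffix.lower() == ".json":
                clds.append(cld_io.read_cld(path))
            else:
                clds.extend(cld_io.read_clds(path)
                            if _is_edgelist(path) else [cld_io.read_cld(path)])
        vocab = (VocabularyMap.from_csv(vocabulary_path)
                 if vocabulary_path else None)
        return cls(clds, vocabulary=vocab)

    def fit(self, variable_cut: float | None = None, edge_min_count: int = 2,
            sensitivity_deltas=ParingConfig().sensitivity_deltas,
            normalisation: str = "max", resolve: str = "abort") -> "CollationResults":
        """Run canonicalisation, merge, DEMATEL and paring.

        ``variable_cut=None`` adopts the advisory largest-gap suggestion
        (recorded in the results' provenance as such).
        """
        canonical: list[CLD] = []
        reports: list[CombinationReport] = []
        for cld in self.clds:
            c, r = apply_vocabulary(cld, self.vocabulary)
            canonical.append(c)
            reports.append(r)

        conflicts = detect_conflicts(canonical)
        merged = merge(canonical, resolve=resolve)
        scores = dematel_scores(strip_polarity(merged), normalisation=normalisation)

        cut_suggested = suggest_cut(scores) if len(merged.index) >= 3 else None
        cut = variable_cut if variable_cut is not None else cut_suggested
        if cut is None:
            raise ValueError("too few variables to suggest a cut; pass variable_cut")
        config = ParingConfig(variable_cut=cut, edge_min_count=edge_min_count,
                              sensitivity_deltas=tuple(sensitivity_deltas))
        summary_cld = pare(merged, scores, config, clds=canonical)
        sens = sensitivity(scores, cut, config.sensitivity_deltas)
        return CollationResults(
            model=self, canonical_clds=canonical, combination_reports=reports,
            conflicts=conflicts, merged=merged, scores=scores,
            paring_config=config, suggested_cut=cut_suggested,
            summary_cld=summary_cld, sensitivity_result=sens,
        )


def _is_edgelist(path: Path) -> bool:
    import csv
    with open(path, newline="") as fh:
        header = next(csv.reader(fh), [])
    return [h.strip().lower() for h in header[:4]] == [
        "cld_id", "source", "target", "polarity"]


@dataclass
class CollationResults:
    """Fitted collation: estimates, diagnostics, and the summary diagram."""

    model: CLDCollation
    canonical_clds: list[CLD]
    combination_reports: list[CombinationReport]
    conflicts: object
    merged: MergedMatrix
    scores: DematelScores
    paring_config: ParingConfig
    suggested_cut: float | None
    summary_cld: SummaryCLD
    sensitivity_result: SensitivityResult
    extra: dict = field(default_factory=dict)

    # -- convenience views -------------------------------------------------
    @property
    def n_unique_variables(self) -> int:
        return len(self.merged.index)

    @property
    def n_unique_links(self) -> int:
        return self.merged.n_links

    def ranking(self) -> pd.DataFrame:
        """Retained variables: rank, variable, prominence, relation, frequency."""
        return self.summary_cld.ranking_frame()

    def scatter(self) -> pd.DataFrame:
        return scatter_export(self.scores)

    def summary(self) -> str:
        """Human-readable fit summary (scores printed to 2 dp)."""
        cfg = self.paring_config
        lines = [
            "CLD collation summary",
            "=====================",
            f"diagrams merged:        {len(self.canonical_clds)}",
            f"unique variables:       {self.n_unique_variables}",
            f"unique causal links:    {self.n_unique_links}",
            f"variable cut (R+C >=):  {cfg.variable_cut:.4g}"
            + ("  [suggested]" if self.suggested_cut is not None
               and cfg.variable_cut == self.suggested_cut else ""),
            f"edge cut (count >=):    {cfg.edge_min_count}",
            f"retained variables:     {len(self.summary_cld.variables)}",
            f"retained links:         {len(self.summary_cld.links)}",
            "",
            "Ranking of retained variables",
            "-----------------------------",
        ]
        df = self.ranking().copy()
        df["prominence"] = df["prominence"].map(lambda x: f"{x:.2f}")
        df["relation"] = df["relation"].map(lambda x: f"{x:.2f}")
        lines.append(df.to_string(index=False))
        lines.append("")
        lines.append("Sensitivity of the variable cut")
        lines.append("-------------------------------")
        sens = self.sensitivity_result.to_frame().copy()
        sens["threshold"] = sens["threshold"].map(lambda x: f"{x:.2f}")
        lines.append(sens.to_string(index=False))
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def save(self, outdir, *, summary_formats=("graphml", "dot", "edgelist")) -> dict:
        """Write all artifacts plus a provenance manifest; returns the manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.merged.to_csv(outdir / "merged_matrix.csv")
        self.merged.to_edge_list().to_csv(outdir / "merged_edges.csv", index=False)
        self.scores.ranked().to_csv(outdir / "dematel_scores.csv", index=False)
        self.scatter().to_csv(outdir / "scatter.csv", index=False)
        self.ranking().to_csv(outdir / "ranking.csv", index=False)
        self.sensitivity_result.to_frame().to_csv(
            outdir / "sensitivity.csv", index=False)
        suffix = {"graphml": ".graphml", "dot": ".dot", "edgelist": ".csv"}
        for fmt in summary_formats:
            cld_io.write_summary(self.summary_cld, outdir / f"summary{suffix[fmt]}",
                                 fmt=fmt)
        report = CombinationReport()
        for r in self.combination_reports:
            report.actions.extend(r.actions)
        report.to_csv(outdir / "combination_report.csv")

        manifest = {
            "n_clds": len(self.canonical_clds),
            "cld_ids": [c.cld_id for c in self.canonical_clds],
            "unique_variables": self.n_unique_variables,
            "unique_links": self.n_unique_links,
            "variable_cut": self.paring_config.variable_cut,
            "edge_min_count": self.paring_config.edge_min_count,
            "sensitivity_deltas": list(self.paring_config.sensitivity_deltas),
            "retained_variables": len(self.summary_cld.variables),
            "retained_links": len(self.summary_cld.links),
            "artifact_hashes": {},
        }
        for name in sorted(p.name for p in outdir.iterdir() if p.is_file()
                           and p.name != "manifest.json"):
            digest = hashlib.sha256((outdir / name).read_bytes()).hexdigest()
            manifest["artifact_hashes"][name] = digest
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return manifest
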