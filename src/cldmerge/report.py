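"""Human-readable reports of a collation run.

``render_report`` assembles a markdown document with four sections —
ranking table, scatter data, sensitivity table, summary diagram edges —
from whatever artifacts are available; a missing artifact yields an
explicit placeholder rather than an error.  Scores are printed to two
decimals, matching how such rankings are usually published.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["render_report", "plot_scatter"]

_PLACEHOLDER = "_not available for this run_"


def _md_table(df: pd.DataFrame) -> str:
    cols = [str(c) for c in df.columns]
    rows = [[("" if pd.isna(v) else str(v)) for v in rec]
            for rec in df.itertuples(index=False)]
    widths = [max(len(c), *(len(r[i]) for r in rows)) if rows else len(c)
              for i, c in enumerate(cols)]
    def line(cells):
        return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
    out = [line(cols), "|" + "|".join("-" * (w + 2) for w in widths) + "|"]
    out += [line(r) for r in rows]
    return "\n".join(out)


def _fmt(df: pd.DataFrame, two_dp=("prominence", "relation", "threshold")) -> str:
    df = df.copy()
    for col in df.columns:
        if col in two_dp:
            df[col] = df[col].map(lambda x: f"{float(x):.2f}")
    return _md_table(df)


def render_report(artifacts: dict) -> str:
    """Render a markdown report.

    ``artifacts`` may contain ``ranking``, ``scatter``, ``sensitivity``
    (DataFrames) and ``summary`` (a SummaryCLD or an edges DataFrame);
    ``title`` and ``manifest`` are optional extras.
    """
    lines = [f"# {artifacts.get('title', 'CLD collation report')}", ""]

    manifest = artifacts.get("manifest")
    if manifest:
        lines += ["## Run",
                  "",
                  f"- diagrams merged: {manifest.get('n_clds', '?')}",
                  f"- unique variables: {manifest.get('unique_variables', '?')}",
                  f"- unique causal links: {manifest.get('unique_links', '?')}",
                  f"- variable cut (R+C >=): {manifest.get('variable_cut', '?')}",
                  f"- edge cut (diagram count >=): {manifest.get('edge_min_count', '?')}",
                  ""]

    lines += ["## Variable ranking", ""]
    ranking = artifacts.get("ranking")
    lines += [_fmt(ranking) if ranking is not None and len(ranking) else _PLACEHOLDER, ""]

    lines += ["## Prominence / relation scatter data", ""]
    scatter = artifacts.get("scatter")
    lines += [_fmt(scatter) if scatter is not None and len(scatter) else _PLACEHOLDER, ""]

    lines += ["## Cut-point sensitivity", ""]
    sens = artifacts.get("sensitivity")
    lines += [_fmt(sens) if sens is not None and len(sens) else _PLACEHOLDER, ""]

    lines += ["## Summary diagram", ""]
    summary = artifacts.get("summary")
    if summary is None:
        lines += [_PLACEHOLDER, ""]
    else:
        edges = summary if isinstance(summary, pd.DataFrame) else pd.DataFrame(
            [{"source": l.source, "target": l.target, "count": l.count,
              "polarity": "+" if (l.polarity or 1) > 0 else "-"}
             for l in summary.links])
        if len(edges):
            lines += [_md_table(edges), ""]
        else:
            lines += ["_summary diagram has no links_", ""]
        if not isinstance(summary, pd.DataFrame) and summary.isolated_variables:
            lines += ["Isolated retained variables: "
                      + ", ".join(summary.isolated_variables), ""]
    return "\n".join(lines)


def plot_scatter(scores, cut: float | None = None, ax=None):
    """Prominence (x) vs relation (y) scatter plot; needs matplotlib."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    ax.scatter(scores.prominence, scores.relation, s=18)
    if cut is not None:
        ax.axvline(cut, linestyle="--", linewidth=1)
    ax.axhline(0.0, linewidth=0.6, color="grey")
    ax.set_xlabel("prominence (R + C)")
    ax.set_ylabel("relation (R - C)")
    return ax
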