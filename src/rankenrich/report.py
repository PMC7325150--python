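"""Self-contained HTML report: result tables plus embedded charts.

The report is a single file with every chart inlined as a base64 PNG, so it
can be mailed around and opened offline with zero network requests.  Apart
from one timestamp line the output is byte-stable for identical inputs.
"""

from __future__ import annotations

import base64
import io
from datetime import datetime, timezone
from typing import Sequence

import matplotlib.pyplot as plt
import pandas as pd

from .enrichment import ResultTable
from .plots import global_figures, set_detail_figures, _check_contrasts

__all__ = ["render_html"]

_CSS = """
body { font-family: sans-serif; margin: 2em auto; max-width: 70em; color: #222; }
h1, h2 { color: #113; }
table { border-collapse: collapse; font-size: 0.85em; }
th, td { border: 1px solid #ccc; padding: 0.25em 0.6em; text-align: right; }
th { background: #eef; }
td:first-child, th:first-child { text-align: left; }
img { max-width: 100%; border: 1px solid #eee; margin: 0.5em 0; }
.meta { color: #666; font-size: 0.9em; }
"""


def _fig_to_img(fig: plt.Figure, label: str) -> str:
    buf = io.BytesIO()
    fig.savefig(
        buf, format="png", dpi=90, bbox_inches="tight",
        metadata={"Software": "rankenrich"},
    )
    plt.close(fig)
    data = base64.b64encode(buf.getvalue()).decode("ascii")
    return f'<figure><img alt="{label}" src="data:image/png;base64,{data}"/></figure>'


def render_html(
    result: ResultTable,
    ranked: pd.DataFrame,
    path,
    profile: pd.DataFrame | None = None,
    library=None,
    detail_sets: Sequence[str] | None = None,
    title: str = "Multi-contrast enrichment report",
) -> None:
    """Write a single self-contained HTML report.

    Contains the analysis metadata, the full prioritised result table, the
    global diagnostic charts and (when *library* is given) detail charts for
    *detail_sets*, defaulting to the result's top-priority selection.
    """
    _check_contrasts(ranked.shape[1])
    parts: list[str] = [
        "<!DOCTYPE html>",
        f"<html><head><meta charset='utf-8'><title>{title}</title>",
        f"<style>{_CSS}</style></head><body>",
        f"<h1>{title}</h1>",
        "<p class='timestamp meta'>Generated: "
        + datetime.now(timezone.utc).strftime("%Y-%m-%d %H:%M:%S UTC")
        + "</p>",
        "<h2>Analysis</h2><ul class='meta'>",
        f"<li>contrasts: {', '.join(result.contrasts)}</li>",
        f"<li>genes in profile: {result.n_genes}</li>",
        f"<li>gene sets tested: {len(result.table)} "
        f"(excluded by size filter: {result.n_sets_excluded}, "
        f"minimum size {result.min_size})</li>",
        f"<li>prioritisation: {result.priority}</li>",
        f"<li>sets with FDR &lt; 0.05: {int((result.table['p.manovaFDR'] < 0.05).sum())}</li>",
        "</ul>",
        "<h2>Global diagnostics</h2>",
    ]
    for label, fig in global_figures(result, ranked, profile):
        parts.append(_fig_to_img(fig, label))

    parts.append("<h2>Enrichment results</h2>")
    parts.append(result.table.to_html(index=False, float_format="%.4g", border=0))

    if library is not None:
        if detail_sets is None:
            detail_sets = result.detailed_sets
        if detail_sets:
            parts.append("<h2>Top gene sets</h2>")
        for name in detail_sets:
            parts.append(f"<h3>{name}</h3>")
            for label, fig in set_detail_figures(ranked, library[name].members, name):
                parts.append(_fig_to_img(fig, label))

    parts.append("</body></html>")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(parts))
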