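"""Static plots and the self-contained HTML report.

Plots are rendered with the matplotlib Agg backend to PNG bytes and
embedded base64 into a single HTML page alongside the machine-readable
TSV tables, so the report opens anywhere with no network access.
"""

from __future__ import annotations

import base64
import html as _html
import io
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .abacus import CoverageHistogram  # noqa: E402
from .curves import GrowthCurve  # noqa: E402

__all__ = [
    "plot_histogram",
    "plot_curves",
    "plot_ordered_growth",
    "build_html",
]


def _fig_to_png(fig) -> bytes:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=110, bbox_inches="tight")
    plt.close(fig)
    return buf.getvalue()


def plot_histogram(hist: CoverageHistogram, title: str = "") -> bytes:
    """Bar chart of h(i) for i = 1..n (h(0) is reporting-only)."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    i = np.arange(1, hist.n + 1)
    ax.bar(i, hist.h[1:], color="#4878a8")
    ax.set_xlabel("coverage (number of groups)")
    ax.set_ylabel(f"{hist.kind.value} count" if hist.kind.value != "bp"
                  else "base pairs")
    ax.set_title(title or f"{hist.kind.value} coverage histogram")
    return _fig_to_png(fig)


def plot_curves(curves: Sequence[GrowthCurve], kind: str,
                title: str = "") -> bytes:
    """Growth curves solid, core curves (quorum 1) dashed."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    m = None
    for curve in curves:
        m = np.arange(1, curve.n + 1)
        q = float(curve.spec.quorum) if curve.spec.quorum else 0.0
        style = "--" if q >= 1 else ("-." if q > 0 else "-")
        ax.plot(m, curve.values, style, label=curve.spec.label())
    ax.set_xlabel("number of groups m")
    ax.set_ylabel(f"expected {kind} total")
    ax.set_title(title or f"{kind} growth / core curves")
    if m is not None:
        ax.set_xticks(m if len(m) <= 20 else m[:: max(1, len(m) // 20)])
    ax.legend(fontsize=8)
    return _fig_to_png(fig)


def plot_ordered_growth(labels: Sequence[str], cumulative: np.ndarray,
                        kind: str, title: str = "") -> bytes:
    """Cumulative union per added group along one fixed order (bars)."""
    fig, ax = plt.subplots(figsize=(max(6, 0.4 * len(labels)), 3.5))
    x = np.arange(1, len(labels) + 1)
    base = np.concatenate([[0.0], cumulative[:-1]])
    ax.bar(x, base, color="#c8c8c8")
    ax.bar(x, cumulative - base, bottom=base, color="#4878a8")
    ax.set_xticks(x)
    ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.set_ylabel(f"cumulative {kind} total")
    ax.set_title(title or f"ordered {kind} growth")
    return _fig_to_png(fig)


def _table_html(tsv_text: str) -> str:
    rows = [r.split("\t") for r in tsv_text.strip().split("\n")]
    out = ["<table border='1' cellspacing='0' cellpadding='3'>"]
    for j, row in enumerate(rows):
        tag = "th" if j == 0 else "td"
        cells = "".join(f"<{tag}>{_html.escape(c)}</{tag}>" for c in row)
        out.append(f"<tr>{cells}</tr>")
    out.append("</table>")
    return "\n".join(out)


def build_html(
    title: str,
    sections: Sequence[tuple[str, Optional[str], Optional[bytes]]],
    max_table_rows: int = 200,
) -> str:
    """Assemble a standalone HTML report.

    Each section is (heading, tsv_text or None, png_bytes or None); tables
    are rendered and also embedded verbatim in a <pre> block for
    machine consumption. No external assets are referenced.
    """
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        f"<title>{_html.escape(title)}</title>",
        "<style>body{font-family:sans-serif;margin:2em;}"
        "table{border-collapse:collapse;font-size:12px;}"
        "pre{background:#f4f4f4;padding:8px;overflow-x:auto;}</style>",
        "</head><body>",
        f"<h1>{_html.escape(title)}</h1>",
    ]
    for heading, tsv_text, png in sections:
        parts.append(f"<h2>{_html.escape(heading)}</h2>")
        if png is not None:
            b64 = base64.b64encode(png).decode("ascii")
            parts.append(f"<img src='data:image/png;base64,{b64}'/>")
        if tsv_text is not None:
            lines = tsv_text.strip().split("\n")
            shown = "\n".join(lines[: max_table_rows + 1])
            parts.append(_table_html(shown))
            if len(lines) > max_table_rows + 1:
                parts.append(
                    f"<p>({len(lines) - 1} rows total; table truncated, "
                    "full data below)</p>"
                )
            parts.append(f"<pre>{_html.escape(tsv_text)}</pre>")
    parts.append("</body></html>")
    return "\n".join(parts)
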