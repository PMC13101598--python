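"""Chromatogram plotting and the per-sample HTML batch report.

The report is a single self-contained HTML file: per sample the motif
window chromatogram, the control chromatogram when the control is a
trace read in the same orientation, the noise-model parameters and the
editing table.  Images are embedded as base64 PNGs so the file opens
offline.
"""

from __future__ import annotations

import base64
import io
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from jinja2 import Template

from .batch import BatchResult, ParametersTable
from .detect import EditDetectionResult
from .trace_io import BASES, Chromatogram

__all__ = [
    "plot_chromatogram_window",
    "plot_sample_chromatogram",
    "plot_control_chromatogram",
    "plot_editing_barplot",
    "create_report",
]

# Conventional Sanger channel colours.
CHANNEL_COLORS = {"A": "#2ca02c", "C": "#1f77b4", "G": "#333333", "T": "#d62728"}


def plot_chromatogram_window(
    chrom: Chromatogram,
    call_start: int,
    call_end: int,
    ax: plt.Axes | None = None,
    labels: list[str] | None = None,
    title: str = "",
) -> plt.Axes:
    """Plot the four-channel trace across a call-index window.

    ``labels`` (one per call in the window) annotate the x axis, e.g.
    protospacer positions.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, (call_end - call_start) * 0.45), 2.8))
    margin = 2
    lo_call = max(0, call_start - margin)
    hi_call = min(chrom.n_bases - 1, call_end - 1 + margin)
    peaks = chrom.peak_locations
    spacing = int(peaks[1] - peaks[0]) if chrom.n_bases > 1 else 10
    lo = max(0, int(peaks[lo_call]) - spacing // 2)
    hi = min(chrom.trace_length, int(peaks[hi_call]) + spacing // 2)
    x = range(lo, hi)
    for b in BASES:
        ax.plot(x, chrom.channel_traces[b][lo:hi], color=CHANNEL_COLORS[b], lw=1.2,
                label=b)
    ticks = [int(peaks[i]) for i in range(call_start, call_end)]
    if labels is None:
        labels = [chrom.basecalls[i] for i in range(call_start, call_end)]
    ax.set_xticks(ticks, labels, fontsize=8)
    ax.set_yticks([])
    ax.set_xlim(lo, hi)
    ax.legend(loc="upper right", fontsize=7, ncol=4, frameon=False)
    if title:
        ax.set_title(title, fontsize=9)
    for side in ("top", "right", "left"):
        ax.spines[side].set_visible(False)
    return ax


def plot_sample_chromatogram(result: EditDetectionResult, ax=None) -> plt.Axes:
    """Motif-window trace of the sample, x-labelled by protospacer position."""
    start, end = result.motif_location.sample_interval
    labels = [
        f"{result.sample.basecalls[start + k]}\n{result.motif_location.protospacer_of_offset[k]}"
        for k in range(end - start)
    ]
    return plot_chromatogram_window(
        result.sample, start, end, ax=ax, labels=labels,
        title=f"sample {result.sample.source_name}",
    )


def plot_control_chromatogram(result: EditDetectionResult, ax=None) -> plt.Axes | None:
    """Motif-window trace of the control, or None when not renderable.

    Shown only for trace controls aligned in the same orientation as the
    sample (otherwise the window cannot be displayed base-for-base).
    """
    control = result.control
    if (
        control is None
        or not control.is_trace
        or result.alignment is None
        or result.alignment.control_orientation != "forward"
    ):
        return None
    start, end = result.motif_location.sample_interval
    mapped = [
        result.alignment.pairs[i] for i in range(start, end) if i in result.alignment.pairs
    ]
    if not mapped:
        return None
    lo, hi = min(mapped), max(mapped) + 1
    return plot_chromatogram_window(
        control.chromatogram, lo, hi, ax=ax,
        title=f"control {control.source_name}",
    )


def plot_editing_barplot(result: EditDetectionResult, ax=None) -> plt.Axes:
    """Edit percent per candidate protospacer position, significance-coloured."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 2.5))
    df = result.sample_data
    colors = ["#d62728" if s else "#aaaaaa" for s in df["significant"]]
    ax.bar(df["protospacer_position"].astype(str), 100 * df["edit_percent"],
           color=colors)
    ax.set_xlabel(f"protospacer position ({result.spec.wt_base}"
                  f"→{result.spec.edit_base})", fontsize=8)
    ax.set_ylabel("% edit signal", fontsize=8)
    ax.set_ylim(0, 100)
    return ax


def _fig_to_base64(ax) -> str:
    fig = ax.figure
    buf = io.BytesIO()
    fig.tight_layout()
    fig.savefig(buf, format="png", dpi=110)
    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode()


_TEMPLATE = Template(
    """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Base-edit detection report</title>
<style>
body { font-family: sans-serif; margin: 2em; max-width: 70em; }
table { border-collapse: collapse; font-size: 0.85em; }
td, th { border: 1px solid #ccc; padding: 3px 8px; }
.err { color: #a00; }
h2 { border-bottom: 1px solid #ddd; padding-bottom: 2px; }
</style></head><body>
<h1>Base-edit detection report</h1>
{% if not samples %}<p>No samples were analyzed.</p>{% endif %}
{% for s in samples %}
<h2>{{ s.name }}</h2>
{% if s.error %}
<p class="err">Analysis failed: {{ s.error }}</p>
{% else %}
<p>motif {{ s.motif }} (motif_fwd={{ s.motif_fwd }}, {{ s.wt }}&rarr;{{ s.edit }})</p>
<h3>Sample chromatogram</h3>
<img src="data:image/png;base64,{{ s.sample_png }}">
{% if s.control_png %}
<h3>Control chromatogram</h3>
<img src="data:image/png;base64,{{ s.control_png }}">
{% else %}
<p><i>Control chromatogram not shown (FASTA control, opposite orientation,
or control does not cover the motif).</i></p>
{% endif %}
<h3>Model parameters</h3>
<table><tr><th>zero mass &nu;</th><th>mean &mu;</th><th>dispersion &sigma;</th>
<th>n obs</th></tr>
<tr><td>{{ "%.4f"|format(s.model.zero_mass) }}</td>
<td>{{ "%.4g"|format(s.model.mean) }}</td>
<td>{{ "%.4g"|format(s.model.dispersion) }}</td>
<td>{{ s.model.n_obs }}</td></tr></table>
<h3>Editing data</h3>
{{ s.table_html }}
<h3>Editing barplot</h3>
<img src="data:image/png;base64,{{ s.barplot_png }}">
{% for w in s.warnings %}<p class="err">warning: {{ w }}</p>{% endfor %}
{% endif %}
{% endfor %}
</body></html>
"""
)


def create_report(
    batch: BatchResult,
    out_path: str | Path,
    parameters: ParametersTable | None = None,
) -> Path:
    """Write the batch HTML report; returns the path written."""
    samples = []
    for name, status in batch.statuses.items():
        if status != "ok":
            samples.append({"name": name, "error": status})
            continue
        result = batch.results[name]
        control_ax = plot_control_chromatogram(result)
        samples.append(
            {
                "name": name,
                "error": None,
                "motif": result.spec.motif,
                "motif_fwd": result.spec.motif_fwd,
                "wt": result.spec.wt_base,
                "edit": result.spec.edit_base,
                "sample_png": _fig_to_base64(plot_sample_chromatogram(result)),
                "control_png": _fig_to_base64(control_ax) if control_ax else None,
                "model": result.statistical_parameters,
                "table_html": result.sample_data.to_html(
                    index=False, float_format=lambda v: f"{v:.4g}"
                ),
                "barplot_png": _fig_to_base64(plot_editing_barplot(result)),
                "warnings": result.warnings,
            }
        )
    html = _TEMPLATE.render(samples=samples)
    out_path = Path(out_path)
    out_path.write_text(html)
    return out_path
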