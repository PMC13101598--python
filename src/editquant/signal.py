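"""Per-base channel signal extraction and Phred quality filtering.

Every called base gets the four channel intensities sampled at its peak
location, normalised to percent signals.  The "phred cutoff" is an error
*probability* threshold (default 0.001, i.e. Q30): a base passes when
its probability of being miscalled is at or below the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trace_io import BASES, Chromatogram

__all__ = [
    "SignalTable",
    "build_signal_table",
    "phred_to_error_prob",
    "apply_quality_filter",
]

DEFAULT_PHRED_CUTOFF = 0.001

PERCENT_COLS = [f"percent_{b}" for b in BASES]
HEIGHT_COLS = [f"height_{b}" for b in BASES]


@dataclass
class SignalTable:
    """Per-base signal percentages for one chromatogram.

    ``data`` has one row per called base with columns: ``position``
    (0-based call index), ``called_base``, ``height_A..T``,
    ``percent_A..T``, ``quality``, ``error_prob``, ``valid`` (total
    height > 0), ``passes_quality`` and ``in_kept_range``.
    ``kept_range`` is the half-open call-index interval surviving
    end-trimming (meaningful only after :func:`apply_quality_filter`).
    """

    data: pd.DataFrame
    source_name: str = ""
    phred_cutoff: float | None = None
    kept_range: tuple[int, int] | None = None

    def __len__(self) -> int:
        return len(self.data)


def phred_to_error_prob(q) -> float:
    """Error probability 10^(-Q/10) for a Phred score Q >= 0."""
    q = np.asarray(q)
    if np.any(q < 0):
        raise ValueError("Phred scores must be non-negative")
    out = 10.0 ** (-q / 10.0)
    return float(out) if out.ndim == 0 else out


def build_signal_table(chromatogram: Chromatogram) -> SignalTable:
    """Sample channel heights at every peak and normalise to percents.

    Rows whose four heights are all zero are flagged invalid (``valid``
    False) and carry NaN percents; they are excluded downstream rather
    than raising.
    """
    peaks = chromatogram.peak_locations
    heights = np.column_stack(
        [chromatogram.channel_traces[b][peaks] for b in BASES]
    ).astype(float)
    totals = heights.sum(axis=1)
    valid = totals > 0
    percents = np.full_like(heights, np.nan)
    percents[valid] = heights[valid] / totals[valid, None]

    qualities = chromatogram.qualities
    data = pd.DataFrame(
        {
            "position": np.arange(chromatogram.n_bases),
            "called_base": list(chromatogram.basecalls),
            **{col: heights[:, i] for i, col in enumerate(HEIGHT_COLS)},
            **{col: percents[:, i] for i, col in enumerate(PERCENT_COLS)},
            "quality": qualities,
            "error_prob": phred_to_error_prob(qualities),
            "valid": valid,
            "passes_quality": True,
            "in_kept_range": True,
        }
    )
    return SignalTable(data=data, source_name=chromatogram.source_name)


def apply_quality_filter(
    table: SignalTable, phred_cutoff: float = DEFAULT_PHRED_CUTOFF
) -> SignalTable:
    """Flag rows by quality and trim low-quality read ends.

    A row passes when ``error_prob <= phred_cutoff``.  The longest
    contiguous head and tail of failing rows define the trimmed ends;
    ``kept_range`` is the remaining half-open interval.  Interior
    failing rows stay in range but are flagged, so motif rows are never
    silently dropped.
    """
    if not (0 < phred_cutoff <= 1):
        raise ValueError(f"phred cutoff must be in (0, 1], got {phred_cutoff}")
    data = table.data.copy()
    passes = (data["error_prob"].to_numpy() <= phred_cutoff) & data["valid"].to_numpy()
    data["passes_quality"] = passes

    n = len(data)
    start = 0
    while start < n and not passes[start]:
        start += 1
    end = n
    while end > start and not passes[end - 1]:
        end -= 1
    in_range = np.zeros(n, dtype=bool)
    in_range[start:end] = True
    data["in_kept_range"] = in_range
    return SignalTable(
        data=data,
        source_name=table.source_name,
        phred_cutoff=phred_cutoff,
        kept_range=(start, end),
    )
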