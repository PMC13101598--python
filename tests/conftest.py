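"""Shared synthetic-trace helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from editquant import ControlSequence, SyntheticSpec, synthesize_pair

# GZMA exon 1 splice-donor guide: the A in the canonical window sits at
# protospacer position 5.
GZMA_GUIDE = "TCTTACCTTCAGGAATTAGC"
DNMT3A_GUIDE = "GGACTCACCCGCTTCTGCAG"


def embed_motif(
    motif: str, seed: int, left: int = 50, right: int = 60
) -> tuple[str, int]:
    """Random template with ``motif`` embedded; returns (template, offset)."""
    rng = np.random.default_rng(seed)
    flank_l = "".join(rng.choice(list("ACGT"), left))
    flank_r = "".join(rng.choice(list("ACGT"), right))
    return flank_l + motif + flank_r, left


def synth_pair(
    motif: str = GZMA_GUIDE,
    edits_at: dict[int, tuple[str, float]] | None = None,
    seed: int = 0,
    **spec_kwargs,
):
    """Synthetic (sample, trace-backed control) pair.

    ``edits_at`` maps 1-based protospacer positions (motif read as
    given, forward orientation) to (edit_base, fraction).
    """
    template, offset = embed_motif(motif, seed)
    edits = {}
    for pos, (base, frac) in (edits_at or {}).items():
        edits[offset + pos - 1] = (base, frac)
    spec = SyntheticSpec(
        template_sequence=template, edits=edits, seed=seed, **spec_kwargs
    )
    sample, control = synthesize_pair(spec)
    ctrl = ControlSequence(
        sequence=control.basecalls,
        is_trace=True,
        source_name=control.source_name,
        chromatogram=control,
    )
    return sample, ctrl


@pytest.fixture
def gzma_pair():
    """Unedited pair around the GZMA guide (seed 0)."""
    return synth_pair(seed=0)


def random_chromatogram(seed: int, n_bases: int = 30):
    """A structurally valid random trace (not peak-shaped; for IO tests)."""
    from editquant import Chromatogram

    rng = np.random.default_rng(seed)
    spacing = 10
    traces = {
        b: rng.integers(0, 3000, n_bases * spacing) for b in "ACGT"
    }
    return Chromatogram(
        channel_traces=traces,
        peak_locations=np.arange(n_bases) * spacing + 5,
        basecalls="".join(rng.choice(list("ACGTN"), n_bases, p=[0.24] * 4 + [0.04])),
        qualities=rng.integers(0, 61, n_bases),
        source_name=f"random{seed}",
    )
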