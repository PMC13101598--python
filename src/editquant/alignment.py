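"""Motif location, sample/control alignment and coordinate mapping.

The gRNA protospacer ("motif") is entered 5'->3'.  ``motif_fwd`` states
whether the gRNA and the sequencing primer read the same strand: when
False the motif is searched as its reverse complement and protospacer
numbering runs antiparallel to the read.  Protospacer positions are
1..len(motif) with the highest position adjacent to the PAM.

Sample and control are aligned locally in both orientations and the
higher-scoring orientation wins, so the control file orientation is
matched to the sample automatically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .trace_io import ControlSequence, reverse_complement

__all__ = [
    "MotifSpec",
    "MotifLocation",
    "AlignmentMap",
    "MotifNotFoundError",
    "AmbiguousMotifError",
    "ControlMismatchError",
    "locate_motif",
    "align_sample_control",
    "control_bases_at_motif",
]

UNALIGNED = "unaligned"

# Conservative Sanger-appropriate local-alignment scores.
MATCH_SCORE = 2
MISMATCH_SCORE = -3
GAP_OPEN_SCORE = -5
GAP_EXTEND_SCORE = -2

# Motif search tolerates mismatches so heavily edited samples still
# locate: budget is ceil(20% of motif length).
MISMATCH_FRACTION = 0.2


class MotifNotFoundError(ValueError):
    pass


class AmbiguousMotifError(ValueError):
    pass


class ControlMismatchError(ValueError):
    pass


@dataclass
class MotifSpec:
    """gRNA motif plus the wild-type/edited base pair under study.

    ``wt_base`` and ``edit_base`` are given on the *read* strand: for an
    adenine base editor they are A->G when motif_fwd is true and T->C
    when false.
    """

    motif: str
    motif_fwd: bool
    wt_base: str
    edit_base: str

    def __post_init__(self) -> None:
        self.motif = self.motif.upper()
        self.wt_base = self.wt_base.upper()
        self.edit_base = self.edit_base.upper()
        if not (10 <= len(self.motif) <= 30):
            raise ValueError(
                f"motif length must be 10-30 nt, got {len(self.motif)}"
            )
        if any(ch not in "ACGT" for ch in self.motif):
            raise ValueError("motif must be over A, C, G, T")
        for name, b in (("wt", self.wt_base), ("edit", self.edit_base)):
            if b not in "ACGT":
                raise ValueError(f"{name} base must be one of A, C, G, T, got {b!r}")
        if self.wt_base == self.edit_base:
            raise ValueError("wt and edit base must differ")
        if self.wt_base not in self.oriented_motif:
            raise ValueError(
                f"motif (oriented for motif_fwd={self.motif_fwd}) contains no "
                f"{self.wt_base!r}; nothing to test"
            )

    @property
    def oriented_motif(self) -> str:
        """The motif as it should appear in the read."""
        return self.motif if self.motif_fwd else reverse_complement(self.motif)


@dataclass
class MotifLocation:
    """Placement of the motif in the sample read.

    ``sample_interval`` is a 0-based half-open call-index range;
    ``protospacer_of_offset[k]`` gives the 1-based protospacer position
    of call index ``sample_interval[0] + k``.
    """

    sample_interval: tuple[int, int]
    motif_fwd: bool
    n_mismatches: int
    protospacer_of_offset: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        length = self.sample_interval[1] - self.sample_interval[0]
        if not self.protospacer_of_offset:
            if self.motif_fwd:
                self.protospacer_of_offset = tuple(range(1, length + 1))
            else:
                self.protospacer_of_offset = tuple(range(length, 0, -1))

    def call_index(self, protospacer_position: int) -> int:
        """Sample call index carrying the given protospacer position."""
        k = self.protospacer_of_offset.index(protospacer_position)
        return self.sample_interval[0] + k


@dataclass
class AlignmentMap:
    """Monotone pairing of sample call indices to control indices.

    ``pairs`` maps sample index -> index into the *oriented* control
    sequence (the reverse complement when ``control_orientation`` is
    "reverse-complement"), so the base looked up through the map is
    already on the read strand.
    """

    pairs: dict[int, int]
    control_orientation: str  # "forward" | "reverse-complement"
    score: float
    identity: float
    oriented_control: str

    def control_base(self, sample_index: int) -> str:
        i = self.pairs.get(sample_index)
        return UNALIGNED if i is None else self.oriented_control[i]


def _mismatch_scan(text: str, pattern: str) -> np.ndarray:
    """Hamming distance of ``pattern`` against every window of ``text``."""
    m = len(pattern)
    n = len(text) - m + 1
    if n <= 0:
        return np.empty(0, dtype=int)
    t = np.frombuffer(text.encode(), dtype=np.uint8)
    p = np.frombuffer(pattern.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(t, m)
    return (windows != p).sum(axis=1)


def locate_motif(sample_basecalls: str, spec: MotifSpec) -> MotifLocation:
    """Find the (oriented) motif in the sample base calls.

    Allows up to ceil(20% of motif length) mismatches so that already
    edited or noisy bases do not defeat the search.  Exactly one best
    hit is required: two or more loci tying at the minimal mismatch
    count raise :class:`AmbiguousMotifError`.
    """
    sample = sample_basecalls.upper()
    target = spec.oriented_motif
    m = len(target)
    if len(sample) < m:
        raise MotifNotFoundError(
            f"sample ({len(sample)} nt) shorter than motif {spec.motif}"
        )
    budget = math.ceil(MISMATCH_FRACTION * m)
    dists = _mismatch_scan(sample, target)
    best = int(dists.min())
    if best > budget:
        raise MotifNotFoundError(
            f"motif {spec.motif} not found in sample within {budget} mismatches "
            f"(closest window has {best})"
        )
    hits = np.flatnonzero(dists == best)
    # Windows overlapping the single best locus are distinct loci only
    # when separated by at least a motif length.
    if len(hits) > 1:
        raise AmbiguousMotifError(
            f"motif {spec.motif} matches {len(hits)} loci equally well "
            f"({best} mismatches) at sample positions {hits.tolist()}"
        )
    start = int(hits[0])
    return MotifLocation(
        sample_interval=(start, start + m),
        motif_fwd=spec.motif_fwd,
        n_mismatches=best,
    )


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN_SCORE
    aligner.extend_gap_score = GAP_EXTEND_SCORE
    return aligner

_MIN_IDENTITY = 0.5


def align_sample_control(
    sample_basecalls: str, control: ControlSequence
) -> AlignmentMap:
    """Local alignment of the sample against the control, both strands.

    The higher-scoring orientation is kept; matched/mismatched columns
    become index pairs (gap columns produce no pair).  Identity below
    0.5 over the aligned span raises :class:`ControlMismatchError`.
    """
    sample = sample_basecalls.upper()
    if len(sample) < 20 or len(control.sequence) < 20:
        raise ValueError("sample and control must both be at least 20 nt")
    aligner = _aligner()
    candidates = []
    for orientation, ctrl_seq in (
        ("forward", control.sequence.upper()),
        ("reverse-complement", reverse_complement(control.sequence.upper())),
    ):
        aln = aligner.align(sample, ctrl_seq)[0]
        candidates.append((aln.score, orientation, ctrl_seq, aln))
    candidates.sort(key=lambda c: c[0], reverse=True)
    score, orientation, ctrl_seq, aln = candidates[0]

    pairs: dict[int, int] = {}
    matches = 0
    for (s0, s1), (c0, c1) in zip(*aln.aligned):
        for k in range(s1 - s0):
            si, ci = s0 + k, c0 + k
            pairs[si] = ci
            if sample[si] == ctrl_seq[ci]:
                matches += 1
    if not pairs:
        raise ControlMismatchError(
            f"control {control.source_name or '<control>'} does not align to sample"
        )
    identity = matches / len(pairs)
    # Unrelated sequences still produce a short, locally perfect span, so
    # a genuine control must also cover a substantial part of the shorter
    # sequence, not just exceed the identity floor.
    min_span = max(20, min(len(sample), len(control.sequence)) // 2)
    if identity < _MIN_IDENTITY or len(pairs) < min_span:
        raise ControlMismatchError(
            f"control {control.source_name or '<control>'} does not match sample "
            f"(best identity {identity:.2f} over {len(pairs)} aligned columns "
            f"in {orientation} orientation)"
        )
    return AlignmentMap(
        pairs=pairs,
        control_orientation=orientation,
        score=float(score),
        identity=identity,
        oriented_control=ctrl_seq,
    )


def control_bases_at_motif(
    location: MotifLocation,
    alignment: AlignmentMap,
    control: ControlSequence,
) -> dict[int, str]:
    """Read-strand control base for every protospacer position.

    Positions falling in an alignment gap (or outside the aligned span)
    map to ``"unaligned"``.
    """
    start, end = location.sample_interval
    out: dict[int, str] = {}
    for k in range(end - start):
        pos = location.protospacer_of_offset[k]
        out[pos] = alignment.control_base(start + k)
    return out
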