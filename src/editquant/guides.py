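"""Protospacer arithmetic: editing-window enumeration and PAM offsets.

Protospacer positions are numbered 1-20 from the 5' end, position 20
adjacent to the PAM.  The canonical adenine-base-editor window is
positions 4-9, i.e. 11-16 nucleotides upstream of the PAM.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["EditingWindow", "window_positions", "pam_offset"]

PROTOSPACER_LENGTH = 20


@dataclass(frozen=True)
class EditingWindow:
    """Inclusive protospacer position range accessible to the deaminase."""

    start: int = 4
    end: int = 9

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end <= PROTOSPACER_LENGTH):
            raise ValueError(
                f"window must satisfy 1 <= start <= end <= {PROTOSPACER_LENGTH}, "
                f"got [{self.start}, {self.end}]"
            )


def window_positions(
    protospacer: str,
    window: EditingWindow = EditingWindow(),
    target_base: str = "A",
) -> list[int]:
    """Positions of ``target_base`` inside the editing window.

    ``protospacer`` must be the full 20-nt guide, 5'->3'.  Returned
    positions are 1-based and sorted.
    """
    protospacer = protospacer.upper()
    if len(protospacer) != PROTOSPACER_LENGTH:
        raise ValueError(
            f"protospacer must be {PROTOSPACER_LENGTH} nt, got {len(protospacer)}"
        )
    target_base = target_base.upper()
    if target_base not in "ACGT":
        raise ValueError(f"target base must be one of A, C, G, T, got {target_base!r}")
    return [
        p
        for p in range(window.start, window.end + 1)
        if protospacer[p - 1] == target_base
    ]


def pam_offset(position: int) -> int:
    """Nucleotides upstream of the PAM for a protospacer position.

    Position 20 is PAM-adjacent (offset 0); position 4 is 16 nt
    upstream.
    """
    if not (1 <= position <= PROTOSPACER_LENGTH):
        raise ValueError(
            f"protospacer position must be in 1..{PROTOSPACER_LENGTH}, got {position}"
        )
    return PROTOSPACER_LENGTH - position
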