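"""Chromatogram container and ABIF/FASTA input-output.

A Sanger chromatogram is represented as four per-channel fluorescence
intensity series (one per nucleotide), together with the basecaller's
peak locations, base calls and Phred qualities.  Reading uses
Biopython's ABI parser; a minimal ABIF writer is provided so that
synthetic traces can round-trip through real files.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = [
    "Chromatogram",
    "ControlSequence",
    "TraceFormatError",
    "read_ab1",
    "read_control",
    "write_abif",
    "reverse_complement",
    "reverse_complement_chromatogram",
]

BASES = ("A", "C", "G", "T")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


class TraceFormatError(ValueError):
    """Raised when a trace file is malformed or lacks a required tag."""


@dataclass
class Chromatogram:
    """In-memory representation of an analyzed Sanger trace.

    Parameters
    ----------
    channel_traces
        Mapping base -> intensity series (non-negative ints), all four
        channels present and of equal length.
    peak_locations
        0-based index into the intensity series for each called base,
        strictly increasing.
    basecalls
        One symbol per peak, over {A,C,G,T,N}.
    qualities
        Per-base Phred Q scores (integers >= 0).
    source_name
        Identifier, usually the file name.
    """

    channel_traces: dict[str, np.ndarray]
    peak_locations: np.ndarray
    basecalls: str
    qualities: np.ndarray
    source_name: str = ""

    def __post_init__(self) -> None:
        self.channel_traces = {
            b: np.asarray(v, dtype=np.int64) for b, v in self.channel_traces.items()
        }
        self.peak_locations = np.asarray(self.peak_locations, dtype=np.int64)
        self.qualities = np.asarray(self.qualities, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        if set(self.channel_traces) != set(BASES):
            raise ValueError(
                f"channel_traces must have exactly the keys {BASES}, "
                f"got {sorted(self.channel_traces)}"
            )
        lengths = {len(v) for v in self.channel_traces.values()}
        if len(lengths) != 1:
            raise ValueError("all four channel series must have identical length")
        n_points = lengths.pop()
        n = len(self.basecalls)
        if not (len(self.peak_locations) == n == len(self.qualities)):
            raise ValueError(
                "peak_locations, basecalls and qualities must have equal length "
                f"(got {len(self.peak_locations)}, {n}, {len(self.qualities)})"
            )
        if n == 0:
            raise ValueError("chromatogram has no called bases")
        if np.any(np.diff(self.peak_locations) <= 0):
            raise ValueError("peak_locations must be strictly increasing")
        if self.peak_locations[0] < 0 or self.peak_locations[-1] >= n_points:
            raise ValueError("peak_locations out of range of the trace")
        if any(ch not in "ACGTN" for ch in self.basecalls):
            raise ValueError("basecalls restricted to A, C, G, T, N")
        if np.any(self.qualities < 0):
            raise ValueError("qualities must be non-negative")
        for b, v in self.channel_traces.items():
            if np.any(v < 0):
                raise ValueError(f"negative intensity in channel {b}")

    @property
    def n_bases(self) -> int:
        return len(self.basecalls)

    @property
    def trace_length(self) -> int:
        return len(self.channel_traces["A"])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Chromatogram):
            return NotImplemented
        return (
            self.basecalls == other.basecalls
            and np.array_equal(self.peak_locations, other.peak_locations)
            and np.array_equal(self.qualities, other.qualities)
            and all(
                np.array_equal(self.channel_traces[b], other.channel_traces[b])
                for b in BASES
            )
        )


@dataclass
class ControlSequence:
    """A control reference: a plain sequence, optionally backed by a trace."""

    sequence: str
    is_trace: bool = False
    source_name: str = ""
    chromatogram: Chromatogram | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("control sequence is empty")
        if self.is_trace:
            if self.chromatogram is None:
                raise ValueError("trace-backed control requires a chromatogram")
            if self.chromatogram.basecalls != self.sequence:
                raise ValueError("control sequence differs from its trace basecalls")


# --- ABIF ------------------------------------------------------------------
#
# ABIF is a big-endian directory of tagged entries.  We rely on Biopython
# for reading; writing emits the minimal tag set an analyzed trace needs:
# DATA9-12 (analyzed channels, filter-wheel order FWO_), PLOC2, PBAS2,
# PCON2.  Element types: 1 byte, 2 char, 4 int16.

_REQUIRED_TAGS = ("FWO_1", "DATA9", "DATA10", "DATA11", "DATA12")

_DIR_STRUCT = struct.Struct(">4sihhii4xi")  # name,num,etype,esize,nelem,dsize,(offset)


def read_ab1(path: str | Path) -> Chromatogram:
    """Read an ABIF (.ab1) file into a :class:`Chromatogram`.

    Uses the analyzed trace channels (DATA9-DATA12) mapped to bases via
    the filter-wheel-order tag FWO_, the basecaller peak locations
    (PLOC), base calls (PBAS) and qualities (PCON).

    Raises
    ------
    TraceFormatError
        If the file does not start with the ABIF magic or lacks a
        required tag (the message names the tag).
    """
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic != b"ABIF":
        raise TraceFormatError(f"{path.name}: not an ABIF file (bad magic {magic!r})")
    record = SeqIO.read(str(path), "abi")
    raw = record.annotations["abif_raw"]

    for tag in _REQUIRED_TAGS:
        if tag not in raw:
            raise TraceFormatError(f"{path.name}: required ABIF tag {tag[:4]} missing")

    def pick(name: str) -> tuple[str, object]:
        # Basecaller entries use tag number 2; accept 1 as fallback.
        for key in (f"{name}2", f"{name}1"):
            if key in raw:
                return key, raw[key]
        raise TraceFormatError(f"{path.name}: required ABIF tag {name} missing")

    fwo = raw["FWO_1"]
    if isinstance(fwo, bytes):
        fwo = fwo.decode()
    if sorted(fwo) != ["A", "C", "G", "T"]:
        raise TraceFormatError(f"{path.name}: FWO_ tag {fwo!r} is not a permutation of ACGT")
    channels = {
        base: np.asarray(raw[f"DATA{9 + i}"], dtype=np.int64)
        for i, base in enumerate(fwo)
    }

    _, ploc = pick("PLOC")
    _, pbas = pick("PBAS")
    _, pcon = pick("PCON")
    basecalls = pbas.decode() if isinstance(pbas, bytes) else str(pbas)
    if isinstance(pcon, bytes):
        qualities = np.frombuffer(pcon, dtype=np.uint8).astype(np.int64)
    else:
        qualities = np.asarray(pcon, dtype=np.int64)
    return Chromatogram(
        channel_traces=channels,
        peak_locations=np.asarray(ploc, dtype=np.int64),
        basecalls=basecalls,
        qualities=qualities,
        source_name=path.name,
    )


def read_control(path: str | Path) -> ControlSequence:
    """Read a control from .ab1 (trace-backed) or .fa/.fasta (sequence only).

    A multi-record FASTA uses the first record and emits a warning.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".ab1":
        chrom = read_ab1(path)
        return ControlSequence(
            sequence=chrom.basecalls,
            is_trace=True,
            source_name=path.name,
            chromatogram=chrom,
        )
    if suffix in (".fa", ".fasta"):
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise TraceFormatError(f"{path.name}: FASTA file contains no records")
        if len(records) > 1:
            warnings.warn(
                f"{path.name}: multiple FASTA records; using the first ({records[0].id})",
                stacklevel=2,
            )
        seq = str(records[0].seq).upper()
        return ControlSequence(sequence=seq, is_trace=False, source_name=path.name)
    raise TraceFormatError(
        f"{path.name}: unsupported control extension {suffix!r} (expected .ab1, .fa or .fasta)"
    )


def _dir_entry(name: bytes, number: int, etype: int, esize: int, nelem: int, data: bytes,
               data_offset: int) -> tuple[bytes, bytes, int]:
    """Return (entry bytes, payload written out-of-line, new offset)."""
    dsize = len(data)
    if dsize <= 4:
        offset_field = data.ljust(4, b"\x00")
        entry = struct.pack(">4sihhii", name, number, etype, esize, nelem, dsize)
        entry += offset_field + b"\x00\x00\x00\x00"
        return entry, b"", data_offset
    entry = struct.pack(">4sihhiiii", name, number, etype, esize, nelem, dsize,
                        data_offset, 0)
    return entry, data, data_offset + dsize


def write_abif(chromatogram: Chromatogram, path: str | Path) -> None:
    """Write a minimal valid ABIF file that :func:`read_ab1` reproduces.

    Emits DATA9-12 in FWO_ order "GATC" (the conventional filter-wheel
    order), PLOC2, PBAS2, PCON2.  Intensities and peak locations must
    fit an int16 / uint16 respectively.
    """
    chromatogram.validate()
    path = Path(path)
    fwo = "GATC"
    for b in BASES:
        if chromatogram.channel_traces[b].max(initial=0) > 32767:
            raise ValueError("channel intensities exceed int16 range of ABIF DATA tags")
    if chromatogram.peak_locations[-1] > 32767:
        raise ValueError("peak locations exceed int16 range of ABIF PLOC tag")
    if chromatogram.qualities.max(initial=0) > 255:
        raise ValueError("qualities exceed the 0-255 ABIF PCON range")

    entries: list[tuple[bytes, int, int, int, int, bytes]] = []

    def short_array(values: np.ndarray) -> bytes:
        return values.astype(">i2").tobytes()

    for i, base in enumerate(fwo):
        data = short_array(chromatogram.channel_traces[base])
        entries.append((b"DATA", 9 + i, 4, 2, len(data) // 2, data))
    entries.append((b"FWO_", 1, 2, 1, 4, fwo.encode()))
    ploc = short_array(chromatogram.peak_locations)
    entries.append((b"PLOC", 2, 4, 2, len(ploc) // 2, ploc))
    pbas = chromatogram.basecalls.encode()
    entries.append((b"PBAS", 2, 2, 1, len(pbas), pbas))
    pcon = chromatogram.qualities.astype(np.uint8).tobytes()
    entries.append((b"PCON", 2, 2, 1, len(pcon), pcon))  # char data, like real ab1

    header_size = 128
    dir_entry_size = 28
    data_offset = header_size
    dir_bytes = b""
    payload = b""
    # First pass computes payload placement; entries with data > 4 bytes
    # are written after the 128-byte header, directory last.
    for name, number, etype, esize, nelem, data in entries:
        entry, out, data_offset = _dir_entry(name, number, etype, esize, nelem, data,
                                             data_offset)
        dir_bytes += entry
        payload += out
    dir_offset = data_offset

    header = b"ABIF"
    header += struct.pack(">h", 101)  # version 1.01
    header += struct.pack(">4sihhiiii", b"tdir", 1, 1023, dir_entry_size,
                          len(entries), len(entries) * dir_entry_size, dir_offset, 0)
    header = header.ljust(header_size, b"\x00")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(payload)
        fh.write(dir_bytes)


def reverse_complement_chromatogram(chrom: Chromatogram) -> Chromatogram:
    """The same trace read from the opposite end of the molecule.

    Reverses every channel series, swaps complementary channels, mirrors
    peak locations and reverse-complements the base calls.
    """
    n = chrom.trace_length
    pair = {"A": "T", "T": "A", "C": "G", "G": "C"}
    channels = {b: chrom.channel_traces[pair[b]][::-1].copy() for b in BASES}
    return Chromatogram(
        channel_traces=channels,
        peak_locations=(n - 1 - chrom.peak_locations)[::-1].copy(),
        basecalls=reverse_complement(chrom.basecalls),
        qualities=chrom.qualities[::-1].copy(),
        source_name=chrom.source_name + "(rc)",
    )
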