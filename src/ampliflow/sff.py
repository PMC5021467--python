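"""Reading and writing 454 Standard Flowgram Format (SFF) files.

SFF is the binary container the 454 pyrosequencing pipeline uses for raw
reads: per-flow light-intensity signals (the *flowgram*), called bases, the
flow at which each base was called, per-base qualities and clip points.
Flow signals encode homopolymer run length — a run of n identical bases
ideally yields a signal of n at its single flow — which is why downstream
homopolymer analysis needs flow-space access and not just base calls.

This module implements the public v1 layout: big-endian, a common header
carrying the flow order and key sequence, then one record per read, each
8-byte padded.  ``flow_index_per_base`` is delta-encoded on disk but kept as
absolute 1-based flow numbers in memory; conversion happens only at the I/O
boundary.  The optional read-index block is skipped on read and omitted on
write.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

SFF_MAGIC = 0x2E736666  # ".sff"
SFF_VERSION = b"\x00\x00\x00\x01"
DEFAULT_KEY = "TCAG"
DEFAULT_FLOW_CYCLE = "TACG"

_VALID_FLOW_CHARS = set("ACGT")


class SffFormatError(ValueError):
    """Raised when a file does not conform to the SFF v1 layout."""


class SffValidationError(ValueError):
    """Raised when an in-memory read violates the FlowRead invariants."""


def _pad8(n: int) -> int:
    return (8 - n % 8) % 8


@dataclass(frozen=True)
class SffHeader:
    """Common header of an SFF file.

    ``flow_order`` has one character per flow; its length fixes the number
    of flows every read in the file carries.
    """

    flow_order: str
    key_sequence: str = DEFAULT_KEY
    index_offset: int = 0
    index_length: int = 0

    def __post_init__(self) -> None:
        if not self.flow_order:
            raise SffValidationError("flow_order must be non-empty")
        bad = set(self.flow_order) - _VALID_FLOW_CHARS
        if bad:
            raise SffValidationError(f"flow_order contains invalid characters: {sorted(bad)}")

    @property
    def number_of_flows(self) -> int:
        return len(self.flow_order)

    @classmethod
    def with_cycles(cls, n_cycles: int, cycle: str = DEFAULT_FLOW_CYCLE,
                    key_sequence: str = DEFAULT_KEY) -> "SffHeader":
        """Header with ``n_cycles`` repeats of the nucleotide flow cycle."""
        return cls(flow_order=cycle * n_cycles, key_sequence=key_sequence)


@dataclass
class FlowRead:
    """One read in flow space.

    ``flow_values`` are stored as integer hundredths of a flow unit (the
    on-disk quantization); use :attr:`signals` for float values.
    ``flow_index_per_base`` holds, for each called base, the absolute
    1-based flow at which it was called; all bases of one homopolymer run
    share a flow.  Clip points are 1-based, 0 meaning absent.  ``strand``
    is assigned by downstream alignment, never stored in the file.
    """

    name: str
    flow_values: np.ndarray          # int, hundredths
    flow_index_per_base: np.ndarray  # int, 1-based absolute
    bases: str
    quality: np.ndarray              # int, phred
    clip_qual_left: int = 0
    clip_qual_right: int = 0
    clip_adapter_left: int = 0
    clip_adapter_right: int = 0
    strand: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.flow_values = np.asarray(self.flow_values, dtype=np.int64)
        self.flow_index_per_base = np.asarray(self.flow_index_per_base, dtype=np.int64)
        self.quality = np.asarray(self.quality, dtype=np.int64)

    @property
    def signals(self) -> np.ndarray:
        """Flow signals in flow units (homopolymer-length scale)."""
        return self.flow_values / 100.0

    @property
    def n_bases(self) -> int:
        return len(self.bases)

    def validate(self, header: SffHeader) -> None:
        """Check the FlowRead invariants against ``header``; raise on violation."""
        n = self.n_bases
        if not (len(self.flow_index_per_base) == n == len(self.quality)):
            raise SffValidationError(
                f"read {self.name!r}: bases/flow_index/quality lengths differ "
                f"({n}/{len(self.flow_index_per_base)}/{len(self.quality)})")
        if len(self.flow_values) != header.number_of_flows:
            raise SffValidationError(
                f"read {self.name!r}: {len(self.flow_values)} flow values, "
                f"header declares {header.number_of_flows} flows")
        if np.any(self.flow_values < 0):
            raise SffValidationError(f"read {self.name!r}: negative flow value")
        if n:
            idx = self.flow_index_per_base
            if np.any(np.diff(idx) < 0):
                raise SffValidationError(f"read {self.name!r}: flow_index_per_base decreases")
            if idx[0] < 1 or idx[-1] > header.number_of_flows:
                raise SffValidationError(
                    f"read {self.name!r}: flow index outside [1, {header.number_of_flows}]")
            deltas = np.diff(idx, prepend=0)
            if np.any(deltas > 255):
                raise SffValidationError(
                    f"read {self.name!r}: flow-index gap exceeds the uint8 delta encoding")
            for i, b in enumerate(self.bases):
                if header.flow_order[idx[i] - 1] != b:
                    raise SffValidationError(
                        f"read {self.name!r}: base {i} ({b}) does not match "
                        f"flow {idx[i]} ({header.flow_order[idx[i] - 1]})")

    def clipped(self) -> "FlowRead":
        """Quality/adapter-clipped view of the read (bases, indices, quals).

        Flow values are untouched: flow-space lookups stay valid because
        ``flow_index_per_base`` keeps absolute flow numbers.
        """
        left = max(1, max(self.clip_qual_left, self.clip_adapter_left))
        rights = [c for c in (self.clip_qual_right, self.clip_adapter_right) if c > 0]
        right = min(rights) if rights else self.n_bases
        lo, hi = left - 1, right
        return replace(
            self,
            flow_index_per_base=self.flow_index_per_base[lo:hi],
            bases=self.bases[lo:hi],
            quality=self.quality[lo:hi],
            clip_qual_left=0, clip_qual_right=0,
            clip_adapter_left=0, clip_adapter_right=0,
        )


def base_to_flow(read: FlowRead, base_index: int) -> int:
    """Absolute 1-based flow at which base ``base_index`` (0-based) was called."""
    if not 0 <= base_index < read.n_bases:
        raise IndexError(
            f"base index {base_index} out of range for read {read.name!r} "
            f"of {read.n_bases} bases")
    return int(read.flow_index_per_base[base_index])


# ---------------------------------------------------------------------------
# binary layout

_COMMON_HEADER = struct.Struct(">I4sQIIHHHB")
_READ_HEADER = struct.Struct(">HHIHHHH")


def write_sff(header: SffHeader, reads: list[FlowRead], path: str | Path) -> None:
    """Write ``reads`` under ``header`` to ``path``.

    Every read is validated first; nothing is written if any read violates
    its invariants.  No index block is emitted (index_offset/length 0).
    """
    reads = list(reads)
    for read in reads:
        read.validate(header)
    flow_chars = header.flow_order.encode("ascii")
    key = header.key_sequence.encode("ascii")
    head_len = _COMMON_HEADER.size + len(flow_chars) + len(key)
    head_len += _pad8(head_len)
    blob = bytearray()
    blob += _COMMON_HEADER.pack(
        SFF_MAGIC, SFF_VERSION, 0, 0, len(reads), head_len,
        len(key), header.number_of_flows, 1)
    blob += flow_chars + key
    blob += b"\x00" * _pad8(len(blob))
    for read in reads:
        name = read.name.encode("ascii")
        rh_len = _READ_HEADER.size + len(name)
        rh_len += _pad8(rh_len)
        blob += _READ_HEADER.pack(
            rh_len, len(name), read.n_bases,
            read.clip_qual_left, read.clip_qual_right,
            read.clip_adapter_left, read.clip_adapter_right)
        blob += name
        blob += b"\x00" * _pad8(_READ_HEADER.size + len(name))
        blob += np.asarray(read.flow_values, dtype=">u2").tobytes()
        deltas = np.diff(read.flow_index_per_base, prepend=0)
        blob += deltas.astype(np.uint8).tobytes()
        blob += read.bases.encode("ascii")
        blob += read.quality.astype(np.uint8).tobytes()
        data_len = 2 * header.number_of_flows + 3 * read.n_bases
        blob += b"\x00" * _pad8(data_len)
    Path(path).write_bytes(bytes(blob))


def read_sff(path: str | Path) -> tuple[SffHeader, list[FlowRead]]:
    """Parse an SFF v1 file into its header and reads.

    Raises :class:`SffFormatError` naming the offending byte offset on a bad
    magic/version, and the read index on a truncated record.
    """
    data = Path(path).read_bytes()
    if len(data) < _COMMON_HEADER.size:
        raise SffFormatError(f"{path}: truncated common header (offset 0)")
    (magic, version, index_offset, index_length, n_reads,
     head_len, key_len, n_flows, fmt_code) = _COMMON_HEADER.unpack_from(data, 0)
    if magic != SFF_MAGIC:
        raise SffFormatError(f"{path}: bad magic number at offset 0 ({magic:#010x})")
    if version != SFF_VERSION:
        raise SffFormatError(f"{path}: unsupported version at offset 4 ({version!r})")
    if fmt_code != 1:
        raise SffFormatError(f"{path}: unknown flowgram format code {fmt_code} at offset 30")
    pos = _COMMON_HEADER.size
    flow_order = data[pos:pos + n_flows].decode("ascii")
    pos += n_flows
    key_sequence = data[pos:pos + key_len].decode("ascii")
    header = SffHeader(flow_order=flow_order, key_sequence=key_sequence,
                       index_offset=index_offset, index_length=index_length)
    pos = head_len
    reads: list[FlowRead] = []
    for i in range(n_reads):
        if index_offset and pos == index_offset:
            pos += index_length + _pad8(index_length)  # skip optional index block
        try:
            (rh_len, name_len, n_bases, cql, cqr, cal, car) = _READ_HEADER.unpack_from(data, pos)
        except struct.error as exc:
            raise SffFormatError(f"{path}: truncated header of read {i}") from exc
        name = data[pos + _READ_HEADER.size: pos + _READ_HEADER.size + name_len].decode("ascii")
        pos += rh_len
        data_len = 2 * n_flows + 3 * n_bases
        end = pos + data_len
        if end > len(data):
            raise SffFormatError(f"{path}: truncated data section of read {i} ({name!r})")
        flow_values = np.frombuffer(data[pos:pos + 2 * n_flows], dtype=">u2").astype(np.int64)
        pos += 2 * n_flows
        deltas = np.frombuffer(data[pos:pos + n_bases], dtype=np.uint8).astype(np.int64)
        pos += n_bases
        bases = data[pos:pos + n_bases].decode("ascii")
        pos += n_bases
        quality = np.frombuffer(data[pos:pos + n_bases], dtype=np.uint8).astype(np.int64)
        pos += n_bases
        pos += _pad8(data_len)
        reads.append(FlowRead(
            name=name,
            flow_values=flow_values,
            flow_index_per_base=np.cumsum(deltas),
            bases=bases,
            quality=quality,
            clip_qual_left=cql, clip_qual_right=cqr,
            clip_adapter_left=cal, clip_adapter_right=car,
        ))
    return header, reads


# ---------------------------------------------------------------------------
# flow-space enumeration of a template (shared by simulator and oracles)

def template_flow_runs(template: str, flow_order: str) -> list[tuple[int, str, int]]:
    """Enumerate the flows that carry each homopolymer run of ``template``.

    Walks the flow order from flow 1, consuming the template run by run:
    every flow whose nucleotide differs from the current run base yields a
    zero-signal flow; the matching flow carries the whole run.  Returns
    ``(flow_number_1based, run_base, run_length)`` per run.

    Raises ValueError if the flow order is exhausted before the template —
    the caller must size the header (number of cycles) to the template.
    """
    runs: list[tuple[str, int]] = []
    for base in template:
        if runs and runs[-1][0] == base:
            runs[-1] = (base, runs[-1][1] + 1)
        else:
            runs.append((base, 1))
    out: list[tuple[int, str, int]] = []
    flow = 0  # 0-based scan position
    for base, length in runs:
        while flow < len(flow_order) and flow_order[flow] != base:
            flow += 1
        if flow >= len(flow_order):
            raise ValueError(
                f"flow order of {len(flow_order)} flows exhausted before template end")
        out.append((flow + 1, base, length))
        flow += 1
    return out
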