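"""MID demultiplexing and semi-global alignment of reads to amplicons.

Alignment is base-space, semi-global (free end gaps) with affine gap
penalties; each read is tried against every amplicon in both orientations
and kept for the best-scoring combination, provided it reaches a minimum
identity over its aligned columns.  Reads are amplicon-length, so a single
best hit is the expected regime; chimeras and partial hits fall below the
identity floor and land in the unaligned bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .amplicons import AmpliconDef, revcomp
from .sff import FlowRead

# Scoring defaults for amplicon-length pyrosequencing reads; gap cost of a
# length-L gap is open + (L-1)*extend.
MATCH_SCORE = 2.0
MISMATCH_SCORE = -3.0
GAP_OPEN = -5.0
GAP_EXTEND = -2.0
MIN_IDENTITY = 0.80


class DemultiplexConfigError(ValueError):
    """MID set admits ambiguous assignment (two MIDs too close)."""


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_prefix(read: FlowRead, k: int) -> FlowRead:
    """Drop the first ``k`` called bases (e.g. a matched MID), keeping the
    flowgram and absolute flow indices intact."""
    from dataclasses import replace
    return replace(read,
                   flow_index_per_base=read.flow_index_per_base[k:],
                   bases=read.bases[k:],
                   quality=read.quality[k:])


def demultiplex(reads: list[FlowRead], mids: dict[str, str],
                *, max_mismatch: int = 1,
                ) -> tuple[dict[str, list[FlowRead]], list[FlowRead]]:
    """Assign reads to samples by their 5' MID barcode.

    A read is assigned to the unique MID matching its 5' end within
    ``max_mismatch`` mismatches; the MID bases are trimmed from assigned
    reads.  Returns (sample -> reads, unassigned).  MIDs pairwise within
    Hamming distance 2 make single-mismatch assignment ambiguous and are
    rejected up front.
    """
    items = list(mids.items())
    for i, (sa, ma) in enumerate(items):
        for sb, mb in items[i + 1:]:
            if len(ma) == len(mb) and _hamming(ma, mb) <= 2 * max_mismatch:
                raise DemultiplexConfigError(
                    f"MIDs for {sa!r} and {sb!r} are within Hamming distance "
                    f"{2 * max_mismatch}; assignment would be ambiguous")
    assigned: dict[str, list[FlowRead]] = {sample: [] for sample in mids}
    unassigned: list[FlowRead] = []
    for read in reads:
        hits = [(sample, len(mid)) for sample, mid in mids.items()
                if len(read.bases) >= len(mid)
                and _hamming(read.bases[:len(mid)], mid) <= max_mismatch]
        if len(hits) == 1:
            sample, k = hits[0]
            assigned[sample].append(trim_prefix(read, k))
        else:
            unassigned.append(read)
    return assigned, unassigned


@dataclass
class AlignedRead:
    """A read placed on an amplicon reference.

    ``pairs`` lists (reference_position, oriented_read_position) columns in
    reference order; ``None`` on one side marks a gap (deletion in the read
    / insertion relative to the reference).  End overhangs (free end gaps)
    are not included.  ``oriented_bases`` is the read in reference
    orientation; for reverse-strand reads, oriented position ``i`` maps back
    to instrument base ``len(read) - 1 - i`` in the read's own flow space.
    """

    read: FlowRead
    amplicon: str
    strand: str                     # '+' or '-'
    oriented_bases: str
    pairs: list[tuple[int | None, int | None]]
    score: float
    identity: float

    def to_instrument_index(self, oriented_index: int) -> int:
        if self.strand == "+":
            return oriented_index
        return len(self.oriented_bases) - 1 - oriented_index

    def reference_range(self) -> tuple[int, int]:
        refs = [r for r, _ in self.pairs if r is not None]
        return refs[0], refs[-1] + 1


def make_aligner(match: float = MATCH_SCORE, mismatch: float = MISMATCH_SCORE,
                 gap_open: float = GAP_OPEN, gap_extend: float = GAP_EXTEND,
                 ) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # free end gaps on both sequences (overlap / semi-global alignment)
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Bio.Align naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def _pairs_from_alignment(alignment) -> list[tuple[int | None, int | None]]:
    blocks_t, blocks_q = alignment.aligned
    pairs: list[tuple[int | None, int | None]] = []
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
        if prev_t is not None:
            # interior gaps only; leading overhang is a free end gap
            for t in range(prev_t, ts):
                pairs.append((t, None))
            for q in range(prev_q, qs):
                pairs.append((None, q))
        pairs.extend(zip(range(ts, te), range(qs, qe)))
        prev_t, prev_q = te, qe
    return pairs


def assign_and_align(read: FlowRead, amplicons: list[AmpliconDef],
                     *, aligner: Align.PairwiseAligner | None = None,
                     min_identity: float = MIN_IDENTITY,
                     ) -> AlignedRead | None:
    """Align ``read`` to the best amplicon in the better orientation.

    Returns ``None`` (unaligned bin) when the best alignment's identity over
    aligned columns falls below ``min_identity`` or the read is empty.
    """
    if not amplicons:
        raise ValueError("no amplicons defined")
    if not read.bases:
        return None
    if aligner is None:
        aligner = make_aligner()
    rc = revcomp(read.bases)
    best = None
    for amp in amplicons:
        for strand, seq in (("+", read.bases), ("-", rc)):
            score = aligner.score(amp.reference_sequence, seq)
            if best is None or score > best[0]:
                best = (score, amp, strand, seq)
    score, amp, strand, seq = best
    alignment = next(iter(aligner.align(amp.reference_sequence, seq)))
    pairs = _pairs_from_alignment(alignment)
    matched = sum(1 for r, q in pairs
                  if r is not None and q is not None
                  and amp.reference_sequence[r] == seq[q])
    # identity over the read, not just the aligned columns: a short perfect
    # overlap of a foreign read must not pass the floor
    identity = matched / len(seq)
    if identity < min_identity:
        return None
    return AlignedRead(read=read, amplicon=amp.name, strand=strand,
                       oriented_bases=seq, pairs=pairs,
                       score=float(score), identity=identity)
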