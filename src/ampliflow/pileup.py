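"""Per-column pileups over aligned reads and candidate-variant extraction.

Counting conventions: depth at a column is the number of reads whose aligned
span covers it (deleted bases included); insertions are anchored to the
reference column *after which* they occur and counted against that column's
depth; deletions are anchored at their first deleted column.  Every
non-reference event seen in at least one read becomes a RawVariant — the
downstream filter, not the caller, decides what survives.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum

from .align import AlignedRead
from .amplicons import AmpliconDef


class VariantKind(str, Enum):
    SUBSTITUTION = "substitution"
    INSERTION = "insertion"
    DELETION = "deletion"
    DELINS = "delins"


@dataclass
class PileupColumn:
    """Counts at one reference position of one amplicon.

    ``observations`` maps an event key to per-strand counts {'+': n, '-': n}.
    Event keys: ("match",), ("sub", base), ("ins", seq) for an insertion
    occurring after this column, ("del", length) for a deletion starting
    here.
    """

    reference_position: int
    ref_base: str
    depth_forward: int = 0
    depth_reverse: int = 0
    observations: dict[tuple, Counter] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return self.depth_forward + self.depth_reverse

    def add(self, event: tuple, strand: str) -> None:
        self.observations.setdefault(event, Counter())[strand] += 1


@dataclass
class RawVariant:
    """A candidate sequence change with its per-strand support.

    ``reference_position`` is 0-based on the amplicon; for insertions it is
    the position *before which* the sequence is inserted (i.e. one past the
    anchor column).  ``fraction`` is support / depth at the anchor column.
    """

    amplicon: str
    reference_position: int
    kind: VariantKind
    ref_allele: str
    alt_allele: str
    reads_forward: int
    reads_reverse: int
    depth: int
    depth_forward: int
    depth_reverse: int

    @property
    def support(self) -> int:
        return self.reads_forward + self.reads_reverse

    @property
    def fraction(self) -> float:
        return self.support / self.depth if self.depth else 0.0

    def key(self) -> tuple:
        return (self.amplicon, self.reference_position, self.kind.value,
                self.ref_allele, self.alt_allele)


def pileup_and_call(alignments: list[AlignedRead], amplicon: AmpliconDef,
                    ) -> tuple[list[PileupColumn], list[RawVariant]]:
    """Build per-column counts for ``amplicon`` and emit every observed
    non-reference event as a RawVariant."""
    ref = amplicon.reference_sequence
    columns = [PileupColumn(reference_position=i, ref_base=ref[i])
               for i in range(len(ref))]
    for aln in alignments:
        if aln.amplicon != amplicon.name:
            raise ValueError(
                f"alignment of read {aln.read.name!r} belongs to {aln.amplicon!r}, "
                f"not {amplicon.name!r}")
        strand = aln.strand
        lo, hi = aln.reference_range()
        for c in range(lo, hi):
            if strand == "+":
                columns[c].depth_forward += 1
            else:
                columns[c].depth_reverse += 1
        # walk columns, merging gap runs into single events
        i = 0
        pairs = aln.pairs
        n = len(pairs)
        while i < n:
            r, q = pairs[i]
            if r is not None and q is not None:
                base = aln.oriented_bases[q]
                columns[r].add(("match",) if base == ref[r] else ("sub", base), strand)
                i += 1
            elif q is None:  # deletion run anchored at first deleted column
                j = i
                while j < n and pairs[j][1] is None and pairs[j][0] is not None:
                    j += 1
                length = j - i
                columns[r].add(("del", length), strand)
                i = j
            else:  # insertion run anchored after preceding reference column
                j = i
                seq = []
                while j < n and pairs[j][0] is None:
                    seq.append(aln.oriented_bases[pairs[j][1]])
                    j += 1
                anchor = None
                for k in range(i - 1, -1, -1):
                    if pairs[k][0] is not None:
                        anchor = pairs[k][0]
                        break
                if anchor is not None:  # insertion before the first column: end gap artefact
                    columns[anchor].add(("ins", "".join(seq)), strand)
                i = j
    variants: list[RawVariant] = []
    for col in columns:
        for event, by_strand in sorted(col.observations.items(), key=repr):
            if event == ("match",):
                continue
            fwd, rev = by_strand.get("+", 0), by_strand.get("-", 0)
            tag = event[0]
            if tag == "sub":
                kind, refa, alta, pos = (VariantKind.SUBSTITUTION, col.ref_base,
                                         event[1], col.reference_position)
            elif tag == "del":
                length = event[1]
                pos = col.reference_position
                kind, refa, alta = VariantKind.DELETION, ref[pos:pos + length], ""
            else:
                kind, refa, alta = VariantKind.INSERTION, "", event[1]
                pos = col.reference_position + 1
            variants.append(RawVariant(
                amplicon=amplicon.name, reference_position=pos, kind=kind,
                ref_allele=refa, alt_allele=alta,
                reads_forward=fwd, reads_reverse=rev,
                depth=col.depth, depth_forward=col.depth_forward,
                depth_reverse=col.depth_reverse))
    return columns, variants
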