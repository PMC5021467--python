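"""Coding-DNA (HGVS "c.") nomenclature for variants on a gene model.

Normalization follows the conventions that make variant strings comparable
across tools: shared flanking bases between the replaced and replacement
sequences are trimmed (prefix first, then suffix — so a delins never ends
with a base it also deletes), pure insertions and deletions are shifted to
their 3'-most position on the coding strand, and an insertion that repeats
the immediately preceding sequence is written as a duplication.  Protein
(p.) nomenclature is out of scope; reports carry c. strings only.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genemodel import CodingPosition, GeneModel


class VariantConsistencyError(ValueError):
    """Reference allele disagrees with the gene-model sequence."""


@dataclass(frozen=True)
class HgvsVariant:
    """A normalized coding-notation variant.

    ``genomic_start`` is the 0-based position of the first affected base
    (for insertions, of the base *before which* the sequence is inserted)
    after normalization; ``ref``/``alt`` are in coding-strand orientation.
    """

    c_string: str
    kind: str                    # substitution | deletion | insertion | dup | delins
    genomic_start: int
    ref: str
    alt: str
    c_start: CodingPosition
    c_end: CodingPosition | None = None

    def __str__(self) -> str:
        return self.c_string


def _trim(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    while ref and alt and ref[0] == alt[0]:
        pos += 1
        ref, alt = ref[1:], alt[1:]
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    return pos, ref, alt


def _shift3(seq: str, pos: int, allele: str, is_deletion: bool) -> tuple[int, str]:
    """Shift a pure indel to its 3'-most equivalent placement.

    For a deletion of ``allele`` at ``pos``: moving right one base is
    possible whenever the base after the deleted span equals the first
    deleted base.  For an insertion of ``allele`` before ``pos``: possible
    whenever the base at ``pos`` equals the first inserted base.  The allele
    rotates as the window slides.
    """
    allele = allele
    if is_deletion:
        while pos + len(allele) < len(seq) and seq[pos + len(allele)] == allele[0]:
            allele = allele[1:] + seq[pos + len(allele)]
            pos += 1
    else:
        while pos < len(seq) and seq[pos] == allele[0]:
            allele = allele[1:] + allele[0]
            pos += 1
    return pos, allele


def normalize_variant(model: GeneModel, genomic_pos: int, ref: str, alt: str) -> HgvsVariant:
    """Normalize a genomic-coordinate variant and emit its c. string.

    ``genomic_pos`` is 0-based on the model's (coding-orientation) genomic
    sequence; ``ref`` is the replaced reference sequence (may be empty for a
    pure insertion *before* ``genomic_pos``), ``alt`` the replacement.
    """
    seq = model.genomic_sequence
    if seq[genomic_pos:genomic_pos + len(ref)] != ref:
        raise VariantConsistencyError(
            f"reference allele {ref!r} does not match the model sequence "
            f"{seq[genomic_pos:genomic_pos + len(ref)]!r} at {genomic_pos}")
    pos, ref, alt = _trim(genomic_pos, ref, alt)
    if not ref and not alt:
        raise ValueError("variant is a no-op after trimming")
    c = model.genomic_to_coding

    if ref and alt:
        if len(ref) == 1 and len(alt) == 1:
            return HgvsVariant(
                c_string=f"c.{c(pos)}{ref}>{alt}", kind="substitution",
                genomic_start=pos, ref=ref, alt=alt, c_start=c(pos))
        start, end = c(pos), c(pos + len(ref) - 1)
        span = str(start) if len(ref) == 1 else f"{start}_{end}"
        return HgvsVariant(
            c_string=f"c.{span}delins{alt}", kind="delins",
            genomic_start=pos, ref=ref, alt=alt, c_start=start,
            c_end=end if len(ref) > 1 else None)

    if ref:  # pure deletion, 3'-shifted
        pos, ref = _shift3(seq, pos, ref, is_deletion=True)
        start, end = c(pos), c(pos + len(ref) - 1)
        span = str(start) if len(ref) == 1 else f"{start}_{end}"
        return HgvsVariant(
            c_string=f"c.{span}del{ref}", kind="deletion",
            genomic_start=pos, ref=ref, alt="", c_start=start,
            c_end=end if len(ref) > 1 else None)

    # pure insertion before ``pos``, 3'-shifted; duplications spelled as dup
    pos, alt = _shift3(seq, pos, alt, is_deletion=False)
    k = len(alt)
    if pos - k >= 0 and seq[pos - k:pos] == alt:
        start, end = c(pos - k), c(pos - 1)
        span = str(start) if k == 1 else f"{start}_{end}"
        return HgvsVariant(
            c_string=f"c.{span}dup{alt}", kind="dup",
            genomic_start=pos - k, ref="", alt=alt, c_start=start,
            c_end=end if k > 1 else None)
    left, right = c(pos - 1), c(pos)
    return HgvsVariant(
        c_string=f"c.{left}_{right}ins{alt}", kind="insertion",
        genomic_start=pos, ref="", alt=alt, c_start=left, c_end=right)
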