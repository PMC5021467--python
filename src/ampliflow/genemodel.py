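"""Gene models from GenBank records and genomic <-> coding coordinates.

A GeneModel holds the genomic sequence in *coding-strand orientation*
(minus-strand genes are reverse-complemented on parse), the ordered exons
and the CDS bounds.  Coordinate conversion follows coding-DNA ("c.")
conventions: exonic positions are 1-based CDS indices, 5' UTR positions are
negative, 3' UTR positions carry a ``*`` prefix, and intronic positions are
expressed as the nearest exon boundary plus a signed offset (``212+1`` is
the first base of the intron after coding position 212; ``81-12`` is 12
bases before the exon starting at coding position 81).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .amplicons import revcomp


class GeneModelError(ValueError):
    """Raised on GenBank records this module cannot represent."""


@dataclass(frozen=True)
class CodingPosition:
    """A c.-coordinate: anchor plus intronic offset.

    ``anchor`` is the c. string of the nearest exonic base ("212", "-12",
    "*45"); ``offset`` is 0 for exonic positions, positive after an exon
    end, negative before an exon start.
    """

    anchor: str
    offset: int = 0

    def __str__(self) -> str:
        if self.offset > 0:
            return f"{self.anchor}+{self.offset}"
        if self.offset < 0:
            return f"{self.anchor}{self.offset}"
        return self.anchor

    @property
    def sort_key(self) -> tuple:
        a = self.anchor
        if a.startswith("*"):
            region, val = 2, int(a[1:])
        else:
            val = int(a)
            region = 0 if val < 0 else 1
        return (region, val, self.offset)


@dataclass(frozen=True)
class GeneModel:
    """Transcript structure on a genomic segment, coding orientation.

    ``exons`` are 0-based half-open genomic intervals ordered 5'->3';
    ``cds_start``/``cds_end`` bound the CDS (half-open) inside the exon
    union.  ``strand`` records the orientation of the original record.
    """

    gene: str
    genomic_sequence: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    strand: int = 1
    transcript_id: str = ""

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.exons:
            if not 0 <= start < end <= len(self.genomic_sequence):
                raise GeneModelError(f"exon [{start},{end}) outside the genomic sequence")
            if start <= prev_end:
                raise GeneModelError("exons overlap or are unordered")
            prev_end = end
        in_exon = lambda p: any(s <= p < e for s, e in self.exons)
        if not (in_exon(self.cds_start) and in_exon(self.cds_end - 1)):
            raise GeneModelError("CDS bounds fall outside the exon union")

    # -- transcript arithmetic ------------------------------------------------

    def _tx(self, pos: int) -> int:
        """0-based transcript coordinate of an exonic genomic position."""
        acc = 0
        for start, end in self.exons:
            if start <= pos < end:
                return acc + (pos - start)
            acc += end - start
        raise ValueError(f"position {pos} is intronic")

    @property
    def _cds_tx(self) -> tuple[int, int]:
        return self._tx(self.cds_start), self._tx(self.cds_end - 1)

    def _c_of_exonic(self, pos: int) -> str:
        t = self._tx(pos)
        t0, t1 = self._cds_tx
        if t < t0:
            return str(t - t0)          # negative: 5' UTR
        if t <= t1:
            return str(t - t0 + 1)
        return f"*{t - t1}"             # 3' UTR

    def genomic_to_coding(self, pos: int) -> CodingPosition:
        """c.-coordinate of a genomic position within the transcript span."""
        if not self.exons[0][0] <= pos < self.exons[-1][1]:
            raise ValueError(f"position {pos} beyond the transcript span "
                             f"[{self.exons[0][0]}, {self.exons[-1][1]})")
        for start, end in self.exons:
            if start <= pos < end:
                return CodingPosition(self._c_of_exonic(pos))
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if e0 <= pos < s1:
                d_prev = pos - (e0 - 1)
                d_next = s1 - pos
                if d_prev <= d_next:
                    return CodingPosition(self._c_of_exonic(e0 - 1), d_prev)
                return CodingPosition(self._c_of_exonic(s1), -d_next)
        raise AssertionError("unreachable")

    def coding_to_genomic(self, c: CodingPosition) -> int:
        """Inverse of :meth:`genomic_to_coding`."""
        anchor = c.anchor
        t0, t1 = self._cds_tx
        if anchor.startswith("*"):
            t = t1 + int(anchor[1:])
        else:
            val = int(anchor)
            t = t0 + val - 1 if val > 0 else t0 + val
        acc = 0
        genomic = None
        for start, end in self.exons:
            if acc <= t < acc + (end - start):
                genomic = start + (t - acc)
                break
            acc += end - start
        if genomic is None:
            raise ValueError(f"coding position {c} beyond the transcript")
        return genomic + c.offset

    def exon_intervals(self) -> list[tuple[int, int]]:
        return list(self.exons)


# ---------------------------------------------------------------------------
# GenBank I/O

def parse_genbank(path: str | Path) -> GeneModel:
    """Build a GeneModel from a single-gene GenBank flat file.

    Requires one CDS feature; exon features are used when present, else the
    CDS parts stand in for exons.  Minus-strand genes are flipped into
    coding orientation (sequence reverse-complemented, coordinates
    mirrored).  Compound locations crossing the origin are rejected.
    """
    record = SeqIO.read(str(path), "genbank")
    seq = str(record.seq).upper()
    cds = [f for f in record.features if f.type == "CDS"]
    if not cds:
        raise GeneModelError(f"{path}: no CDS feature")
    cds_feature = cds[0]
    strand = cds_feature.location.strand or 1
    exon_feats = [f for f in record.features if f.type == "exon"]
    locs = exon_feats if exon_feats else [cds_feature]
    exons: list[tuple[int, int]] = []
    for f in locs:
        for part in f.location.parts:
            exons.append((int(part.start), int(part.end)))
    exons.sort()
    for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
        if s1 < e0:
            raise GeneModelError(f"{path}: overlapping exon parts (possible "
                                 "origin-crossing join, unsupported)")
    cds_start = int(cds_feature.location.start)
    cds_end = int(cds_feature.location.end)
    gene = ""
    for f in record.features:
        if f.type == "gene" and "gene" in f.qualifiers:
            gene = f.qualifiers["gene"][0]
            break
    if not gene:
        gene = cds_feature.qualifiers.get("gene", [record.name])[0]
    transcript = cds_feature.qualifiers.get("transcript_id", [""])[0]
    if strand == -1:
        L = len(seq)
        seq = revcomp(seq)
        exons = sorted((L - e, L - s) for s, e in exons)
        cds_start, cds_end = L - cds_end, L - cds_start
    return GeneModel(gene=gene, genomic_sequence=seq, exons=tuple(exons),
                     cds_start=cds_start, cds_end=cds_end, strand=strand,
                     transcript_id=transcript)


def write_genbank(model: GeneModel, path: str | Path, *, strand: int = 1) -> None:
    """Serialize a GeneModel back to a GenBank flat file (round-trip helper).

    With ``strand=-1`` the record is written in the opposite orientation;
    parsing it back yields the identical model.
    """
    seq = model.genomic_sequence
    exons = list(model.exons)
    cds_start, cds_end = model.cds_start, model.cds_end
    if strand == -1:
        L = len(seq)
        seq = revcomp(seq)
        exons = sorted((L - e, L - s) for s, e in exons)
        cds_start, cds_end = L - cds_end, L - cds_start
    record = SeqRecord(Seq(seq), id=model.transcript_id or model.gene,
                       name=(model.gene or "GENE")[:16],
                       description=f"synthetic gene model for {model.gene}",
                       annotations={"molecule_type": "DNA"})
    record.features.append(SeqFeature(
        FeatureLocation(0, len(seq), strand=strand), type="gene",
        qualifiers={"gene": [model.gene]}))
    for s, e in exons:
        record.features.append(SeqFeature(
            FeatureLocation(s, e, strand=strand), type="exon",
            qualifiers={"gene": [model.gene]}))
    qualifiers = {"gene": [model.gene]}
    if model.transcript_id:
        qualifiers["transcript_id"] = [model.transcript_id]
    record.features.append(SeqFeature(
        FeatureLocation(cds_start, cds_end, strand=strand), type="CDS",
        qualifiers=qualifiers))
    SeqIO.write(record, str(path), "genbank")
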