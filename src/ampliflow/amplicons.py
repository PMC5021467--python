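"""Amplicon definitions and their tab-separated interchange format."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AmpliconDef:
    """One PCR amplicon: the unit of alignment, validation and reporting.

    ``reference_sequence`` is primer-inclusive; ``genomic_offset`` is the
    0-based position of reference base 0 on the gene's genomic sequence
    (coding-strand orientation).  ``roi`` optionally restricts validation to
    a set of amplicon-local positions.
    """

    name: str
    reference_sequence: str
    genomic_offset: int = 0
    forward_primer: str = ""
    reverse_primer: str = ""
    mid: str = ""
    roi: frozenset[int] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        seq = self.reference_sequence
        if not seq:
            raise ValueError(f"amplicon {self.name!r}: empty reference sequence")
        if set(seq) - set("ACGTN"):
            raise ValueError(f"amplicon {self.name!r}: reference must be upper-case ACGTN")
        if self.forward_primer and not seq.startswith(self.forward_primer):
            raise ValueError(f"amplicon {self.name!r}: forward primer is not a prefix")
        if self.reverse_primer and not seq.endswith(revcomp(self.reverse_primer)):
            raise ValueError(
                f"amplicon {self.name!r}: reverse-complemented reverse primer is not a suffix")

    def __len__(self) -> int:
        return len(self.reference_sequence)

    @property
    def genomic_span(self) -> tuple[int, int]:
        """0-based half-open genomic interval covered by this amplicon."""
        return self.genomic_offset, self.genomic_offset + len(self.reference_sequence)


_COLUMNS = ["name", "reference_sequence", "genomic_offset",
            "forward_primer", "reverse_primer", "mid"]


def read_amplicon_table(path: str | Path) -> list[AmpliconDef]:
    """Load amplicon definitions from a TSV with columns
    name / reference_sequence / genomic_offset / forward_primer /
    reverse_primer / mid (primers and mid may be empty)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(AmpliconDef(
            name=row.name,
            reference_sequence=row.reference_sequence,
            genomic_offset=int(row.genomic_offset),
            forward_primer=getattr(row, "forward_primer", ""),
            reverse_primer=getattr(row, "reverse_primer", ""),
            mid=getattr(row, "mid", ""),
        ))
    return out


def write_amplicon_table(amplicons: list[AmpliconDef], path: str | Path) -> None:
    pd.DataFrame(
        [{c: getattr(a, c) for c in _COLUMNS} for a in amplicons]
    ).to_csv(path, sep="\t", index=False)
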