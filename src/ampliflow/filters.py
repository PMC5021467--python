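"""Amplicon validation and variant filtering rules.

The screening logic is deliberately simple and total: an amplicon is
*validated* when every region-of-interest base reaches the minimum depth
(only the minimum matters); a candidate variant is kept when it has enough
supporting reads, appears on both strands (unless only one strand covers
the site at all), and exceeds the minimum allele fraction.  Variant
detection is independent of amplicon validation, so real mutations in
under-covered amplicons are still reported — the amplicon is merely flagged
for resequencing.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .pileup import PileupColumn, RawVariant


@dataclass(frozen=True)
class FilterConfig:
    """Screening thresholds.

    min_depth: reads required at every ROI base to validate an amplicon (default 40).
    min_variant_fraction: minimum allele fraction to keep a variant (default 0.20, inclusive).
    min_variant_reads: minimum supporting reads (default 4, inclusive).
    roi_upstream / roi_downstream: bases added before/after each exon to form
        the region of interest (defaults 20 and 6, covering splice sites).
    require_both_strands: demand support on both strands when both are covered.
    """

    min_depth: int = 40
    min_variant_fraction: float = 0.20
    min_variant_reads: int = 4
    roi_upstream: int = 20
    roi_downstream: int = 6
    require_both_strands: bool = True

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0 < self.min_variant_fraction <= 1:
            raise ValueError("min_variant_fraction must be in (0, 1]")
        if self.min_variant_reads < 1:
            raise ValueError("min_variant_reads must be >= 1")
        if self.roi_upstream < 0 or self.roi_downstream < 0:
            raise ValueError("ROI margins must be non-negative")


class VariantStatus(str, Enum):
    VALIDATED = "validated"
    REJECTED_SUPPORT = "rejected_support"
    REJECTED_STRAND = "rejected_strand"
    REJECTED_FREQUENCY = "rejected_frequency"


@dataclass
class ValidatedVariant:
    """A RawVariant with its filter decision.

    ``amplicon_validated`` records the coverage status of the whole amplicon
    independently of the variant's own status: a variant can be validated in
    a non-validated amplicon (it is then flagged for review in the report).
    """

    variant: RawVariant
    status: VariantStatus
    amplicon_validated: bool = True
    in_roi: bool = True

    @property
    def is_validated(self) -> bool:
        return self.status is VariantStatus.VALIDATED


def decide_variant(support_forward: int, support_reverse: int,
                   coverage_forward: int, coverage_reverse: int,
                   fraction: float, config: FilterConfig) -> VariantStatus:
    """Total, deterministic filter decision.

    Precedence: support count, then strand representation, then fraction.
    The strand rule rejects only when the unsupporting strand actually has
    coverage — a site covered by one strand only is exempt.
    """
    support = support_forward + support_reverse
    if support < config.min_variant_reads:
        return VariantStatus.REJECTED_SUPPORT
    if config.require_both_strands:
        if (support_forward == 0 and coverage_forward >= 1) or \
           (support_reverse == 0 and coverage_reverse >= 1):
            return VariantStatus.REJECTED_STRAND
    if fraction < config.min_variant_fraction:
        return VariantStatus.REJECTED_FREQUENCY
    return VariantStatus.VALIDATED


def filter_variants(raw: list[RawVariant], config: FilterConfig,
                    amplicon_validated: bool,
                    roi: set[int] | None = None) -> list[ValidatedVariant]:
    """Apply the filter rules to every candidate from one amplicon pileup."""
    out = []
    for v in raw:
        status = decide_variant(v.reads_forward, v.reads_reverse,
                                v.depth_forward, v.depth_reverse,
                                v.fraction, config)
        out.append(ValidatedVariant(
            variant=v, status=status,
            amplicon_validated=amplicon_validated,
            in_roi=(roi is None or v.reference_position in roi)))
    return out


def validate_amplicon(columns: list[PileupColumn], roi: set[int],
                      config: FilterConfig) -> tuple[bool, list[int]]:
    """Amplicon coverage validation over its region of interest.

    Validated iff the minimum total depth over ``roi`` (amplicon-local
    positions) reaches ``config.min_depth``.  Returns the failing positions
    for the resequencing worklist.
    """
    if not roi:
        raise ValueError("empty region of interest")
    depth_at = {c.reference_position: c.depth for c in columns}
    failing = sorted(p for p in roi if depth_at.get(p, 0) < config.min_depth)
    return not failing, failing


def roi_positions(exons: list[tuple[int, int]], amplicons,
                  config: FilterConfig) -> dict[str, set[int]]:
    """Per-amplicon region-of-interest positions (amplicon-local).

    Each exon ``[start, end)`` (genomic, coding-strand) is widened to
    ``[start - roi_upstream, end + roi_downstream)``; the union of widened
    exons is intersected with each amplicon's genomic span and translated to
    amplicon-local coordinates.  Exons covered by no amplicon are reported
    via the returned ``"__uncovered__"`` pseudo-entry being non-empty.
    """
    widened: set[int] = set()
    for start, end in exons:
        widened.update(range(start - config.roi_upstream, end + config.roi_downstream))
    out: dict[str, set[int]] = {}
    covered: set[int] = set()
    for amp in amplicons:
        lo, hi = amp.genomic_span
        local = {g - lo for g in widened if lo <= g < hi}
        out[amp.name] = local
        covered.update(g for g in widened if lo <= g < hi)
    exon_positions = {g for start, end in exons for g in range(start, end)}
    out["__uncovered__"] = exon_positions - covered
    return out
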