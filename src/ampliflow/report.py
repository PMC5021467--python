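"""Result reporting: variant tables, coverage matrices, worklists, VCF.

The canonical machine-readable outputs are TSV; a colour-coded spreadsheet
is written alongside for bench review (green validated, orange needing
review, grey rejected).  A variant can be validated inside a non-validated
amplicon — such rows, and rows whose homopolymer histogram was ambiguous,
are marked ``needs_review``.

The module also ships a packaged fixture: the published three-way
comparison of a composite control sample (28 Sanger-confirmed variants)
called by this kind of flowgram pipeline versus an alternative commercial
analysis, with per-call allele fractions and low-depth flags.  The tally
functions recompute the summary counts (confirmed variants, false
positives, depth-explained false positives, false negatives) from the raw
rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .filters import ValidatedVariant, VariantStatus
from .homopolymer import HpLabel

COMPARISON_FIXTURE = "composite_sample_comparison.tsv"


@dataclass
class ReportRow:
    """One variant observation in one sample, ready for the final report."""

    sample: str
    amplicon: str
    amplicon_validated: bool
    c_string: str
    kind: str
    genomic_position: int
    fraction: float
    depth: int
    reads_forward: int
    reads_reverse: int
    status: str
    homopolymer_label: str = ""
    known_neutral: bool = False
    needs_review: bool = False
    annotation: str = ""   # reserved for downstream impact predictors

    @classmethod
    def from_variant(cls, sample: str, vv: ValidatedVariant, c_string: str,
                     kind: str, genomic_position: int,
                     hp_label: str = "") -> "ReportRow":
        needs_review = (not vv.amplicon_validated) or hp_label in (
            HpLabel.AMBIGUOUS.value, "manual_review")
        return cls(
            sample=sample, amplicon=vv.variant.amplicon,
            amplicon_validated=vv.amplicon_validated,
            c_string=c_string, kind=kind, genomic_position=genomic_position,
            fraction=vv.variant.fraction, depth=vv.variant.depth,
            reads_forward=vv.variant.reads_forward,
            reads_reverse=vv.variant.reads_reverse,
            status=vv.status.value, homopolymer_label=hp_label,
            needs_review=needs_review)


def rows_to_frame(rows: list[ReportRow]) -> pd.DataFrame:
    cols = ["sample", "amplicon", "amplicon_validated", "c_string", "kind",
            "genomic_position", "fraction", "depth", "reads_forward",
            "reads_reverse", "status", "homopolymer_label", "known_neutral",
            "needs_review", "annotation"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in rows],
                        columns=cols)


# ---------------------------------------------------------------------------
# neutral-variant list

def load_neutral_list(path: str | Path) -> set[str]:
    """One normalized c. string per line; '#' starts a comment.  Malformed
    lines are skipped with a warning naming the line number."""
    out: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        entry = line.split("#", 1)[0].strip()
        if not entry:
            continue
        if " " in entry or not entry.startswith("c."):
            warnings.warn(f"{path}:{lineno}: malformed neutral-list entry "
                          f"{entry!r} skipped")
            continue
        out.add(entry)
    return out


def annotate_known(rows: list[ReportRow], neutral: set[str]) -> list[ReportRow]:
    """Flag rows whose normalized c. string matches the neutral list exactly.

    Everything unmatched stays unflagged for manual interpretation; matching
    is by exact normalized string, so unnormalized aliases (e.g. the ins
    spelling of a dup) never match.
    """
    for row in rows:
        row.known_neutral = row.c_string in neutral
    return rows


def flag_duplicate_amplicons(rows: list[ReportRow],
                             fraction_margin: float = 0.2) -> list[ReportRow]:
    """Mark calls seen in more than one amplicon at the same position.

    Poorly represented regions are sometimes amplified in duplicate;
    pileups stay per amplicon, so one variant can yield a row per
    amplicon.  Concordant duplicates are annotated; duplicates whose
    fractions differ by more than ``fraction_margin`` are additionally
    flagged for review.
    """
    groups: dict[tuple, list[ReportRow]] = {}
    for row in rows:
        groups.setdefault((row.sample, row.c_string), []).append(row)
    for group in groups.values():
        amplicons = {r.amplicon for r in group}
        if len(amplicons) < 2:
            continue
        fractions = [r.fraction for r in group]
        discordant = max(fractions) - min(fractions) > fraction_margin
        for r in group:
            r.annotation = ("duplicate_amplicon_discordant" if discordant
                            else "duplicate_amplicon")
            if discordant:
                r.needs_review = True
    return rows


# ---------------------------------------------------------------------------
# output files

_STATUS_FILL = {
    VariantStatus.VALIDATED.value: "C6EFCE",      # green
    VariantStatus.REJECTED_SUPPORT.value: "D9D9D9",
    VariantStatus.REJECTED_STRAND.value: "D9D9D9",
    VariantStatus.REJECTED_FREQUENCY.value: "D9D9D9",
}
_REVIEW_FILL = "FFE699"  # orange


def write_reports(rows: list[ReportRow], coverage: pd.DataFrame,
                  out_dir: str | Path, *,
                  failed_amplicons: pd.DataFrame | None = None,
                  gene: str = "gene", write_xlsx: bool = True,
                  genome_sequence: str | None = None,
                  write_vcf: bool = False) -> dict[str, Path]:
    """Write the report family into ``out_dir``; returns name -> path.

    Outputs: variant report (TSV + coloured XLSX), per-sample x per-amplicon
    coverage matrix (minimum ROI depth, failures visible as values below the
    threshold), no-variant amplicon list, resequencing worklist, and an
    optional VCF 4.2 of validated variants.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    frame = rows_to_frame(rows)
    paths["variants_tsv"] = out_dir / "variant_report.tsv"
    frame.to_csv(paths["variants_tsv"], sep="\t", index=False)
    if write_xlsx:
        paths["variants_xlsx"] = out_dir / "variant_report.xlsx"
        _write_colored_xlsx(frame, paths["variants_xlsx"])
    paths["coverage_tsv"] = out_dir / "coverage_matrix.tsv"
    coverage.to_csv(paths["coverage_tsv"], sep="\t", index=True)
    called = frame[frame["status"] == VariantStatus.VALIDATED.value]
    with_variants = set(zip(called["sample"], called["amplicon"]))
    no_variant = [dict(sample=s, amplicon=a)
                  for s in coverage.index for a in coverage.columns
                  if (s, a) not in with_variants]
    paths["no_variant_tsv"] = out_dir / "no_variant_amplicons.tsv"
    pd.DataFrame(no_variant, columns=["sample", "amplicon"]).to_csv(
        paths["no_variant_tsv"], sep="\t", index=False)
    paths["worklist_tsv"] = out_dir / "resequence_worklist.tsv"
    if failed_amplicons is None:
        failed_amplicons = pd.DataFrame(columns=["sample", "amplicon", "failing_positions"])
    failed_amplicons.to_csv(paths["worklist_tsv"], sep="\t", index=False)
    if write_vcf:
        if genome_sequence is None:
            raise ValueError("VCF export needs the genomic sequence for anchor bases")
        paths["vcf"] = out_dir / "validated_variants.vcf"
        _write_vcf(frame, genome_sequence, gene, paths["vcf"])
    return paths


def _write_colored_xlsx(frame: pd.DataFrame, path: Path) -> None:
    from openpyxl import Workbook
    from openpyxl.styles import PatternFill

    wb = Workbook()
    ws = wb.active
    ws.title = "variants"
    ws.append(list(frame.columns))
    for _, row in frame.iterrows():
        ws.append(list(row))
        fill_hex = _REVIEW_FILL if row["needs_review"] else \
            _STATUS_FILL.get(row["status"], "FFFFFF")
        fill = PatternFill("solid", fgColor=fill_hex)
        for cell in ws[ws.max_row]:
            cell.fill = fill
    wb.save(path)


def _write_vcf(frame: pd.DataFrame, genome: str, gene: str, path: Path) -> None:
    """Minimal VCF 4.2 of validated calls, left-anchored per VCF convention."""
    lines = ["##fileformat=VCFv4.2",
             f"##contig=<ID={gene},length={len(genome)}>",
             '##INFO=<ID=AF,Number=1,Type=Float,Description="Allele fraction">',
             '##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">',
             '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample">',
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
    validated = frame[frame["status"] == VariantStatus.VALIDATED.value]
    for _, row in validated.iterrows():
        g = int(row["genomic_position"])
        kind = row["kind"]
        if kind == "substitution":
            pos1, ref, alt = g + 1, genome[g], row["c_string"].split(">")[-1]
        elif kind in ("deletion", "delins"):
            ref_len = _ref_len_from_row(row)
            anchor = genome[g - 1]
            pos1 = g
            ref = anchor + genome[g:g + ref_len]
            ins = row["c_string"].split("ins")[-1] if "ins" in row["c_string"] else ""
            alt = anchor + ins
        else:  # insertion / dup
            ins = row["c_string"].split("ins")[-1] if "ins" in row["c_string"] \
                else row["c_string"].split("dup")[-1]
            if kind == "dup":
                g = g + len(ins)  # dup stores the start of the duplicated unit
            pos1 = g
            ref = genome[g - 1]
            alt = ref + ins
        info = f"AF={row['fraction']:.4f};DP={int(row['depth'])};SAMPLE={row['sample']}"
        lines.append(f"{gene}\t{pos1}\t.\t{ref}\t{alt}\t.\tPASS\t{info}")
    path.write_text("\n".join(lines) + "\n")


def _ref_len_from_row(row: pd.Series) -> int:
    c = row["c_string"]
    body = c[2:]
    if "delins" in body:
        span = body.split("delins")[0]
    elif "del" in body:
        span = body.split("del")[0]
    else:
        return 0
    if "_" in span:
        a, b = span.split("_")
        try:
            return int(b) - int(a) + 1
        except ValueError:
            return 1
    return max(1, len(body.split("del", 1)[1].split("ins")[0]) or 1)


# ---------------------------------------------------------------------------
# packaged composite-sample comparison fixture

def load_comparison_table(path: str | Path | None = None) -> pd.DataFrame:
    """The packaged three-way composite-sample comparison (or an external
    copy of the same schema)."""
    if path is None:
        source = resources.files("ampliflow").joinpath("data", COMPARISON_FIXTURE)
        with resources.as_file(source) as p:
            return pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False).fillna("")
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False).fillna("")


def tally_comparison(table: pd.DataFrame) -> dict[str, int]:
    """Summary counts of the three-way comparison, recomputed from the rows.

    sanger_validated: variants confirmed by the reference method.
    flow_false_positives: flow-pipeline calls absent from the reference;
    flow_fp_low_depth: the subset explained by <40-read coverage.
    alt_false_positives / alt_false_negatives: same for the alternative
    analysis; false negatives exclude calls the alternative itself flagged
    as under-covered (those go to the resequencing worklist, not the
    discordance count).
    """
    sanger = table["sanger"] != ""
    flow = table["flow_call"] != ""
    alt = table["alt_call"] != ""
    flow_low = table["flow_flag"] == "lowdepth"
    alt_low = table["alt_flag"] == "lowdepth"
    return {
        "sanger_validated": int(sanger.sum()),
        "flow_false_positives": int((flow & ~sanger).sum()),
        "flow_fp_low_depth": int((flow & ~sanger & flow_low).sum()),
        "flow_false_negatives": int((sanger & ~flow & ~flow_low).sum()),
        "alt_false_positives": int((alt & ~sanger).sum()),
        "alt_false_negatives": int((sanger & ~alt & ~alt_low).sum()),
    }
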