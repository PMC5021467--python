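"""End-to-end orchestration: SFF -> demultiplex -> align -> call -> filter ->
homopolymer analysis -> annotation -> reports.

Every stage logs its counts into a MANIFEST written next to the reports; a
failure preserves the outputs of the stages already completed and records
the completion point.  Reruns with identical inputs and configuration
produce byte-identical TSV reports: iteration follows the configured sample
order and variants are sorted by amplicon and position throughout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .align import assign_and_align, demultiplex, make_aligner, AlignedRead
from .amplicons import AmpliconDef, read_amplicon_table
from .config import PipelineConfig
from .filters import (FilterConfig, ValidatedVariant, VariantStatus,
                      filter_variants, roi_positions, validate_amplicon)
from .genemodel import GeneModel, parse_genbank
from .hgvs import normalize_variant
from .homopolymer import (HpLabel, build_histogram, detect_context,
                          extract_signals, render_histogram, sidecar_name,
                          write_sidecar)
from .pileup import RawVariant, VariantKind, pileup_and_call
from .report import (ReportRow, annotate_known, flag_duplicate_amplicons,
                     load_neutral_list, rows_to_frame, write_reports)
from .sff import read_sff

logger = logging.getLogger("ampliflow")

MANUAL_REVIEW = "manual_review"


@dataclass
class PipelineResult:
    """In-memory product of a run, for tests and downstream tooling."""

    rows: list[ReportRow]
    coverage: pd.DataFrame
    failed_amplicons: pd.DataFrame
    counts: dict[str, int]
    paths: dict[str, Path] = field(default_factory=dict)

    @property
    def calls(self) -> list[ReportRow]:
        """Final variant calls: validated, and not dismissed as a
        homopolymer artefact by the (auto) classifier."""
        return [r for r in self.rows
                if r.status == VariantStatus.VALIDATED.value
                and r.homopolymer_label != HpLabel.ARTEFACT.value]


def run_pipeline(config: PipelineConfig, *,
                 write_outputs: bool = True) -> PipelineResult:
    out_dir = Path(config.out_dir)
    if write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "counts": {}}

    def _stage(name: str, **counts: int) -> None:
        manifest["stages"].append(name)
        manifest["counts"].update(counts)
        logger.info("stage %s: %s", name, counts)
        if write_outputs:
            (out_dir / "MANIFEST.json").write_text(json.dumps(manifest, indent=1))

    try:
        for label, p in (("sff", config.sff), ("amplicon table", config.amplicon_table)):
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"missing {label}: {p!r}")
        amplicons = read_amplicon_table(config.amplicon_table)
        model: GeneModel | None = None
        if config.genbank:
            model = parse_genbank(config.genbank)
        neutral = load_neutral_list(config.neutral_list) if config.neutral_list else set()
        header, reads = read_sff(config.sff)
        if not config.use_full_reads:
            reads = [r.clipped() for r in reads]
        _stage("read_sff", reads_total=len(reads))

        samples = dict(config.samples) or {"sample": ""}
        if any(m for m in samples.values()):
            by_sample, unassigned = demultiplex(reads, samples)
        else:
            by_sample, unassigned = {next(iter(samples)): reads}, []
        _stage("demultiplex", reads_unassigned=len(unassigned),
               **{f"reads_{s}": len(rs) for s, rs in by_sample.items()})

        aligner = make_aligner(config.alignment.match_score,
                               config.alignment.mismatch_score,
                               config.alignment.gap_open,
                               config.alignment.gap_extend)
        rois = _roi_map(model, amplicons, config.filters)
        rows: list[ReportRow] = []
        coverage_cells: dict[tuple[str, str], int] = {}
        failed_rows: list[dict] = []
        unaligned_names: list[tuple[str, str]] = []
        column_records: list[dict] = []
        hp_dir = out_dir / "homopolymers"
        for sample in samples:
            sample_reads = by_sample.get(sample, [])
            by_amp: dict[str, list[AlignedRead]] = {a.name: [] for a in amplicons}
            for read in sample_reads:
                aln = assign_and_align(read, amplicons, aligner=aligner,
                                       min_identity=config.alignment.min_identity)
                if aln is None:
                    unaligned_names.append((sample, read.name))
                else:
                    by_amp[aln.amplicon].append(aln)
            for amp in amplicons:
                alns = by_amp[amp.name]
                columns, raw = pileup_and_call(alns, amp)
                roi = rois[amp.name]
                validated_amp, failing = validate_amplicon(columns, roi, config.filters)
                depth_at = {c.reference_position: c.depth for c in columns}
                coverage_cells[(sample, amp.name)] = min(
                    (depth_at.get(p, 0) for p in roi), default=0)
                if not validated_amp:
                    failed_rows.append(dict(sample=sample, amplicon=amp.name,
                                            failing_positions=";".join(map(str, failing))))
                if config.export_column_coverage:
                    for col in columns:
                        column_records.append(dict(
                            sample=sample, amplicon=amp.name,
                            genomic_position=amp.genomic_offset + col.reference_position,
                            depth_forward=col.depth_forward,
                            depth_reverse=col.depth_reverse))
                decided = filter_variants(raw, config.filters, validated_amp, roi)
                for vv in sorted(decided, key=lambda v: (v.variant.reference_position,
                                                         v.variant.kind.value,
                                                         v.variant.alt_allele)):
                    if not vv.is_validated:
                        continue
                    hp_label = _homopolymer_step(
                        vv.variant, amp, alns, header.flow_order, config,
                        hp_dir if write_outputs and config.render_histograms else None)
                    c_string, kind, gpos = _annotate(vv.variant, amp, model)
                    rows.append(ReportRow.from_variant(
                        sample, vv, c_string, kind, gpos, hp_label))
        _stage("align_call_filter", reads_unaligned=len(unaligned_names),
               validated_variant_rows=len(rows),
               amplicon_failures=len(failed_rows))

        flag_duplicate_amplicons(rows)
        annotate_known(rows, neutral)
        coverage = pd.DataFrame(
            [[coverage_cells[(s, a.name)] for a in amplicons] for s in samples],
            index=pd.Index(list(samples), name="sample"),
            columns=[a.name for a in amplicons])
        failed = pd.DataFrame(failed_rows,
                              columns=["sample", "amplicon", "failing_positions"])
        result = PipelineResult(rows=rows, coverage=coverage,
                                failed_amplicons=failed,
                                counts=dict(manifest["counts"]))
        if write_outputs:
            genome = model.genomic_sequence if model else None
            result.paths = write_reports(
                rows, coverage, out_dir, failed_amplicons=failed,
                gene=model.gene if model else "amplicon_panel",
                genome_sequence=genome,
                write_vcf=config.write_vcf and genome is not None)
            rows_to_frame(rows).to_csv(out_dir / "variant_rows.tsv",
                                       sep="\t", index=False)
            pd.DataFrame(unaligned_names, columns=["sample", "read"]).to_csv(
                out_dir / "unaligned_reads.tsv", sep="\t", index=False)
            if config.export_column_coverage:
                pd.DataFrame(column_records).to_csv(
                    out_dir / "coverage_per_base.tsv", sep="\t", index=False)
        _stage("report", report_rows=len(rows))
        result.counts = dict(manifest["counts"])
        return result
    except Exception:
        if write_outputs:
            manifest["failed"] = True
            (out_dir / "MANIFEST.json").write_text(json.dumps(manifest, indent=1))
        raise


def _roi_map(model: GeneModel | None, amplicons: list[AmpliconDef],
             config: FilterConfig) -> dict[str, set[int]]:
    if model is None:
        return {a.name: set(range(len(a.reference_sequence))) for a in amplicons}
    rois = roi_positions(model.exon_intervals(), amplicons, config)
    uncovered = rois.pop("__uncovered__", set())
    if uncovered:
        logger.warning("exonic positions covered by no amplicon: %d", len(uncovered))
    # an amplicon whose span misses every ROI base is validated on its full length
    return {name: (roi or set(range(len(next(a for a in amplicons if a.name == name)))))
            for name, roi in rois.items()}


def _homopolymer_step(variant: RawVariant, amp: AmpliconDef,
                      alignments: list[AlignedRead], flow_order: str,
                      config: PipelineConfig, hp_dir: Path | None) -> str:
    site = detect_context(variant, amp.reference_sequence, config.min_run_length)
    if site is None:
        return ""
    signals, _excluded = extract_signals(site, alignments, flow_order)
    if signals.size == 0:
        return MANUAL_REVIEW
    hist = build_histogram(signals, site.n)
    classification = None
    if config.classifier.mode == "auto":
        classification = hist.classify(
            min_separation=config.classifier.min_separation,
            centering=config.classifier.centering,
            min_minor_weight=config.filters.min_variant_fraction,
            variance_floor=config.classifier.variance_floor)
        label = classification.label.value
    else:
        label = MANUAL_REVIEW
    if hp_dir is not None:
        hp_dir.mkdir(parents=True, exist_ok=True)
        suffix = ".jpeg" if config.image_format == "jpeg" else ".png"
        render_histogram(hist, site, hp_dir / (sidecar_name(site) + suffix),
                         classification=classification)
    elif hp_dir is None and config.render_histograms is False:
        pass
    return label


def _annotate(variant: RawVariant, amp: AmpliconDef,
              model: GeneModel | None) -> tuple[str, str, int]:
    gpos = amp.genomic_offset + variant.reference_position
    if model is None:
        ref = variant.ref_allele or "-"
        alt = variant.alt_allele or "-"
        return f"{amp.name}:g.{gpos + 1}{ref}>{alt}", variant.kind.value, gpos
    hv = normalize_variant(model, gpos, variant.ref_allele, variant.alt_allele)
    return hv.c_string, hv.kind, hv.genomic_start


def run_from_yaml(path: str | Path) -> PipelineResult:
    from .config import config_from_yaml
    return run_pipeline(config_from_yaml(path))
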