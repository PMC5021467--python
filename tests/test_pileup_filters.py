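"""Pileup counting, the screening decision table, and ROI construction."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ampliflow.align import assign_and_align
from ampliflow.amplicons import AmpliconDef
from ampliflow.filters import (FilterConfig, VariantStatus, decide_variant,
                               filter_variants, roi_positions,
                               validate_amplicon)
from ampliflow.pileup import PileupColumn, RawVariant, VariantKind, pileup_and_call
from ampliflow.sff import SffHeader
from ampliflow.simulate import NoiseModel, VariantSpec, simulate_cohort, simulate_read

from oracles import filter_decision_literal


def _align_all(templates, amplicon, seed=0):
    header = SffHeader.with_cycles(len(amplicon.reference_sequence) + 10)
    rng = np.random.default_rng(seed)
    noise = NoiseModel(0.0, 0.0, 0.1)
    out = []
    for i, t in enumerate(templates):
        read = simulate_read(t, header.flow_order, noise, rng, name=f"r{i}")
        aln = assign_and_align(read, [amplicon])
        assert aln is not None
        out.append(aln)
    return out


REF = "ACGTTGCAATGCCATGCGTCGATCGGTACGTTAGC"
AMP = AmpliconDef(name="a", reference_sequence=REF)


class TestPileup:
    def test_identical_reads_no_variants(self):
        alns = _align_all([REF] * 10, AMP)
        columns, raw = pileup_and_call(alns, AMP)
        assert raw == []
        assert all(c.depth == 10 for c in columns)

    def test_six_ref_four_alt_fraction(self):
        alt = REF[:12] + ("G" if REF[12] != "G" else "C") + REF[13:]
        alns = _align_all([REF] * 6 + [alt] * 4, AMP)
        _, raw = pileup_and_call(alns, AMP)
        assert len(raw) == 1
        v = raw[0]
        assert v.kind is VariantKind.SUBSTITUTION
        assert v.reference_position == 12
        assert v.depth == 10 and v.support == 4
        assert v.fraction == pytest.approx(0.40)

    def test_deletion_and_insertion_anchoring(self):
        deleted = REF[:8] + REF[10:]            # drop bases 8,9
        inserted = REF[:20] + "TT" + REF[20:]   # insert before base 20
        alns = _align_all([REF] * 5 + [deleted] * 3 + [inserted] * 2, AMP)
        _, raw = pileup_and_call(alns, AMP)
        kinds = {v.kind: v for v in raw}
        d = kinds[VariantKind.DELETION]
        assert d.reference_position == 8 and d.ref_allele == REF[8:10]
        i = kinds[VariantKind.INSERTION]
        assert i.reference_position == 20 and i.alt_allele == "TT"

    def test_counts_match_bruteforce_recount(self, rng):
        """Pileup counts equal an independent per-pair recount over a noisy
        simulated stack of reads on both strands."""
        templates = [REF] * 12
        header = SffHeader.with_cycles(len(REF) + 10)
        noise = NoiseModel(sigma0=0.25, sigma_slope=0.02)
        alns = []
        from ampliflow.amplicons import revcomp
        for i in range(24):
            t = REF if i % 2 == 0 else revcomp(REF)
            read = simulate_read(t, header.flow_order, noise, rng, name=f"n{i}")
            aln = assign_and_align(read, [AMP])
            if aln:
                alns.append(aln)
        columns, _ = pileup_and_call(alns, AMP)
        # oracle: recount depth and per-column match/sub directly from pairs
        for col in columns:
            p = col.reference_position
            depth_f = depth_r = 0
            events: dict = {}
            for aln in alns:
                lo, hi = aln.reference_range()
                if lo <= p < hi:
                    if aln.strand == "+":
                        depth_f += 1
                    else:
                        depth_r += 1
                for r, q in aln.pairs:
                    if r == p and q is not None:
                        b = aln.oriented_bases[q]
                        key = ("match",) if b == REF[p] else ("sub", b)
                        events[key] = events.get(key, 0) + 1
            assert (col.depth_forward, col.depth_reverse) == (depth_f, depth_r)
            for key, count in events.items():
                assert sum(col.observations.get(key, {}).values()) == count
            # conservation: aligned-base events never exceed depth
            aligned = sum(sum(c.values()) for k, c in col.observations.items()
                          if k[0] in ("match", "sub"))
            assert aligned <= col.depth


class TestFilterRules:
    CFG = FilterConfig()

    def test_support_boundary(self):
        assert decide_variant(2, 1, 5, 5, 0.5, self.CFG) is VariantStatus.REJECTED_SUPPORT
        assert decide_variant(2, 2, 5, 5, 0.5, self.CFG) is VariantStatus.VALIDATED

    def test_single_strand_exemption(self):
        # all support forward, reverse strand entirely uncovered -> validated
        assert decide_variant(10, 0, 10, 0, 0.5, self.CFG) is VariantStatus.VALIDATED
        # reverse covered but unsupporting -> strand rejection
        assert decide_variant(10, 0, 10, 5, 0.5, self.CFG) is VariantStatus.REJECTED_STRAND

    def test_fraction_boundary_inclusive(self):
        assert decide_variant(4, 4, 20, 20, 0.19, self.CFG) is VariantStatus.REJECTED_FREQUENCY
        assert decide_variant(4, 4, 20, 20, 0.20, self.CFG) is VariantStatus.VALIDATED

    def test_exhaustive_truth_table(self):
        """Decision equivalence with the literal rule transcription over the
        full (support x coverage x fraction) grid — zero discrepancies."""
        cfg = self.CFG
        mismatches = []
        for cf, cr in itertools.product(range(11), repeat=2):
            for sf in range(cf + 1):
                for sr in range(cr + 1):
                    depth = cf + cr
                    fracs = {0.0, 0.1, 0.19, 0.2, 0.21, 0.5, 1.0}
                    if depth:
                        fracs.add((sf + sr) / depth)
                    for frac in fracs:
                        got = decide_variant(sf, sr, cf, cr, frac, cfg).value
                        want = filter_decision_literal(
                            sf, sr, cf, cr, frac,
                            cfg.min_variant_reads, cfg.min_variant_fraction,
                            cfg.require_both_strands)
                        if got != want:
                            mismatches.append((sf, sr, cf, cr, frac, got, want))
        assert mismatches == []

    def test_simulation_truth_recovery(self, panel):
        """Zero noise, defaults: exactly the injected variants with fraction
        >= 0.20 and >= 4 supporting reads are validated."""
        templates = {"amp1": panel.templates["amp1"]}
        local = panel.local(0, panel.sub_site - 160)  # an exon-1 position
        specs = [
            VariantSpec("amp1", position=40, ref=templates["amp1"][40],
                        alt="A" if templates["amp1"][40] != "A" else "G",
                        fraction=0.5),
            VariantSpec("amp1", position=90, ref=templates["amp1"][90],
                        alt="C" if templates["amp1"][90] != "C" else "T",
                        fraction=0.05),  # below the fraction threshold
        ]
        _, reads, truth = simulate_cohort(templates, specs, depth=100,
                                          mids={"P1": ""},
                                          noise=NoiseModel(0.0, 0.0, 0.1),
                                          seed=17)
        reads = [r.clipped() for r in reads]
        amp = panel.amplicons[0]
        alns = [assign_and_align(r, [amp]) for r in reads]
        columns, raw = pileup_and_call([a for a in alns if a], amp)
        decided = filter_variants(raw, FilterConfig(), True)
        validated = {(v.variant.reference_position, v.variant.alt_allele)
                     for v in decided if v.is_validated}
        truth_frac = truth.reads["variants"].str.contains("40:").mean()
        assert validated == {(40, specs[0].alt)} or truth_frac < 0.2


class TestAmpliconValidation:
    def test_depth_40_boundary(self):
        cfg = FilterConfig()
        cols = [PileupColumn(i, "A", depth_forward=20, depth_reverse=20)
                for i in range(10)]
        ok, failing = validate_amplicon(cols, set(range(10)), cfg)
        assert ok and failing == []
        cols[3].depth_forward = 19  # 39 total at position 3
        ok, failing = validate_amplicon(cols, set(range(10)), cfg)
        assert not ok and failing == [3]

    def test_random_roi_matches_min_oracle(self, rng):
        cfg = FilterConfig()
        for _ in range(50):
            depths = rng.integers(0, 120, size=30)
            cols = [PileupColumn(i, "A", depth_forward=int(d), depth_reverse=0)
                    for i, d in enumerate(depths)]
            roi = set(map(int, rng.choice(30, size=rng.integers(1, 30),
                                          replace=False)))
            ok, failing = validate_amplicon(cols, roi, cfg)
            assert ok == (min(depths[sorted(roi)]) >= cfg.min_depth)
            assert failing == sorted(p for p in roi if depths[p] < cfg.min_depth)

    def test_empty_roi_is_config_error(self):
        with pytest.raises(ValueError):
            validate_amplicon([], set(), FilterConfig())


class TestRoi:
    AMPS = [AmpliconDef(name="w", reference_sequence="A" * 300, genomic_offset=0)]

    def test_default_margins(self):
        rois = roi_positions([(100, 200)], self.AMPS, FilterConfig())
        assert rois["w"] == set(range(80, 206))

    def test_zero_margins_equal_exon(self):
        cfg = FilterConfig(roi_upstream=0, roi_downstream=0)
        rois = roi_positions([(100, 200)], self.AMPS, cfg)
        assert rois["w"] == set(range(100, 200))

    def test_overlapping_exons_union_oracle(self, rng):
        cfg = FilterConfig()
        for _ in range(20):
            exons = sorted((int(s), int(s) + int(rng.integers(5, 60)))
                           for s in rng.integers(0, 250, size=4))
            rois = roi_positions(exons, self.AMPS, cfg)
            expected = set()
            for s, e in exons:
                expected |= set(range(max(0, s - 20), min(300, e + 6)))
            assert rois["w"] == expected

    def test_uncovered_exon_reported(self):
        rois = roi_positions([(100, 200), (500, 550)], self.AMPS, FilterConfig())
        assert rois["__uncovered__"] == set(range(500, 550))
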