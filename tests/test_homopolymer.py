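"""Homopolymer context detection, signal extraction, histograms, classifier."""

from __future__ import annotations

import json

import numpy as np
import pytest

from ampliflow.align import assign_and_align
from ampliflow.amplicons import AmpliconDef
from ampliflow.homopolymer import (HpLabel, build_histogram, classify,
                                   detect_context, extract_signals,
                                   read_sidecar, render_histogram,
                                   sidecar_name)
from ampliflow.pileup import RawVariant, VariantKind
from ampliflow.sff import SffHeader
from ampliflow.simulate import NoiseModel, simulate_read

from oracles import homopolymer_run_by_scan


def _raw(kind, pos, ref="", alt="", amplicon="a"):
    return RawVariant(amplicon=amplicon, reference_position=pos, kind=kind,
                      ref_allele=ref, alt_allele=alt, reads_forward=5,
                      reads_reverse=5, depth=20, depth_forward=10,
                      depth_reverse=10)


class TestDetectContext:
    def test_deletion_in_seven_a_run(self):
        ref = "CAAAAAAAG"
        site = detect_context(_raw(VariantKind.DELETION, 4, ref="A"), ref, 3)
        assert site is not None
        assert (site.run_base, site.run_start, site.run_end, site.n) == ("A", 1, 8, 7)

    def test_short_run_is_not_context(self):
        site = detect_context(_raw(VariantKind.DELETION, 2, ref="T"), "CGTAG", 3)
        assert site is None

    def test_substitution_never_has_context(self):
        site = detect_context(_raw(VariantKind.SUBSTITUTION, 3, ref="A", alt="G"),
                              "CAAAAAG", 3)
        assert site is None

    def test_insertion_adjacent_to_run(self):
        ref = "CAAAAAG"
        # insertion of A before position 6 (right boundary of the run)
        site = detect_context(_raw(VariantKind.INSERTION, 6, alt="A"), ref, 3)
        assert site is not None and site.n == 5

    def test_mixed_sequence_insertion_ignored(self):
        site = detect_context(_raw(VariantKind.INSERTION, 3, alt="AG"),
                              "CAAAAAG", 3)
        assert site is None

    def test_agrees_with_linear_scan_oracle(self, rng):
        """Every single-base del/ins over random references agrees with the
        brute-force run scanner."""
        for _ in range(30):
            ref = "".join(rng.choice(list("ACGT"), 60))
            for pos in range(1, len(ref) - 1):
                v = _raw(VariantKind.DELETION, pos, ref=ref[pos])
                site = detect_context(v, ref, 3)
                start, end = homopolymer_run_by_scan(ref, pos)
                if end - start >= 3:
                    assert site is not None
                    assert (site.run_start, site.run_end) == (start, end)
                else:
                    assert site is None


class TestExtractSignals:
    REF = "ACGTTGCATGCAAAAAAAGTCGATCGGTACGTTAGC"  # 7-A run at 12..19
    AMP = AmpliconDef(name="a", reference_sequence=REF)

    def _site(self):
        v = _raw(VariantKind.DELETION, 12, ref="A")
        return detect_context(v, self.REF, 3)

    def _align(self, templates, noise=NoiseModel(0.0, 0.0, 0.1), seed=0):
        header = SffHeader.with_cycles(len(self.REF) + 10)
        rng = np.random.default_rng(seed)
        alns = []
        for i, t in enumerate(templates):
            r = simulate_read(t, header.flow_order, noise, rng, name=f"r{i}")
            aln = assign_and_align(r, [self.AMP])
            assert aln is not None
            alns.append(aln)
        return header, alns

    def test_single_zero_noise_read(self):
        header, alns = self._align([self.REF])
        signals, excluded = extract_signals(self._site(), alns, header.flow_order)
        assert excluded == 0
        assert signals.tolist() == [7.0]

    def test_het_deletion_zero_noise(self):
        deleted = self.REF[:12] + self.REF[13:]
        header, alns = self._align([self.REF] * 5 + [deleted] * 5)
        signals, _ = extract_signals(self._site(), alns, header.flow_order)
        assert sorted(signals.tolist()) == [6.0] * 5 + [7.0] * 5

    def test_reverse_strand_reads_contribute(self):
        from ampliflow.amplicons import revcomp
        header, alns = self._align([self.REF, revcomp(self.REF)])
        assert {a.strand for a in alns} == {"+", "-"}
        signals, excluded = extract_signals(self._site(), alns, header.flow_order)
        assert excluded == 0 and signals.tolist() == [7.0, 7.0]

    def test_noisy_signals_match_per_read_oracle(self):
        noise = NoiseModel(sigma0=0.15, sigma_slope=0.0)
        header, alns = self._align([self.REF] * 30, noise=noise, seed=3)
        signals, _ = extract_signals(self._site(), alns, header.flow_order)
        # oracle: for each read, find its own A-run flow by scanning bases
        expected = []
        for aln in alns:
            read = aln.read
            idx = read.bases.find("AAA", 8)  # the long A run
            flow = read.flow_index_per_base[idx]
            expected.append(read.flow_values[flow - 1] / 100.0)
        assert sorted(signals.tolist()) == sorted(expected)

    def test_non_spanning_reads_excluded(self):
        header, alns = self._align([self.REF, self.REF[:15]])
        signals, excluded = extract_signals(self._site(), alns, header.flow_order)
        assert len(signals) == 1 and excluded == 1


class TestHistogram:
    def test_two_close_signals_one_coarse_bin(self):
        hist = build_histogram([6.95, 7.04], 7)
        assert hist.coarse_percent[7] == pytest.approx(100.0)

    def test_het_case_bins(self):
        hist = build_histogram([6.0] * 5 + [7.0] * 5, 7)
        assert hist.coarse_percent[6] == pytest.approx(50.0)
        assert hist.coarse_percent[7] == pytest.approx(50.0)
        fine = dict(zip(hist.fine_edges.round(1), hist.fine_counts))
        assert fine[6.0] == 5 and fine[7.0] == 5

    def test_mass_conservation_random(self, rng):
        for _ in range(20):
            signals = rng.uniform(0, 9, size=rng.integers(1, 200))
            hist = build_histogram(signals, 5)
            assert hist.fine_counts.sum() == len(signals)
            assert hist.coarse_percent.sum() == pytest.approx(100.0, abs=0.5)
            # recount oracle
            for edge, count in zip(hist.fine_edges, hist.fine_counts):
                assert count == np.sum((signals >= edge - 1e-9)
                                       & (signals < edge + 0.1 - 1e-9))

    def test_empty_signals_error(self):
        with pytest.raises(ValueError):
            build_histogram([], 7)


class TestClassifier:
    def test_tight_het(self):
        cls = classify(build_histogram([6.0] * 50 + [7.0] * 50, 7))
        assert cls.label is HpLabel.HETEROZYGOUS_INDEL
        assert cls.mode_positions == pytest.approx([6.0, 7.0], abs=0.05)

    def test_unimodal_between_integers_is_artefact(self):
        rng = np.random.default_rng(1)
        signals = rng.normal(6.5, 0.2, size=100)
        cls = classify(build_histogram(signals, 7))
        assert cls.label is HpLabel.ARTEFACT

    def test_wild_type_and_homozygous(self):
        rng = np.random.default_rng(2)
        wt = classify(build_histogram(rng.normal(7.0, 0.15, 150), 7))
        assert wt.label is HpLabel.WILD_TYPE
        hom = classify(build_histogram(rng.normal(6.0, 0.15, 150), 7))
        assert hom.label is HpLabel.HOMOZYGOUS_INDEL

    def test_seeded_het_replicates(self):
        """0.5 N(6, 0.15) + 0.5 N(7, 0.15), 200 signals: the bimodal verdict
        must hold in >= 95% of 100 seeded replicates."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            signals = np.concatenate([rng.normal(6.0, 0.15, 100),
                                      rng.normal(7.0, 0.15, 100)])
            cls = classify(build_histogram(signals, 7))
            hits += cls.label is HpLabel.HETEROZYGOUS_INDEL
        assert hits >= 95

    def test_noise_monotonicity_never_promotes_to_het(self):
        """Pure wild-type signal with growing sigma may degrade to artefact
        or ambiguous but never to a heterozygous verdict at sub-threshold
        mode separation."""
        for sigma in (0.1, 0.2, 0.3, 0.4):
            for seed in range(10):
                rng = np.random.default_rng(seed)
                signals = rng.normal(7.0, sigma, size=120)
                cls = classify(build_histogram(signals, 7))
                if cls.label is HpLabel.HETEROZYGOUS_INDEL:
                    assert cls.mode_positions[1] - cls.mode_positions[0] >= 0.5

    def test_degenerate_constant_signals(self):
        cls = classify(build_histogram([6.0] * 10, 7))
        assert cls.label is HpLabel.HOMOZYGOUS_INDEL


class TestRendering:
    def test_render_writes_image_and_sidecar(self, tmp_path):
        from ampliflow.homopolymer import HomopolymerSite
        site = HomopolymerSite(amplicon="a", run_base="A", run_start=12, run_end=19)
        hist = build_histogram([6.0] * 5 + [7.0] * 5, 7)
        out = tmp_path / (sidecar_name(site) + ".png")
        render_histogram(hist, site, out)
        assert out.exists() and out.stat().st_size > 0
        sidecar = out.with_suffix(".json")
        data = json.loads(sidecar.read_text())
        assert data["fine_counts"] == hist.fine_counts.tolist()
        assert data["n"] == 7
        # round trip through the sidecar reader
        hist2, site2, cls2 = read_sidecar(sidecar)
        assert hist2.fine_counts.tolist() == hist.fine_counts.tolist()
        assert site2 == site and cls2 is None

    def test_batch_deterministic_names(self, tmp_path):
        from ampliflow.homopolymer import HomopolymerSite
        names = set()
        for start in range(20):
            site = HomopolymerSite(amplicon="ampX", run_base="G",
                                   run_start=start, run_end=start + 5)
            hist = build_histogram([5.0] * 4, 5)
            out = tmp_path / (sidecar_name(site) + ".png")
            render_histogram(hist, site, out)
            names.add(out.name)
        assert len(names) == 20
        assert len(list(tmp_path.glob("hp_ampX_*.png"))) == 20
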