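# ampliflow

Amplicon pyrosequencing variant screening with flowgram-level homopolymer
artefact review.

## The problem

Diagnostic resequencing of genes such as *BRCA1*/*BRCA2* screens every
coding exon of a patient panel through PCR amplicons read on a
flow-space sequencer (454/pyrosequencing-style chemistry).  These
instruments read a homopolymer run of *n* identical bases as a **single
flow** whose light intensity should equal *n*; base calling rounds that
signal to the nearest integer.  Long runs are measured poorly, so the
rounded calls scatter between *n* − 1, *n* and *n* + 1 and the variant
caller reports spurious indels — the dominant false-positive class of the
technology, and an unacceptable one in a diagnostic setting.

The discriminating information is still present in the raw data.  Across
the reads of one sample, the distribution of the flow signal at the run is:

* **wild type** — one population centred on *n*;
* **heterozygous indel** — two populations, at *n* and *n* ± 1;
* **homozygous indel** — one population centred on *n* ± 1;
* **artefact** — one population sitting *between* integers (e.g. 6.5 for a
  7-base run): poor quantitation, not a discrete allele.

`ampliflow` implements the full desk workflow around that observation:
SFF (Standard Flowgram Format) I/O, MID barcode demultiplexing,
semi-global alignment of reads to amplicon references, pileup-based
candidate calling, screening rules (minimum depth 40 over the region of
interest, allele fraction ≥ 20 %, ≥ 4 supporting reads, both strands
required where both are covered), dual-resolution flowgram histograms with
an optional mixture-model classifier, HGVS c.-notation annotation from a
GenBank gene model, neutral-variant auto-annotation and colour-coded
reports — plus a pyrosequencing simulator so every stage is testable
without instrument data.

## The statistic at the core

For a candidate indel inside a homopolymer run of wild-type length *n*,
the per-read flow signals *s₁…s_d* at the run's flow are histogrammed at
two resolutions: 0.1-wide bins (read counts — the real distribution) and
integer bins covering [*k* − ½, *k* + ½) (percent of reads — the base
caller's view).  The automatic classifier fits 1- and 2-component Gaussian
mixtures to the signals, selects the component count by BIC, and labels:

* 2 components, mode separation ≥ 0.5 flow units, minor weight ≥ 20 % →
  `heterozygous_indel`;
* 1 component with mean within 0.25 of *n* → `wild_type`; of *n* ± 1 →
  `homozygous_indel`; strictly between the bands → `artefact`;
* anything else → `ambiguous` (flagged for manual review).

Classification is **manual by default** — the histograms and their JSON
sidecars are the deliverable, and the reviewer decides — with
`classifier.mode: auto` enabling the labels above.

## Worked example

Classify a flowgram histogram for a 7-base run, once for a true
heterozygous deletion (signals split 7.0 / 6.0) and once for the artefact
regime (one broad population at 6.5):

```python
import numpy as np
from ampliflow import build_histogram, classify

rng = np.random.default_rng(7)
signals = np.concatenate([rng.normal(7.0, 0.15, 60), rng.normal(6.0, 0.15, 60)])
hist = build_histogram(signals, n=7)
verdict = classify(hist)
print({int(b): round(float(p), 1)
       for b, p in zip(hist.coarse_bins, hist.coarse_percent) if p})
print(verdict.label.value, [round(m, 2) for m in verdict.mode_positions])

v2 = classify(build_histogram(rng.normal(6.5, 0.35, 120), n=7))
print(v2.label.value, [round(m, 2) for m in v2.mode_positions])
```

prints

```
{6: 50.0, 7: 50.0}
heterozygous_indel [5.99, 6.97]
artefact [6.45]
```

The integer-bin view (`{6: 50.0, 7: 50.0}`) is what a rounding base
caller reports — a 50 % indel in both cases.  The fine-grained modes tell
them apart: two tight populations at 6 and 7 (a real heterozygote) versus
one population centred on 6.45 (a misread homopolymer, dismissed).

The same decision runs end to end from files:

```sh
ampliflow simulate scenario.yaml --out cohort.sff     # SFF + truth tables
ampliflow run config.yaml                             # full pipeline
ampliflow classify-hp out/homopolymers/               # re-label sidecars
ampliflow report out/                                 # re-render reports
```

`run` writes `variant_report.tsv` (+ colour-coded `.xlsx`), a per-sample ×
per-amplicon coverage matrix, a no-variant amplicon list, a resequencing
worklist, histogram images with JSON sidecars, an optional VCF 4.2 export
and a MANIFEST of stage counts.

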