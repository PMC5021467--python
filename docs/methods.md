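# Methods

This note documents the models, rules and numerical choices behind
`ampliflow`, and what the synthetic-data studies do and do not demonstrate.

## Flow-space data model

A pyrosequencing read is a vector of flow signals, one per nucleotide flow
of a fixed cyclic order (default `TACG`), preceded on the instrument by the
key sequence `TCAG`.  A homopolymer run of *n* identical bases is read at a
single flow whose signal ideally equals *n*; base calling rounds each
signal to the nearest integer.  Files use the public SFF v1 layout
(big-endian; signals quantized to hundredths in a uint16; per-base flow
indices delta-encoded in a uint8).  In memory, flow indices are absolute
1-based flow numbers; the delta conversion happens only at the I/O
boundary, so slicing a read (clipping, barcode trimming) never invalidates
flow lookups.  The optional read-index block is skipped on read and
omitted on write — processing is sequential.  Stored flow values are
treated as the quantities to histogram; no carry-forward or
incomplete-extension correction is applied (out of scope).

## Alignment and calling

Reads are assigned to samples by their 5′ MID barcode (unique match within
one mismatch; barcode sets with pairwise Hamming distance ≤ 2 are rejected
as ambiguous).  Each read is aligned semi-globally — free terminal
overhangs on either sequence, affine gaps — against every amplicon in both
orientations, keeping the best; scoring defaults are match +2, mismatch
−3, gap open −5, gap extend −2, chosen for amplicon-length reads with rare
gaps.  A read whose matched fraction over its whole length falls below 80 %
goes to a counted unaligned bin; identity is measured over the read, not
the aligned columns, so a short perfect overlap of a foreign read cannot
pass.  Alignment is base-space; flow-space alignment is not reproduced.

Pileups count per-column, per-strand events.  Insertions are anchored to
the reference column after which they occur, deletions at their first
deleted column; alignment ties are left to the aligner, and placement
ambiguity in repeats is resolved later by HGVS 3′ normalization, which is
placement-invariant by construction.  Every non-reference event seen in at
least one read becomes a candidate; the filter, not the caller, decides.

## Screening rules

An amplicon is validated when the **minimum** total depth over its region
of interest reaches 40 reads; the ROI is the union of exons widened by 20
bases upstream and 6 downstream (splice sites), intersected with the
amplicon.  A candidate variant is validated when it has ≥ 4 supporting
reads, support on both strands (waived when one strand has no coverage at
all), and allele fraction ≥ 20 %; all thresholds inclusive, checked in the
order support → strand → fraction, so each rejection has one reason.
Variant detection is deliberately independent of amplicon validation: a
validated variant in an under-covered amplicon is reported and flagged for
review rather than dropped, and the amplicon itself lands on the
resequencing worklist.

## Homopolymer analysis

A candidate indel has homopolymer context when its inserted/deleted
sequence is a repetition of one base and the maximal reference run
containing (deletion) or adjacent to (insertion) it is at least
`min_run_length` = 3 bases — the shortest run where signal quantitation
noise plausibly produces indel miscalls; the threshold is configurable.
Each spanning read contributes the signal of the flow carrying the run in
its *own* flow space (for reverse-strand reads, the complemented base's
flow): flow signals are instrument-native per read, and no transformation
to a common strand is attempted.  Reads not spanning the run plus one
flank are excluded and counted; for reads with the run fully deleted, the
run base's near-zero flow within the current cycle is used.

The histogram keeps fine 0.1-wide bins (read counts) and integer bins as
percent of reads (the rounding base caller's view).  The automatic
classifier fits 1- and 2-component Gaussian mixtures (variance floor 1e−3
as the covariance regularizer; fixed random state; 3 initializations for
the 2-component fit), selects by BIC, and applies: two components with
mode separation ≥ 0.5 flow units and minor weight ≥ the variant-fraction
threshold → heterozygous; otherwise the (pooled or dominant) single
population is read off its mean with a ±0.25 centring band around *n*
(wild type) and *n* ± 1 (homozygous); a mean strictly between the bands is
the artefact zone; anything else is ambiguous.  The 0.5 separation is half
the one-flow-unit distance between genuine alleles; 0.25 splits each unit
interval into centred versus between-integer regions.  Classification is
off by default — histogram reading is a reviewer's decision in routine
use, and the automated verdict is an extension — and when on, its verdict
is stored in the JSON sidecar next to the raw signals it was derived from.
In auto mode, a validated indel whose histogram is labelled `artefact` is
excluded from the final calls; `ambiguous` labels and calls in
non-validated amplicons are marked `needs_review`.

## Annotation and reports

Gene models come from single-gene GenBank records (exon features, one CDS;
minus-strand genes are flipped into coding orientation on parse).
Coordinates follow c.-notation conventions: 1-based CDS positions,
negative 5′ UTR, `*` 3′ UTR, intronic positions as nearest-exon-boundary ±
offset.  Variant normalization trims shared flanking bases (prefix first,
then suffix — a delins never retains a base it also deletes), shifts pure
indels to the 3′-most placement on the coding strand, and spells an
insertion that repeats the preceding sequence as `dup`.  Protein-level
nomenclature and impact prediction are out of scope; the report carries an
empty annotation column for downstream tools.  Neutral-variant
auto-annotation matches exact normalized strings — catalogue lists are
string sets, and an unnormalized alias is deliberately not matched.
Canonical outputs are TSV; the coloured spreadsheet is cosmetic; the VCF
export left-anchors indels per VCF convention.

## Simulator

The generator emulates the flow-space error regime with a two-parameter
Gaussian noise model: at a run of length *n* the signal is drawn from
N(*n*, σ(*n*)) truncated at 0, with σ(*n*) = σ₀ + *slope*·*n* (defaults
σ₀ = 0.1, slope = 0.01), and empty flows from N(0, σ₀).  The defaults keep
per-read indel miscalls below 1 % for runs up to n = 7 (normal-tail bound
2Φ(−0.5/σ(7)) ≈ 0.3 %), matching a regime where wild-type runs are mostly
read correctly but long-run artefacts are plausible.  Designated artefact
runs draw with σ = 0.35 and mean *n* − 0.5 — the undercall regime that
produces the monomodal between-integers distribution of a misread strong
homopolymer.  Cohorts draw each read's haplotype per variant by its target
fraction (binomial), assign strands 50/50 by default, prepend the sample
MID and the key, and are written as standard SFF with plain-text truth
tables.  Base qualities decrease with the distance of the signal from its
rounded integer (downstream stages use clips only).  The simulator is not
a calibrated 454 error model: no carry-forward/incomplete extension, no
emulsion-PCR duplicates or chimeras, no quality-by-cycle decay.  Passing
tests therefore demonstrate correct mechanics and decision logic under a
clean noise model, not performance on degraded real runs.

## Problem sizes and numerics

The test and acceptance studies run at desk scale, chosen to exercise
every decision boundary while keeping the suites quick: two ~150-bp
amplicons on a 420-bp synthetic gene, cohort depths 20–300, a
6 × 3 × 2 × 3 classifier grid (run lengths 4–9, depths 40/100/200, σ
0.1/0.2, allele fractions 0/0.5/1) with four seeded replicates per cell
plus artefact cells at σ 0.35, 1000-read SFF round trips, 500 alignment
oracle instances ≤ 30 bp, and 1000 normalization instances on a
repeat-rich 600-bp sequence.  All randomness flows from explicit seeds;
reruns are byte-identical.  Degenerate inputs are handled explicitly:
zero-variance signal sets bypass the mixture fit, empty signal sets raise,
empty ROIs are configuration errors, and a read violating its invariants
blocks an SFF write before any bytes are written.

## Known limitations

Base-space alignment can misplace indels near amplicon ends; only
single-sample germline screening is covered (no somatic pairing, no
probabilistic genotyping, no base-quality recalibration); homopolymer
review assumes one candidate run at a time (no multi-run joint phasing);
the GenBank parser handles single-gene records without origin-crossing
joins; duplicate amplicons covering the same position are piled up
separately and merged only at report level.
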