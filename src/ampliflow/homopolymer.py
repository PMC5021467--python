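"""Homopolymer-context detection and flowgram-histogram classification.

Pyrosequencing encodes a homopolymer run of length n as a single flow whose
signal should be n.  Long runs are measured poorly: the signal distribution
across reads widens, and integer rounding then produces spurious indel
calls.  The discriminating observation is the *shape* of the per-read
signal distribution at the run's flow:

* heterozygous indel — two populations, one centred on n and one on n+1
  (insertion) or n-1 (deletion);
* homozygous indel — a single population centred on n+1 or n-1;
* artefact — a single population sitting *between* integers, the signature
  of poor quantitation rather than a discrete allele;
* wild type — a single population centred on n.

The histogram is kept at two resolutions: fine 0.1-wide bins (read counts)
showing the real distribution, and coarse integer bins (percent of reads)
mimicking what a base caller that rounds each signal would report.

The automated classifier fits one- and two-component Gaussian mixtures to
the signals, picks the component count by BIC, and applies the rules above
with configurable margins.  It is off by default — histogram interpretation
is a manual review step in routine use — and its verdict is always stored
next to the raw data it was derived from.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path

import numpy as np

from .align import AlignedRead
from .amplicons import revcomp
from .pileup import RawVariant, VariantKind
from .sff import base_to_flow


class HpLabel(str, Enum):
    WILD_TYPE = "wild_type"
    HETEROZYGOUS_INDEL = "heterozygous_indel"
    HOMOZYGOUS_INDEL = "homozygous_indel"
    ARTEFACT = "artefact"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class HomopolymerSite:
    """A reference homopolymer run containing a candidate indel.

    ``run_start``/``run_end`` are 0-based half-open on the amplicon
    reference; ``n = run_end - run_start`` is the wild-type run length.
    """

    amplicon: str
    run_base: str
    run_start: int
    run_end: int
    variant: RawVariant | None = field(default=None, compare=False)

    @property
    def n(self) -> int:
        return self.run_end - self.run_start


def detect_context(variant: RawVariant, reference: str,
                   min_run_length: int = 3) -> HomopolymerSite | None:
    """Homopolymer context test for a candidate variant.

    Returns the maximal run of identical reference bases containing (for
    deletions) or adjacent to (for insertions) the variant, provided the
    inserted/deleted sequence is a repetition of the run base and the
    wild-type run length reaches ``min_run_length``.  Substitutions and
    delins never have a homopolymer context here.
    """
    if variant.kind not in (VariantKind.INSERTION, VariantKind.DELETION):
        return None
    allele = variant.ref_allele if variant.kind is VariantKind.DELETION else variant.alt_allele
    if not allele or len(set(allele)) != 1:
        return None
    base = allele[0]
    pos = variant.reference_position
    if variant.kind is VariantKind.DELETION:
        if reference[pos:pos + len(allele)] != allele:
            return None
        anchor = pos
    else:
        # insertion before ``pos``: adjacent run on either side
        if pos < len(reference) and reference[pos] == base:
            anchor = pos
        elif pos > 0 and reference[pos - 1] == base:
            anchor = pos - 1
        else:
            return None
    if reference[anchor] != base:
        return None
    start = anchor
    while start > 0 and reference[start - 1] == base:
        start -= 1
    end = anchor + 1
    while end < len(reference) and reference[end] == base:
        end += 1
    if end - start < min_run_length:
        return None
    return HomopolymerSite(amplicon=variant.amplicon, run_base=base,
                           run_start=start, run_end=end, variant=variant)


def extract_signals(site: HomopolymerSite, alignments: list[AlignedRead],
                    flow_order: str) -> tuple[np.ndarray, int]:
    """Flow signals of all reads across the run, one value per spanning read.

    Each read contributes the signal of the flow that carries the run in its
    *own* flow space: for reverse-strand reads that is the flow of the
    complemented base.  Reads must span the run plus one flanking base on
    each side; others are excluded and counted.  For reads in which the run
    is fully deleted, the signal of the run base's flow within the current
    cycle (a near-zero flow) is used.

    Returns (signals, n_excluded).
    """
    signals: list[float] = []
    excluded = 0
    lo, hi = site.run_start - 1, site.run_end + 1
    for aln in alignments:
        rmin, rmax = aln.reference_range()
        if rmin > lo or rmax < hi:
            excluded += 1
            continue
        in_run = [(r, q) for r, q in aln.pairs
                  if r is not None and site.run_start <= r < site.run_end and q is not None]
        read = aln.read
        if in_run:
            # prefer a base that actually is the run base
            chosen = next(((r, q) for r, q in in_run
                           if aln.oriented_bases[q] == site.run_base), in_run[0])
            inst = aln.to_instrument_index(chosen[1])
            flow = base_to_flow(read, inst)
            signals.append(read.flow_values[flow - 1] / 100.0)
            continue
        # run fully deleted in this read: locate the run base's flow in the
        # cycle following the read base 5' (instrument orientation) of the run
        if aln.strand == "+":
            flank_ref = site.run_start - 1
            target = site.run_base
        else:
            flank_ref = site.run_end
            target = revcomp(site.run_base)
        flank = [(r, q) for r, q in aln.pairs if r == flank_ref and q is not None]
        if not flank:
            excluded += 1
            continue
        inst = aln.to_instrument_index(flank[0][1])
        flow = base_to_flow(read, inst)
        found = None
        for f in range(flow + 1, min(flow + len("ACGT") + 1, len(flow_order) + 1)):
            if flow_order[f - 1] == target:
                found = f
                break
        if found is None:
            excluded += 1
            continue
        signals.append(read.flow_values[found - 1] / 100.0)
    return np.asarray(signals, dtype=float), excluded


@dataclass
class FlowHistogram:
    """Dual-resolution histogram of flow signals at one homopolymer run.

    ``fine_edges[i]`` is the left edge of the 0.1-wide bin with count
    ``fine_counts[i]`` (read counts); ``coarse_bins[k]`` are integer signal
    values with ``coarse_percent[k]`` percent of reads rounding to them —
    the base caller's view of the same data.
    """

    signals: np.ndarray
    n: int
    fine_edges: np.ndarray
    fine_counts: np.ndarray
    coarse_bins: np.ndarray
    coarse_percent: np.ndarray

    def classify(self, **kwargs) -> "HpClassification":
        return classify(self, **kwargs)


def build_histogram(signals: np.ndarray | list[float], n: int) -> FlowHistogram:
    """Bin ``signals`` at 0.1 (counts) and 1.0 (percent) resolution.

    Fine bins are half-open [k/10, (k+1)/10) aligned at multiples of 0.1;
    coarse bin k covers [k-0.5, k+0.5), i.e. integer rounding.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.size == 0:
        raise ValueError("no spanning reads: cannot build a histogram")
    fine_idx = np.floor(signals * 10 + 1e-9).astype(int)
    n_fine = int(fine_idx.max()) + 1
    fine_counts = np.bincount(fine_idx, minlength=n_fine)
    fine_edges = np.arange(n_fine) / 10.0
    coarse_idx = np.floor(signals + 0.5).astype(int)
    n_coarse = int(coarse_idx.max()) + 1
    coarse_counts = np.bincount(coarse_idx, minlength=n_coarse)
    keep = np.arange(n_coarse)
    return FlowHistogram(
        signals=signals, n=n,
        fine_edges=fine_edges, fine_counts=fine_counts,
        coarse_bins=keep, coarse_percent=100.0 * coarse_counts / signals.size)


@dataclass
class HpClassification:
    """Verdict of the mixture-model analysis of one flow histogram.

    ``evidence`` is the margin by which the decisive quantity clears its
    threshold (mode separation beyond 0.5 for two populations, distance
    inside the 0.25 centring band for one); negative margins never occur —
    they map to ``ambiguous`` or ``artefact`` by the rules.
    """

    label: HpLabel
    mode_positions: list[float]
    evidence: float
    weights: list[float]
    n_components: int


def classify(hist: FlowHistogram, *,
             min_separation: float = 0.5,
             centering: float = 0.25,
             min_minor_weight: float = 0.20,
             variance_floor: float = 1e-3,
             random_state: int = 0) -> HpClassification:
    """Classify a flow histogram as wild type, real indel or artefact.

    One- and two-component Gaussian mixtures are fitted to the signals and
    compared by BIC.  Two well-separated populations (mode separation >=
    ``min_separation`` flow units, minor weight >= ``min_minor_weight``)
    indicate a heterozygous indel.  A single population is read off its
    mean: within ``centering`` of n -> wild type; of n±1 -> homozygous
    indel; strictly between the bands -> artefact (poor quantitation);
    anything else -> ambiguous.
    """
    from sklearn.mixture import GaussianMixture

    x = hist.signals.reshape(-1, 1)
    n = hist.n
    if x.size < 2 or np.ptp(x) == 0.0:
        mean = float(x.mean())
        return _one_population(mean, n, centering, weights=[1.0], modes=[mean])
    gm1 = GaussianMixture(1, reg_covar=variance_floor,
                          random_state=random_state).fit(x)
    gm2 = GaussianMixture(2, n_init=3, reg_covar=variance_floor,
                          random_state=random_state).fit(x)
    use_two = gm2.bic(x) < gm1.bic(x)
    if use_two:
        means = gm2.means_.ravel()
        weights = gm2.weights_.ravel()
        order = np.argsort(means)
        means, weights = means[order], weights[order]
        separation = float(means[1] - means[0])
        minor = float(weights.min())
        if separation >= min_separation and minor >= min_minor_weight:
            return HpClassification(
                label=HpLabel.HETEROZYGOUS_INDEL,
                mode_positions=[float(m) for m in means],
                evidence=separation - min_separation,
                weights=[float(w) for w in weights],
                n_components=2)
        if minor < min_minor_weight and separation >= min_separation:
            # a dominant population plus a sub-threshold satellite
            major = float(means[int(np.argmax(weights))])
            return _one_population(major, n, centering,
                                   weights=[float(w) for w in weights],
                                   modes=[float(m) for m in means])
        # two overlapping components: effectively one population
        pooled = float(np.average(means, weights=weights))
        return _one_population(pooled, n, centering,
                               weights=[float(w) for w in weights],
                               modes=[float(m) for m in means])
    mean = float(gm1.means_.ravel()[0])
    return _one_population(mean, n, centering, weights=[1.0], modes=[mean])


def _one_population(mean: float, n: int, centering: float,
                    *, weights: list[float], modes: list[float]) -> HpClassification:
    def result(label: HpLabel, evidence: float) -> HpClassification:
        return HpClassification(label=label, mode_positions=modes,
                                evidence=evidence, weights=weights,
                                n_components=len(modes))
    if abs(mean - n) <= centering:
        return result(HpLabel.WILD_TYPE, centering - abs(mean - n))
    for target in (n - 1, n + 1):
        if target >= 0 and abs(mean - target) <= centering:
            return result(HpLabel.HOMOZYGOUS_INDEL, centering - abs(mean - target))
    if n - 1 < mean < n + 1:
        # strictly between the centring bands: the artefact zone
        return result(HpLabel.ARTEFACT,
                      min(abs(mean - n), abs(mean - (n - 1)), abs(mean - (n + 1))) - centering)
    return result(HpLabel.AMBIGUOUS, 0.0)


# ---------------------------------------------------------------------------
# rendering and sidecars

def render_histogram(hist: FlowHistogram, site: HomopolymerSite,
                     out_path: str | Path, *,
                     classification: HpClassification | None = None) -> Path:
    """Dual-axis histogram figure: fine 0.1 bins as read counts (red), coarse
    integer bins as percent of reads (blue).  Format follows the file suffix
    (.png or .jpeg).  A JSON sidecar with the underlying data is written
    next to the image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_path = Path(out_path)
    fig, ax_fine = plt.subplots(figsize=(7, 4))
    ax_coarse = ax_fine.twinx()
    ax_coarse.bar(hist.coarse_bins, hist.coarse_percent, width=0.9,
                  color="tab:blue", alpha=0.35, label="% of reads (integer bins)")
    ax_fine.bar(hist.fine_edges + 0.05, hist.fine_counts, width=0.095,
                color="tab:red", label="reads per 0.1 interval")
    ax_fine.axvline(site.n, color="grey", ls="--", lw=0.8)
    ax_fine.set_xlabel("flow signal intensity")
    ax_fine.set_ylabel("reads per 0.1 bin", color="tab:red")
    ax_coarse.set_ylabel("% of reads per integer bin", color="tab:blue")
    title = f"{site.amplicon} {site.run_base}x{site.n} @ {site.run_start}"
    if classification is not None:
        title += f" — {classification.label.value}"
    ax_fine.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    write_sidecar(hist, site, out_path.with_suffix(".json"), classification=classification)
    return out_path


def sidecar_name(site: HomopolymerSite) -> str:
    """Deterministic site-keyed stem for histogram outputs."""
    return f"hp_{site.amplicon}_{site.run_start}_{site.run_base}{site.n}"


def write_sidecar(hist: FlowHistogram, site: HomopolymerSite,
                  path: str | Path,
                  classification: HpClassification | None = None) -> None:
    payload = {
        "amplicon": site.amplicon,
        "run_base": site.run_base,
        "run_start": site.run_start,
        "run_end": site.run_end,
        "n": site.n,
        "signals": [float(s) for s in hist.signals],
        "fine_edges": [float(e) for e in hist.fine_edges],
        "fine_counts": [int(c) for c in hist.fine_counts],
        "coarse_bins": [int(b) for b in hist.coarse_bins],
        "coarse_percent": [float(p) for p in hist.coarse_percent],
    }
    if classification is not None:
        payload["classification"] = {
            "label": classification.label.value,
            "mode_positions": classification.mode_positions,
            "evidence": classification.evidence,
            "weights": classification.weights,
            "n_components": classification.n_components,
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_sidecar(path: str | Path) -> tuple[FlowHistogram, HomopolymerSite, HpClassification | None]:
    data = json.loads(Path(path).read_text())
    site = HomopolymerSite(amplicon=data["amplicon"], run_base=data["run_base"],
                           run_start=data["run_start"], run_end=data["run_end"])
    hist = build_histogram(np.asarray(data["signals"]), data["n"])
    cls = None
    if "classification" in data:
        c = data["classification"]
        cls = HpClassification(label=HpLabel(c["label"]),
                               mode_positions=c["mode_positions"],
                               evidence=c["evidence"], weights=c["weights"],
                               n_components=c["n_components"])
    return hist, site, cls
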