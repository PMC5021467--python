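"""Synthetic 454-style pyrosequencing reads with a homopolymer noise model.

The generator emulates the flow-space error regime of pyrosequencing: at the
flow carrying a homopolymer run of length n the measured signal is drawn
around n with a standard deviation that grows with run length,
``sigma(n) = sigma0 + sigma_slope * n``, truncated at zero.  Bases are then
called by rounding each signal to the nearest integer — exactly the
quantization step that turns a poorly measured long run into a spurious
indel.  Designated *artefact* sites draw their signal with an inflated
standard deviation and a mean shifted half a flow unit toward undercall,
reproducing the monomodal between-integers signal distribution that a
misread strong homopolymer shows, as opposed to the bimodal (heterozygous)
or integer-shifted (homozygous) distributions of real indels.

Cohorts are written as standard SFF plus a plain-text truth table, so the
whole pipeline is testable without instrument data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sff import (DEFAULT_FLOW_CYCLE, DEFAULT_KEY, FlowRead, SffHeader,
                  template_flow_runs, write_sff)


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian flow-signal noise, length-proportional.

    sigma0: baseline standard deviation (flow units) for a run of length 0.
    sigma_slope: per-unit-run-length increment; sigma(n) = sigma0 + sigma_slope * n.
    artefact_sigma: inflated sigma applied at designated artefact runs.
    Signals are truncated at 0.
    """

    sigma0: float = 0.1
    sigma_slope: float = 0.01
    artefact_sigma: float = 0.35
    artefact_mean_shift: float = -0.5  # flow units, undercall regime

    def __post_init__(self) -> None:
        if self.sigma0 < 0 or self.sigma_slope < 0:
            raise ValueError("sigma0 and sigma_slope must be non-negative")
        if self.artefact_sigma <= self.sigma0:
            raise ValueError("artefact_sigma must exceed sigma0")

    def sigma(self, run_length: int) -> float:
        return self.sigma0 + self.sigma_slope * run_length


@dataclass(frozen=True)
class ArtefactSite:
    """A homopolymer run (template coordinates, 0-based half-open) whose
    flows are drawn with the artefact noise regime."""

    template_name: str
    run_start: int
    run_end: int


@dataclass(frozen=True)
class VariantSpec:
    """A variant injected into an amplicon at a target allele fraction.

    ``position`` is 0-based on the amplicon reference; ``ref``/``alt`` are
    the replaced and replacement sequences (empty alt = deletion, empty ref
    = insertion after ``position - 1`` convention is avoided: insertions use
    ref="" and insert *before* ``position``).
    """

    amplicon: str
    position: int
    ref: str
    alt: str
    fraction: float = 0.5

    def apply(self, reference: str) -> str:
        if reference[self.position:self.position + len(self.ref)] != self.ref:
            raise ValueError(
                f"variant ref {self.ref!r} does not match amplicon "
                f"{self.amplicon!r} at {self.position}")
        return reference[:self.position] + self.alt + reference[self.position + len(self.ref):]


def _required_cycles(template: str, flow_cycle: str) -> int:
    # worst case one cycle per run, plus slack for noise-extended payloads
    n_runs = 1 + sum(1 for a, b in zip(template, template[1:]) if a != b)
    return n_runs + 8


def simulate_read(template: str, flow_order: str, noise: NoiseModel,
                  rng: np.random.Generator, *, name: str = "read",
                  artefact_runs: frozenset[int] | set[int] = frozenset(),
                  key: str = "") -> FlowRead:
    """Simulate one read of ``key + template`` over ``flow_order``.

    ``artefact_runs`` holds 0-based template positions belonging to runs that
    draw from the artefact regime.  Bases are called by rounding the signal
    at each flow; ``flow_index_per_base`` points every called base at its
    flow.  Deterministic for a fixed ``rng`` state.
    """
    if not template:
        raise ValueError("empty template")
    full = key + template
    runs = template_flow_runs(full, flow_order)
    n_flows = len(flow_order)
    flow_values = np.zeros(n_flows, dtype=np.int64)
    # true signal per flow
    truth = np.zeros(n_flows, dtype=float)
    is_artefact_flow = np.zeros(n_flows, dtype=bool)
    pos = 0
    for flow_1b, _base, length in runs:
        truth[flow_1b - 1] = length
        run_positions = range(pos - len(key), pos - len(key) + length)
        if any(p in artefact_runs for p in run_positions):
            is_artefact_flow[flow_1b - 1] = True
        pos += length
    sigmas = np.where(truth > 0, noise.sigma0 + noise.sigma_slope * truth, noise.sigma0)
    means = truth.astype(float)
    sigmas = np.where(is_artefact_flow, noise.artefact_sigma, sigmas)
    means = np.where(is_artefact_flow, means + noise.artefact_mean_shift, means)
    signals = means + sigmas * rng.standard_normal(n_flows)
    signals = np.maximum(signals, 0.0)
    if noise.sigma0 == 0 and noise.sigma_slope == 0:
        signals = np.where(is_artefact_flow, signals, truth)
    flow_values = np.round(signals * 100).astype(np.int64)
    called = np.round(flow_values / 100.0).astype(np.int64)
    bases_parts: list[str] = []
    index_parts: list[int] = []
    qual_parts: list[int] = []
    for f in range(n_flows):
        k = int(called[f])
        if k <= 0:
            continue
        # the container's uint8 delta encoding cannot place a call more than
        # 255 flows after the previous one; drop such isolated noise calls
        if index_parts and f + 1 - index_parts[-1] > 255:
            continue
        frac = abs(flow_values[f] / 100.0 - k)
        q = max(5, int(round(40 - 70 * frac)))  # monotone in distance to integer
        bases_parts.append(flow_order[f] * k)
        index_parts.extend([f + 1] * k)
        qual_parts.extend([q] * k)
    bases = "".join(bases_parts)
    key_bases = len(key)
    read = FlowRead(
        name=name,
        flow_values=flow_values,
        flow_index_per_base=np.array(index_parts, dtype=np.int64),
        bases=bases,
        quality=np.array(qual_parts, dtype=np.int64),
        clip_qual_left=key_bases + 1 if key_bases else 0,
    )
    return read


@dataclass
class TruthTable:
    """Ground truth of a simulated cohort."""

    variants: pd.DataFrame       # sample, amplicon, position, ref, alt, fraction
    artefacts: pd.DataFrame      # sample, amplicon, run_start, run_end
    reads: pd.DataFrame          # read name, sample, amplicon, template, strand

    def write(self, path: str | Path) -> None:
        path = Path(path)
        self.variants.to_csv(path, sep="\t", index=False)
        self.artefacts.to_csv(path.with_suffix(".artefacts.tsv"),
                              sep="\t", index=False)
        self.reads.to_csv(path.with_suffix(".reads.tsv"), sep="\t", index=False)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def simulate_cohort(amplicons: dict[str, str],
                    variants: list[VariantSpec],
                    depth: int | dict[str, int],
                    mids: dict[str, str],
                    noise: NoiseModel,
                    seed: int,
                    *,
                    strand_ratio: float = 0.5,
                    artefact_sites: list[ArtefactSite] | None = None,
                    flow_cycle: str = DEFAULT_FLOW_CYCLE,
                    key: str = DEFAULT_KEY,
                    out_sff: str | Path | None = None,
                    ) -> tuple[SffHeader, list[FlowRead], TruthTable]:
    """Simulate a multiplexed amplicon cohort.

    Per sample and amplicon, ``depth`` reads are drawn; each read carries the
    variant haplotype with probability equal to the variant's target
    fraction (binomial sampling), a strand (forward with probability
    ``strand_ratio``) and the sample's MID prepended.  Reverse reads are the
    reverse complement of the (possibly variant) template with the MID still
    at the 5' end of the read, as sequenced.  All randomness flows from
    ``seed``.
    """
    artefact_sites = artefact_sites or []
    rng = np.random.default_rng(seed)
    for v in variants:
        if v.amplicon not in amplicons:
            raise ValueError(f"variant targets unknown amplicon {v.amplicon!r}")
        v.apply(amplicons[v.amplicon])  # raises if inconsistent
    by_amp: dict[str, list[VariantSpec]] = {}
    for v in variants:
        by_amp.setdefault(v.amplicon, []).append(v)
    art_by_template: dict[str, list[ArtefactSite]] = {}
    for site in artefact_sites:
        if site.template_name not in amplicons:
            raise ValueError(f"artefact site targets unknown template {site.template_name!r}")
        tmpl = amplicons[site.template_name]
        run = tmpl[site.run_start:site.run_end]
        if len(set(run)) != 1 or len(run) < 2:
            raise ValueError(
                f"artefact site {site.template_name}[{site.run_start}:{site.run_end}] "
                "is not a homopolymer run")
        art_by_template.setdefault(site.template_name, []).append(site)

    max_template = max((len(m) + len(s) for s in amplicons.values() for m in mids.values()),
                       default=0) + len(key)
    n_cycles = max(_required_cycles("ACGT" * (max_template // 4 + 2), flow_cycle), 8)
    header = SffHeader.with_cycles(n_cycles, cycle=flow_cycle, key_sequence=key)

    reads: list[FlowRead] = []
    truth_reads = []
    truth_vars = []
    truth_art = []
    counter = 0
    for sample, mid in mids.items():
        for amp_name, ref in amplicons.items():
            d = depth[amp_name] if isinstance(depth, dict) else depth
            amp_vars = by_amp.get(amp_name, [])
            for v in amp_vars:
                truth_vars.append(dict(sample=sample, amplicon=amp_name,
                                       position=v.position, ref=v.ref, alt=v.alt,
                                       fraction=v.fraction))
            for site in art_by_template.get(amp_name, []):
                truth_art.append(dict(sample=sample, amplicon=amp_name,
                                      run_start=site.run_start, run_end=site.run_end))
            for _ in range(d):
                template = ref
                carried: list[str] = []
                # one variant per amplicon template at a time, applied 3'->5'
                for v in sorted(amp_vars, key=lambda v: -v.position):
                    if rng.random() < v.fraction:
                        template = v.apply(template)
                        carried.append(f"{v.position}:{v.ref}>{v.alt}")
                art_positions: set[int] = set()
                for site in art_by_template.get(amp_name, []):
                    art_positions.update(range(site.run_start, site.run_end))
                strand = "+" if rng.random() < strand_ratio else "-"
                if strand == "+":
                    payload = mid + template
                    art = {p + len(mid) for p in art_positions}
                else:
                    rc = _revcomp(template)
                    payload = mid + rc
                    L = len(template)
                    art = {len(mid) + (L - 1 - p) for p in art_positions}
                name = f"SIM{counter:07d}"
                counter += 1
                reads.append(simulate_read(payload, header.flow_order, noise, rng,
                                           name=name, artefact_runs=art, key=key))
                truth_reads.append(dict(read=name, sample=sample, amplicon=amp_name,
                                        strand=strand,
                                        variants=";".join(sorted(carried)) or "."))
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = TruthTable(
        variants=pd.DataFrame(truth_vars, columns=["sample", "amplicon", "position",
                                                   "ref", "alt", "fraction"]),
        artefacts=pd.DataFrame(truth_art, columns=["sample", "amplicon",
                                                   "run_start", "run_end"]),
        reads=pd.DataFrame([truth_reads[i] for i in order],
                           columns=["read", "sample", "amplicon", "strand", "variants"]),
    )
    if out_sff is not None:
        write_sff(header, reads, out_sff)
    return header, reads, truth
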