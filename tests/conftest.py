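"""Shared fixtures: a deterministic synthetic gene panel and cohorts."""

from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from ampliflow.amplicons import AmpliconDef
from ampliflow.genemodel import GeneModel
from ampliflow.simulate import NoiseModel


@dataclass(frozen=True)
class Panel:
    """A two-amplicon synthetic gene panel with known homopolymer runs.

    Exon 1 carries a 7-A run (a_run) suitable for real-indel injection;
    exon 2 carries a 6-G run (g_run) used as the designated artefact site
    and a clean substitution site.
    """

    model: GeneModel
    amplicons: list[AmpliconDef]
    a_run: tuple[int, int]       # genomic, 0-based half-open
    g_run: tuple[int, int]
    sub_site: int                # genomic

    @property
    def templates(self) -> dict[str, str]:
        g = self.model.genomic_sequence
        return {a.name: a.reference_sequence for a in self.amplicons}

    def local(self, amplicon_index: int, genomic_pos: int) -> int:
        return genomic_pos - self.amplicons[amplicon_index].genomic_offset


def build_panel(seed: int = 11) -> Panel:
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("ACGT"), 420))
    # avoid incidental long homopolymers that would shadow the designed runs
    for i in range(2, len(seq)):
        while seq[i] == seq[i - 1] == seq[i - 2]:
            seq[i] = "ACGT"[rng.integers(0, 4)]
    seq[99] = "C"
    seq[100:107] = list("AAAAAAA")
    seq[107] = "G"
    seq[239] = "T"
    seq[240:246] = list("GGGGGG")
    seq[246] = "A"
    genome = "".join(seq)
    model = GeneModel(gene="GENE1", genomic_sequence=genome,
                      exons=((50, 150), (200, 320)),
                      cds_start=60, cds_end=300, transcript_id="TX1")
    amplicons = [
        AmpliconDef(name="amp1", reference_sequence=genome[30:180], genomic_offset=30),
        AmpliconDef(name="amp2", reference_sequence=genome[180:340], genomic_offset=180),
    ]
    return Panel(model=model, amplicons=amplicons,
                 a_run=(100, 107), g_run=(240, 246), sub_site=260)


@pytest.fixture(scope="session")
def panel() -> Panel:
    return build_panel()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240925)


@pytest.fixture(scope="session")
def default_noise() -> NoiseModel:
    return NoiseModel()


MIDS = {"P1": "ACGAGTGCGT", "P2": "ACGCTCGACA",
        "P3": "AGACGCACGT", "P4": "AGCACTGTAG"}
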