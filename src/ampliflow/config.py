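"""Pipeline configuration: defaults, validation, YAML round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .filters import FilterConfig


@dataclass(frozen=True)
class ClassifierConfig:
    """Homopolymer classifier settings.

    ``mode`` is ``manual`` (histograms and sidecars are produced, labels
    left to the reviewer) or ``auto`` (mixture-model labels applied)."""

    mode: str = "manual"
    min_separation: float = 0.5
    centering: float = 0.25
    variance_floor: float = 1e-3

    def __post_init__(self) -> None:
        if self.mode not in ("manual", "auto"):
            raise ValueError(f"classifier mode must be manual|auto, got {self.mode!r}")
        if not 0 < self.min_separation <= 2:
            raise ValueError("min_separation out of range (0, 2]")
        if not 0 < self.centering < 0.5:
            raise ValueError("centering out of range (0, 0.5)")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be positive")


@dataclass(frozen=True)
class AlignmentConfig:
    match_score: float = 2.0
    mismatch_score: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    min_identity: float = 0.80

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity out of range (0, 1]")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the end-to-end run needs; mirrors the CLI flags."""

    sff: str = ""
    amplicon_table: str = ""
    genbank: str = ""
    out_dir: str = "ampliflow_out"
    neutral_list: str = ""
    samples: dict[str, str] = field(default_factory=dict)  # sample -> MID
    filters: FilterConfig = field(default_factory=FilterConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    alignment: AlignmentConfig = field(default_factory=AlignmentConfig)
    min_run_length: int = 3
    use_full_reads: bool = False     # default: quality-clipped portion only
    render_histograms: bool = True
    export_column_coverage: bool = False  # BED-graph-like per-base TSV
    image_format: str = "jpeg"
    write_vcf: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_run_length < 2:
            raise ValueError("min_run_length must be >= 2")
        if self.image_format not in ("jpeg", "png"):
            raise ValueError("image_format must be jpeg|png")


def config_to_yaml(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))


def config_from_yaml(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(data)


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data)
    for key, cls in (("filters", FilterConfig),
                     ("classifier", ClassifierConfig),
                     ("alignment", AlignmentConfig)):
        if key in data and isinstance(data[key], dict):
            data[key] = cls(**data[key])
    return PipelineConfig(**data)
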