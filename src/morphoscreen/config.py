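"""Run configuration: one validated block of every stage's parameters.

All screening thresholds live here with their conventional defaults:
YAP/TAZ ratio hit at |Z| >= 1.5, shape hit at normal-fraction Z <= -1,
phenocluster cut at uncentered PCC > 0.73, proteomics cuts |log2| > 0.5
with permutation FDR < 0.05, focal-adhesion track filters (>= 5 frames,
mean axial ratio < 3), and 30-degree Golgi angle bins.

A single global seed is fanned out deterministically to per-module seeds
via ``module_seed`` (SHA-256 of ``"<seed>:<module>"``, reduced mod 2^31).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields, asdict

import yaml

__all__ = ["RunConfig", "module_seed", "load_config"]


def module_seed(global_seed: int, module: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{module}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class SegmentationConfig:
    smoothing_sigma: float = 2.0
    min_nucleus_area: int = 40
    min_cell_area: int = 100
    ring_width_px: int = 4
    band_width_px: int = 3


@dataclass
class ClassifierConfig:
    min_exemplars: int = 20
    l2_C: float = 1.0
    holdout_fraction: float = 0.25
    normal_box_population: str = "pooled"


@dataclass
class ScoringConfig:
    yap_z_threshold: float = 1.5
    normal_z_threshold: float = -1.0
    min_cells_per_well: int = 50
    min_mock_wells: int = 8
    plate_normalize: bool = True


@dataclass
class ClusteringConfig:
    pcc_threshold: float = 0.73
    linkage: str = "average"


@dataclass
class AdhesionConfig:
    frame_interval_min: float = 3.0
    min_track_frames: int = 5
    max_mean_axial_ratio: float = 3.0
    stability_fraction: float = 0.90
    n_boot: int = 5000


@dataclass
class ProteomicsConfig:
    n_perm: int = 1000
    s0: float = 0.1
    alpha: float = 0.05
    log2_cut: float = 0.5
    fdr_method: str = "sam"


@dataclass
class PolarityConfig:
    bin_width_deg: float = 30.0


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "morphoscreen_out"
    log_level: str = "INFO"
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    adhesions: AdhesionConfig = field(default_factory=AdhesionConfig)
    proteomics: ProteomicsConfig = field(default_factory=ProteomicsConfig)
    polarity: PolarityConfig = field(default_factory=PolarityConfig)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "segmentation": SegmentationConfig,
    "classifier": ClassifierConfig,
    "scoring": ScoringConfig,
    "clustering": ClusteringConfig,
    "adhesions": AdhesionConfig,
    "proteomics": ProteomicsConfig,
    "polarity": PolarityConfig,
}


def _build_section(cls, data: dict, name: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"config section {name!r}: unknown keys {sorted(unknown)}")
    return cls(**data)


def load_config(path_or_dict) -> RunConfig:
    """Load a RunConfig from a YAML path or a plain dict; unknown keys reject."""
    if isinstance(path_or_dict, dict):
        raw = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    top_allowed = {"seed", "output_dir", "log_level", *_SECTIONS}
    unknown = set(raw) - top_allowed
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    kwargs = {k: raw[k] for k in ("seed", "output_dir", "log_level") if k in raw}
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs[name] = _build_section(cls, dict(raw[name] or {}), name)
    return RunConfig(**kwargs)
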