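"""Pipeline configuration: schema-validated YAML with provenance hashing.

Unknown keys are rejected so typos fail loudly; every output directory gets
a ``config_used.yaml`` whose SHA-256 hash is stamped into the report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "config_hash"]


@dataclass
class SimulateConfig:
    n_control: int = 5
    n_diabetic: int = 8
    n_slices: int = 4
    voxel_size: float = 0.006
    points_per_region: int = 3
    raman_noise_sd: float = 10.0
    indent_noise_sd: float = 5.0
    bending_noise_sd: float = 0.05


@dataclass
class BendingSection:
    span_mm: float = 7.0
    preload_N: float = 2.0
    yield_secant_fraction: float = 0.10
    failure_drop_fraction: float = 0.10
    stiffness_window_fraction: float = 0.20


@dataclass
class IndenterSection:
    epsilon: float = 0.75
    beta: float = 1.0
    E_indenter_GPa: float = 1141.0
    nu_indenter: float = 0.07
    nu_sample: float = 0.3
    fit_range_hi: float = 0.95
    fit_range_lo: float = 0.20


@dataclass
class RamanSection:
    truncate_lo: float = 280.0
    truncate_hi: float = 2000.0
    rcf_radius: float = 400.0
    rcf_iterations: int = 3
    rcf_intensity_fraction: float = 0.5
    rcf_smooth_sigma: float = 3.0


@dataclass
class GeometrySection:
    sigma: float = 0.0
    threshold: float = 0.5
    tmd_slope: float = 1200.0
    tmd_intercept: float = 0.0


@dataclass
class StatsSection:
    diabetic_glucose_threshold: float = 250.0
    significance_level: float = 0.05


@dataclass
class PipelineConfig:
    seed: int = 0
    log_level: str = "INFO"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    geometry: GeometrySection = field(default_factory=GeometrySection)
    bending: BendingSection = field(default_factory=BendingSection)
    indenter: IndenterSection = field(default_factory=IndenterSection)
    raman: RamanSection = field(default_factory=RamanSection)
    stats: StatsSection = field(default_factory=StatsSection)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "simulate": SimulateConfig,
    "geometry": GeometrySection,
    "bending": BendingSection,
    "indenter": IndenterSection,
    "raman": RamanSection,
    "stats": StatsSection,
}


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load and validate a YAML config; unknown keys raise with the field name."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        raw.update(overrides)
    cfg = PipelineConfig()
    for key, value in raw.items():
        if key in ("seed", "log_level"):
            setattr(cfg, key, value)
        elif key in _SECTIONS:
            if not isinstance(value, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            section_cls = _SECTIONS[key]
            section = getattr(cfg, key)
            valid = set(section.__dataclass_fields__)
            for k, v in value.items():
                if k not in valid:
                    raise ValueError(f"unknown config field {key}.{k!r}")
                setattr(section, k, v)
        else:
            raise ValueError(f"unknown config field {key!r}")
    return cfg


def config_hash(cfg: PipelineConfig) -> str:
    canonical = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def dump_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
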