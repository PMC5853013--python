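"""Run configuration: documented defaults, YAML overrides, CLI precedence.

Defaults mirror the analysis constants: 10 % cycle threshold, spectral
cutoff caps of 4 Hz (bradykinesia) and 20 Hz (rigidity) with a 10 %
magnitude threshold, Bonferroni alpha 0.05.  Precedence is CLI flag >
config file > default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .synthetic import CohortSpec


@dataclass
class ExtractConfig:
    threshold_frac: float = 0.10
    seg_band: str = "raw"  # raw | highpass | bradykinesia
    segmentation_mode: str = "task_axis_abs"
    smoothness_mode: str = "gyro_norm"
    smoothness_band: str = "raw"
    power_axis_policy: str = "task"  # task | sum3
    sparc_omega_c_max_bradykinesia: float = 4.0
    sparc_omega_c_max_rigidity: float = 20.0
    sparc_magnitude_threshold: float = 0.10


@dataclass
class StatsConfig:
    alpha: float = 0.05
    n_comparisons: int | None = None  # default: number of locations tested
    equal_var: bool = True
    greenhouse_geisser: bool = False


@dataclass
class RunConfig:
    simulate: CohortSpec = field(default_factory=CohortSpec)
    extract: ExtractConfig = field(default_factory=ExtractConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _update_dataclass(obj, values: dict, context: str) -> None:
    for key, val in values.items():
        if not hasattr(obj, key):
            raise KeyError(f"unknown config key {context}.{key}")
        current = getattr(obj, key)
        if isinstance(current, tuple) and isinstance(val, list):
            val = tuple(val)
        setattr(obj, key, val)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from defaults, an optional YAML file and overrides.

    Raises ``KeyError`` naming the offending key for unknown entries and
    ``yaml.YAMLError`` for malformed files.
    """
    cfg = RunConfig()
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
    if overrides:
        for section, vals in overrides.items():
            data.setdefault(section, {})
            if isinstance(vals, dict):
                data[section].update(vals)
            else:
                data[section] = vals
    for section, vals in data.items():
        if section == "seed":
            cfg.seed = int(vals)
        elif section in ("simulate", "extract", "stats"):
            if not isinstance(vals, dict):
                raise ValueError(f"config section {section!r} must be a mapping")
            _update_dataclass(getattr(cfg, section), vals, section)
        else:
            raise KeyError(f"unknown config section {section!r}")
    return cfg
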