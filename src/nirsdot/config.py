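"""Serializable pipeline configuration with validated defaults."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration fields; message names every one."""


@dataclass
class PipelineConfig:
    # acquisition
    fs: float = 5.0
    run_length_s: float = 600.0  # N = 3000 samples at 5 Hz
    # anatomy / montage
    n_vertices: int = 250
    roi_radius_mm: float = 10.0
    n_sources: int = 4
    n_detectors: int = 8
    decay_scale_mm: float = 12.0
    fov_threshold: float = 0.1
    # paradigm
    n_trials: int = 30
    trial_duration_s: float = 0.2
    iti_range_s: tuple[float, float] = (2.0, 60.0)
    initial_rest_s: float = 60.0
    # simulation
    model_id: int = 1
    snr_db: list[float] = field(default_factory=lambda: [0.0])
    n_replicates: int = 1
    # deconvolution
    window_s: tuple[float, float] = (-5.0, 30.0)
    drift_cutoff_hz: float = 0.01
    alpha: float = 0.05
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        errors = []
        if self.fs <= 0:
            errors.append("fs must be positive")
        if self.run_length_s <= 0:
            errors.append("run_length_s must be positive")
        if not 0 < self.alpha < 1:
            errors.append("alpha must be in (0, 1)")
        if not 0 < self.fov_threshold <= 1:
            errors.append("fov_threshold must be in (0, 1]")
        if self.model_id not in (1, 2, 3, 4):
            errors.append("model_id must be 1-4")
        if self.n_trials < 1:
            errors.append("n_trials must be >= 1")
        if self.n_replicates < 1:
            errors.append("n_replicates must be >= 1")
        if self.window_s[1] <= self.window_s[0]:
            errors.append("window_s upper bound must exceed lower bound")
        if errors:
            raise ConfigError("; ".join(errors))
        self.iti_range_s = tuple(self.iti_range_s)
        self.window_s = tuple(self.window_s)
        self.snr_db = list(self.snr_db)

    @property
    def n_samples(self) -> int:
        return int(round(self.run_length_s * self.fs))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["iti_range_s"] = list(d["iti_range_s"])
        d["window_s"] = list(d["window_s"])
        return d


def load_config(path) -> PipelineConfig:
    """Read a YAML/JSON config; defaults fill missing keys, unknown keys
    are rejected by name."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(
        text or "{}"
    )
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path) -> None:
    path = Path(path)
    d = config.to_dict()
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(d, sort_keys=True))
    else:
        path.write_text(json.dumps(d, indent=2, sort_keys=True))
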