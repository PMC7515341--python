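"""Pipeline configuration: every tunable with its default, validated at load.

Precedence when assembling an effective config: defaults < config file <
explicit overrides (CLI flags). The effective config is embedded in output
artifacts so results stay auditable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    # artifact removal
    median_window: int = 5
    median_rel_threshold: float = 0.2
    # resampling
    resample_hz: float = 4.0
    # AR spectrum / TFSI
    ar_order: int = 16
    tfsi_window_s: float = 64.0
    tfsi_hop_s: float = 4.0
    n_freq: int = 256
    # entropy quantization
    quantizer_levels: int = 256
    entropy_log_base: float = 10.0
    # evaluation
    cv_n_per_group: int = 300
    cv_n_repeats: int = 500
    cv_k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.median_window < 3 or self.median_window % 2 == 0:
            raise ValueError("median_window must be an odd integer >= 3")
        if not 0 < self.median_rel_threshold < 1:
            raise ValueError("median_rel_threshold must lie in (0, 1)")
        if self.resample_hz <= 0:
            raise ValueError("resample_hz must be positive")
        if self.ar_order < 1:
            raise ValueError("ar_order must be >= 1")
        if not 0 < self.tfsi_window_s <= 300:
            raise ValueError("tfsi_window_s must lie in (0, 300]")
        if self.tfsi_hop_s <= 0:
            raise ValueError("tfsi_hop_s must be positive")
        if self.tfsi_window_s * self.resample_hz <= 2 * self.ar_order:
            raise ValueError("TFSI window too short for the AR order")
        if self.n_freq < 2 or self.quantizer_levels < 2:
            raise ValueError("n_freq and quantizer_levels must be >= 2")
        if self.entropy_log_base <= 1:
            raise ValueError("entropy_log_base must exceed 1")
        if min(self.cv_n_per_group, self.cv_n_repeats) < 1 or self.cv_k < 2:
            raise ValueError("invalid cross-validation parameters")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load YAML or JSON, then apply explicit overrides on top."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def with_overrides(self, **overrides) -> "PipelineConfig":
        return dataclasses.replace(
            self, **{k: v for k, v in overrides.items() if v is not None}
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
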