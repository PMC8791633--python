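"""Analysis configuration.

Collects every threshold and bin size used by the opto-tagging and
spatial-modulation analyses in one place, so that a whole cohort run is
reproducible from a single small config file.  Defaults are the study's
canonical values (2.5 cm pixels, sigma = 1 pixel, 20 ms occupancy mask,
1 cm/s speed threshold, 20 ms latency window, 0.1 ms PSTH bins, 4 ms
direct-activation threshold, >=200 ms interpulse inclusion, <=5 mW power,
6 ms burst ISI, >50 spikes and >=3 laps for spatial inclusion).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised for invalid analysis configuration values."""


@dataclass
class AnalysisConfig:
    # spatial map construction
    pixel_size_cm: float = 2.5
    kernel_sigma_px: float = 1.0
    kernel_truncate_sigma: float = 4.0
    occupancy_mask_s: float = 0.020
    speed_threshold_cm_s: float = 1.0
    speed_smooth_s: float = 0.25
    linear_bin_cm: float = 2.5
    linear_sigma_bins: float = 1.0
    # opto-tagging
    latency_window_ms: float = 20.0
    psth_bin_ms: float = 0.1
    direct_latency_threshold_ms: float = 4.0
    min_interpulse_ms: float = 200.0
    max_power_mW: float = 5.0
    exclude_train_hz: tuple = (40.0,)
    response_probability_min: float = 0.5
    # cell typing / inclusion
    burst_isi_ms: float = 6.0
    min_spikes: int = 50
    min_laps: int = 3
    interneuron_rate_hz: float = 10.0
    narrow_waveform_ms: float = 0.4
    # reproducibility
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "pixel_size_cm", "kernel_sigma_px", "kernel_truncate_sigma",
            "occupancy_mask_s", "speed_threshold_cm_s", "speed_smooth_s",
            "linear_bin_cm", "linear_sigma_bins", "latency_window_ms",
            "psth_bin_ms", "direct_latency_threshold_ms", "min_interpulse_ms",
            "max_power_mW", "burst_isi_ms", "interneuron_rate_hz",
            "narrow_waveform_ms",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)!r}")
        if self.min_spikes < 0 or self.min_laps < 0:
            raise ConfigError("min_spikes and min_laps must be non-negative")
        if not 0.0 <= self.response_probability_min <= 1.0:
            raise ConfigError("response_probability_min must lie in [0, 1]")
        self.exclude_train_hz = tuple(float(f) for f in self.exclude_train_hz)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["exclude_train_hz"] = list(self.exclude_train_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)


def read_config(path: str | Path) -> AnalysisConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return AnalysisConfig.from_dict(data)


def write_config(config: AnalysisConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return path
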