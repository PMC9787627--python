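"""Pipeline configuration and the firmware parameter presets.

The breathing pipeline is controlled by a small set of parameters: the
sampling rate, the low-pass cut-off and order, the three dispersion-detector
parameters (lag, threshold, influence), the minimum time distance between
accepted exhalation peaks (debounce), the analysis window length Tw, and
physiological plausibility bounds on per-breath inhalation/exhalation
durations.  Six presets (ids 0-5) reproduce the parameter sets used to tune
the original chest-band firmware; preset 5 is the optimized set and the
default.  Peak time distances are stored in seconds (converted once from the
millisecond presets at this boundary).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import yaml

__all__ = ["PipelineConfig", "PRESETS", "load_preset", "ConfigError"]


class ConfigError(ValueError):
    """Raised for invalid pipeline configurations."""


# (fc_hz, lag, threshold, influence, t_min_peak_s); set 0 is the starting
# set, set 5 the optimized one.
PRESETS: dict[int, tuple[float, int, float, float, float]] = {
    0: (0.5, 56, 2.95, 0.58, 1.100),
    1: (0.6, 52, 2.95, 0.58, 1.100),
    2: (0.6, 56, 2.90, 0.58, 1.100),
    3: (0.6, 56, 2.85, 0.58, 1.000),
    4: (0.6, 58, 2.85, 0.58, 1.000),
    5: (0.6, 60, 2.87, 0.58, 1.000),
}


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of the breathing-extraction pipeline.

    Attributes
    ----------
    fs : float
        Front-sensor sampling rate in Hz (the back sensor is read twice per
        front sample, half a period before and after).
    fc : float
        Low-pass cut-off frequency in Hz applied to the differential signal.
    filter_order : int
        Butterworth filter order (causal IIR).
    lag : int
        Dispersion-detector history window, in samples.
    threshold : float
        Dispersion-detector threshold, in multiples of the moving SD.
    influence : float
        Weight in [0, 1] given to flagged samples in the detector's
        filtered history (0 = ignore peaks entirely, 1 = no damping).
    t_min_peak : float
        Debounce: minimum time in seconds between accepted exhalation peaks.
    tw : float
        Analysis window length Tw in seconds.
    ti_bounds, te_bounds : (float, float)
        Physiological plausibility bounds, in seconds, on per-breath
        inhalation/exhalation durations; candidates outside are discarded.
    preset_id : int or None
        The preset this config was derived from, if any.
    """

    fs: float = 100.0
    fc: float = 0.6
    filter_order: int = 2
    lag: int = 60
    threshold: float = 2.87
    influence: float = 0.58
    t_min_peak: float = 1.0
    tw: float = 30.0
    ti_bounds: tuple[float, float] = (0.4, 8.0)
    te_bounds: tuple[float, float] = (0.4, 8.0)
    preset_id: int | None = 5

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigError(f"fs must be positive, got {self.fs}")
        if not (0 < self.fc < self.fs / 2):
            raise ConfigError(
                f"fc must lie in (0, fs/2) = (0, {self.fs / 2}), got {self.fc}"
            )
        if self.filter_order < 1:
            raise ConfigError("filter_order must be >= 1")
        if self.lag < 2:
            raise ConfigError("lag must be >= 2 samples")
        if self.threshold <= 0:
            raise ConfigError("threshold must be positive")
        if not 0.0 <= self.influence <= 1.0:
            raise ConfigError("influence must lie in [0, 1]")
        if self.t_min_peak < 0:
            raise ConfigError("t_min_peak must be non-negative")
        if self.tw <= 0:
            raise ConfigError("tw must be positive")
        for name, (lo, hi) in (("ti_bounds", self.ti_bounds),
                               ("te_bounds", self.te_bounds)):
            if not (0 < lo < hi):
                raise ConfigError(f"{name} must satisfy 0 < lo < hi, got ({lo}, {hi})")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ti_bounds"] = list(self.ti_bounds)
        d["te_bounds"] = list(self.te_bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("ti_bounds", "te_bounds"):
            if key in d:
                d[key] = tuple(float(v) for v in d[key])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError("config YAML must map field names to values")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Short stable digest of the configuration, for run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


def load_preset(preset_id: int, fs: float = 100.0) -> PipelineConfig:
    """Return the pipeline configuration for firmware parameter set 0-5."""
    try:
        fc, lag, threshold, influence, t_min = PRESETS[preset_id]
    except (KeyError, TypeError) as exc:
        raise ConfigError(
            f"unknown preset id {preset_id!r}; valid ids are 0-5"
        ) from exc
    return PipelineConfig(
        fs=fs, fc=fc, lag=lag, threshold=threshold, influence=influence,
        t_min_peak=t_min, preset_id=preset_id,
    )
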