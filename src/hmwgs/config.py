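"""Centralized run configuration with YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .errors import ValidationError


@dataclass
class CallConfig:
    """Parameters of the identification pipeline."""

    k: float = 3.0  # RT window half-width multiplier on the reference SD
    window: tuple[float, float] = (25.0, 42.0)  # HMW region, minutes
    min_height: float | None = None  # AU; None = 5% of window maximum
    smooth_width: float = 0.05  # minutes
    oe_threshold: float = 1.5  # overexpression area ratio (inclusive)

    def __post_init__(self) -> None:
        self.window = tuple(self.window)  # type: ignore[assignment]
        if self.k <= 0 or self.oe_threshold <= 0 or self.smooth_width < 0:
            raise ValidationError("k, oe_threshold must be > 0 and smooth_width >= 0")


@dataclass
class SimConfig:
    """Parameters of the synthetic chromatogram/gel generator."""

    peak_sigma: float = 0.15  # Gaussian peak width, minutes
    amplitude: float = 100.0  # AU; doubled for Bx7OE
    oe_factor: float = 2.0
    rt_jitter_scale: float = 0.0  # multiplier on reference SDs; 0 = noise-free
    baseline_noise_sd: float = 0.0  # AU
    grid_step: float = 0.01  # minutes
    time_range: tuple[float, float] = (20.0, 60.0)
    lmw_clutter: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.time_range = tuple(self.time_range)  # type: ignore[assignment]
        if self.peak_sigma <= 0 or self.grid_step <= 0:
            raise ValidationError("peak_sigma and grid_step must be positive")
        if self.rt_jitter_scale < 0 or self.baseline_noise_sd < 0:
            raise ValidationError("jitter and noise scales must be non-negative")


def config_to_dict(call_cfg: CallConfig, sim_cfg: SimConfig) -> dict:
    d = {"call": asdict(call_cfg), "sim": asdict(sim_cfg)}
    d["call"]["window"] = list(call_cfg.window)  # JSON-stable
    d["sim"]["time_range"] = list(sim_cfg.time_range)
    return d


def load_config(path) -> tuple[CallConfig, SimConfig]:
    """Load a flat YAML file with optional ``call:`` and ``sim:`` sections."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    call_kwargs = dict(raw.get("call", {}))
    sim_kwargs = dict(raw.get("sim", {}))
    for kwargs, cls in ((call_kwargs, CallConfig), (sim_kwargs, SimConfig)):
        known = {f.name for f in fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValidationError(f"unknown {cls.__name__} keys in {path}: {sorted(unknown)}")
    return CallConfig(**call_kwargs), SimConfig(**sim_kwargs)
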