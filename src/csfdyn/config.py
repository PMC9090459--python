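"""YAML pipeline configuration with schema validation.

One file configures every stage (signal reduction, infusion analysis,
drainage summary, prediction, simulator). Unknown keys are rejected and all
numeric fields are range-checked on load; CLI flags override file values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace

import yaml

from .errors import ParseError
from .simulate import SimConfig


@dataclass
class SignalConfig:
    window_s: float = 10.0
    rap_span_n: int = 40
    cardiac_band: tuple = (0.67, 3.0)
    amp_method: str = "spectral"

    def validate(self):
        if self.window_s <= 0:
            raise ValueError("signal.window_s must be positive")
        if self.rap_span_n < 3:
            raise ValueError("signal.rap_span_n must be at least 3")
        lo, hi = self.cardiac_band
        if not 0 < lo < hi:
            raise ValueError("signal.cardiac_band must be an increasing positive pair")
        if self.amp_method not in ("spectral", "peak_to_peak"):
            raise ValueError("signal.amp_method must be spectral or peak_to_peak")


@dataclass
class InfusionConfig:
    rate_ml_min: float = 1.5
    baseline_min: float = 10.0
    steadiness_mmhg: float = 1.0
    slope_thresh: float = 0.2
    sustain_min: float = 5.0
    rout_terminate: float = 18.0

    def validate(self):
        if self.rate_ml_min <= 0:
            raise ValueError("infusion.rate_ml_min must be positive")
        if self.baseline_min <= 0 or self.sustain_min <= 0:
            raise ValueError("infusion durations must be positive")
        if self.slope_thresh <= 0 or self.steadiness_mmhg <= 0:
            raise ValueError("infusion thresholds must be positive")


@dataclass
class DrainageConfig:
    drain_rate_ml_h: float = 12.5
    smoothing: bool = True
    # exclude one correlation span plus settling after each segment boundary
    washin_s: float = 600.0

    def validate(self):
        if not 10.0 <= self.drain_rate_ml_h <= 15.0:
            raise ValueError("drainage.drain_rate_ml_h must lie in [10, 15] ml/h")
        if self.washin_s < 0:
            raise ValueError("drainage.washin_s must be nonnegative")


@dataclass
class PredictConfig:
    alpha_screen: float = 0.10
    hl_groups: int = 10
    ci_method: str = "delong"

    def validate(self):
        if not 0 < self.alpha_screen < 1:
            raise ValueError("predict.alpha_screen must lie in (0, 1)")
        if self.hl_groups < 3:
            raise ValueError("predict.hl_groups must be at least 3")
        if self.ci_method not in ("delong", "bootstrap"):
            raise ValueError("predict.ci_method must be delong or bootstrap")


@dataclass
class PipelineConfig:
    signal: SignalConfig = field(default_factory=SignalConfig)
    infusion: InfusionConfig = field(default_factory=InfusionConfig)
    drainage: DrainageConfig = field(default_factory=DrainageConfig)
    predict: PredictConfig = field(default_factory=PredictConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        self.signal.validate()
        self.infusion.validate()
        self.drainage.validate()
        self.predict.validate()
        self.sim.validate()
        return self

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "signal": SignalConfig,
    "infusion": InfusionConfig,
    "drainage": DrainageConfig,
    "predict": PredictConfig,
    "sim": SimConfig,
}


def _build_section(cls, data, name):
    if not isinstance(data, dict):
        raise ParseError(f"config section {name!r} must be a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ParseError(f"unknown keys in config section {name!r}: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return cls(**coerced)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config root must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ParseError(f"{path}: unknown top-level config keys {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs[name] = _build_section(cls, raw[name], name)
    if "seed" in raw:
        if not isinstance(raw["seed"], int):
            raise ParseError(f"{path}: seed must be an integer")
        kwargs["seed"] = raw["seed"]
    cfg = PipelineConfig(**kwargs)
    try:
        cfg.validate()
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return cfg


def with_overrides(cfg: PipelineConfig, **section_overrides) -> PipelineConfig:
    """Return a copy of ``cfg`` with per-section field overrides applied.

    ``with_overrides(cfg, sim={'r_out': 10})`` replaces fields inside the
    named sections; validation is re-run.
    """
    updates = {}
    for name, changes in section_overrides.items():
        if name == "seed":
            updates["seed"] = changes
            continue
        if name not in _SECTIONS:
            raise ValueError(f"unknown config section {name!r}")
        updates[name] = replace(getattr(cfg, name), **changes)
    return replace(cfg, **updates).validate()
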