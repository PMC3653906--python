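"""Run configuration: every numeric constant of the pipeline in one place."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields

from .errors import ConfigError


@dataclass(frozen=True)
class Tolerances:
    """Matching/filter tolerances of the platform."""

    ppm: float = 50.0            # cross-sample mass identity (<50 ppm)
    dt_min: float = 0.35         # cross-sample time identity / post-calibration control
    snr: float = 4.0             # minimum signal-to-noise ratio
    min_spectra: int = 3         # minimum consecutive spectra
    min_charge_excl: int = 1     # keep only z > this
    deconv_ppm: float = 25.0     # within-run charge-deconvolution mass tolerance
    deconv_dt_min: float = 0.1   # within-run co-elution tolerance


@dataclass(frozen=True)
class CalibrationConfig:
    span: float | None = None    # LOWESS window fraction; None = adaptive (~30 anchors)
    min_anchors: int = 10
    anchor_dt: float = 2.0       # coarse window for finding anchors pre-calibration


@dataclass(frozen=True)
class NormalizationConfig:
    min_hk: int = 3              # minimum housekeeping detections


@dataclass(frozen=True)
class AnalysisConfig:
    stage_cutpoints: tuple[float, ...] = (60.0, 30.0, 15.0)
    presence_frac: float = 0.5   # keep peptides present in > this fraction of samples
    cutoff: float = 0.55         # prognostic classifier cutoff
    k_clusters: int = 4


@dataclass(frozen=True)
class RunConfig:
    tolerances: Tolerances = field(default_factory=Tolerances)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int | None = None

    def __post_init__(self):
        t = self.tolerances
        for name in ("ppm", "dt_min", "snr", "deconv_ppm", "deconv_dt_min"):
            if getattr(t, name) <= 0:
                raise ConfigError(f"tolerance {name} must be positive, got {getattr(t, name)}")
        if t.min_spectra < 0 or t.min_charge_excl < 0:
            raise ConfigError("signal count thresholds must be non-negative")
        if self.calibration.span is not None and not 0 < self.calibration.span <= 1:
            raise ConfigError(f"calibration span must be in (0, 1], got {self.calibration.span}")
        if self.calibration.min_anchors < 2:
            raise ConfigError("min_anchors must be >= 2")
        if self.normalization.min_hk < 1:
            raise ConfigError("min_hk must be >= 1")
        a = self.analysis
        if not 0 <= a.presence_frac < 1:
            raise ConfigError(f"presence_frac must be in [0, 1), got {a.presence_frac}")
        if any(x <= y for x, y in zip(a.stage_cutpoints, a.stage_cutpoints[1:])):
            raise ConfigError("stage cutpoints must be strictly decreasing")
        if a.k_clusters < 1:
            raise ConfigError("k_clusters must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["analysis"]["stage_cutpoints"] = list(self.analysis.stage_cutpoints)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(dc, block):
            known = {f.name for f in fields(dc)}
            unknown = set(block) - known
            if unknown:
                raise ConfigError(f"unknown config key(s) {sorted(unknown)} in {dc.__name__}")
            return dc(**block)

        kwargs = {}
        if "tolerances" in d:
            kwargs["tolerances"] = build(Tolerances, d["tolerances"])
        if "calibration" in d:
            kwargs["calibration"] = build(CalibrationConfig, d["calibration"])
        if "normalization" in d:
            kwargs["normalization"] = build(NormalizationConfig, d["normalization"])
        if "analysis" in d:
            block = dict(d["analysis"])
            if "stage_cutpoints" in block:
                block["stage_cutpoints"] = tuple(block["stage_cutpoints"])
            kwargs["analysis"] = build(AnalysisConfig, block)
        if "seed" in d:
            kwargs["seed"] = d["seed"]
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        try:
            return cls.from_dict(json.loads(text))
        except json.JSONDecodeError as exc:
            raise ConfigError(f"invalid config JSON: {exc}") from exc
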