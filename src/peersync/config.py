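"""Run configuration: one YAML document drives the whole pipeline.

The document has optional blocks ``cohort`` (synthetic-study parameters),
``preprocess``, ``hrv``, ``wavelet`` and ``models``; every key defaults to
the module defaults, and the parsed config round-trips losslessly through
serialization.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from . import simulate
from .wavelet import WaveletSpec

__all__ = ["RunConfig", "load_config", "dump_config", "config_hash"]


@dataclass(frozen=True)
class PreprocessOptions:
    outlier_threshold: float = 0.30
    max_gap_s: float = 2.0
    exclusion_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.outlier_threshold < 1:
            raise ValueError("outlier_threshold must be in (0, 1)")
        if self.max_gap_s <= 0:
            raise ValueError("max_gap_s must be positive")
        if not 0 < self.exclusion_fraction <= 1:
            raise ValueError("exclusion_fraction must be in (0, 1]")


@dataclass(frozen=True)
class HRVOptions:
    band: tuple[float, float] = (0.15, 0.40)
    window_s: float = 120.0
    shift_s: float = 60.0
    resample_hz: float = 4.0
    log_transform: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError("HRV band must be an increasing positive interval")


@dataclass(frozen=True)
class WaveletOptions:
    omega0: float = 6.0
    scales_per_octave: int = 12
    hf_band: tuple[float, float] = (0.125, 0.5)
    lf_band: tuple[float, float] = (0.031, 0.125)
    interval_s: float = 20.0
    story_min: int = 8
    discussion_min: int = 10
    coi_mask: bool = True

    def __post_init__(self) -> None:
        for band in (self.hf_band, self.lf_band):
            if not 0 < band[0] < band[1]:
                raise ValueError(f"invalid band {band}")

    def spec(self) -> WaveletSpec:
        return WaveletSpec(
            omega0=self.omega0,
            scales_per_octave=self.scales_per_octave,
            freq_min_hz=min(self.lf_band[0], self.hf_band[0]),
            freq_max_hz=max(self.lf_band[1], self.hf_band[1]),
        )


@dataclass(frozen=True)
class ModelOptions:
    screening_alpha: float = 0.05
    random_slope_time: bool = False
    ar1: bool = False


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    output_dir: str = "peersync_out"
    log_level: str = "INFO"
    cohort: simulate.CohortConfig = field(default_factory=simulate.CohortConfig)
    preprocess: PreprocessOptions = field(default_factory=PreprocessOptions)
    hrv: HRVOptions = field(default_factory=HRVOptions)
    wavelet: WaveletOptions = field(default_factory=WaveletOptions)
    models: ModelOptions = field(default_factory=ModelOptions)


def _build(cls, payload: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in payload:
            continue
        v = payload[f.name]
        if dataclasses.is_dataclass(f.type) or f.name in (
                "cohort", "preprocess", "hrv", "wavelet", "models",
                "cardiac", "coupling", "effects"):
            sub_cls = {
                "cohort": simulate.CohortConfig,
                "preprocess": PreprocessOptions,
                "hrv": HRVOptions,
                "wavelet": WaveletOptions,
                "models": ModelOptions,
                "cardiac": simulate.CardiacConfig,
                "coupling": simulate.CouplingConfig,
                "effects": simulate.EffectConfig,
            }[f.name]
            v = _build(sub_cls, v)
        elif isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    unknown = set(payload) - {f.name for f in dataclasses.fields(cls)}
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    cfg = _build(RunConfig, payload)
    # the cohort inherits the run seed unless it sets its own
    if "cohort" not in payload or "seed" not in (payload.get("cohort") or {}):
        cfg = dataclasses.replace(
            cfg, cohort=dataclasses.replace(cfg.cohort, seed=cfg.seed))
    return cfg


def _plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_plain(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    return obj


def dump_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(cfg), fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(_plain(cfg), sort_keys=True).encode()).hexdigest()[:16]
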