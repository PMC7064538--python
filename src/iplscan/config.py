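"""Analysis configuration: defaults, YAML round trip and provenance hashing.

Every tunable stage parameter lives here with its standard default (70th
percentile seeding, 1-4 µm diameters, 0.1 Hz detrending cutoff, 64 Hz target
rate, 10 depth bins per polarity, 21 Fourier frequencies over 64 taps).
Configs load from YAML with light validation — unknown keys and wrong types
are rejected — and hash to a provenance stamp carried by every output table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["AnalysisConfig", "load_config", "save_config", "config_hash"]


@dataclass
class SimSection:
    n_roi: int = 60
    n_batch: int = 4
    repeats: int = 4
    psi_sd: float = 0.15
    noise_sigma: float = 0.5
    render_movie: bool = False
    movie_n_roi: int = 30


@dataclass
class RoiSection:
    percentile: float = 70.0
    d_min_um: float = 1.0
    d_max_um: float = 4.0
    quality_min: float = 0.3


@dataclass
class PreprocessSection:
    target_rate_hz: float = 64.0
    cutoff_hz: float = 0.1
    filter_order: int = 2


@dataclass
class DepthSection:
    fallback_switch: float = 0.24
    gcl_border_depth: float = -1.1
    inl_border_depth: float = 1.9


@dataclass
class LinearSection:
    n_bins: int = 10
    depth_lo: float = -1.0
    depth_hi: float = 2.0


@dataclass
class EncodingSection:
    variants: tuple = ("depth_stretch", "depth_plus_batch", "depth_batch_interaction",
                       "per_roi_stretch", "per_roi_kernel")
    lr: float = 0.05
    n_iter: int = 1200
    patience: int = 400
    ev_tolerance: float = 0.02


@dataclass
class AnalysisConfig:
    """Top-level configuration for the pipeline and CLI."""

    seed: int = 0
    sim: SimSection = field(default_factory=SimSection)
    rois: RoiSection = field(default_factory=RoiSection)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    depth: DepthSection = field(default_factory=DepthSection)
    linear: LinearSection = field(default_factory=LinearSection)
    encoding: EncodingSection = field(default_factory=EncodingSection)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["encoding"]["variants"] = list(d["encoding"]["variants"])
        return d


_SECTIONS = {
    "sim": SimSection,
    "rois": RoiSection,
    "preprocess": PreprocessSection,
    "depth": DepthSection,
    "linear": LinearSection,
    "encoding": EncodingSection,
}


def _build_section(cls, data: dict):
    valid = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(valid)
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    coerced = {}
    for key, value in data.items():
        if key == "variants":
            coerced[key] = tuple(value)
            continue
        target = valid[key].type
        try:
            if target in ("int",) or valid[key].default.__class__ is int:
                coerced[key] = int(value)
            elif valid[key].default.__class__ is float:
                coerced[key] = float(value)
            elif valid[key].default.__class__ is bool:
                coerced[key] = bool(value)
            else:
                coerced[key] = value
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad value for {cls.__name__}.{key}: {value!r}") from exc
    return cls(**coerced)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> AnalysisConfig:
    """Load a YAML config (or defaults) with validation; apply overrides last."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data = {**data, **overrides}
    unknown = set(data) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    kwargs: dict = {}
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    for name, cls in _SECTIONS.items():
        if name in data:
            if not isinstance(data[name], dict):
                raise ConfigError(f"config section {name!r} must be a mapping")
            kwargs[name] = _build_section(cls, data[name])
    return AnalysisConfig(**kwargs)


def save_config(config: AnalysisConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return path


def config_hash(config: AnalysisConfig) -> str:
    """Short provenance hash of the canonicalized config."""
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
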