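"""Pipeline configuration: nested keys, strict validation, seed fan-out.

Configuration is a plain YAML mapping with one section per pipeline stage
(``chromatic``, ``features``, ``irelief``, ``rvm``, ``fusion``, ``fill``,
``eval``, ``synth``) plus a global ``seed`` and ``log_level``.  Unknown keys
are rejected rather than silently ignored.  CLI flags override file values.

One global seed fans out to per-stage seeds by fixed offsets so that each
stage is reproducible in isolation without any two stages sharing a stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .chromatic import ChromaticParams
from .features import FeatureConfig

log = logging.getLogger(__name__)

# fixed per-stage seed offsets from the global seed
SEED_OFFSETS = {"synth": 0, "sampling": 101, "irelief": 211, "rvm": 307}


@dataclass(frozen=True)
class IReliefSettings:
    sigma: float = 0.5
    tol: float = 1e-4
    max_iter: int = 100
    seed: int | None = None


@dataclass(frozen=True)
class RvmSettings:
    kernel_width: float = 0.5
    max_em_iter: int = 200
    prune_threshold: float = 1e9
    max_train: int = 600  # balanced-subsample cap on classifier training size
    seed: int | None = None


@dataclass(frozen=True)
class FusionSettings:
    mode: str = "and"


@dataclass(frozen=True)
class FillSettings:
    criterion: str = "boundary_mean"


@dataclass(frozen=True)
class EvalSettings:
    iou_threshold: float = 0.5


@dataclass(frozen=True)
class SynthSettings:
    height: int = 192
    width: int = 256
    n_fruit: int = 4
    radius_min: int = 18
    radius_max: int = 30
    illumination: str = "sunny"
    occlusion_fraction: float = 0.15
    noise_sd: float = 8.0
    label_majority_fraction: float = 0.5
    n_per_group: int = 200


@dataclass(frozen=True)
class PipelineConfig:
    chromatic: ChromaticParams = field(default_factory=ChromaticParams)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    irelief: IReliefSettings = field(default_factory=IReliefSettings)
    rvm: RvmSettings = field(default_factory=RvmSettings)
    fusion: FusionSettings = field(default_factory=FusionSettings)
    fill: FillSettings = field(default_factory=FillSettings)
    eval: EvalSettings = field(default_factory=EvalSettings)
    synth: SynthSettings = field(default_factory=SynthSettings)
    seed: int = 0
    log_level: str = "INFO"

    def stage_seed(self, stage: str) -> int:
        """Derive a per-stage seed from the global one by a fixed offset."""
        explicit = getattr(getattr(self, stage, None), "seed", None)
        if explicit is not None:
            return int(explicit)
        return int(self.seed) + SEED_OFFSETS.get(stage, 0)

    def to_dict(self) -> dict:
        def as_plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: as_plain(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, tuple):
                return [as_plain(v) for v in obj]
            return obj

        return as_plain(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _build_section(cls, payload: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(
            f"unknown config key(s) in section {section!r}: {sorted(unknown)}"
        )
    if cls is FeatureConfig and "offsets" in payload:
        payload = dict(payload)
        payload["offsets"] = tuple(tuple(o) for o in payload["offsets"])
    return cls(**payload)


_SECTIONS = {
    "chromatic": ChromaticParams,
    "features": FeatureConfig,
    "irelief": IReliefSettings,
    "rvm": RvmSettings,
    "fusion": FusionSettings,
    "fill": FillSettings,
    "eval": EvalSettings,
    "synth": SynthSettings,
}


def config_from_dict(payload: dict) -> PipelineConfig:
    """Build a validated config from a nested mapping; unknown keys raise."""
    payload = dict(payload or {})
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = payload.pop(name, {})
        if not isinstance(section, dict):
            raise ValueError(f"config section {name!r} must be a mapping")
        kwargs[name] = _build_section(cls, section, name)
    seed = payload.pop("seed", 0)
    log_level = payload.pop("log_level", "INFO")
    if payload:
        raise ValueError(f"unknown top-level config key(s): {sorted(payload)}")
    return PipelineConfig(seed=int(seed), log_level=str(log_level), **kwargs)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config file, or the all-defaults config when path is None."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path!s} must contain a mapping")
    return config_from_dict(raw)


def echo_config(cfg: PipelineConfig) -> None:
    """Log the effective configuration and its hash (provenance record)."""
    log.info("effective config (hash %s): %s", cfg.config_hash(), cfg.to_dict())
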