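"""Pipeline configuration: nested dataclasses loadable from YAML/JSON."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .segmentation import SegmentationParams
from .synthetic_scene import ImagingConfig, SceneConfig


@dataclass(frozen=True)
class AnalysisParams:
    alpha: float = 0.01
    test_unit: str = "plate"  # sample unit for row/column t-tests
    bonferroni: bool = False
    distance_mode: str = "perpendicular"  # {"perpendicular", "vertical"}
    loess_span: float = 0.5
    loess_degree: int = 2


@dataclass(frozen=True)
class PipelineConfig:
    scene: SceneConfig = field(default_factory=SceneConfig)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    n_plates: int = 6
    seed: int = 0

    def with_seed(self, seed: int) -> "PipelineConfig":
        scene = dataclasses.replace(self.scene, rng_seed=seed)
        return dataclasses.replace(self, seed=seed, scene=scene)


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    kwargs = dict(data)
    for key in ("axis_ratio_range",):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    if "capture_prob" in kwargs and isinstance(kwargs["capture_prob"], list):
        kwargs["capture_prob"] = np.asarray(kwargs["capture_prob"], dtype=float)
    return cls(**kwargs)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML (or JSON) file; ``None``
    returns the defaults. Raises ``ValueError`` on invalid content."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return PipelineConfig()
    if not isinstance(raw, dict):
        raise ValueError("config file must hold a mapping at top level")
    sections = {
        "scene": SceneConfig,
        "imaging": ImagingConfig,
        "segmentation": SegmentationParams,
        "analysis": AnalysisParams,
    }
    kwargs = {}
    for name, cls in sections.items():
        if name in raw:
            if not isinstance(raw[name], dict):
                raise ValueError(f"config section {name!r} must be a mapping")
            kwargs[name] = _build(cls, raw[name])
    for scalar in ("n_plates", "seed"):
        if scalar in raw:
            kwargs[scalar] = int(raw[scalar])
    unknown = set(raw) - set(sections) - {"n_plates", "seed"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    cfg = PipelineConfig(**kwargs)
    # a top-level seed overrides the scene's own seed for one-stop control
    if "seed" in raw:
        cfg = cfg.with_seed(cfg.seed)
    return cfg


def config_to_dict(cfg: PipelineConfig) -> dict:
    """JSON-serializable dict of the full configuration (for provenance)."""

    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: convert(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, tuple):
            return list(obj)
        if isinstance(obj, float) and not np.isfinite(obj):
            return str(obj)
        return obj

    return convert(cfg)


def dump_provenance(cfg: PipelineConfig, path: str | Path, version: str) -> None:
    payload = {"config": config_to_dict(cfg), "seed": cfg.seed, "version": version}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
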