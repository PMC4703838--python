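"""Run configuration: lossless YAML round trip with unknown-key rejection.

A :class:`RunConfig` gathers every module's knobs (scene, photoreaction,
segmentation, detection, classifier thresholds, analysis windows) plus the
seed and output directory, so a whole run is reproducible from one file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

from .calcium_events import DetectionConfig
from .photochemistry import PhotoreactionParams
from .response_analysis import ClassifierThresholds
from .synth_calcium import PopulationParams, TraceParams, TransientShape
from .synth_imaging import SceneParams
from .uncaging_quant import SegmentationParams
from . import io as _io

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class AnalysisWindows:
    """Frame/time windows of the two analysis chains."""

    n_pre_frames: int = 5
    n_post_frames: int = 10
    dF_post_frames: int = 3
    completeness_threshold: float = 0.05
    bin_s: float = 60.0
    pre_window_s: float = 600.0
    post_window_s: float = 600.0


@dataclass(frozen=True)
class TitrationConfig:
    """Laser levels and dose mapping of the titration simulation."""

    laser_levels: tuple[float, ...] = (1.0, 2.5, 5.0, 10.0, 25.0, 50.0)
    dose_per_percent: float = 0.12
    n_scans: int = 1


@dataclass(frozen=True)
class CalciumMixConfig:
    """Class proportions of the simulated calcium population."""

    initiated: float = 0.15
    potentiated: float = 0.25
    transient_suppression: float = 0.20
    terminated: float = 0.20
    no_change: float = 0.20
    n_cells: int = 100

    def as_mix(self) -> dict[str, float]:
        return {
            "initiated": self.initiated,
            "potentiated": self.potentiated,
            "transient_suppression": self.transient_suppression,
            "terminated": self.terminated,
            "no_change": self.no_change,
        }


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration of an end-to-end run."""

    scene: SceneParams = field(default_factory=SceneParams)
    reaction: PhotoreactionParams = field(
        default_factory=lambda: PhotoreactionParams(k_u=1.0, k_b=0.1, k_a=0.05, dose=1.0)
    )
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    population: PopulationParams = field(default_factory=PopulationParams)
    windows: AnalysisWindows = field(default_factory=AnalysisWindows)
    titration: TitrationConfig = field(default_factory=TitrationConfig)
    calcium_mix: CalciumMixConfig = field(default_factory=CalciumMixConfig)
    seed: int = 0
    out_dir: str = "uncagekit_out"
    log_level: str = "INFO"


def _to_dict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_dict(v) for v in obj]
    return obj


def _from_dict(cls: type, data: dict) -> Any:
    field_map = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(field_map)
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {name: _coerce(name, value, cls) for name, value in data.items()}
    return cls(**kwargs)


# nested dataclass types per RunConfig field (tuples restored from YAML lists)
_NESTED: dict[str, type] = {
    "scene": SceneParams,
    "reaction": PhotoreactionParams,
    "segmentation": SegmentationParams,
    "detection": DetectionConfig,
    "thresholds": ClassifierThresholds,
    "population": PopulationParams,
    "windows": AnalysisWindows,
    "titration": TitrationConfig,
    "calcium_mix": CalciumMixConfig,
    "base": TraceParams,
    "shape": TransientShape,
}


def _coerce(name: str, value: Any, parent: type) -> Any:
    if isinstance(value, dict):
        if name not in _NESTED:
            raise ValueError(f"unexpected nested section {name!r} in {parent.__name__}")
        return _from_dict(_NESTED[name], value)
    if isinstance(value, list):
        return tuple(value)
    return value


def load_config(path: str) -> RunConfig:
    """Load a RunConfig from YAML, rejecting unknown keys at every level."""
    return _from_dict(RunConfig, _io.load_yaml(path))


def save_config(path: str, config: RunConfig) -> None:
    """Serialize a RunConfig to YAML (lossless with :func:`load_config`)."""
    _io.dump_yaml(path, _to_dict(config))
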