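"""Pipeline configuration: nested blocks, strict schema, two profiles.

The ``paper`` profile carries the full-scale settings (8/7-stage 2D
localizer, 6/5-stage residual 3D segmenter, four 128x192x192 patches,
batch sizes 12/4, 1000 epochs).  The ``desk`` profile scales every problem
size down so the complete cascade trains and evaluates on a single CPU in
minutes: small phantoms, shallow narrow networks, small patches and short
schedules.  Unknown configuration keys are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "PROFILES"]


def _from_dict(cls, d: dict, path: str):
    names = {f.name for f in fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown config keys under '{path}': {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name in d:
            v = d[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


@dataclass(frozen=True)
class PreprocessBlock:
    target_spacing: tuple = (0.59, 0.46, 0.46)
    epsilon: float = 0.5  # ROI inflation factor
    augment: bool = True


@dataclass(frozen=True)
class LocnetBlock:
    encoder_stages: int = 8
    base_channels: int = 32
    max_channels: int = 320
    threshold: float = 0.5
    margin: int = 8
    batch_size: int = 12
    epochs: int = 1000
    slice_stride: int = 1  # train on every n-th slice


@dataclass(frozen=True)
class SegnetBlock:
    encoder_stages: int = 6
    base_channels: int = 32
    max_channels: int = 320
    avgpool_stages: tuple = (1, 2)
    patch_size: tuple = (128, 192, 192)
    n_patches: int = 4
    batch_size: int = 4
    epochs: int = 1000


@dataclass(frozen=True)
class TrainBlock:
    initial_lr: float = 0.01
    poly_exponent: float = 0.9
    momentum: float = 0.99
    w_bce: float = 1.0
    w_dice: float = 1.0
    deep_supervision: bool = True
    grad_clip: float = 12.0
    k_folds: int = 5


@dataclass(frozen=True)
class StenosisBlock:
    step: float = 0.25
    plane_size: int = 64
    plane_spacing: float = 0.15
    smooth_window: int = 3
    guard_mm: float = 2.0
    end_guard_mm: float = 2.0
    rvd_strategy: str = "distal_ica"


@dataclass(frozen=True)
class MetricsBlock:
    spec_on_crop: bool = True  # specificity evaluated on the ROI crop


@dataclass(frozen=True)
class PhantomBlock:
    grid_shape: tuple = (192, 352, 352)
    spacing: tuple = (0.59, 0.46, 0.46)
    segment_length: float = 50.0
    noise_sd: float = 8.0


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    profile: str = "paper"
    preprocess: PreprocessBlock = field(default_factory=PreprocessBlock)
    locnet: LocnetBlock = field(default_factory=LocnetBlock)
    segnet: SegnetBlock = field(default_factory=SegnetBlock)
    train: TrainBlock = field(default_factory=TrainBlock)
    stenosis: StenosisBlock = field(default_factory=StenosisBlock)
    metrics: MetricsBlock = field(default_factory=MetricsBlock)
    phantom: PhantomBlock = field(default_factory=PhantomBlock)

    def stage_seed(self, stage: str) -> int:
        """Fan the global seed out to a per-stage seed (re-runnable stages)."""
        offsets = {"phantom": 1, "preprocess": 2, "locnet": 3, "segnet": 4,
                   "stenosis": 5, "metrics": 6, "cohort": 7}
        return (self.seed * 101 + offsets[stage]) % (2**31 - 1)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


#: Profile presets: block-level overrides applied before user config.
PROFILES: dict[str, dict] = {
    "paper": {},
    "desk": {
        "preprocess": {"target_spacing": (1.0, 0.8, 0.8)},
        "locnet": {"encoder_stages": 4, "base_channels": 8, "max_channels": 64,
                   "batch_size": 4, "epochs": 6, "slice_stride": 3},
        "segnet": {"encoder_stages": 4, "base_channels": 8, "max_channels": 64,
                   "patch_size": (16, 16, 16), "n_patches": 2, "batch_size": 4,
                   "epochs": 24},
        "phantom": {"grid_shape": (48, 72, 72), "spacing": (1.0, 0.8, 0.8),
                    "segment_length": 16.0, "noise_sd": 8.0},
    },
}

_BLOCKS = {
    "preprocess": PreprocessBlock,
    "locnet": LocnetBlock,
    "segnet": SegnetBlock,
    "train": TrainBlock,
    "stenosis": StenosisBlock,
    "metrics": MetricsBlock,
    "phantom": PhantomBlock,
}


def build_config(profile: str = "paper", overrides: dict | None = None,
                 seed: int | None = None) -> PipelineConfig:
    """Assemble a config from a profile plus (nested) override dict."""
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    merged: dict = {k: dict(v) for k, v in PROFILES[profile].items()}
    overrides = overrides or {}
    top_unknown = set(overrides) - (set(_BLOCKS) | {"seed", "profile"})
    if top_unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(top_unknown)}")
    for k, v in overrides.items():
        if k in _BLOCKS:
            if not isinstance(v, dict):
                raise ValueError(f"config block '{k}' must be a mapping")
            merged.setdefault(k, {}).update(v)
    blocks = {name: _from_dict(cls, merged.get(name, {}), name)
              for name, cls in _BLOCKS.items()}
    if seed is None:
        seed = int(overrides.get("seed", 0))
    return PipelineConfig(seed=seed, profile=profile, **blocks)


def load_config(path=None, profile: str = "paper", seed: int | None = None) -> PipelineConfig:
    """Load a YAML config file on top of a profile's defaults."""
    overrides = {}
    if path is not None:
        with open(Path(path)) as f:
            overrides = yaml.safe_load(f) or {}
        if not isinstance(overrides, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        profile = overrides.pop("profile", profile)
    return build_config(profile=profile, overrides=overrides, seed=seed)
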