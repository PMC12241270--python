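"""Configuration dataclasses for every pipeline stage.

Each stage validates its own block; :class:`PipelineConfig` bundles them and
can be loaded from a YAML file.  Defaults follow the reference protocol
(0.5–8 Hz order-3 Butterworth, 15-s windows with 66.67 % overlap, Adam at
1e-4, batch 16, k = 5) except where a value is an artifact choice, in which
case the docstring of the owning module explains it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Tuple

import yaml


class ConfigurationError(ValueError):
    """A config block violates one of its invariants."""


@dataclass
class SimConfig:
    """Synthetic PPG study design.

    ``link_strength`` scales the planted morphology–BP coupling: at 1.0 the
    diastolic/systolic amplitude ratio and systolic width carry the full BP
    signal, at 0.0 the waveform is independent of the labels.
    """

    sampling_rate: float = 125.0
    record_duration: float = 60.0
    n_records: int = 10
    heart_rate_range: Tuple[float, float] = (55.0, 95.0)
    sbp_range: Tuple[float, float] = (90.0, 180.0)
    dbp_range: Tuple[float, float] = (55.0, 110.0)
    noise_sd: float = 0.02
    wander_amplitude: float = 0.3
    wander_freq: float = 0.25
    link_strength: float = 1.0
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.sampling_rate <= 16:
            raise ConfigurationError(
                "sampling_rate must exceed 16 Hz (twice the 8 Hz passband edge)"
            )
        for name in ("heart_rate_range", "sbp_range", "dbp_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ConfigurationError(f"{name} is empty: {(lo, hi)}")
        if not 0.0 <= self.link_strength <= 1.0:
            raise ConfigurationError("link_strength must lie in [0, 1]")
        if self.record_duration <= 0 or self.n_records < 0:
            raise ConfigurationError("record_duration and n_records must be positive")
        if self.noise_sd < 0 or self.wander_amplitude < 0:
            raise ConfigurationError("noise_sd and wander_amplitude must be >= 0")
        return self


@dataclass
class FilterSpec:
    """Butterworth band-pass specification (second-order sections)."""

    lowcut: float = 0.5
    highcut: float = 8.0
    order: int = 3
    zero_phase: bool = True

    def validate(self, sampling_rate: float) -> "FilterSpec":
        if not 0 < self.lowcut < self.highcut:
            raise ConfigurationError("need 0 < lowcut < highcut")
        if self.highcut >= sampling_rate / 2:
            raise ConfigurationError(
                f"highcut {self.highcut} Hz >= Nyquist {sampling_rate / 2} Hz"
            )
        if self.order < 1:
            raise ConfigurationError("order must be >= 1")
        return self


@dataclass
class RenderSpec:
    """Deterministic polyline rasterization parameters."""

    height: int = 224
    width: int = 224
    line_value: int = 0
    background_value: int = 255
    margin: int = 8
    line_thickness: int = 2
    channels: int = 3

    def validate(self) -> "RenderSpec":
        if self.height < 32 or self.width < 32:
            raise ConfigurationError("height and width must be >= 32")
        if self.margin >= self.height / 4:
            raise ConfigurationError("margin must be < height/4")
        if self.line_thickness < 1:
            raise ConfigurationError("line_thickness must be >= 1")
        if not (0 <= self.line_value <= 255 and 0 <= self.background_value <= 255):
            raise ConfigurationError("intensities must lie in [0, 255]")
        return self


@dataclass
class BackboneConfig:
    """Feature-extraction backbone.

    ``resnet50`` is the pretrained deep residual trunk (optional torch
    dependency); ``tiny`` is a three-block strided CNN that keeps the whole
    suite self-contained on CPU.
    """

    kind: str = "tiny"
    pretrained: bool = False
    freeze: bool = False
    token_channels: int = 32
    seed: int = 0

    def validate(self) -> "BackboneConfig":
        if self.kind not in ("resnet50", "tiny"):
            raise ConfigurationError(f"unknown backbone kind {self.kind!r}")
        if self.pretrained and self.kind != "resnet50":
            raise ConfigurationError("pretrained weights exist only for resnet50")
        expected = {"resnet50": 2048, "tiny": 32}[self.kind]
        if self.token_channels != expected:
            raise ConfigurationError(
                f"token_channels for {self.kind} must be {expected}"
            )
        return self


@dataclass
class MHCAConfig:
    """Multi-head cross-attention fusion block.

    ``attend_over='tokens'`` attends across the backbone's spatial token
    grid; ``'vector'`` uses the pooled embedding as a single token (the
    literal single-vector reading, where softmax over one key degenerates to
    a pass-through of the value).  ``fusion_mode='concat'`` concatenates the
    heads and projects with W^O; ``'head_mean'`` averages the per-head
    outputs instead.
    """

    d_model: int = 256
    n_heads: int = 4
    attend_over: str = "tokens"
    fusion_mode: str = "concat"
    seed: int = 0

    def validate(self) -> "MHCAConfig":
        if self.d_model % self.n_heads != 0:
            raise ConfigurationError("d_model must be divisible by n_heads")
        if self.attend_over not in ("tokens", "vector"):
            raise ConfigurationError("attend_over must be 'tokens' or 'vector'")
        if self.fusion_mode not in ("concat", "head_mean"):
            raise ConfigurationError("fusion_mode must be 'concat' or 'head_mean'")
        return self

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 200
    val_split: float = 0.1
    k_folds: int = 5
    early_stop_patience: int = 10
    lr_factor: float = 0.5
    lr_patience: int = 5
    loss: str = "mse"
    seed: int = 0
    split_by: str = "window"
    # > 0: return the average of the last k epochs' weights instead of the
    # best-validation checkpoint (tail averaging; stabilizes small-sample
    # runs where the validation split is too small to select epochs)
    tail_average: int = 0
    # > 0: each training window is re-rendered every epoch from a random
    # sub-span of uniform length in [1 - frac, 1] of the window — a time
    # rescaling that decorrelates beat density (heart rate) from the labels
    augment_time_crop: float = 0.0
    # models trained per fold with different seeds; predictions averaged
    # over the converged members (an undertrained restart, identified by its
    # validation loss, is dropped)
    ensemble: int = 1
    # > 0: test-time augmentation — each prediction is the mean over the
    # full window plus this many random time-crops (same crop range as
    # augment_time_crop)
    tta_crops: int = 0

    def validate(self) -> "TrainConfig":
        if not 0 < self.val_split < 1:
            raise ConfigurationError("val_split must lie in (0, 1)")
        if self.k_folds < 2:
            raise ConfigurationError("k_folds must be >= 2")
        if self.early_stop_patience < 1 or self.lr_patience < 1:
            raise ConfigurationError("patience values must be >= 1")
        if self.split_by not in ("window", "subject"):
            raise ConfigurationError("split_by must be 'window' or 'subject'")
        if not 0 <= self.augment_time_crop < 1 or self.ensemble < 1 or self.tail_average < 0:
            raise ConfigurationError(
                "need 0 <= augment_time_crop < 1, ensemble >= 1, tail_average >= 0"
            )
        if self.loss != "mse":
            raise ConfigurationError("only the 'mse' loss is supported")
        return self


@dataclass
class EvalConfig:
    n_boot: int = 1000
    alpha: float = 0.05
    loa_multiplier: float = 1.96
    seed: int = 0

    def validate(self) -> "EvalConfig":
        if self.n_boot < 1 or not 0 < self.alpha < 1:
            raise ConfigurationError("need n_boot >= 1 and alpha in (0, 1)")
        return self


@dataclass
class PipelineConfig:
    """All stage blocks plus the global seed and segmentation settings."""

    sim: SimConfig = field(default_factory=SimConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    render: RenderSpec = field(default_factory=RenderSpec)
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    fusion: MHCAConfig = field(default_factory=MHCAConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    evaluate: EvalConfig = field(default_factory=EvalConfig)
    window_s: float = 15.0
    overlap_frac: float = 2.0 / 3.0
    seed: int = 0
    out_dir: str = "runs/default"

    def validate(self) -> "PipelineConfig":
        self.sim.validate()
        self.filter.validate(self.sim.sampling_rate)
        self.render.validate()
        self.backbone.validate()
        self.fusion.validate()
        self.train.validate()
        self.evaluate.validate()
        return self

    def reseed(self, seed: int) -> "PipelineConfig":
        """Derive all block seeds from one global seed."""
        self.seed = seed
        for block, off in (
            (self.sim, 1),
            (self.backbone, 2),
            (self.fusion, 3),
            (self.train, 4),
            (self.evaluate, 5),
        ):
            block.seed = (seed * 7919 + off) % (2**31 - 1)
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw = {}
        blocks = {
            "sim": SimConfig,
            "filter": FilterSpec,
            "render": RenderSpec,
            "backbone": BackboneConfig,
            "fusion": MHCAConfig,
            "train": TrainConfig,
            "evaluate": EvalConfig,
        }
        for key, val in d.items():
            if key in blocks:
                block = blocks[key](**val)
                # YAML lists come back as lists; dataclass fields expect tuples
                for f in ("heart_rate_range", "sbp_range", "dbp_range"):
                    if hasattr(block, f):
                        setattr(block, f, tuple(getattr(block, f)))
                kw[key] = block
            else:
                kw[key] = val
        return cls(**kw).validate()

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def derive_seed(seed: int, *offsets: int) -> int:
    """Deterministically derive a sub-seed below 2**31."""
    h = hashlib.sha256(repr((seed,) + offsets).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


__all__ = [
    "ConfigurationError",
    "SimConfig",
    "FilterSpec",
    "RenderSpec",
    "BackboneConfig",
    "MHCAConfig",
    "TrainConfig",
    "EvalConfig",
    "PipelineConfig",
    "derive_seed",
]
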