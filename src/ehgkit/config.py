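"""Pipeline configuration: one YAML document driving every stage.

Groups the band-pass filter, wavelet, sample-entropy, network and split
settings so a run is fully described by (config, seed).  Values default to
the study conditions: 0.1-3 Hz order-4 Butterworth, db1 at 3 levels,
SampEn(m=2, r=0.15*SD), 64->30->10->2 network with rho=0.05, beta=8,
lambda=0.001, and a 100-train / 50-test per-class split.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import yaml

from .autoencoder import SAEHyperParams
from .complexity import SampEnParams
from .preprocess import FilterSpec
from .wavelet import WaveletSpec

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    fs: float = 200.0
    n_points: int = 4096
    n_channels: int = 16
    # band-pass
    filter_low_hz: float = 0.1
    filter_high_hz: float = 3.0
    filter_order: int = 4
    filter_zero_phase: bool = True
    # wavelet
    wavelet: str = "db1"
    levels: int = 3
    boundary: str = "periodization"
    use_reconstructed_bands: bool = False
    # sample entropy
    sampen_m: int = 2
    sampen_r: float = 0.15
    sampen_relative_r: bool = True
    # SSAE
    hidden_sizes: Tuple[int, ...] = (30, 10)
    rho: float = 0.05
    beta: float = 8.0
    lambda_: float = 0.001
    pretrain_lr: float = 0.1
    pretrain_epochs: int = 400
    fine_tune_lr: float = 0.5
    fine_tune_epochs: int = 200
    # baselines
    elm_hidden: int = 20
    # split
    n_train_per_class: int = 100
    n_test_per_class: int = 50
    normalization: str = "train"  # or "global"
    # seeds
    seed: int = 0

    # --- derived spec objects ----------------------------------------
    def filter_spec(self) -> FilterSpec:
        return FilterSpec(
            low_hz=self.filter_low_hz,
            high_hz=self.filter_high_hz,
            order=self.filter_order,
            zero_phase=self.filter_zero_phase,
        )

    def wavelet_spec(self) -> WaveletSpec:
        return WaveletSpec(name=self.wavelet, levels=self.levels, boundary=self.boundary)

    def sampen_params(self) -> SampEnParams:
        return SampEnParams(
            m=self.sampen_m, r=self.sampen_r, relative_r=self.sampen_relative_r
        )

    def sae_hyper(self) -> SAEHyperParams:
        return SAEHyperParams(
            rho=self.rho,
            beta=self.beta,
            lambda_=self.lambda_,
            epsilon=self.pretrain_lr,
            epochs=self.pretrain_epochs,
        )

    def validate(self) -> None:
        """Run every sub-spec constructor so bad values fail before any work."""
        self.filter_spec()
        if self.filter_high_hz >= self.fs / 2:
            raise ValueError("filter_high_hz must be below Nyquist")
        self.wavelet_spec()
        self.sampen_params()
        self.sae_hyper()
        if self.n_points % (2**self.levels) != 0:
            raise ValueError("n_points must be divisible by 2**levels")
        if self.normalization not in ("train", "global"):
            raise ValueError("normalization must be 'train' or 'global'")

    # --- serialization ------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["hidden_sizes"] = list(self.hidden_sizes)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "hidden_sizes" in d:
            d["hidden_sizes"] = tuple(d["hidden_sizes"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        d = asdict(self)
        d["hidden_sizes"] = list(self.hidden_sizes)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]
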