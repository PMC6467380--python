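"""Subband sample-entropy feature vectors and [0,1] feature normalization.

Each channel of a segment is decomposed with a 3-level Haar transform and the
sample entropy of cD1, cD2, cD3 and cA3 is computed, giving 4 features per
channel (64 for the 16-channel default).  Ordering is channel-major and
fixed: for each channel, [SampEn(cD1), SampEn(cD2), SampEn(cD3), SampEn(cA3)].

Feature tables are min-max scaled to [0,1].  The scaling state is learned on
the training split only and then applied (with clipping) to held-out data to
avoid leakage; a ``global`` mode that fits on the full table is also offered.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .complexity import SampEnParams, sample_entropy
from .preprocess import Segment
from .wavelet import WaveletSpec, wavedec, waverec, WaveletDecomposition

logger = logging.getLogger(__name__)

__all__ = [
    "SUBBAND_NAMES",
    "FeatureVector",
    "FeatureTable",
    "Normalizer",
    "extract_features",
    "build_feature_table",
    "fit_normalizer",
    "apply_normalizer",
]

SUBBAND_NAMES = ("cD1", "cD2", "cD3", "cA3")


def feature_names(n_channels: int, levels: int = 3) -> List[str]:
    names = []
    subbands = [f"cD{j}" for j in range(1, levels + 1)] + [f"cA{levels}"]
    for c in range(1, n_channels + 1):
        names.extend(f"ch{c}_{s}" for s in subbands)
    return names


@dataclass
class FeatureVector:
    """One segment's entropy features in fixed channel-major order."""

    values: np.ndarray
    names: List[str]
    label: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size != len(self.names):
            raise ValueError("feature values/names length mismatch")


def _reconstruct_band(dec: WaveletDecomposition, which: str) -> np.ndarray:
    """Time-domain band signal D_j(n) or A_J(n) from one coefficient set."""
    zeroed = WaveletDecomposition(
        cA=np.zeros_like(dec.cA) if which.startswith("cD") else dec.cA.copy(),
        cD=[
            d.copy() if which == f"cD{j + 1}" else np.zeros_like(d)
            for j, d in enumerate(dec.cD)
        ],
        spec=dec.spec,
        n_original=dec.n_original,
    )
    return waverec(zeroed)


def extract_features(
    seg: Segment,
    wspec: WaveletSpec = WaveletSpec(),
    params: SampEnParams = SampEnParams(),
    use_reconstructed_bands: bool = False,
    sentinel_cap: Optional[float] = None,
) -> FeatureVector:
    """Compute the subband-entropy feature vector for one segment.

    By default the entropies are taken over the raw wavelet coefficients;
    ``use_reconstructed_bands`` switches to the time-domain band signals
    D_j(n), A_J(n) instead.  Undefined entropies (no template matches) are
    replaced by ``sentinel_cap``, defaulting to the largest finite entropy
    in the vector, so downstream classifiers always see finite inputs.
    """
    values: List[float] = []
    for ch in range(seg.n_channels):
        dec = wavedec(seg.data[ch], wspec)
        for name, coeffs in dec.subbands():
            series = _reconstruct_band(dec, name) if use_reconstructed_bands else coeffs
            values.append(sample_entropy(series, params))
    arr = np.asarray(values, dtype=np.float64)
    infinite = ~np.isfinite(arr)
    if infinite.any():
        cap = sentinel_cap
        if cap is None:
            finite = arr[np.isfinite(arr)]
            cap = float(finite.max()) if finite.size else 0.0
        logger.warning(
            "replaced %d undefined entropies with cap %.4g", int(infinite.sum()), cap
        )
        arr[infinite] = cap
    return FeatureVector(
        values=arr, names=feature_names(seg.n_channels, wspec.levels), label=seg.label
    )


@dataclass
class FeatureTable:
    """n_samples x n_features matrix with labels and feature names."""

    X: np.ndarray
    labels: List[str]
    names: List[str]

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float64))
        if self.X.shape[0] != len(self.labels):
            raise ValueError("row count does not match number of labels")
        if self.X.shape[1] != len(self.names):
            raise ValueError("column count does not match number of feature names")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def y(self, positive: str = "labor") -> np.ndarray:
        """Integer labels with the positive class (labor) mapped to 1."""
        return np.array([1 if lab == positive else 0 for lab in self.labels])

    def subset(self, idx: Sequence[int]) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            X=self.X[idx], labels=[self.labels[i] for i in idx], names=list(self.names)
        )

    def to_csv(self, path) -> None:
        frame = pd.DataFrame(self.X, columns=self.names)
        frame["label"] = self.labels
        frame.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        frame = pd.read_csv(path, float_precision="round_trip")
        if "label" not in frame.columns:
            raise ValueError(f"{path}: feature CSV must contain a 'label' column")
        labels = frame.pop("label").tolist()
        return cls(X=frame.to_numpy(dtype=np.float64), labels=labels, names=list(frame.columns))


def build_feature_table(
    segments: Sequence[Segment],
    wspec: WaveletSpec = WaveletSpec(),
    params: SampEnParams = SampEnParams(),
    **kwargs,
) -> FeatureTable:
    """Feature-extract a list of segments into one table."""
    if not segments:
        raise ValueError("no segments supplied")
    vectors = [extract_features(s, wspec, params, **kwargs) for s in segments]
    return FeatureTable(
        X=np.vstack([v.values for v in vectors]),
        labels=[v.label for v in vectors],
        names=vectors[0].names,
    )


@dataclass
class Normalizer:
    """Per-feature min-max state mapping learned ranges onto [0,1]."""

    minimum: np.ndarray
    maximum: np.ndarray

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {"minimum": self.minimum.tolist(), "maximum": self.maximum.tolist()}
            )
        )

    @classmethod
    def from_json(cls, path) -> "Normalizer":
        d = json.loads(Path(path).read_text())
        return cls(
            minimum=np.asarray(d["minimum"], dtype=np.float64),
            maximum=np.asarray(d["maximum"], dtype=np.float64),
        )


def fit_normalizer(table: FeatureTable) -> Normalizer:
    """Learn per-feature min/max (on the training split only, normally)."""
    if table.n_samples == 0:
        raise ValueError("cannot fit a normalizer on an empty table")
    return Normalizer(
        minimum=table.X.min(axis=0), maximum=table.X.max(axis=0)
    )


def apply_normalizer(table: FeatureTable, state: Normalizer) -> FeatureTable:
    """Scale to [0,1] with the learned state; out-of-range values clip.

    Features that were constant during fitting (max == min) map to 0.
    """
    span = state.maximum - state.minimum
    safe_span = np.where(span > 0, span, 1.0)
    scaled = (table.X - state.minimum) / safe_span
    scaled = np.where(span > 0, scaled, 0.0)
    scaled = np.clip(scaled, 0.0, 1.0)
    return FeatureTable(X=scaled, labels=list(table.labels), names=list(table.names))
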