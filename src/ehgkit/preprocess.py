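"""Loading, band-pass filtering and segmentation of multichannel EHG records.

Uterine electrical activity of interest lies between 0.1 and 3 Hz; recordings
are band-pass filtered with a Butterworth filter before analysis.  Fixed-length
analysis windows (4096 samples at 200 Hz by default) are cut at explicit start
indices; an RMS-based heuristic can propose burst locations when no manual
annotation is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "PREGNANCY",
    "LABOR",
    "EHGRecord",
    "Segment",
    "FilterSpec",
    "load_record",
    "bandpass_filter",
    "extract_segments",
    "suggest_burst_starts",
    "save_segments",
    "load_segments",
]

PREGNANCY = "pregnancy"
LABOR = "labor"
UNKNOWN = "unknown"
_LABELS = (PREGNANCY, LABOR, UNKNOWN)


@dataclass
class EHGRecord:
    """Multichannel uterine-EMG time series.

    ``data`` is channels x samples (float64); ``fs`` the sampling frequency
    in Hz.  The class label is ``"pregnancy"``, ``"labor"`` or ``"unknown"``.
    """

    data: np.ndarray
    fs: float
    channel_names: List[str] = field(default_factory=list)
    label: str = UNKNOWN
    source_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if self.data.shape[0] < 1:
            raise ValueError("record needs at least one channel")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("record contains NaN/Inf samples")
        if self.label not in _LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Segment:
    """One fixed-length analysis window (channels x n_points) with a label."""

    data: np.ndarray
    label: str
    origin: Tuple[str, int] = ("", 0)
    fs: float = 200.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.label not in (PREGNANCY, LABOR):
            raise ValueError(f"segment label must be pregnancy or labor, got {self.label!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("segment contains NaN/Inf samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_points(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification (default 0.1-3 Hz, order 4)."""

    low_hz: float = 0.1
    high_hz: float = 3.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("need 0 < low_hz < high_hz")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")

    def validate_against(self, fs: float) -> None:
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"high_hz={self.high_hz} must be below the Nyquist frequency {fs / 2}"
            )


def load_record(
    path,
    format: str = "csv",
    fs: float = 200.0,
    label: str = UNKNOWN,
    source_id: Optional[str] = None,
) -> EHGRecord:
    """Read a multichannel record from disk.

    ``csv``: one column per channel, no header, amplitudes only; ``fs`` comes
    from the caller/config.  ``wfdb``: PhysioNet header+signal convention via
    the optional :mod:`wfdb` package (sampling rate taken from the header).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        try:
            frame = pd.read_csv(
                path, header=None, dtype=np.float64, float_precision="round_trip"
            )
        except (ValueError, pd.errors.ParserError) as exc:
            raise ValueError(f"could not parse {path} as a numeric CSV: {exc}") from exc
        if frame.isna().any().any():
            raise ValueError(f"{path}: ragged or non-numeric columns (NaN after parse)")
        data = frame.to_numpy().T  # columns are channels
        return EHGRecord(
            data=data, fs=fs, label=label, source_id=source_id or path.stem
        )
    if format == "wfdb":
        try:
            import wfdb  # optional adapter; not needed for CSV workflows
        except ImportError as exc:
            raise ImportError(
                "WFDB support requires the optional 'wfdb' package "
                "(pip install wfdb); CSV loading needs no extra dependency"
            ) from exc
        rec = wfdb.rdrecord(str(path.with_suffix("")))
        return EHGRecord(
            data=rec.p_signal.T,
            fs=float(rec.fs),
            channel_names=list(rec.sig_name),
            label=label,
            source_id=source_id or path.stem,
        )
    raise ValueError(f"unknown format {format!r}; expected 'csv' or 'wfdb'")


def bandpass_filter(record: EHGRecord, spec: FilterSpec = FilterSpec()) -> EHGRecord:
    """Band-pass each channel independently; zero-phase by default.

    Forward-backward (``sosfiltfilt``) application removes phase distortion
    that would otherwise leak into the entropy features; set
    ``spec.zero_phase=False`` for a causal single pass.
    """
    spec.validate_against(record.fs)
    sos = sps.butter(
        spec.order,
        [spec.low_hz, spec.high_hz],
        btype="bandpass",
        fs=record.fs,
        output="sos",
    )
    if spec.zero_phase:
        filtered = sps.sosfiltfilt(sos, record.data, axis=1)
    else:
        filtered = sps.sosfilt(sos, record.data, axis=1)
    return EHGRecord(
        data=filtered,
        fs=record.fs,
        channel_names=list(record.channel_names),
        label=record.label,
        source_id=record.source_id,
    )


def extract_segments(
    record: EHGRecord, starts: Sequence[int], n_points: int = 4096
) -> List[Segment]:
    """Cut labelled windows of ``n_points`` samples at the given starts."""
    if record.label not in (PREGNANCY, LABOR):
        raise ValueError("record label must be set to pregnancy or labor before segmentation")
    segments = []
    for start in starts:
        start = int(start)
        if start < 0 or start + n_points > record.n_samples:
            raise IndexError(
                f"segment [{start}, {start + n_points}) out of range for "
                f"record of length {record.n_samples}"
            )
        segments.append(
            Segment(
                data=record.data[:, start : start + n_points].copy(),
                label=record.label,
                origin=(record.source_id, start),
                fs=record.fs,
            )
        )
    return segments


def suggest_burst_starts(
    record: EHGRecord, n_points: int = 4096, threshold_factor: float = 1.5
) -> List[int]:
    """Propose non-overlapping window starts over high-activity bursts.

    Candidate windows (hop = n_points / 4) are scored by RMS pooled across
    channels; windows exceeding ``threshold_factor`` times the median window
    RMS are accepted greedily in order of decreasing RMS, skipping overlaps,
    so one strong burst yields one suggestion.  Returned starts are sorted
    ascending.  A stand-in for tocogram-guided manual burst annotation.
    """
    n = record.n_samples
    if n < n_points:
        return []
    if threshold_factor == 0:  # degenerate: every window qualifies
        return [int(s) for s in range(0, n - n_points + 1, n_points)]
    hop = max(1, n_points // 4)
    starts = np.arange(0, n - n_points + 1, hop)
    rms = np.array(
        [float(np.sqrt(np.mean(record.data[:, s : s + n_points] ** 2))) for s in starts]
    )
    threshold = threshold_factor * float(np.median(rms))
    accepted: List[int] = []
    for i in np.argsort(-rms, kind="stable"):
        s, v = int(starts[i]), rms[i]
        if v <= threshold:
            break  # remaining candidates are all below threshold
        if all(abs(s - a) >= n_points for a in accepted):
            accepted.append(s)
    return sorted(accepted)


def save_segments(segments: Sequence[Segment], out_dir) -> Path:
    """Write one CSV per segment (samples x channels) plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, seg in enumerate(segments):
        name = f"segment_{i:04d}.csv"
        # %.17g guarantees float64 round-trips bitwise through text
        np.savetxt(out_dir / name, seg.data.T, delimiter=",", fmt="%.17g")
        entries.append(
            {
                "file": name,
                "label": seg.label,
                "source_id": seg.origin[0],
                "start": int(seg.origin[1]),
                "fs": seg.fs,
                "n_channels": seg.n_channels,
                "n_points": seg.n_points,
            }
        )
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps({"segments": entries}, indent=1))
    return manifest


def load_segments(manifest_path) -> List[Segment]:
    """Inverse of :func:`save_segments`."""
    manifest_path = Path(manifest_path)
    meta = json.loads(manifest_path.read_text())
    segments = []
    for entry in meta["segments"]:
        data = np.loadtxt(manifest_path.parent / entry["file"], delimiter=",", ndmin=2).T
        segments.append(
            Segment(
                data=data,
                label=entry["label"],
                origin=(entry["source_id"], entry["start"]),
                fs=entry["fs"],
            )
        )
    return segments
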