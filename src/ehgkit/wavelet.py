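"""Multilevel discrete wavelet transform with the db1 (Haar) wavelet.

The electrohysterogram feature pipeline decomposes each 200 Hz channel into
three dyadic subbands and computes sample entropy of the coefficient vectors.
Only the 2-tap Daubechies-1 (Haar) wavelet is supported: its analysis filters
are the orthonormal sum/difference pair

    cA_k = (x_{2k} + x_{2k+1}) / sqrt(2)
    cD_k = (x_{2k} - x_{2k+1}) / sqrt(2)

which conserves energy exactly and admits perfect reconstruction.  Each
decomposition level halves the effective sampling rate, so level-j detail
coefficients nominally cover the band [fs/2^{j+1}, fs/2^j] Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

_SQRT2 = np.sqrt(2.0)

__all__ = [
    "WaveletSpec",
    "WaveletDecomposition",
    "dwt_step",
    "idwt_step",
    "wavedec",
    "waverec",
    "band_ranges",
]


@dataclass(frozen=True)
class WaveletSpec:
    """Wavelet family, decomposition depth and boundary handling.

    Parameters
    ----------
    name : str
        Wavelet name; only ``"db1"`` (Haar) is implemented.
    levels : int
        Number of decomposition levels J >= 1.
    boundary : str
        ``"periodization"`` (default; requires the signal length to be
        divisible by 2**J) or ``"zero-pad"`` (odd-length approximation
        branches are padded with a trailing zero at each level).
    """

    name: str = "db1"
    levels: int = 3
    boundary: str = "periodization"

    def __post_init__(self) -> None:
        if self.name != "db1":
            raise ValueError(f"only the db1 (Haar) wavelet is supported, got {self.name!r}")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.boundary not in ("periodization", "zero-pad"):
            raise ValueError(f"unknown boundary mode {self.boundary!r}")


@dataclass
class WaveletDecomposition:
    """Coefficients of a J-level Haar decomposition of one scalar series.

    ``cD[j-1]`` holds the level-j detail coefficients; ``cA`` the level-J
    approximation.  ``n_original`` is kept so zero-padded transforms can be
    inverted to the exact input length.
    """

    cA: np.ndarray
    cD: List[np.ndarray]  # cD[0] is level 1 (finest), cD[-1] is level J
    spec: WaveletSpec
    n_original: int

    @property
    def levels(self) -> int:
        return len(self.cD)

    def subbands(self) -> List[Tuple[str, np.ndarray]]:
        """Named coefficient vectors in feature order: cD1..cDJ then cAJ."""
        out = [(f"cD{j + 1}", c) for j, c in enumerate(self.cD)]
        out.append((f"cA{self.levels}", self.cA))
        return out

    def energy(self) -> float:
        return float(sum(np.sum(c**2) for c in self.cD) + np.sum(self.cA**2))


def dwt_step(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """One level of orthonormal Haar analysis.

    Returns ``(cA, cD)`` of half length.  The input length must be even;
    callers handle padding for odd lengths.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("dwt_step expects a 1-D array")
    if x.size % 2 != 0:
        raise ValueError(f"dwt_step requires even length, got {x.size}")
    even = x[0::2]
    odd = x[1::2]
    cA = (even + odd) / _SQRT2
    cD = (even - odd) / _SQRT2
    return cA, cD


def idwt_step(cA: np.ndarray, cD: np.ndarray) -> np.ndarray:
    """Inverse of :func:`dwt_step` (exact, orthonormal synthesis)."""
    cA = np.asarray(cA, dtype=np.float64)
    cD = np.asarray(cD, dtype=np.float64)
    if cA.shape != cD.shape:
        raise ValueError(f"coefficient length mismatch: {cA.shape} vs {cD.shape}")
    x = np.empty(2 * cA.size, dtype=np.float64)
    x[0::2] = (cA + cD) / _SQRT2
    x[1::2] = (cA - cD) / _SQRT2
    return x


def wavedec(x: Sequence[float], spec: WaveletSpec = WaveletSpec()) -> WaveletDecomposition:
    """Recursive J-level Haar decomposition of the approximation branch."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("wavedec expects a 1-D array")
    n = x.size
    if n < 2**spec.levels:
        raise ValueError(f"signal length {n} too short for {spec.levels} levels")
    if spec.boundary == "periodization" and n % (2**spec.levels) != 0:
        raise ValueError(
            f"periodization requires length divisible by 2^{spec.levels}, got {n}"
        )
    approx = x
    details: List[np.ndarray] = []
    for _ in range(spec.levels):
        if approx.size % 2 != 0:  # only reachable in zero-pad mode
            approx = np.append(approx, 0.0)
        approx, d = dwt_step(approx)
        details.append(d)
    return WaveletDecomposition(cA=approx, cD=details, spec=spec, n_original=n)


def waverec(d: WaveletDecomposition) -> np.ndarray:
    """Invert :func:`wavedec`; exact to floating-point rounding."""
    approx = np.asarray(d.cA, dtype=np.float64)
    for detail in reversed(d.cD):
        detail = np.asarray(detail, dtype=np.float64)
        if d.spec.boundary == "zero-pad" and approx.size == detail.size + 1:
            approx = approx[:-1]  # drop the zero pad introduced at this level
        if approx.size != detail.size:
            raise ValueError(
                f"inconsistent coefficient lengths: cA-branch {approx.size}, cD {detail.size}"
            )
        approx = idwt_step(approx, detail)
    return approx[: d.n_original]


def band_ranges(spec: WaveletSpec, fs: float) -> List[Tuple[str, float, float]]:
    """Nominal frequency band of each component, finest detail first.

    Level-j details cover [fs/2^{j+1}, fs/2^j]; the level-J approximation
    covers [0, fs/2^{J+1}].  Returns ``(name, low_hz, high_hz)`` tuples in
    the order D1..DJ, AJ.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    bands = [
        (f"D{j}", fs / 2 ** (j + 1), fs / 2**j) for j in range(1, spec.levels + 1)
    ]
    bands.append((f"A{spec.levels}", 0.0, fs / 2 ** (spec.levels + 1)))
    return bands
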