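"""Sample entropy (SampEn) of a scalar time series.

SampEn(m, r, N) = -ln(B^{m+1}(r) / B^m(r)) where B^m counts ordered template
pairs (i != j) of length m whose Chebyshev distance is <= r, and B^{m+1}
counts the same over length-(m+1) templates.  Both counts run over the first
N - m template vectors so the ratio is the conditional probability that
sequences matching for m points also match for m + 1 points (the
Richman-Moorman convention); self-matches are excluded.  Larger values mean
a more irregular series.

The tolerance r is interpreted in absolute amplitude units, or as a multiple
of the series standard deviation when ``relative_r`` is set (the prevailing
convention in the EHG-entropy literature, default r = 0.15 * SD).

Two interchangeable implementations are provided:

* :func:`sample_entropy` — production path; a numba-compiled counting loop
  when numba is importable, otherwise a vectorised numpy fallback.  Both
  produce identical integer match counts.
* :func:`sample_entropy_oracle` — the literal O(N^2 m) double loop, kept
  deliberately unoptimised as an independent reference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["SampEnParams", "sample_entropy", "sample_entropy_oracle"]


@dataclass(frozen=True)
class SampEnParams:
    """Embedding dimension m, tolerance r, and how r is interpreted."""

    m: int = 2
    r: float = 0.15
    relative_r: bool = True

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r <= 0:
            raise ValueError("tolerance r must be > 0")

    def resolve_r(self, x: np.ndarray) -> float:
        """Absolute tolerance for a concrete series."""
        if not self.relative_r:
            return float(self.r)
        return float(self.r * np.std(x))


def _counts_numpy(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Ordered-pair match counts (B^m, B^{m+1}) via boolean recurrence.

    within[i, j] tells whether |x_i - x_j| <= r; a length-m template match is
    the AND of m diagonal shifts of that matrix.
    """
    n = x.size
    nt = n - m  # number of templates, shared by both lengths
    within = np.abs(x[:, None] - x[None, :]) <= r
    match = within[:nt, :nt].copy()
    for k in range(1, m):
        match &= within[k : k + nt, k : k + nt]
    b_m = int(match.sum()) - nt  # remove self-matches on the diagonal
    match &= within[m : m + nt, m : m + nt]
    b_m1 = int(match.sum()) - nt
    return b_m, b_m1


try:  # pragma: no cover - exercised implicitly when numba is installed
    from numba import njit

    @njit(cache=True)
    def _counts_numba(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
        n = x.size
        nt = n - m
        b_m = 0
        b_m1 = 0
        for i in range(nt):
            for j in range(i + 1, nt):
                ok = True
                for k in range(m):
                    if abs(x[i + k] - x[j + k]) > r:
                        ok = False
                        break
                if ok:
                    b_m += 1
                    if abs(x[i + m] - x[j + m]) <= r:
                        b_m1 += 1
        return 2 * b_m, 2 * b_m1  # ordered pairs

    _counts = _counts_numba
except ImportError:  # pragma: no cover
    _counts = _counts_numpy


def sample_entropy(x: np.ndarray, p: SampEnParams = SampEnParams()) -> float:
    """SampEn in nats; ``inf`` (with a warning) when no templates match.

    A constant series returns exactly 0.0: every template matches every
    other at both lengths, so the conditional probability is 1.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("sample_entropy expects a 1-D array")
    n = x.size
    if n <= p.m + 1:
        raise ValueError(f"need N > m + 1 = {p.m + 1}, got N = {n}")
    r_abs = p.resolve_r(x)
    if r_abs == 0.0:  # zero-variance series in relative mode
        return 0.0
    b_m, b_m1 = _counts(x, p.m, r_abs)
    if b_m == 0 or b_m1 == 0:
        warnings.warn(
            f"sample entropy undefined (B^m={b_m}, B^(m+1)={b_m1}); returning inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.inf
    return -math.log(b_m1 / b_m)


def sample_entropy_oracle(x: np.ndarray, p: SampEnParams = SampEnParams()) -> float:
    """Brute-force reference: explicit double loop over all template pairs."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("sample_entropy_oracle expects a 1-D array")
    n = x.size
    if n <= p.m + 1:
        raise ValueError(f"need N > m + 1 = {p.m + 1}, got N = {n}")
    r_abs = p.resolve_r(x)
    if r_abs == 0.0:
        return 0.0
    m = p.m
    nt = n - m
    b_m = 0
    b_m1 = 0
    for i in range(nt):
        for j in range(nt):
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r_abs:
                b_m += 1
                if abs(x[i + m] - x[j + m]) <= r_abs:
                    b_m1 += 1
    if b_m == 0 or b_m1 == 0:
        warnings.warn(
            "sample entropy undefined in oracle; returning inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.inf
    return -math.log(b_m1 / b_m)
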