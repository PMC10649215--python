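"""Single-parameter least-squares parabolic fitting over a sliding window.

For each sample ``(n, y(n))`` of an ECG record, a parabola anchored at that
sample, ``y'(i) = a (n - i)^2 + y(n)``, is fitted over the symmetric window
``i = n-w .. n+w``.  The coefficient is chosen so the fit residuals sum to
zero across the window (a moment-matching fit; equivalently the
``1/(n-i)^2``-weighted least-squares solution), which gives the closed form

    a = C * ( -L * y(n) + sum_{i=n-w}^{n+w} y(i) ),   C = 1 / sum_k k^2,

where ``L = 2w + 1`` is the window length.  This costs only ``L + 1``
additions and 2 multiplications per sample — no divisions — and recovers
the exact coefficient whenever the data really are a parabola through
``(n, y(n))``.  The *parabolic height*
``H = |a| * w^2`` — the vertical span of the fitted parabola across the
window — is the sole feature the R-peak detector thresholds.  Because the
coefficient depends on the signal only through ``-L*y(n) + sum y(i)``, any
additive constant (the isoelectric-line level) cancels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class SignalTooShortError(ValueError):
    """Record has fewer samples than the fitting window length."""


@dataclass(frozen=True)
class SignalRecord:
    """A sampled single-channel ECG in physical units.

    Parameters
    ----------
    samples : array-like of float
        Amplitudes, typically millivolts (WFDB gain already applied).
    fs : float
        Sampling frequency in Hz, > 0.
    record_id : str
        Free-text label used in tables and logs.
    """

    samples: np.ndarray
    fs: float
    record_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples must all be finite")
        if not (self.fs > 0):
            raise ValueError(f"fs must be positive, got {self.fs}")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs


@dataclass(frozen=True)
class FitConfig:
    """Window geometry and precomputed normalization for the parabola fit.

    ``L = 2w + 1`` and ``C = 1 / sum_{k=-w..w} k^2 = 3 / (w (w+1) L)``.
    """

    w: int
    L: int = field(init=False)
    C: float = field(init=False)

    def __post_init__(self) -> None:
        if not isinstance(self.w, (int, np.integer)) or isinstance(self.w, bool):
            raise ValueError(f"half-width w must be an integer, got {self.w!r}")
        if self.w < 1:
            raise ValueError(f"half-width w must be >= 1, got {self.w}")
        w = int(self.w)
        L = 2 * w + 1
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "L", L)
        object.__setattr__(self, "C", 3.0 / (w * (w + 1) * L))

    @classmethod
    def from_window_length(cls, L: int) -> "FitConfig":
        """Build from an odd window length ``L`` (the tables quote L, not w)."""
        if L < 3 or L % 2 == 0:
            raise ValueError(f"window length L must be odd and >= 3, got {L}")
        return cls(w=(L - 1) // 2)


def window_constant(w: int) -> FitConfig:
    """Return the fit configuration (L, C) for half-width ``w``.

    ``C`` equals the reciprocal of the direct sum of squared offsets
    ``sum_{k=-w..w} k^2``; the closed form avoids the summation.
    """
    return FitConfig(w=w)


@dataclass(frozen=True)
class HeightSeries:
    """Per-sample parabolic height and curvature sign for a record.

    ``H[n] >= 0`` everywhere and ``H[n] = 0`` for the first and last ``w``
    samples, where the window does not fit; ``a_sign`` is -1 for an upward
    peak (negative coefficient), +1 for downward, 0 for flat.
    """

    H: np.ndarray
    a_sign: np.ndarray
    w: int

    @property
    def valid_range(self) -> tuple[int, int]:
        """Inclusive 0-based index range where the fit window is complete."""
        return (self.w, self.H.size - 1 - self.w)


def fit_coefficient(record: SignalRecord, n: int, cfg: FitConfig) -> float:
    """Coefficient ``a`` of the parabola anchored at sample ``n``.

    The fit zeroes the summed residual over the window (moment matching),
    so ``a = C * (-L y(n) + sum y(i))``.  Negative ``a`` means an upward
    peak, positive a downward one.

    Raises
    ------
    IndexError
        If the window ``[n-w, n+w]`` is not fully inside the record.
    """
    y = record.samples
    w = cfg.w
    if n < w or n > y.size - 1 - w:
        raise IndexError(
            f"center {n} outside valid range [{w}, {y.size - 1 - w}] for w={w}"
        )
    window_sum = float(np.sum(y[n - w : n + w + 1]))
    return cfg.C * (-cfg.L * float(y[n]) + window_sum)


def parabolic_height(a: float, w: int) -> float:
    """Vertical span ``H = |a| w^2`` of the fitted parabola (always >= 0)."""
    if w < 1:
        raise ValueError(f"half-width w must be >= 1, got {w}")
    return abs(a) * w * w


def height_series(record: SignalRecord, cfg: FitConfig) -> HeightSeries:
    """Parabolic height at every sample of a record.

    Uses a prefix-sum sliding window (one addition per incoming sample, one
    subtraction per window evaluation), so the whole series costs O(N)
    regardless of the window length.  Boundary samples where the window does
    not fit get ``H = 0``.

    Raises
    ------
    SignalTooShortError
        If the record is shorter than the window length ``L``.
    """
    y = record.samples
    N = y.size
    if N < cfg.L:
        raise SignalTooShortError(
            f"record of {N} samples is shorter than window length L={cfg.L}"
        )
    w = cfg.w
    # prefix[k] = sum of y[:k]; window sum at n is prefix[n+w+1] - prefix[n-w]
    prefix = np.concatenate(([0.0], np.cumsum(y)))
    window_sums = prefix[2 * w + 1 :] - prefix[: N - 2 * w]
    a = cfg.C * (-cfg.L * y[w : N - w] + window_sums)

    H = np.zeros(N, dtype=np.float64)
    sign = np.zeros(N, dtype=np.int8)
    H[w : N - w] = np.abs(a) * (w * w)
    sign[w : N - w] = np.sign(a)
    return HeightSeries(H=H, a_sign=sign, w=w)
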