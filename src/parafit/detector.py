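"""Adaptive-threshold R-peak detection on the parabolic-height feature.

A window of length ``L = 2w+1`` sweeps the record left to right.  At each
sample the parabolic height ``H`` is compared against an adaptive threshold
``Hth``: samples with ``H > Hth`` are *candidates*, the running argmax of
``H`` during a search episode is the *best candidate*, and a best candidate
that survives unchallenged for ``ncand`` samples is registered as an R peak.
On every registration the threshold is re-derived from a depth-``M`` moving
average of registered heights, scaled by ``alphaH`` and clamped to
``[Hmin, Hmax]``.  If ``nth`` samples elapse with no registration, ``Hmin``
is mixed into the average instead, so the threshold decays toward its floor
during silence and the detector can re-acquire low-amplitude beats.

Two tuned parameter profiles are shipped: ``"qtdb-250hz"`` and
``"mitdb-360hz"``.  No automatic rescaling between sampling rates is
attempted; each profile is specific to its native rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .parabolic import FitConfig, SignalRecord, SignalTooShortError, height_series

__all__ = [
    "DetectorParams",
    "DetectorState",
    "PeakList",
    "PROFILES",
    "NATIVE_FS",
    "m_mean",
    "saturate",
    "detect",
    "StreamingDetector",
]


@dataclass(frozen=True)
class DetectorParams:
    """The seven tuned numbers that fully specify the detector.

    Attributes
    ----------
    Hmin, Hmax : float
        Threshold floor and ceiling, in the signal's amplitude units (mV
        for PhysioNet records); ``0 < Hmin <= Hmax``.
    alphaH : float
        Scaling of the moving-average height into a threshold, in (0, 1].
    ncand : int
        Candidate-search timeout in samples; doubles as the refractory
        interval between registrations.
    nth : int
        Silence interval (samples) after which the threshold decays.
    L : int
        Parabola window length in samples, odd, >= 3.
    M : int
        Depth of the registered-height history buffer.
    """

    Hmin: float
    Hmax: float
    alphaH: float
    ncand: int
    nth: int
    L: int
    M: int

    def __post_init__(self) -> None:
        if not (0 < self.Hmin <= self.Hmax):
            raise ValueError(f"need 0 < Hmin <= Hmax, got {self.Hmin}, {self.Hmax}")
        if not (0 < self.alphaH <= 1):
            raise ValueError(f"alphaH must be in (0, 1], got {self.alphaH}")
        if self.ncand < 1 or self.nth < 1:
            raise ValueError("ncand and nth must be >= 1")
        if self.L < 3 or self.L % 2 == 0:
            raise ValueError(f"L must be odd and >= 3, got {self.L}")
        if self.M < 1:
            raise ValueError(f"M must be >= 1, got {self.M}")

    @property
    def w(self) -> int:
        return (self.L - 1) // 2

    def fit_config(self) -> FitConfig:
        return FitConfig(w=self.w)

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "DetectorParams":
        """Load the seven keys from a JSON config file, with overrides."""
        cfg = json.loads(Path(path).read_text())
        unknown = set(cfg) - {f.name for f in _param_fields()}
        if unknown:
            raise ValueError(f"unknown parameter keys in {path}: {sorted(unknown)}")
        cfg.update(overrides)
        return cls(**cfg)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


def _param_fields():
    import dataclasses

    return dataclasses.fields(DetectorParams)


#: Tuned profiles: exhaustive-search values for the QT database at 250 Hz
#: and the MIT-BIH arrhythmia database at 360 Hz.
PROFILES: dict[str, DetectorParams] = {
    "qtdb-250hz": DetectorParams(
        Hmin=0.3, Hmax=1.1, alphaH=0.335, ncand=70, nth=480, L=17, M=4
    ),
    "mitdb-360hz": DetectorParams(
        Hmin=0.45, Hmax=0.9, alphaH=0.45, ncand=115, nth=691, L=35, M=4
    ),
}

#: Sampling rate each profile was tuned at.
NATIVE_FS: dict[str, float] = {"qtdb-250hz": 250.0, "mitdb-360hz": 360.0}


def saturate(h: float, Hmin: float, Hmax: float) -> float:
    """Clamp a threshold into ``[Hmin, Hmax]``."""
    if Hmin > Hmax:
        raise ValueError(f"Hmin={Hmin} exceeds Hmax={Hmax}")
    return min(max(h, Hmin), Hmax)


@dataclass
class DetectorState:
    """Mutable sweep state; create via :meth:`initial`.

    ``history`` holds the last ``M`` registered parabolic heights, newest
    first.  ``ns`` is the sample index of the last registration or decay
    event — the clock for the silence-decay rule.
    """

    Hth: float
    candidate_found: bool
    nbest: int
    Hbest: float
    ns: int
    history: list[float] = field(default_factory=list)

    @classmethod
    def initial(cls, params: DetectorParams, start: int = 0) -> "DetectorState":
        # Conservative start: history primed at Hmax so the first threshold
        # sits high and the silence decay lowers it if beats are small.
        return cls(
            Hth=saturate(params.alphaH * params.Hmax, params.Hmin, params.Hmax),
            candidate_found=False,
            nbest=start,
            Hbest=0.0,
            ns=start,
            history=[params.Hmax] * params.M,
        )


def m_mean(state: DetectorState, h_new: float, M: int | None = None) -> float:
    """Push ``h_new`` into the height history and return the buffer mean.

    The buffer shifts by one (oldest dropped, ``h1 <- h_new``); the state is
    mutated in place.
    """
    if M is None:
        M = len(state.history)
    state.history = [h_new] + state.history[: M - 1]
    return sum(state.history) / M


@dataclass(frozen=True)
class PeakList:
    """Registered R peaks: strictly increasing sample indices plus heights."""

    indices: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        hts = np.asarray(self.heights, dtype=np.float64)
        if idx.shape != hts.shape:
            raise ValueError("indices and heights must have equal length")
        if idx.size > 1 and not np.all(np.diff(idx) > 0):
            raise ValueError("peak indices must be strictly increasing")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "heights", hts)

    def __len__(self) -> int:
        return self.indices.size

    def times(self, fs: float) -> np.ndarray:
        """Peak locations in seconds."""
        return self.indices / fs


def _sweep_step(state: DetectorState, params: DetectorParams, n: int, H: float):
    """Advance the sweep by one sample; return a registered (index, height)
    pair or None.  Mirrors the per-sample body of the detection loop."""
    registered = None
    if H > state.Hth:
        state.candidate_found = True
        if H > state.Hbest:
            state.nbest = n
            state.Hbest = H
    if state.candidate_found and n - state.nbest > params.ncand:
        state.candidate_found = False
        registered = (state.nbest, state.Hbest)
        state.Hth = params.alphaH * m_mean(state, state.Hbest, params.M)
        state.ns = state.nbest
        state.Hbest = 0.0
    if n - state.ns > params.nth:
        state.Hth = params.alphaH * m_mean(state, params.Hmin, params.M)
        state.ns = n
    state.Hth = saturate(state.Hth, params.Hmin, params.Hmax)
    return registered


def _flush(state: DetectorState, params: DetectorParams):
    """Register a still-pending best candidate at end of record."""
    if not state.candidate_found:
        return None
    state.candidate_found = False
    registered = (state.nbest, state.Hbest)
    state.Hth = saturate(
        params.alphaH * m_mean(state, state.Hbest, params.M),
        params.Hmin,
        params.Hmax,
    )
    state.ns = state.nbest
    state.Hbest = 0.0
    return registered


def detect(
    record: SignalRecord,
    params: DetectorParams,
    initial_state: DetectorState | None = None,
    final_flush: bool = True,
) -> PeakList:
    """Run the full detection sweep over a record.

    Parameters
    ----------
    record : SignalRecord
        Single-channel ECG; must be at least ``params.L`` samples long.
    params : DetectorParams
        Tuned parameter set (see :data:`PROFILES`).
    initial_state : DetectorState, optional
        Resume from a previous sweep's state instead of the conservative
        default initialization.
    final_flush : bool
        If True (default) a best candidate still pending when the record
        ends is registered, so a true final beat is not dropped.  Disable
        for the strict sweep that only registers after the full timeout.

    Returns
    -------
    PeakList
        Strictly increasing peak sample indices with their parabolic
        heights.  Consecutive peaks are always more than ``ncand`` samples
        apart.
    """
    cfg = params.fit_config()
    hs = height_series(record, cfg)  # raises SignalTooShortError if needed
    w = cfg.w
    N = len(record)
    state = initial_state if initial_state is not None else DetectorState.initial(
        params, start=w
    )

    H = hs.H
    idx: list[int] = []
    hts: list[float] = []
    for n in range(w, N - w):
        reg = _sweep_step(state, params, n, H[n])
        if reg is not None:
            idx.append(reg[0])
            hts.append(reg[1])
    if final_flush:
        reg = _flush(state, params)
        if reg is not None:
            idx.append(reg[0])
            hts.append(reg[1])
    return PeakList(indices=np.array(idx, dtype=np.int64), heights=np.array(hts))


class StreamingDetector:
    """Sample-by-sample façade over the detection sweep.

    Feed samples in order with :meth:`process`; each call returns a newly
    registered peak index (in the global sample numbering) or None.  The
    output over any chunking of a signal equals the one-shot
    :func:`detect` on the concatenation, because both paths share the same
    prefix-sum arithmetic and state machine.  A peak is emitted
    ``w + ncand + 1`` samples after its apex enters the stream.
    """

    def __init__(self, params: DetectorParams, state: DetectorState | None = None):
        self.params = params
        self.cfg = params.fit_config()
        self._prefix: list[float] = [0.0]  # prefix[k] = sum of first k samples
        self._y: list[float] = []
        self._n_in = 0  # samples consumed
        self.state = state if state is not None else DetectorState.initial(
            params, start=self.cfg.w
        )
        self._flushed = False

    def process(self, sample: float) -> int | None:
        """Consume one sample; return a registered peak index or None."""
        if self._flushed:
            raise RuntimeError("stream already finished")
        y = float(sample)
        self._y.append(y)
        self._prefix.append(self._prefix[-1] + y)
        self._n_in += 1
        w, L, C = self.cfg.w, self.cfg.L, self.cfg.C
        n = self._n_in - 1 - w  # center whose window just completed
        if n < w:
            return None
        window_sum = self._prefix[n + w + 1] - self._prefix[n - w]
        a = C * (-L * self._y[n] + window_sum)
        H = abs(a) * (w * w)
        reg = _sweep_step(self.state, self.params, n, H)
        return reg[0] if reg is not None else None

    def process_chunk(self, samples) -> list[int]:
        """Convenience: process an array of samples, collect emitted peaks."""
        return [p for s in samples for p in [self.process(s)] if p is not None]

    def finish(self, final_flush: bool = True) -> int | None:
        """End the stream; optionally flush a pending best candidate."""
        self._flushed = True
        if final_flush:
            reg = _flush(self.state, self.params)
            if reg is not None:
                return reg[0]
        return None


def load_profile(name_or_path: str) -> DetectorParams:
    """Resolve a named profile or a JSON config path to parameters."""
    if name_or_path in PROFILES:
        return PROFILES[name_or_path]
    p = Path(name_or_path)
    if p.exists():
        return DetectorParams.from_json(p)
    raise KeyError(
        f"unknown profile {name_or_path!r}; choose from {sorted(PROFILES)} "
        "or pass a JSON config path"
    )
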