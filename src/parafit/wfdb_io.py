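"""Minimal reader/writer for PhysioNet WFDB records and annotations.

Supports what the QT and MIT-BIH databases actually use: ``.hea`` headers,
``.dat`` signal files in formats 212 (packed 12-bit pairs) and 16
(little-endian int16), and MIT-format ``.atr`` annotation files.  Samples
are returned in physical units, ``(adc - baseline) / gain``.

This is a self-contained codec, not a full WFDB implementation: multi-
segment records, non-zero ``initval`` skews, and the rarer signal formats
(8, 80, 24, 32, 310, ...) are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "WFDBFormatError",
    "read_wfdb_record",
    "write_wfdb_record",
    "read_annotations",
    "write_annotations",
]


class WFDBFormatError(ValueError):
    """Header or data file could not be parsed."""


@dataclass(frozen=True)
class _SignalSpec:
    filename: str
    fmt: int
    gain: float
    baseline: int
    units: str


# MIT annotation-code table (code number -> display symbol).
_CODE_TO_SYM = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
_SYM_TO_CODE = {v: k for k, v in _CODE_TO_SYM.items()}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


def _parse_header(hea_path: Path):
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise WFDBFormatError(f"empty header {hea_path}")
    top = lines[0].split()
    if len(top) < 4:
        raise WFDBFormatError(f"malformed record line in {hea_path}: {lines[0]!r}")
    record_name = top[0].split("/")[0]
    nsig = int(top[1])
    fs = float(top[2].split("/")[0])  # strip counter-frequency suffix
    nsamp = int(top[3])
    if nsig < 1 or len(lines) < 1 + nsig:
        raise WFDBFormatError(f"header {hea_path} lists {nsig} signals")

    specs = []
    for ln in lines[1 : 1 + nsig]:
        f = ln.split()
        if len(f) < 2:
            raise WFDBFormatError(f"malformed signal line: {ln!r}")
        fmt = int(f[1].split("x")[0].split(":")[0].split("+")[0])
        gain_field = f[2] if len(f) > 2 else "200"
        units = "mV"
        if "/" in gain_field:
            gain_field, units = gain_field.split("/", 1)
        baseline = None
        if "(" in gain_field:
            gain_field, rest = gain_field.split("(", 1)
            baseline = int(rest.rstrip(")"))
        gain = float(gain_field) if float(gain_field) != 0 else 200.0
        adczero = int(f[4]) if len(f) > 4 else 0
        if baseline is None:
            baseline = adczero
        specs.append(
            _SignalSpec(
                filename=f[0], fmt=fmt, gain=gain, baseline=baseline, units=units
            )
        )
    return record_name, fs, nsamp, specs


def _decode_212(raw: bytes, nsig: int, nsamp: int) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8)
    n_pairs = b.size // 3
    b = b[: n_pairs * 3].reshape(-1, 3).astype(np.int32)
    first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    first = np.where(first > 2047, first - 4096, first)
    second = np.where(second > 2047, second - 4096, second)
    flat = np.empty(n_pairs * 2, dtype=np.int32)
    flat[0::2] = first
    flat[1::2] = second
    total = nsig * nsamp
    if flat.size < total:
        raise WFDBFormatError("format-212 data file shorter than header promises")
    return flat[:total].reshape(nsamp, nsig)


def _decode_16(raw: bytes, nsig: int, nsamp: int) -> np.ndarray:
    flat = np.frombuffer(raw, dtype="<i2").astype(np.int32)
    total = nsig * nsamp
    if flat.size < total:
        raise WFDBFormatError("format-16 data file shorter than header promises")
    return flat[:total].reshape(nsamp, nsig)


def read_wfdb_record(path: str | Path, channel: int = 0):
    """Read one channel of a WFDB record in physical units.

    Parameters
    ----------
    path : str or Path
        Record path with or without the ``.hea`` extension.
    channel : int
        0-based signal index (PhysioNet benchmarks use channel 0).

    Returns
    -------
    (samples, fs, record_name, units)
    """
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    record_name, fs, nsamp, specs = _parse_header(hea)
    if not (0 <= channel < len(specs)):
        raise ValueError(f"channel {channel} not in record with {len(specs)} signals")

    # All benchmark records keep every signal in one interleaved .dat file.
    spec = specs[channel]
    dat = hea.parent / spec.filename
    raw = dat.read_bytes()
    same_file = [i for i, s in enumerate(specs) if s.filename == spec.filename]
    nsig = len(same_file)
    if spec.fmt == 212:
        adc = _decode_212(raw, nsig, nsamp)
    elif spec.fmt == 16:
        adc = _decode_16(raw, nsig, nsamp)
    else:
        raise WFDBFormatError(f"unsupported WFDB signal format {spec.fmt}")
    col = same_file.index(channel)
    physical = (adc[:, col].astype(np.float64) - spec.baseline) / spec.gain
    return physical, fs, record_name, spec.units


def write_wfdb_record(
    path: str | Path,
    samples: np.ndarray,
    fs: float,
    gain: float = 200.0,
    units: str = "mV",
) -> None:
    """Write a single-channel record as ``.hea`` + format-16 ``.dat``."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".hea" else path
    y = np.asarray(samples, dtype=np.float64)
    adc = np.clip(np.rint(y * gain), -32768, 32767).astype("<i2")
    name = base.name
    base.with_suffix(".hea").write_text(
        f"{name} 1 {fs:g} {y.size}\n"
        f"{name}.dat 16 {gain:g}(0)/{units} 16 0 {int(adc[0]) if adc.size else 0} 0 0 ECG\n"
    )
    base.with_suffix(".dat").write_bytes(adc.tobytes())


def read_annotations(path: str | Path):
    """Read a MIT-format annotation file (``.atr``/``.qrs``/...).

    Returns ``(indices, symbols)``: absolute sample numbers and the
    display symbol of every annotation, beats and non-beats alike.
    """
    raw = Path(path).read_bytes()
    words = np.frombuffer(raw, dtype="<u2")
    indices: list[int] = []
    symbols: list[str] = []
    t = 0
    i = 0
    while i < words.size:
        word = int(words[i])
        code = word >> 10
        data = word & 0x3FF
        i += 1
        if code == 0 and data == 0:  # end of file
            break
        if code == _SKIP:
            if i + 1 >= words.size:
                raise WFDBFormatError("truncated SKIP pseudo-annotation")
            interval = (int(words[i]) << 16) | int(words[i + 1])
            if interval >= 1 << 31:
                interval -= 1 << 32
            t += interval
            i += 2
        elif code == _AUX:
            i += (data + 1) // 2  # skip aux bytes (padded to word boundary)
        elif code in (_NUM, _SUB, _CHN):
            pass  # modifier pseudo-annotations carry no time
        else:
            t += data
            indices.append(t)
            symbols.append(_CODE_TO_SYM.get(code, "?"))
    return np.asarray(indices, dtype=np.int64), symbols


def write_annotations(path: str | Path, indices, symbols) -> None:
    """Write a MIT-format annotation file readable by :func:`read_annotations`."""
    indices = np.asarray(indices, dtype=np.int64)
    if len(symbols) != indices.size:
        raise ValueError("indices and symbols must have equal length")
    out = bytearray()

    def emit(word: int) -> None:
        out.extend(int(word).to_bytes(2, "little"))

    t = 0
    for idx, sym in zip(indices, symbols):
        code = _SYM_TO_CODE.get(sym, 13)  # unknown symbols -> Q
        delta = int(idx) - t
        if delta < 0:
            raise ValueError("annotation indices must be non-decreasing")
        if delta > 1023:
            emit(_SKIP << 10)
            emit((delta >> 16) & 0xFFFF)
            emit(delta & 0xFFFF)
            delta = 0
        emit((code << 10) | delta)
        t = int(idx)
    emit(0)  # EOF word
    Path(path).write_bytes(bytes(out))
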