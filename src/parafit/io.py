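"""Record and annotation I/O: WFDB dispatch, CSV formats, result tables.

CSV signal files are two columns ``sample_index,amplitude`` preceded by
comment lines holding metadata (``# fs=250`` is required; ``# record_id=``
optional).  Annotation CSVs are two columns ``sample_index,label``.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .detector import PeakList
from .evaluation import AnnotationSet, EvalResult
from .parabolic import SignalRecord
from . import wfdb_io

__all__ = [
    "read_record",
    "read_csv_record",
    "write_csv_record",
    "read_annotation_csv",
    "write_annotation_csv",
    "read_annotation_set",
    "write_peaks_csv",
    "results_table",
]


def read_record(path: str | Path, format: str | None = None, channel: int = 0) -> SignalRecord:
    """Read an ECG record from WFDB or CSV.

    ``format`` is ``"wfdb"`` or ``"csv"``; inferred from the extension
    when None (``.csv`` -> csv, anything else -> wfdb).
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "wfdb"
    if format == "csv":
        if channel != 0:
            raise ValueError("CSV records are single-channel")
        return read_csv_record(path)
    if format == "wfdb":
        samples, fs, name, _units = wfdb_io.read_wfdb_record(path, channel=channel)
        return SignalRecord(samples=samples, fs=fs, record_id=name)
    raise ValueError(f"unknown record format {format!r}")


def read_csv_record(path: str | Path) -> SignalRecord:
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[float] = []
    with open(path, newline="") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    k, v = line.lstrip("#").split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            parts = line.split(",")
            if parts[0] in ("sample_index", "index", "n"):  # optional header row
                continue
            rows.append(float(parts[-1]))
    if "fs" not in meta:
        raise ValueError(f"CSV record {path} is missing the required '# fs=' metadata")
    return SignalRecord(
        samples=np.asarray(rows),
        fs=float(meta["fs"]),
        record_id=meta.get("record_id", path.stem),
    )


def write_csv_record(path: str | Path, record: SignalRecord) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# fs={record.fs:g}\n# record_id={record.record_id}\n")
        fh.write("sample_index,amplitude\n")
        for i, v in enumerate(record.samples):
            fh.write(f"{i},{float(v)!r}\n")


def read_annotation_csv(path: str | Path) -> AnnotationSet:
    idx: list[int] = []
    labels: list[str] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#") or row[0] == "sample_index":
                continue
            idx.append(int(row[0]))
            labels.append(row[1] if len(row) > 1 else "N")
    return AnnotationSet(indices=np.asarray(idx, dtype=np.int64), labels=tuple(labels))


def write_annotation_csv(path: str | Path, ann: AnnotationSet) -> None:
    labels = ann.labels or ("N",) * len(ann)
    with open(path, "w", newline="") as fh:
        fh.write("sample_index,label\n")
        for i, s in zip(ann.indices, labels):
            fh.write(f"{i},{s}\n")


def read_annotation_set(path: str | Path) -> AnnotationSet:
    """Read annotations from a WFDB ``.atr``-style file or a CSV."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return read_annotation_csv(path)
    indices, symbols = wfdb_io.read_annotations(path)
    return AnnotationSet(indices=indices, labels=tuple(symbols))


def write_peaks_csv(path: str | Path, peaks: PeakList, fs: float) -> None:
    """Detected peaks as ``sample_index,time_s`` CSV."""
    with open(path, "w", newline="") as fh:
        fh.write("sample_index,time_s\n")
        for n in peaks.indices:
            fh.write(f"{n},{n / fs:.6f}\n")


def results_table(results: list[EvalResult], pooled: EvalResult | None = None) -> pd.DataFrame:
    """Benchmark table with one row per record plus an optional totals row."""
    rows = [r.as_row() for r in results]
    if pooled is not None:
        rows.append(pooled.as_row())
    return pd.DataFrame(rows, columns=["Record", "Total", "TP", "FN", "FP", "S", "P", "DER"])
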