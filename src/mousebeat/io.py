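"""Reading and writing ECG traces.

Two formats are supported:

* ``csv`` — two-column text (``time_s,voltage_mV``) with a header row;
  lossless for float64 voltages.
* ``record`` — a WFDB-style two-file record: a plain-text header
  (``<name>.hea``) naming sample rate, length, gain and baseline, and a
  16-bit little-endian ``.dat`` file. Voltages round-trip to within one
  ADC quantisation step (1/gain mV).
"""

from __future__ import annotations

import csv as _csv
from pathlib import Path

import numpy as np

from .ecg import ECGTrace

__all__ = ["read_ecg", "write_ecg"]

_CSV_COLUMNS = ("time_s", "voltage_mV")


def write_ecg(trace: ECGTrace, path: str | Path, format: str = "csv",
              gain: float = 2000.0) -> None:
    """Write a trace as CSV or a WFDB-style int16 record.

    ``gain`` (record format only) is the ADC scale in counts per mV.
    """
    path = Path(path)
    if format == "csv":
        t = trace.times_s
        with open(path, "w", newline="") as fh:
            w = _csv.writer(fh)
            w.writerow([*_CSV_COLUMNS, f"subject={trace.subject_id}",
                        f"genotype={trace.genotype}", f"fs={trace.fs:.10g}"])
            for ti, vi in zip(t, trace.samples):
                w.writerow([f"{ti:.6f}", f"{vi:.6f}"])
    elif format == "record":
        base = path.with_suffix("")
        counts = np.clip(np.rint(trace.samples * gain), -32768, 32767).astype("<i2")
        hea = (
            f"{base.name} 1 {trace.fs:.10g} {trace.samples.size} {trace.start_s:.10g}\n"
            f"{base.name}.dat 16 {gain:.10g} 0\n"
            f"# subject={trace.subject_id} genotype={trace.genotype}\n"
        )
        base.with_suffix(".hea").write_text(hea)
        counts.tofile(base.with_suffix(".dat"))
    else:
        raise ValueError(f"unknown ECG format {format!r} (expected 'csv' or 'record')")


def read_ecg(path: str | Path, format: str = "csv") -> ECGTrace:
    """Read a trace written by :func:`write_ecg`."""
    path = Path(path)
    if format == "csv":
        return _read_csv(path)
    if format == "record":
        return _read_record(path)
    raise ValueError(f"unknown ECG format {format!r} (expected 'csv' or 'record')")


def _read_csv(path: Path) -> ECGTrace:
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, newline="") as fh:
        reader = _csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, expected header "
                             f"{','.join(_CSV_COLUMNS)}") from None
        if tuple(h.strip() for h in header[:2]) != _CSV_COLUMNS:
            raise ValueError(
                f"{path}: line 1: expected columns {','.join(_CSV_COLUMNS)}, "
                f"got {','.join(header[:2])!r}"
            )
        meta = {}
        for tok in header[2:]:
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k.strip()] = v.strip()
        t, v = [], []
        for ln, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                t.append(float(row[0]))
                v.append(float(row[1]))
            except (ValueError, IndexError):
                raise ValueError(f"{path}: line {ln}: malformed row {row!r}") from None
    t = np.asarray(t)
    v = np.asarray(v)
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    fs = float(meta["fs"]) if "fs" in meta else 1.0 / float(np.median(np.diff(t)))
    return ECGTrace(v, fs, subject_id=meta.get("subject", ""),
                    genotype=meta.get("genotype", ""), start_s=float(t[0]))


def _read_record(path: Path) -> ECGTrace:
    base = Path(path).with_suffix("")
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    lines = hea.read_text().splitlines()
    try:
        _, _nsig, fs_s, n_s, start_s = lines[0].split()
        sig = lines[1].split()
        gain = float(sig[2])
    except (IndexError, ValueError):
        raise ValueError(f"{hea}: malformed record header") from None
    meta = {}
    for ln in lines[2:]:
        if ln.startswith("#"):
            for tok in ln[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
    counts = np.fromfile(base.with_suffix(".dat"), dtype="<i2")
    if counts.size != int(n_s):
        raise ValueError(f"{base}.dat: expected {n_s} samples, found {counts.size}")
    return ECGTrace(counts / gain, float(fs_s), subject_id=meta.get("subject", ""),
                    genotype=meta.get("genotype", ""), start_s=float(start_s))
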