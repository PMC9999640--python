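"""Readers and writers for the pipeline's on-disk formats.

* ECG traces as two-column CSV (``time_s, amplitude_mV``) — the native
  interchange format of the package;
* single-signal WFDB record pairs (text ``.hea`` header + format-16
  little-endian ``.dat``), enough to exchange traces with PhysioNet-style
  tooling;
* cohort manifests, decomposition sets (wide CSV + JSON sidecar) and RT
  result tables as CSV.

All writers are deterministic: identical inputs give byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .emd import IMFSet
from .records import ECGRecord, ParseError
from .rt import RTResult

__all__ = [
    "write_record_csv", "read_record_csv",
    "write_record_wfdb", "read_record_wfdb",
    "write_manifest", "read_manifest",
    "write_imfset", "read_imfset",
    "write_rt_results", "read_rt_results",
]

_WFDB_GAIN = 1000  # ADC units per mV
_TIME_JITTER_PPM = 1.0


# ---------------------------------------------------------------- CSV traces

def write_record_csv(record: ECGRecord, path) -> Path:
    path = Path(path)
    t = np.arange(record.n_samples) / record.sampling_rate
    df = pd.DataFrame({"time_s": t, "amplitude_mV": record.samples})
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def read_record_csv(path, subject_id: str | None = None,
                    group: str | None = None) -> ECGRecord:
    """Read a two-column trace; the sampling rate is inferred from the time
    column, which must be uniform to within 1 ppm."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "amplitude_mV"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    bad = df.index[df["amplitude_mV"].isna() | df["time_s"].isna()]
    if len(bad):
        raise ParseError(f"{path}: missing value at data row {int(bad[0]) + 1}")
    t = df["time_s"].to_numpy(float)
    if t.size < 2:
        raise ParseError(f"{path}: need at least 2 samples to infer a rate")
    dt = np.diff(t)
    mean_dt = float(dt.mean())
    if mean_dt <= 0 or np.max(np.abs(dt - mean_dt)) > _TIME_JITTER_PPM * 1e-6 * mean_dt:
        raise ParseError(f"{path}: time column is not uniformly sampled")
    return ECGRecord(samples=df["amplitude_mV"].to_numpy(float),
                     sampling_rate=1.0 / mean_dt,
                     subject_id=subject_id or path.stem, group=group)


# -------------------------------------------------------------- WFDB records

def write_record_wfdb(record: ECGRecord, record_name, directory=".") -> Path:
    """Write a single-signal WFDB pair (``.hea`` + format-16 ``.dat``).

    Samples are quantized at 1000 ADC units/mV into 16-bit little-endian
    integers, the standard format-16 layout.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = str(record_name)
    adc = np.clip(np.round(record.samples * _WFDB_GAIN), -32768, 32767).astype("<i2")
    checksum = int(adc.astype(np.int64).sum() % 65536)
    if checksum >= 32768:
        checksum -= 65536
    fs = record.sampling_rate
    fs_str = f"{fs:g}"
    lead = record.lead or "ECG"
    hea = (f"{name} 1 {fs_str} {record.n_samples}\n"
           f"{name}.dat 16 {_WFDB_GAIN}/mV 16 0 {int(adc[0])} {checksum} 0 {lead}\n")
    (directory / f"{name}.hea").write_text(hea)
    (directory / f"{name}.dat").write_bytes(adc.tobytes())
    return directory / f"{name}.hea"


def read_record_wfdb(header_path, subject_id: str | None = None,
                     group: str | None = None) -> ECGRecord:
    """Read a single-signal format-16 WFDB pair written by this package
    (or any compatible single-lead record)."""
    header_path = Path(header_path)
    lines = [ln for ln in header_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ParseError(f"{header_path}: empty header")
    rec_fields = lines[0].split()
    if len(rec_fields) < 4:
        raise ParseError(f"{header_path}: malformed record line {lines[0]!r}")
    name, n_sig, fs, n_samples = rec_fields[0], int(rec_fields[1]), \
        float(rec_fields[2]), int(rec_fields[3])
    if n_sig != 1:
        raise ParseError(f"{header_path}: only single-signal records supported")
    sig = lines[1].split()
    if len(sig) < 3 or not sig[1].startswith("16"):
        raise ParseError(f"{header_path}: only format 16 supported, got {lines[1]!r}")
    gain = float(sig[2].split("/")[0].split("(")[0]) or _WFDB_GAIN
    lead = sig[8] if len(sig) > 8 else None
    dat_path = header_path.parent / sig[0]
    raw = np.frombuffer(dat_path.read_bytes(), dtype="<i2")
    if raw.size < n_samples:
        raise ParseError(f"{dat_path}: expected {n_samples} samples, found {raw.size}")
    samples = raw[:n_samples].astype(float) / gain
    return ECGRecord(samples=samples, sampling_rate=fs,
                     subject_id=subject_id or name, lead=lead, group=group)


# ------------------------------------------------------- manifests & results

def write_manifest(entries, path) -> Path:
    """Cohort manifest: subject_id, group, file (relative path)."""
    df = pd.DataFrame(entries, columns=["subject_id", "group", "file"])
    df.to_csv(path, index=False)
    return Path(path)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"subject_id", "group", "file"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: manifest missing columns {sorted(missing)}")
    return df


def write_imfset(imfset: IMFSet, path_csv, config=None) -> Path:
    """Wide CSV (C1..Ck, residual) plus a JSON sidecar with sift metadata."""
    path_csv = Path(path_csv)
    data = {f"C{i + 1}": c for i, c in enumerate(imfset.components)}
    data["residual"] = imfset.residual
    pd.DataFrame(data).to_csv(path_csv, index=False, float_format="%.9g")
    sidecar = {
        "subject_id": imfset.subject_id,
        "sampling_rate": imfset.sampling_rate,
        "sift_counts": list(imfset.sift_counts),
        "n_natural": imfset.n_natural,
        "config": (config.__dict__ if hasattr(config, "__dict__") else config),
    }
    path_csv.with_suffix(".json").write_text(json.dumps(sidecar, indent=2,
                                                        sort_keys=True))
    return path_csv


def read_imfset(path_csv) -> IMFSet:
    path_csv = Path(path_csv)
    df = pd.read_csv(path_csv)
    meta = json.loads(path_csv.with_suffix(".json").read_text())
    comps = [df[c].to_numpy(float) for c in df.columns if c.startswith("C")]
    return IMFSet(components=comps, residual=df["residual"].to_numpy(float),
                  sampling_rate=meta["sampling_rate"],
                  sift_counts=meta["sift_counts"],
                  subject_id=meta["subject_id"], n_natural=meta["n_natural"])


def write_rt_results(results, path, weights=None) -> Path:
    """RT result table: subject_id, group, rt_index_pct, E1..E8."""
    rows = []
    for r in results:
        row = {"subject_id": r.subject_id, "group": r.group,
               "rt_index_pct": round(r.rt_pct, 6)}
        for i, e in enumerate(r.energies.energies):
            row[f"E{i + 1}"] = e
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")
    if weights is not None:
        Path(path).with_suffix(".weights.json").write_text(
            json.dumps({"alpha": weights.alpha, "beta": weights.beta,
                        "gamma": weights.gamma}, indent=2, sort_keys=True))
    return Path(path)


def read_rt_results(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"subject_id", "group", "rt_index_pct"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: results missing columns {sorted(missing)}")
    return df
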