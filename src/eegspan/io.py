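"""File I/O: recordings (EDF and internal HDF5), montages, subject tables.

The internal format is a single HDF5 file per subject holding the voltage
tensor, sampling rate, channel labels and a provenance log of every
operation applied — epoched data plus metadata do not fit flat signal
formats, and round-trips must be bit-identical. EDF is supported for
ingest of raw continuous data (via MNE) and a minimal 16-bit EDF writer
is provided for interchange.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EpochedRecording, Montage, SubjectRecord

__all__ = [
    "read_recording",
    "write_recording",
    "write_edf",
    "load_montage",
    "save_montage",
    "validate_subject_table",
    "read_subject_table",
    "write_subject_table",
]


# ---------------------------------------------------------------------------
# recordings

def write_recording(recording: EpochedRecording, path) -> Path:
    """Write a recording to the internal single-file HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data)
        f.attrs["sampling_rate"] = float(recording.sampling_rate)
        f.attrs["labels"] = json.dumps(list(recording.labels))
        f.attrs["epoch_length"] = (
            -1.0 if recording.epoch_length is None else float(recording.epoch_length)
        )
        f.attrs["provenance"] = json.dumps(recording.provenance)
    return path


def _read_internal(path) -> EpochedRecording:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        epoch_length = float(f.attrs["epoch_length"])
        rec = EpochedRecording(
            data=data,
            sampling_rate=float(f.attrs["sampling_rate"]),
            labels=tuple(json.loads(f.attrs["labels"])),
            epoch_length=None if epoch_length < 0 else epoch_length,
            provenance=list(json.loads(f.attrs["provenance"])),
        )
    return rec


def _read_edf(path) -> EpochedRecording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE holds volts; we work in microvolts
    return EpochedRecording(
        data=data,
        sampling_rate=float(raw.info["sfreq"]),
        labels=tuple(raw.ch_names),
        provenance=[f"read_edf:{Path(path).name}"],
    )


def read_recording(path, format: str | None = None) -> EpochedRecording:
    """Read a recording; ``format`` is ``"edf"``, ``"internal"`` or inferred.

    EDF input is returned continuous (channels × samples); segmentation
    into epochs is a preprocessing step, not an I/O concern.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "internal"
    if format == "edf":
        return _read_edf(path)
    if format == "internal":
        return _read_internal(path)
    raise ValueError(f"unknown recording format {format!r}")


def write_edf(recording: EpochedRecording, path) -> Path:
    """Write a continuous recording as a minimal EDF file.

    16-bit encoding with per-channel physical scaling; one data record
    per second. Epoched data must be flattened by the caller first.
    """
    if recording.is_epoched:
        raise ValueError("EDF export requires continuous data")
    path = Path(path)
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    data = recording.data
    n_ch = data.shape[0]
    n_records = data.shape[1] // fs
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = data[:, : n_records * fs]

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    span = np.where(pmax - pmin <= 0, 1.0, pmax - pmin)
    dmin, dmax = -32768, 32767
    scaled = (data - pmin[:, None]) / span[:, None] * (dmax - dmin) + dmin
    digital = np.rint(scaled).astype("<i2")

    def pad(text, width):
        s = str(text)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join([
        pad("0", 8), pad("X", 80), pad("X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(256 + 256 * n_ch, 8), pad("", 44),
        pad(n_records, 8), pad(1, 8), pad(n_ch, 4),
    ])
    fields = [
        (16, [pad(l, 16) for l in recording.labels]),
        (80, [pad("EEG", 80)] * n_ch),
        (8, [pad("uV", 8)] * n_ch),
        (8, [pad(f"{v:.6g}", 8) for v in pmin]),
        (8, [pad(f"{v:.6g}", 8) for v in pmin + span]),
        (8, [pad(dmin, 8)] * n_ch),
        (8, [pad(dmax, 8)] * n_ch),
        (80, [pad("", 80)] * n_ch),
        (8, [pad(fs, 8)] * n_ch),
        (32, [pad("", 32)] * n_ch),
    ]
    header += b"".join(b"".join(col) for _, col in fields)
    with open(path, "wb") as f:
        f.write(header)
        for r in range(n_records):
            f.write(digital[:, r * fs : (r + 1) * fs].tobytes())
    return path


# ---------------------------------------------------------------------------
# montage

def load_montage(path) -> Montage:
    """Read a whitespace-delimited montage file: ``label x y z`` per line.

    Distances are normalized so the most distant electrode pair has
    d = 1 exactly; coordinates may be in any Cartesian unit.
    """
    labels, coords = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"montage line needs 'label x y z': {line!r}")
        labels.append(parts[0])
        coords.append([float(v) for v in parts[1:]])
    if len(labels) < 2:
        raise ValueError("montage needs at least 2 channels")
    return Montage(tuple(labels), np.asarray(coords))


def save_montage(montage: Montage, path) -> Path:
    path = Path(path)
    lines = [
        f"{lab} {p[0]:.10g} {p[1]:.10g} {p[2]:.10g}"
        for lab, p in zip(montage.labels, montage.positions)
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# subject metadata

_TRUE = {"yes", "true", "1", "y"}
_FALSE = {"no", "false", "0", "n"}


def validate_subject_table(table: pd.DataFrame) -> list[SubjectRecord]:
    """Type-check a metadata table into :class:`SubjectRecord` rows.

    Controls may omit the CRS-R score and imagery flag; patients must
    carry an integer CRS-R.
    """
    required = {"subject_id", "group", "crs_r", "imagery"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    records = []
    for _, row in table.iterrows():
        crs = row["crs_r"]
        if pd.isna(crs) or (isinstance(crs, str) and not crs.strip()):
            crs = None
        else:
            fval = float(crs)
            if fval != int(fval):
                raise ValueError(f"non-integer CRS-R score {crs!r}")
            crs = int(fval)
        imagery = row["imagery"]
        if pd.isna(imagery) or (isinstance(imagery, str) and not imagery.strip()):
            imagery = None
        elif isinstance(imagery, str):
            low = imagery.strip().lower()
            if low in _TRUE:
                imagery = True
            elif low in _FALSE:
                imagery = False
            else:
                raise ValueError(f"unparseable imagery flag {imagery!r}")
        else:
            imagery = bool(imagery)
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                crs_r=crs,
                imagery=imagery,
            )
        )
    return records


def read_subject_table(path) -> list[SubjectRecord]:
    return validate_subject_table(pd.read_csv(path))


def write_subject_table(records, path) -> Path:
    path = Path(path)
    rows = []
    for r in records:
        rows.append({
            "subject_id": r.subject_id,
            "group": r.group,
            "crs_r": "" if r.crs_r is None else r.crs_r,
            "imagery": "" if r.imagery is None else ("yes" if r.imagery else "no"),
        })
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
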