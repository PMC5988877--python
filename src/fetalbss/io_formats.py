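"""Reading and writing multichannel ECG records and R-peak annotation sets.

Supported record formats
------------------------
``csv``
    One column per channel, first row holds channel labels.  The sampling
    rate travels in a JSON sidecar ``<name>.json`` (``{"fs": 1000,
    "labels": [...]}``) next to the CSV file.
``wfdb``
    A minimal subset of the WFDB signal format: text header ``<rec>.hea``
    plus an interleaved little-endian 16-bit ``<rec>.dat`` (format 16).
    Integer samples round-trip bit exactly once the per-channel gain is
    inverted.
``edf``
    Read-only, delegated to :mod:`mne`.  EDF amplitudes are converted from
    volts to millivolts on load.

Annotation files are plain text, one 0-based integer sample index per line.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MultichannelRecord",
    "AnnotationSet",
    "read_record",
    "write_record",
    "read_annotations",
    "write_annotations",
]

#: Default QRS window widths in milliseconds, by wave class.
QRS_WIDTH_MS = {"maternal": 100.0, "fetal": 40.0}


@dataclass
class MultichannelRecord:
    """Sampled multichannel ECG: ``signals`` is (n_channels, n_samples) in mV."""

    signals: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length does not match signal rows")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class AnnotationSet:
    """Sorted R-peak sample indices for one wave class (maternal or fetal)."""

    peaks: np.ndarray
    wave_class: str = "fetal"
    qrs_width_ms: float | None = None

    def __post_init__(self) -> None:
        peaks = np.asarray(self.peaks, dtype=np.int64).ravel()
        if peaks.size and peaks.min() < 0:
            raise ValueError("annotation indices must be non-negative")
        self.peaks = np.unique(peaks)  # sorted, de-duplicated
        if self.qrs_width_ms is None:
            self.qrs_width_ms = QRS_WIDTH_MS.get(self.wave_class, 40.0)

    def __len__(self) -> int:
        return len(self.peaks)

    def times_s(self, fs: float) -> np.ndarray:
        return self.peaks / float(fs)


# ---------------------------------------------------------------------------
# CSV + JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _read_csv(path: Path, fs: float | None) -> MultichannelRecord:
    with open(path) as fh:
        labels = [t.strip() for t in fh.readline().strip().split(",")]
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    sidecar = _sidecar_path(path)
    if fs is None:
        if not sidecar.exists():
            raise ValueError(
                f"sampling rate unknown: pass fs= or provide sidecar {sidecar}"
            )
        meta = json.loads(sidecar.read_text())
        fs = float(meta["fs"])
        labels = list(meta.get("labels", labels))
    return MultichannelRecord(signals=data.T, fs=fs, channel_labels=labels)


def _write_csv(record: MultichannelRecord, path: Path) -> None:
    header = ",".join(record.channel_labels)
    np.savetxt(path, record.signals.T, delimiter=",", header=header,
               comments="", fmt="%.12g")
    _sidecar_path(path).write_text(json.dumps(
        {"fs": record.fs, "labels": record.channel_labels}))


# ---------------------------------------------------------------------------
# Minimal WFDB (header + format-16 .dat)
# ---------------------------------------------------------------------------

_WFDB_GAIN = 200.0  # ADC units per mV, the conventional WFDB default


def _read_wfdb(path: Path) -> MultichannelRecord:
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    lines = [ln for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    rec_name, n_sig, fs, n_samp = lines[0].split()[:4]
    n_sig, fs, n_samp = int(n_sig), float(fs), int(n_samp)
    gains, baselines, labels, dat_files = [], [], [], []
    for ln in lines[1:1 + n_sig]:
        tok = ln.split()
        dat_files.append(tok[0])
        if tok[1] != "16":
            raise ValueError(f"unsupported WFDB format {tok[1]} (only 16)")
        gain_tok = tok[2]
        if "(" in gain_tok:  # gain(baseline)[/units]
            g, rest = gain_tok.split("(", 1)
            baselines.append(int(rest.split(")")[0]))
        else:
            g = gain_tok.split("/")[0]
            baselines.append(0)
        gains.append(float(g.split("/")[0]) or _WFDB_GAIN)
        labels.append(tok[-1])
    if len(set(dat_files)) != 1:
        raise ValueError("multi-file WFDB records are not supported")
    dat = hea.with_name(dat_files[0])
    raw = np.fromfile(dat, dtype="<i2")
    if raw.size != n_sig * n_samp:
        raise ValueError("inconsistent channel lengths in WFDB .dat")
    digital = raw.reshape(n_samp, n_sig).T.astype(float)
    signals = (digital - np.array(baselines)[:, None]) / np.array(gains)[:, None]
    return MultichannelRecord(signals=signals, fs=fs, channel_labels=labels)


def _write_wfdb(record: MultichannelRecord, path: Path) -> None:
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    dat = hea.with_suffix(".dat")
    digital = np.round(record.signals * _WFDB_GAIN)
    if np.abs(digital).max(initial=0) > 32767:
        raise ValueError("signal exceeds 16-bit WFDB range at gain 200")
    digital = digital.astype("<i2")
    lines = [f"{hea.stem} {record.n_channels} {record.fs:g} {record.n_samples}"]
    for lab in record.channel_labels:
        lines.append(f"{dat.name} 16 {_WFDB_GAIN:g}(0)/mV 16 0 0 0 0 {lab}")
    hea.write_text("\n".join(lines) + "\n")
    digital.T.reshape(-1).tofile(dat)


# ---------------------------------------------------------------------------
# EDF (read-only, via mne)
# ---------------------------------------------------------------------------

def _read_edf(path: Path) -> MultichannelRecord:
    import mne  # deferred: heavy import, only needed for EDF

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return MultichannelRecord(
        signals=raw.get_data() * 1e3,  # V -> mV
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
    )


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def read_record(path, format: str = "csv", fs: float | None = None) -> MultichannelRecord:
    """Read a multichannel record at its native sampling rate (no resampling)."""
    path = Path(path)
    if format == "csv":
        if not path.exists():
            raise FileNotFoundError(path)
        return _read_csv(path, fs)
    if format == "wfdb":
        return _read_wfdb(path)
    if format == "edf":
        if not path.exists():
            raise FileNotFoundError(path)
        return _read_edf(path)
    raise ValueError(f"unknown record format {format!r}")


def write_record(record: MultichannelRecord, path, format: str = "csv") -> None:
    path = Path(path)
    if format == "csv":
        _write_csv(record, path)
    elif format == "wfdb":
        _write_wfdb(record, path)
    else:
        raise ValueError(f"unsupported write format {format!r} (csv or wfdb)")


def read_annotations(path, wave_class: str = "fetal",
                     one_based: bool = False) -> AnnotationSet:
    """Read a text annotation file: one integer sample index per line.

    Indices on disk are 0-based by default; ``one_based=True`` converts
    1-based inputs on load.
    """
    path = Path(path)
    peaks = []
    for lineno, token in enumerate(path.read_text().split(), start=1):
        try:
            peaks.append(int(token))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer token {token!r}") from exc
    arr = np.asarray(peaks, dtype=np.int64)
    if one_based:
        arr = arr - 1
    return AnnotationSet(peaks=arr, wave_class=wave_class)


def write_annotations(annotations: AnnotationSet, path) -> None:
    Path(path).write_text(
        "".join(f"{int(p)}\n" for p in annotations.peaks))
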