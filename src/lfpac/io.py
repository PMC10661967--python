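"""Reading and writing continuous multichannel recordings and result tables.

The native on-disk container is deliberately minimal and fully open: a raw
little-endian sample matrix (one file) plus a JSON sidecar (``<path>.json``)
holding the sampling rate, channel labels, subject/group metadata, dtype and
shape.  The matrix is stored channel-major: row ``i`` is channel ``i``'s
complete time series, time-major within the row.  EDF files are supported
read-only as the common physiology interchange format (requires ``mne``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "ResultTable",
    "read_recording",
    "write_recording",
    "read_table",
    "write_table",
    "TABLE_COLUMNS",
]

_SIDECAR_FIELDS = ("fs", "channel_labels", "subject_id", "group", "dtype",
                   "n_channels", "n_samples")

#: Fixed header of every result table: one row per
#: (group, subject, channel-or-"avg", metric, band-or-band-pair) key.
TABLE_COLUMNS = ("group", "subject", "channel", "metric", "band", "value")


@dataclass
class Recording:
    """A continuous multichannel voltage recording.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Voltage traces in arbitrary units, one row per channel.
    fs : float
        Sampling rate in Hz.
    channel_labels : sequence of str
        One label per channel.
    subject_id, group : str
        Subject identifier and experimental group.
    """

    samples: np.ndarray
    fs: float
    channel_labels: Sequence[str] = field(default_factory=list)
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim == 1:
            self.samples = self.samples[np.newaxis, :]
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (n_channels, n_samples) matrix")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if np.isnan(self.samples).any():
            raise ValueError("recording contains NaN samples")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.samples.shape[0])]
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel_labels length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_samples(self, samples: np.ndarray, fs: float | None = None) -> "Recording":
        """Copy of this recording with new sample data (metadata preserved)."""
        return Recording(samples=samples, fs=self.fs if fs is None else fs,
                         channel_labels=list(self.channel_labels),
                         subject_id=self.subject_id, group=self.group)


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".json")


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write ``rec`` as a raw binary matrix plus JSON sidecar.

    The sample dtype is preserved (converted to little-endian) and recorded in
    the sidecar, so ``read_recording(write_recording(rec))`` is bit-exact.
    """
    path = Path(path)
    data = np.ascontiguousarray(rec.samples)
    dtype = data.dtype.newbyteorder("<")
    data = data.astype(dtype, copy=False)
    sidecar = {
        "format": "lfpac-raw",
        "dtype": dtype.str,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "fs": rec.fs,
        "channel_labels": list(rec.channel_labels),
        "subject_id": rec.subject_id,
        "group": rec.group,
        "layout": "channel-major; each row is one channel, time-major within the row",
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    data.tofile(path)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_recording(path: str | Path) -> Recording:
    """Read a recording from the native binary+sidecar container or an EDF file."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_file}")
    meta = json.loads(sidecar_file.read_text())
    for key in _SIDECAR_FIELDS:
        if key not in meta:
            raise ValueError(f"sidecar {sidecar_file} is missing required field '{key}'")
    if not meta["fs"] > 0:
        raise ValueError(f"sidecar fs must be positive, got {meta['fs']}")
    data = np.fromfile(path, dtype=np.dtype(meta["dtype"]))
    expected = int(meta["n_channels"]) * int(meta["n_samples"])
    if data.size != expected:
        raise ValueError(
            f"{path}: sample count {data.size} does not match sidecar "
            f"({meta['n_channels']} channels x {meta['n_samples']} samples)")
    samples = data.reshape(int(meta["n_channels"]), int(meta["n_samples"]))
    return Recording(samples=samples, fs=float(meta["fs"]),
                     channel_labels=meta["channel_labels"],
                     subject_id=meta["subject_id"], group=meta["group"])


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError("EDF support requires the 'mne' package "
                          "(install lfpac[edf])") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    samples = raw.get_data()
    if np.isnan(samples).any():
        raise ValueError(f"{path}: EDF data contains NaN samples")
    return Recording(samples=samples, fs=float(raw.info["sfreq"]),
                     channel_labels=list(raw.ch_names),
                     subject_id=path.stem, group="")


@dataclass
class ResultTable:
    """Tidy table of derived metrics keyed by (group, subject, channel, metric, band).

    ``channel`` is a string channel label or ``"avg"`` for the channel-averaged
    subject-level value.  ``band`` holds a band name or a band pair such as
    ``"theta-low_gamma"``.  Values must be finite and keys unique.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.df, columns=list(TABLE_COLUMNS))
        if list(df.columns) != list(TABLE_COLUMNS):
            raise ValueError(f"result table must have columns {TABLE_COLUMNS}")
        if len(df) and not np.isfinite(df["value"].to_numpy(dtype=float)).all():
            raise ValueError("result table contains non-finite values")
        keys = df[list(TABLE_COLUMNS[:-1])]
        if len(df) and keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate result-table key: {dup}")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_rows(cls, rows: Sequence[Mapping]) -> "ResultTable":
        return cls(pd.DataFrame(list(rows), columns=list(TABLE_COLUMNS)))

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResultTable):
            return NotImplemented
        return self.df.equals(other.df)


def write_table(table: ResultTable, path: str | Path) -> None:
    """Write a result table as comma-delimited text with the fixed header."""
    ResultTable(table.df)  # re-validate (finiteness, key uniqueness)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(path, index=False)


def read_table(path: str | Path) -> ResultTable:
    df = pd.read_csv(path, dtype={"group": str, "subject": str, "channel": str,
                                  "metric": str, "band": str})
    if list(df.columns) != list(TABLE_COLUMNS):
        raise ValueError(f"{path}: malformed header {list(df.columns)}, "
                         f"expected {list(TABLE_COLUMNS)}")
    return ResultTable(df)
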