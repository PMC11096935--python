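"""Reading and writing multichannel neuromonitoring recordings and analysis outputs.

The canonical on-disk format is a CSV with a two-line header: line one carries
the column names (``time,icp,abp,cbfv``), line two the per-column units with
the sampling rate embedded in the time column's unit cell (``s[fs=50]``).
An HDF5 container (one dataset per channel, ``fs``/``unit`` attributes) is
provided for long recordings.  Time is implicit (index / fs); an explicit time
column is validated for uniformity and then discarded.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "Recording",
    "FormatError",
    "read_recording",
    "write_recording",
    "write_results",
]

CHANNELS = ("icp", "abp", "cbfv")
DEFAULT_UNITS = {"icp": "mmHg", "abp": "mmHg", "cbfv": "cm/s"}


class FormatError(ValueError):
    """Raised when an on-disk recording violates the expected layout."""


@dataclass
class TimeSeries:
    """A uniformly sampled single-channel signal.

    Parameters
    ----------
    samples : array of float
        Sample values in the channel's physical unit.
    fs : float
        Sampling rate in Hz (> 0).
    unit : str
        Physical unit label, e.g. ``"mmHg"``.
    label : str
        Channel label, e.g. ``"icp"``.
    """

    samples: np.ndarray
    fs: float
    unit: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Total span covered by the samples, in seconds."""
        return len(self) / self.fs

    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.fs

    def copy(self) -> "TimeSeries":
        return replace(self, samples=self.samples.copy())


@dataclass
class Recording:
    """Synchronized ICP / ABP / CBFV channels sharing one sampling grid."""

    icp: TimeSeries
    abp: TimeSeries
    cbfv: TimeSeries
    start_time: float = 0.0

    def __post_init__(self) -> None:
        fs = {c.fs for c in self.channels().values()}
        if len(fs) != 1:
            raise ValueError(f"channels must share one sampling rate, got {fs}")
        ns = {len(c) for c in self.channels().values()}
        if len(ns) != 1:
            raise ValueError(f"channels must share one length, got {ns}")

    def channels(self) -> dict[str, TimeSeries]:
        return {"icp": self.icp, "abp": self.abp, "cbfv": self.cbfv}

    @property
    def fs(self) -> float:
        return self.icp.fs

    @property
    def n_samples(self) -> int:
        return len(self.icp)

    @property
    def duration(self) -> float:
        return self.icp.duration


_FS_RE = re.compile(r"\[fs=([0-9.eE+-]+)\]")


def _parse_unit_cell(cell: str) -> tuple[str, float | None]:
    m = _FS_RE.search(cell)
    fs = float(m.group(1)) if m else None
    return _FS_RE.sub("", cell).strip(), fs


def _read_csv(path: Path) -> Recording:
    with open(path, "r", encoding="utf-8") as fh:
        names_line = fh.readline().strip()
        units_line = fh.readline().strip()
    names = [c.strip().lower() for c in names_line.split(",")]
    unit_cells = [c.strip() for c in units_line.split(",")]
    if len(unit_cells) != len(names):
        raise FormatError("unit header line does not match column names")
    for ch in CHANNELS:
        if ch not in names:
            raise FormatError(f"missing channel column: {ch!r}")
    fs = None
    units: dict[str, str] = {}
    for name, cell in zip(names, unit_cells):
        unit, cell_fs = _parse_unit_cell(cell)
        units[name] = unit
        if cell_fs is not None:
            fs = cell_fs
    df = pd.read_csv(path, skiprows=2, names=names)
    if df.isna().any().any():
        raise FormatError("mismatched column lengths or non-numeric cells")
    if "time" in names:
        t = df["time"].to_numpy(dtype=float)
        if len(t) > 1:
            dt = np.diff(t)
            if fs is None:
                fs = 1.0 / float(np.median(dt))
            if np.any(np.abs(dt - 1.0 / fs) > 0.01 / fs):
                raise FormatError("time column is not uniform at the declared fs")
    if fs is None:
        raise FormatError("sampling rate not declared and no time column present")
    series = {
        ch: TimeSeries(df[ch].to_numpy(dtype=float), fs=fs, unit=units.get(ch, ""), label=ch)
        for ch in CHANNELS
    }
    return Recording(**series)


def _read_hdf5(path: Path) -> Recording:
    series = {}
    with h5py.File(path, "r") as f:
        for ch in CHANNELS:
            if ch not in f:
                raise FormatError(f"missing channel dataset: {ch!r}")
            ds = f[ch]
            series[ch] = TimeSeries(
                np.asarray(ds[...], dtype=float),
                fs=float(ds.attrs["fs"]),
                unit=str(ds.attrs.get("unit", "")),
                label=ch,
            )
        start = float(f.attrs.get("start_time", 0.0))
    try:
        return Recording(**series, start_time=start)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def read_recording(path: str | Path, format_name: str | None = None) -> Recording:
    """Load a three-channel recording from ``path``.

    ``format_name`` is ``"csv"`` or ``"hdf5"``; when omitted it is inferred
    from the file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_name or ("hdf5" if path.suffix in {".h5", ".hdf5"} else "csv")
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "hdf5":
        return _read_hdf5(path)
    raise FormatError(f"unknown format: {fmt!r}")


def write_recording(
    recording: Recording,
    path: str | Path,
    format_name: str | None = None,
    overwrite: bool = False,
) -> None:
    """Write ``recording`` to ``path`` in CSV or HDF5 layout.

    Refuses to overwrite an existing file unless ``overwrite`` is set.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    if recording.n_samples == 0:
        raise ValueError("refusing to write an empty recording")
    fmt = format_name or ("hdf5" if path.suffix in {".h5", ".hdf5"} else "csv")
    if fmt == "csv":
        fs = recording.fs
        t = np.arange(recording.n_samples) / fs
        cols = {"time": t}
        cols.update({ch: s.samples for ch, s in recording.channels().items()})
        units = [f"s[fs={fs:g}]"] + [
            recording.channels()[ch].unit or DEFAULT_UNITS[ch] for ch in CHANNELS
        ]
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(",".join(cols.keys()) + "\n")
            fh.write(",".join(units) + "\n")
            pd.DataFrame(cols).to_csv(fh, index=False, header=False, float_format="%.9g")
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.attrs["start_time"] = recording.start_time
            for ch, s in recording.channels().items():
                ds = f.create_dataset(ch, data=s.samples)
                ds.attrs["fs"] = s.fs
                ds.attrs["unit"] = s.unit or DEFAULT_UNITS[ch]
    else:
        raise FormatError(f"unknown format: {fmt!r}")


def write_results(
    di_records: Iterable,
    summary: Mapping,
    out_dir: str | Path,
    overwrite: bool = True,
) -> tuple[Path, Path]:
    """Write the per-pulse difference-index table and a JSON summary.

    ``di_records`` is a sequence of :class:`icpulse.similarity.DIRecord` (or
    any object with ``wave_id``, ``period_label``, ``onset_time``, ``di`` and
    ``n_compared`` attributes).  Returns the two paths written.
    """
    records = list(di_records)
    if not records:
        raise ValueError("no difference-index records to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "di_records.csv"
    json_path = out_dir / "summary.json"
    if not overwrite and (csv_path.exists() or json_path.exists()):
        raise FileExistsError(f"results already present in {out_dir}")
    df = pd.DataFrame(
        {
            "wave_id": [r.wave_id for r in records],
            "period_label": [r.period_label for r in records],
            "onset_time": [r.onset_time for r in records],
            "di": [r.di for r in records],
            "n_compared": [r.n_compared for r in records],
        }
    )
    df.to_csv(csv_path, index=False, float_format="%.9g")
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return csv_path, json_path


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    return obj
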