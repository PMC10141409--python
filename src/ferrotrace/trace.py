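"""Transmission-trace container and file I/O.

A :class:`Trace` is a uniformly sampled series of transmitted optical
intensity (volts by convention) plus its sampling rate and provenance
metadata.  Traces round-trip losslessly through HDF5 (one group per trace,
float64 ``transmission`` dataset, attributes for rate/units/filter history,
optional ``truth`` group with generator ground truth) and through CSV
(columns ``time_s``, ``transmission_v``, values at 9 significant digits).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["Trace", "FormatError", "read_trace", "write_trace"]


class FormatError(ValueError):
    """Raised when a trace file is malformed or missing required metadata."""


@dataclass
class Trace:
    """Uniformly sampled transmission series.

    Parameters
    ----------
    values : ndarray
        Transmitted signal samples.
    fs : float
        Sampling rate in Hz.
    units : str
        Physical units of ``values`` ("V" by default).
    t0_offset : float
        Time of the first sample in seconds.
    metadata : dict
        Free-form provenance (source, seed, preset name).  The key
        ``filter_history`` is a list that preprocessing steps append to and
        never overwrite.
    """

    values: np.ndarray
    fs: float
    units: str = "V"
    t0_offset: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite samples")
        self.metadata.setdefault("filter_history", [])

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        return len(self.values) / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0_offset + np.arange(len(self.values)) / self.fs

    def with_values(self, values: np.ndarray, *, fs: float | None = None,
                    history_entry: str | None = None) -> "Trace":
        """Copy of this trace with new samples and an appended history entry."""
        meta = dict(self.metadata)
        meta["filter_history"] = list(meta.get("filter_history", []))
        if history_entry is not None:
            meta["filter_history"].append(history_entry)
        return replace(self, values=np.asarray(values, dtype=np.float64),
                       fs=self.fs if fs is None else fs, metadata=meta)

    def crop(self, t_start: float, t_end: float) -> "Trace":
        """Sub-trace covering ``[t_start, t_end)`` in absolute seconds."""
        i0 = max(0, int(round((t_start - self.t0_offset) * self.fs)))
        i1 = min(len(self.values), int(round((t_end - self.t0_offset) * self.fs)))
        if i1 <= i0:
            raise ValueError("empty crop interval")
        out = replace(self, values=self.values[i0:i1].copy(),
                      t0_offset=self.t0_offset + i0 / self.fs,
                      metadata=dict(self.metadata))
        return out


# ---------------------------------------------------------------------------
# HDF5 layout: group (default "trace") with dataset "transmission" (float64),
# attrs fs / units / t0_offset / filter_history (JSON) / metadata (JSON);
# optional subgroup "truth" holding occupancy, gating_state, boundaries,
# position as datasets.
# ---------------------------------------------------------------------------

_H5_GROUP = "trace"


def write_trace(trace: Trace, path: str | Path, format: str | None = None,
                truth: dict[str, np.ndarray] | None = None) -> None:
    """Write a trace to HDF5 or CSV.

    ``format`` defaults from the file suffix (.h5/.hdf5 vs .csv).  ``truth``
    (ground-truth channels of a synthetic trace) is stored only by HDF5.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            g = f.create_group(_H5_GROUP)
            g.create_dataset("transmission", data=trace.values, dtype="f8")
            g.attrs["fs"] = float(trace.fs)
            g.attrs["units"] = trace.units
            g.attrs["t0_offset"] = float(trace.t0_offset)
            meta = {k: v for k, v in trace.metadata.items() if k != "filter_history"}
            g.attrs["metadata"] = json.dumps(meta, default=str)
            g.attrs["filter_history"] = json.dumps(trace.metadata.get("filter_history", []))
            if truth:
                tg = g.create_group("truth")
                for key, arr in truth.items():
                    tg.create_dataset(key, data=np.asarray(arr))
    elif fmt == "csv":
        df = pd.DataFrame({"time_s": trace.times(), "transmission_v": trace.values})
        df.to_csv(path, index=False, float_format="%.9g")
    else:  # pragma: no cover - guarded by _infer_format
        raise FormatError(f"unknown format {fmt!r}")


def read_trace(path: str | Path, format: str | None = None,
               fs: float | None = None) -> Trace:
    """Read a trace from HDF5 or CSV.

    CSV needs either a ``time_s`` column with uniform spacing (relative
    tolerance 1e-6) or an explicit ``fs``.  HDF5 ground truth, if present,
    is exposed under ``trace.metadata["truth"]``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if _H5_GROUP not in f:
                raise FormatError(f"no '{_H5_GROUP}' group in {path}")
            g = f[_H5_GROUP]
            if "fs" not in g.attrs:
                raise FormatError(f"missing fs attribute in {path}")
            meta = json.loads(g.attrs.get("metadata", "{}"))
            meta["filter_history"] = json.loads(g.attrs.get("filter_history", "[]"))
            trace = Trace(values=g["transmission"][...], fs=float(g.attrs["fs"]),
                          units=str(g.attrs.get("units", "V")),
                          t0_offset=float(g.attrs.get("t0_offset", 0.0)),
                          metadata=meta)
            if "truth" in g:
                trace.metadata["truth"] = {k: g["truth"][k][...] for k in g["truth"]}
            return trace
    if fmt == "csv":
        df = pd.read_csv(path)
        if "transmission_v" not in df.columns:
            raise FormatError("CSV must have a 'transmission_v' column")
        values = df["transmission_v"].to_numpy(dtype=np.float64)
        t0 = 0.0
        if fs is None:
            if "time_s" not in df.columns:
                raise FormatError("CSV without 'time_s' column requires explicit fs")
            t = df["time_s"].to_numpy(dtype=np.float64)
            if len(t) < 2:
                raise FormatError("CSV too short to infer sampling rate")
            dt = np.diff(t)
            if np.max(np.abs(dt - dt[0])) > 1e-6 * abs(dt[0]):
                raise FormatError("non-uniform time column; cannot infer fs")
            fs = 1.0 / dt[0]
            t0 = float(t[0])
        return Trace(values=values, fs=float(fs), t0_offset=t0,
                     metadata={"source": str(path)})
    raise FormatError(f"unknown format {fmt!r}")  # pragma: no cover


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
        if fmt in ("h5", "hdf5"):
            return "hdf5"
        if fmt == "csv":
            return "csv"
        raise FormatError(f"unsupported format {format!r}")
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    if suffix == ".csv":
        return "csv"
    raise FormatError(f"cannot infer format from suffix {suffix!r}")
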