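"""Session container I/O.

HDF5 layout::

    /speed          data + attrs rate_hz, units, t0
    /lfp            data + attrs rate_hz, units, t0
    /ca/<cell_id>   data + attrs rate_hz, units, t0
    /truth/epochs   state, t_start_s, t_end_s columns (optional)
    /truth/ripples  ripple table columns (optional)
    /truth/spikes/<cell_id>  spike times + attr cell_class (optional)

Single traces can also be read from delimited text with a ``t_s,value``
header; the sampling rate is inferred from the timestamps, which must be
uniform.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import RegularTimeSeries
from .synth.session import SyntheticSession

_TRACE_ATTRS = ("rate_hz", "units", "t0")


def _write_trace(group: h5py.Group, name: str, ts: RegularTimeSeries) -> None:
    g = group.create_group(name)
    g.create_dataset("data", data=ts.data)
    g.attrs["rate_hz"] = ts.rate_hz
    g.attrs["units"] = ts.units
    g.attrs["t0"] = ts.t0


def _read_trace(group: h5py.Group, name: str) -> RegularTimeSeries:
    if name not in group:
        raise KeyError(f"session container is missing group '/{name}'")
    g = group[name]
    if "data" not in g:
        raise KeyError(f"group '/{name}' is missing the 'data' dataset")
    for attr in _TRACE_ATTRS:
        if attr not in g.attrs:
            raise KeyError(f"group '/{name}' is missing the '{attr}' attribute")
    return RegularTimeSeries(
        g["data"][...],
        rate_hz=float(g.attrs["rate_hz"]),
        t0=float(g.attrs["t0"]),
        units=str(g.attrs["units"]),
        name=name.split("/")[-1],
    )


def _write_frame(group: h5py.Group, name: str, df: pd.DataFrame) -> None:
    g = group.create_group(name)
    for col in df.columns:
        values = df[col].to_numpy()
        if values.dtype == object or values.dtype.kind in "US":
            values = np.array([str(v).encode() for v in values])
        g.create_dataset(col, data=values)
    g.attrs["columns"] = ",".join(df.columns)


def _read_frame(group: h5py.Group, name: str) -> pd.DataFrame:
    g = group[name]
    cols = str(g.attrs["columns"]).split(",") if g.attrs.get("columns") else list(g)
    data = {}
    for col in cols:
        values = g[col][...]
        if values.dtype.kind == "S":
            values = np.array([v.decode() for v in values])
        data[col] = values
    return pd.DataFrame(data)


def write_session(path: str | Path, session: SyntheticSession) -> None:
    """Write a session (signals + truth tables) to an HDF5 container."""
    with h5py.File(path, "w") as f:
        _write_trace(f, "speed", session.speed)
        if session.lfp is not None:
            _write_trace(f, "lfp", session.lfp)
        ca = f.create_group("ca")
        for ts in session.ca_traces:
            _write_trace(ca, ts.name, ts)
        truth = session.truth or {}
        tg = f.create_group("truth")
        if "epochs" in truth:
            _write_frame(tg, "epochs", truth["epochs"])
        if "ripples" in truth and len(truth["ripples"]):
            _write_frame(tg, "ripples", truth["ripples"])
        if "spikes" in truth:
            sg = tg.create_group("spikes")
            for cell_id, times in truth["spikes"].items():
                d = sg.create_dataset(cell_id, data=np.asarray(times, dtype=float))
                d.attrs["cell_class"] = truth.get("labels", {}).get(cell_id, "")


def read_session(path: str | Path) -> SyntheticSession:
    """Read a session container; raises naming any missing group/attribute."""
    with h5py.File(path, "r") as f:
        speed = _read_trace(f, "speed")
        lfp = _read_trace(f, "lfp") if "lfp" in f else None
        ca = []
        if "ca" in f:
            for name in sorted(f["ca"]):
                ca.append(_read_trace(f["ca"], name))
        truth: dict = {}
        if "truth" in f:
            tg = f["truth"]
            if "epochs" in tg:
                truth["epochs"] = _read_frame(tg, "epochs")
            if "ripples" in tg:
                truth["ripples"] = _read_frame(tg, "ripples")
            if "spikes" in tg:
                truth["spikes"] = {k: tg["spikes"][k][...] for k in tg["spikes"]}
                truth["labels"] = {
                    k: str(tg["spikes"][k].attrs.get("cell_class", ""))
                    for k in tg["spikes"]
                }
    return SyntheticSession(speed=speed, lfp=lfp, ca_traces=ca, truth=truth)


def read_trace_csv(path: str | Path, units: str = "") -> RegularTimeSeries:
    """Read a single trace from delimited text with a ``t_s,value`` header.

    The sampling rate is inferred from the timestamps; non-uniform sampling
    is rejected.
    """
    df = pd.read_csv(path)
    if not {"t_s", "value"}.issubset(df.columns):
        raise ValueError("trace CSV must have 't_s' and 'value' columns")
    t = df["t_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("trace CSV must contain at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-4, atol=1e-9):
        raise ValueError("non-uniform timestamps; a regular sampling grid is required")
    return RegularTimeSeries(
        df["value"].to_numpy(dtype=float), rate_hz=1.0 / dt[0], t0=float(t[0]), units=units
    )
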