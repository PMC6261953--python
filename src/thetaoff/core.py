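"""Core containers shared by every analysis stage.

The backbone type is :class:`RegularTimeSeries`: a uniformly sampled signal
with an explicit sampling rate, start time and unit string. All pipeline
stages (behaviour segmentation, dF/F, LFP filtering, sweep analysis) operate
on this container rather than on bare arrays so that time bookkeeping is done
once, here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class RegularTimeSeries:
    """A uniformly sampled signal.

    Parameters
    ----------
    data
        Sample values, one-dimensional.
    rate_hz
        Sampling rate in Hz; must be positive.
    t0
        Time of the first sample in seconds (default 0).
    units
        Unit string, e.g. ``"cm/s"``, ``"mV"``, ``"%dF/F"``.
    name
        Optional identifier (cell id, channel name).
    """

    data: np.ndarray
    rate_hz: float
    t0: float = 0.0
    units: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1:
            raise ValueError("RegularTimeSeries data must be one-dimensional")
        if not np.isfinite(self.rate_hz) or self.rate_hz <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate_hz}")

    def __len__(self) -> int:
        return self.data.size

    @property
    def dt(self) -> float:
        return 1.0 / self.rate_hz

    @property
    def duration(self) -> float:
        """Total covered time in seconds (n samples x dt)."""
        return self.data.size / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.size) / self.rate_hz

    def index_at(self, t: float) -> int:
        """Index of the sample whose bin contains time ``t``."""
        return int(np.floor((t - self.t0) * self.rate_hz + 1e-9))

    def slice_time(self, t_start: float, t_end: float) -> "RegularTimeSeries":
        """Sub-series covering ``[t_start, t_end)``; bounds clipped to the trace."""
        if t_end <= t_start:
            raise ValueError("t_end must exceed t_start")
        i0 = max(self.index_at(t_start), 0)
        i1 = min(self.index_at(t_end), self.data.size)
        return replace(self, data=self.data[i0:i1], t0=self.t0 + i0 / self.rate_hz)

    def copy_with(self, data: np.ndarray, **kwargs) -> "RegularTimeSeries":
        return replace(self, data=np.asarray(data, dtype=float), **kwargs)

    def interp(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation of the signal at arbitrary times."""
        return np.interp(t, self.times, self.data)


def states_to_epochs(states: np.ndarray, rate_hz: float, t0: float = 0.0):
    """Convert a per-sample integer/str label array into (label, t_start, t_end) runs.

    Epoch boundaries fall on sample-bin edges so that the returned epochs tile
    ``[t0, t0 + n/rate]`` exactly.
    """
    states = np.asarray(states)
    if states.size == 0:
        return []
    change = np.flatnonzero(states[1:] != states[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [states.size]))
    return [
        (states[i0], t0 + i0 / rate_hz, t0 + i1 / rate_hz)
        for i0, i1 in zip(starts, ends)
    ]
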