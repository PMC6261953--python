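"""Behavioural state segmentation of a wheel-speed trace.

Three states are distinguished on the instantaneous speed signal:

* **locomotion** — maximal runs with speed above 2 cm/s whose integrated
  distance is at least 2 cm (walking and running pooled);
* **flickering** — runs above 0.25 cm/s that fail the locomotion criterion
  (too slow or covering less than the minimum distance); brief transitional
  movements, flagged for exclusion from activity analysis;
* **immobility** — everything else (no wheel rotation, with a small numeric
  tolerance for real encoders).

Epochs are non-overlapping, ordered and tile the whole trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import RegularTimeSeries

LOCOMOTION = "locomotion"
IMMOBILITY = "immobility"
FLICKERING = "flickering"


@dataclass
class SegmentationParams:
    locomotion_speed_cm_s: float = 2.0
    locomotion_min_distance_cm: float = 2.0
    flicker_speed_cm_s: float = 0.25
    min_epoch_gap_s: float = 0.0
    median_filter_s: float = 0.0  # optional pre-smoothing, off by default

    def __post_init__(self) -> None:
        if self.flicker_speed_cm_s >= self.locomotion_speed_cm_s:
            raise ValueError("flicker threshold must be below the locomotion threshold")
        for name in (
            "locomotion_speed_cm_s",
            "locomotion_min_distance_cm",
            "flicker_speed_cm_s",
            "min_epoch_gap_s",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class BehaviorEpoch:
    state: str
    t_start_s: float
    t_end_s: float
    distance_cm: float

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s


@dataclass
class BehaviorSegmentation:
    """Ordered epochs tiling the trace; flickering epochs listed in ``excluded``."""

    epochs: list[BehaviorEpoch]
    excluded: list[BehaviorEpoch] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "state": e.state,
                "t_start_s": e.t_start_s,
                "t_end_s": e.t_end_s,
                "distance_cm": e.distance_cm,
                "excluded": e.state == FLICKERING,
            }
            for e in self.epochs
        ]
        return pd.DataFrame(
            rows, columns=["state", "t_start_s", "t_end_s", "distance_cm", "excluded"]
        )

    def by_state(self, state: str) -> list[BehaviorEpoch]:
        return [e for e in self.epochs if e.state == state]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BehaviorSegmentation":
        epochs = [
            BehaviorEpoch(
                state=row["state"],
                t_start_s=float(row["t_start_s"]),
                t_end_s=float(row["t_end_s"]),
                distance_cm=float(row.get("distance_cm", np.nan)),
            )
            for _, row in df.iterrows()
        ]
        return cls(epochs, [e for e in epochs if e.state == FLICKERING])


def epoch_distance(speed: RegularTimeSeries, t_start_s: float, t_end_s: float) -> float:
    """Distance covered in ``[t_start, t_end]``: trapezoidal integral of speed (cm)."""
    if t_end_s <= t_start_s:
        raise ValueError("t_end must exceed t_start")
    t0, t1 = speed.t0, speed.t0 + speed.duration
    if t_start_s < t0 - speed.dt / 2 or t_end_s > t1 + speed.dt / 2:
        raise ValueError("epoch extends outside the speed trace")
    sub = speed.slice_time(t_start_s, t_end_s)
    if len(sub) < 2:
        return float(sub.data.sum()) * speed.dt
    return float(np.trapezoid(sub.data, dx=speed.dt))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[i0, i1) index runs where mask is True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def segment_states(
    speed: RegularTimeSeries, params: SegmentationParams | None = None
) -> BehaviorSegmentation:
    """Segment a speed trace into locomotion / flickering / immobility epochs.

    Candidate runs are maximal runs of samples above the flicker threshold.
    A run is locomotion when its speed exceeds the locomotion threshold and
    its integrated distance reaches the configured minimum; otherwise it is
    flickering. Remaining samples are immobility.
    """
    params = params or SegmentationParams()
    if len(speed) == 0:
        raise ValueError("empty speed trace")
    data = speed.data
    if (data < 0).any():
        warnings.warn("negative speed samples clipped to zero", stacklevel=2)
        data = np.clip(data, 0, None)
    if params.median_filter_s > 0:
        from scipy.signal import medfilt

        k = int(round(params.median_filter_s * speed.rate_hz)) | 1
        data = medfilt(data, k)
    fs, dt = speed.rate_hz, speed.dt

    labels = np.full(data.size, IMMOBILITY, dtype=object)
    moving = data > params.flicker_speed_cm_s
    for i0, i1 in _runs(moving):
        run = data[i0:i1]
        # locomotion sub-runs inside this moving run
        fast = run > params.locomotion_speed_cm_s
        claimed = np.zeros(run.size, dtype=bool)
        for j0, j1 in _runs(fast):
            dist = float(np.trapezoid(run[j0:j1], dx=dt)) if j1 - j0 > 1 else run[j0] * dt
            if dist >= params.locomotion_min_distance_cm:
                labels[i0 + j0 : i0 + j1] = LOCOMOTION
                claimed[j0:j1] = True
        labels[i0:i1][~claimed] = FLICKERING

    # optional merge of same-state runs separated by short gaps
    if params.min_epoch_gap_s > 0:
        max_gap = int(round(params.min_epoch_gap_s * fs))
        runs = _label_runs(labels)
        for k in range(1, len(runs) - 1):
            s_prev, s_gap, s_next = runs[k - 1][0], runs[k][0], runs[k + 1][0]
            i0, i1 = runs[k][1], runs[k][2]
            if s_prev == s_next != s_gap and i1 - i0 <= max_gap:
                labels[i0:i1] = s_prev
        runs = None

    epochs = []
    for state, i0, i1 in _label_runs(labels):
        t_start = speed.t0 + i0 / fs
        t_end = speed.t0 + i1 / fs
        seg = data[i0:i1]
        dist = float(np.trapezoid(seg, dx=dt)) if seg.size > 1 else float(seg.sum()) * dt
        epochs.append(BehaviorEpoch(state, t_start, t_end, dist))
    excluded = [e for e in epochs if e.state == FLICKERING]
    return BehaviorSegmentation(epochs, excluded)


def _label_runs(labels: np.ndarray) -> list[tuple[str, int, int]]:
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [(labels[i0], int(i0), int(i1)) for i0, i1 in zip(starts, ends)]
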