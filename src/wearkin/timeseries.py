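"""Uniformly sampled multichannel time series and the CSV dialect shared by all pipelines.

Every sampled signal in the toolkit — goniometer resistance differences, scapular
strain, raw EMG, knee angles, segment orientations — travels through one of two
containers:

``TimeSeries``
    named real-valued channels on a common uniform time base.
``OrientationStream``
    a unit-quaternion-per-sample orientation of one body segment in a common
    world frame (scalar-first convention, right-handed frames, world z up).

Files are comma-delimited UTF-8 with a mandatory header row whose first column
is ``time_s``.  Floats are written with full ``repr`` precision so that a
write/read round trip is loss-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "TimeSeries",
    "OrientationStream",
    "read_timeseries",
    "write_timeseries",
    "read_orientation",
    "write_orientation",
]

#: absolute tolerance (s) on the deviation of each time step from 1/rate
DT_TOL = 1e-9

#: absolute tolerance on |‖q‖ − 1| for orientation samples
QUAT_NORM_TOL = 1e-9


def _uniform_time_check(t: np.ndarray, rate_hz: float) -> None:
    if rate_hz <= 0:
        raise ValueError("rate_hz must be > 0")
    if t.ndim != 1:
        raise ValueError("time vector must be one-dimensional")
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time not monotone")
        if np.max(np.abs(dt - 1.0 / rate_hz)) >= DT_TOL:
            raise ValueError("non-uniform sampling: time steps deviate from 1/rate_hz")


@dataclass
class TimeSeries:
    """Uniformly sampled multichannel record.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, monotone increasing with uniform step 1/``rate_hz``.
    channels : dict of str -> array
        Named channels, each the same length as ``t``.
    rate_hz : float
        Sampling rate in Hz.
    """

    t: np.ndarray
    channels: dict[str, np.ndarray] = field(default_factory=dict)
    rate_hz: float = 1.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        _uniform_time_check(self.t, self.rate_hz)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name, values in self.channels.items():
            if values.shape != self.t.shape:
                raise ValueError(f"channel {name!r} length differs from time vector")

    @classmethod
    def from_rate(
        cls, rate_hz: float, channels: dict[str, np.ndarray], t0: float = 0.0
    ) -> "TimeSeries":
        """Build a series on the canonical time grid t0 + i/rate."""
        lengths = {len(np.asarray(v)) for v in channels.values()}
        if len(lengths) > 1:
            raise ValueError("channels have unequal lengths")
        n = lengths.pop() if lengths else 0
        t = t0 + np.arange(n) / rate_hz
        return cls(t=t, channels=channels, rate_hz=rate_hz)

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.n > 1 else 0.0

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"channel absent: {name}")
        return self.channels[name]

    def single(self) -> np.ndarray:
        """Return the data of the only channel; error if not exactly one."""
        if len(self.channels) != 1:
            raise ValueError("expected exactly one channel")
        return next(iter(self.channels.values()))


@dataclass
class OrientationStream:
    """Orientation of one segment frame in the common world frame.

    Quaternions are scalar-first ``(w, x, y, z)``, one unit quaternion per
    sample.  Frames are right-handed; the world z axis points up (craniocaudal
    for a standing subject).
    """

    t: np.ndarray
    q: np.ndarray
    segment_id: str = ""
    rate_hz: float = 1.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        _uniform_time_check(self.t, self.rate_hz)
        if self.q.ndim != 2 or self.q.shape != (len(self.t), 4):
            raise ValueError("quaternion array must have shape (n_samples, 4)")
        norms = np.linalg.norm(self.q, axis=1)
        if np.any(np.abs(norms - 1.0) > QUAT_NORM_TOL):
            raise ValueError("non-unit quaternion in orientation stream")

    @property
    def n(self) -> int:
        return len(self.t)

    def as_rotation(self) -> Rotation:
        """Scipy Rotation view (converts from scalar-first storage)."""
        return Rotation.from_quat(self.q[:, [1, 2, 3, 0]])

    @classmethod
    def from_rotation(
        cls, t: np.ndarray, rot: Rotation, rate_hz: float, segment_id: str = ""
    ) -> "OrientationStream":
        q_xyzw = rot.as_quat()
        if q_xyzw.ndim == 1:
            q_xyzw = q_xyzw[None, :]
        q = q_xyzw[:, [3, 0, 1, 2]]
        return cls(t=np.asarray(t, float), q=q, segment_id=segment_id, rate_hz=rate_hz)


def _infer_rate(t: np.ndarray) -> float:
    if len(t) < 2:
        return 1.0
    return 1.0 / float(np.median(np.diff(t)))


def read_timeseries(path, spec: list[str] | None = None) -> TimeSeries:
    """Read a delimited time-series file.

    Parameters
    ----------
    path : path-like
        CSV file whose header starts with ``time_s``.
    spec : list of channel names, optional
        Channels to load.  A listed channel missing from the file raises
        ``KeyError``; with ``spec=None`` all columns are loaded.
    """
    df = pd.read_csv(path)
    if len(df.columns) == 0 or df.columns[0] != "time_s":
        raise ValueError("first column must be time_s")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("time not monotone")
    rate = _infer_rate(t)
    names = list(df.columns[1:]) if spec is None else list(spec)
    channels: dict[str, np.ndarray] = {}
    for name in names:
        if name not in df.columns:
            raise KeyError(f"channel absent: {name}")
        channels[name] = df[name].to_numpy(dtype=float)
    return TimeSeries(t=t, channels=channels, rate_hz=rate)


def write_timeseries(series: TimeSeries, path) -> None:
    """Write a series in the shared CSV dialect at full float precision."""
    df = pd.DataFrame({"time_s": series.t, **series.channels})
    df.to_csv(path, index=False)


_QUAT_COLS = ["qw", "qx", "qy", "qz"]


def read_orientation(path, segment_id: str = "") -> OrientationStream:
    """Read an orientation CSV with columns time_s,qw,qx,qy,qz."""
    ts = read_timeseries(path, spec=_QUAT_COLS)
    q = np.column_stack([ts[c] for c in _QUAT_COLS])
    return OrientationStream(t=ts.t, q=q, segment_id=segment_id, rate_hz=ts.rate_hz)


def write_orientation(stream: OrientationStream, path) -> None:
    channels = {c: stream.q[:, i] for i, c in enumerate(_QUAT_COLS)}
    write_timeseries(
        TimeSeries(t=stream.t, channels=channels, rate_hz=stream.rate_hz), path
    )
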