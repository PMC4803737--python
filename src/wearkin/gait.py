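"""Knee flexion-extension from an IMU pair and sensor-redundancy testing.

The thigh/shank IMU pair measures the knee flexion-extension angle through the
relative rotation ``R_rel = R_thighᵀ·R_shank``; the textile knee goniometer
measures the same quantity after its two-point calibration (0° at full
extension).  If the two channels carry the same information, one of them is
redundant and can be dropped from the sensor set.

Equivalence is quantified by two statistics of the difference
``d(t) = θ_IMU(t) − θ_g(t)`` over an analysis window [t0, t1]:

    X     = time-average of d          (mean difference, deg)
    sigma = sqrt(time-average of d²)   (RMS difference, deg)

discretized with the rectangle rule at the sampling rate, followed by a
one-sample Student t-test of the difference against zero mean.  The null
hypothesis "the two sensors measure the same population" is *verified* when
p > alpha.  Consecutive samples of a movement trace are strongly
autocorrelated, which inflates the naive full-rate test; by default the
difference is decimated to one sample per 0.5 s (approximately independent
samples) before testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.transform import Rotation

from .timeseries import OrientationStream, TimeSeries

__all__ = [
    "RedundancyReport",
    "knee_angle_from_imus",
    "redundancy_stats",
    "redundancy_ttest",
]


@dataclass
class RedundancyReport:
    """Sensor-equivalence test outcome for one activity."""

    X: float
    sigma: float
    t: float
    p: float
    verified: bool
    t0: float
    t1: float
    n_test: int


def knee_angle_from_imus(
    q_thigh: OrientationStream, q_shank: OrientationStream
) -> TimeSeries:
    """Knee flexion-extension angle (deg) from the thigh/shank orientation pair.

    Returns the rotation-angle magnitude of ``R_thighᵀ·R_shank``: 0° at full
    extension, equal to the hinge angle for pure flexion about the
    medio-lateral axis, and invariant to any constant mounting rotation applied
    identically to both sensors.
    """
    if q_thigh.n != q_shank.n:
        raise ValueError("orientation streams have mismatched lengths")
    r_rel = q_thigh.as_rotation().inv() * q_shank.as_rotation()
    angle = np.rad2deg(np.linalg.norm(r_rel.as_rotvec(), axis=1))
    return TimeSeries(
        t=q_thigh.t, channels={"knee_deg": angle}, rate_hz=q_thigh.rate_hz
    )


def _aligned_diff(theta_imu: TimeSeries, theta_g: TimeSeries, window):
    a = theta_imu.single()
    b = theta_g.single()
    if len(a) != len(b):
        raise ValueError("angle series have mismatched lengths")
    t = theta_imu.t
    if window is None:
        mask = np.ones(len(t), dtype=bool)
        t0, t1 = float(t[0]), float(t[-1])
    else:
        t0, t1 = float(window[0]), float(window[1])
        mask = (t >= t0) & (t <= t1)
    if not mask.any():
        raise ValueError("empty analysis window")
    return a[mask] - b[mask], t0, t1


def redundancy_stats(
    theta_imu: TimeSeries, theta_g: TimeSeries, window=None
) -> tuple[float, float]:
    """Mean difference X and RMS difference sigma over the window (deg)."""
    d, _, _ = _aligned_diff(theta_imu, theta_g, window)
    return float(np.mean(d)), float(np.sqrt(np.mean(d**2)))


def redundancy_ttest(
    theta_imu: TimeSeries,
    theta_g: TimeSeries,
    window=None,
    alpha: float = 0.05,
    decimate_s: float | None = 0.5,
) -> RedundancyReport:
    """Student t-test of sensor equivalence on the (decimated) difference.

    ``decimate_s`` subsamples the difference to one sample per that many
    seconds before testing (None tests every sample — valid only when samples
    are independent).  A zero-variance difference is handled by convention:
    identically zero → verified with t = 0; constant nonzero → t infinite,
    not verified.
    """
    d, t0, t1 = _aligned_diff(theta_imu, theta_g, window)
    x_stat = float(np.mean(d))
    sigma = float(np.sqrt(np.mean(d**2)))

    if decimate_s is not None:
        step = max(1, int(round(decimate_s * theta_imu.rate_hz)))
        d_test = d[::step]
    else:
        d_test = d
    if len(d_test) < 2:
        raise ValueError("need at least two samples in the test window")

    if np.ptp(d_test) == 0.0:
        if d_test[0] == 0.0:
            t_val, p_val = 0.0, 1.0
        else:
            t_val, p_val = np.inf * np.sign(d_test[0]), 0.0
    else:
        t_val, p_val = stats.ttest_1samp(d_test, 0.0)
        t_val, p_val = float(t_val), float(p_val)

    return RedundancyReport(
        X=x_stat, sigma=sigma, t=t_val, p=p_val,
        verified=bool(p_val > alpha), t0=t0, t1=t1, n_test=len(d_test),
    )
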