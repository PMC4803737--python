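"""Surface EMG conditioning: band-pass, rectification, MVC normalization, envelope, SNR.

The processing chain mirrors the standard deltoid-monitoring protocol:

1. subtract the mean,
2. 2nd-order Butterworth high-pass at 10 Hz,
3. 2nd-order Butterworth low-pass at 300 Hz,
4. rectify (absolute value),
5. normalize by the maximum-voluntary-contraction (MVC) level,
6. envelope with a 2nd-order Butterworth low-pass at 6 Hz.

All filters are applied forward-backward (zero-phase) since the analyses are
offline; corner frequencies are kept at their nominal values, so the effective
attenuation order doubles.  The MVC level is the largest RMS of the active 6-s
window over the recorded MVC trials, each trial following the fixed
2 s rest / 6 s contraction / 2 s rest timing.  Signal quality is summarized as

    SNR_dB = 20·log10(RMS_signal / RMS_baseline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .timeseries import TimeSeries

__all__ = [
    "EMGConfig",
    "MVCResult",
    "preprocess",
    "envelope",
    "mvc_level",
    "mvc_normalize",
    "rms",
    "snr_db",
]


@dataclass(frozen=True)
class EMGConfig:
    """Filter corners (Hz) and order of the EMG chain."""

    fs: float = 1000.0
    hp_cut: float = 10.0
    lp_cut: float = 300.0
    env_cut: float = 6.0
    order: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.hp_cut < self.lp_cut):
            raise ValueError("need 0 < hp_cut < lp_cut")
        if self.fs <= 2 * self.lp_cut:
            raise ValueError(
                f"sampling rate {self.fs} Hz violates Nyquist for the "
                f"{self.lp_cut} Hz low-pass (need fs > {2 * self.lp_cut} Hz)"
            )
        if self.env_cut >= self.fs / 2:
            raise ValueError("envelope cutoff must be below Nyquist")


@dataclass
class MVCResult:
    """Normalization constant and the per-trial active-window RMS values."""

    mvc_level: float
    trial_rms: np.ndarray


def _data(x, channel: str | None = None) -> np.ndarray:
    if isinstance(x, TimeSeries):
        return x[channel] if channel is not None else x.single()
    return np.asarray(x, dtype=float)


def _like(ts: TimeSeries, values: np.ndarray, name: str) -> TimeSeries:
    return TimeSeries(t=ts.t, channels={name: values}, rate_hz=ts.rate_hz)


def _filtfilt(x: np.ndarray, cut: float, btype: str, cfg: EMGConfig) -> np.ndarray:
    sos = sps.butter(cfg.order, cut, btype=btype, fs=cfg.fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def preprocess(raw: TimeSeries, cfg: EMGConfig, channel: str | None = None) -> TimeSeries:
    """Mean-subtract, band-pass (HP then LP, cascaded 2nd-order stages), rectify."""
    x = _data(raw, channel)
    x = x - x.mean()
    x = _filtfilt(x, cfg.hp_cut, "highpass", cfg)
    x = _filtfilt(x, cfg.lp_cut, "lowpass", cfg)
    return _like(raw, np.abs(x), "emg_rect")


def envelope(rectified: TimeSeries, cfg: EMGConfig, channel: str | None = None) -> TimeSeries:
    """Low-pass the rectified signal at the envelope corner (unity DC gain)."""
    x = _data(rectified, channel)
    return _like(rectified, _filtfilt(x, cfg.env_cut, "lowpass", cfg), "emg_env")


def rms(x) -> float:
    """Root mean square, sqrt(mean(x²))."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("RMS of empty signal")
    return float(np.sqrt(np.mean(x**2)))


def mvc_level(
    mvc_trials, cfg: EMGConfig, rest_s: float = 2.0, active_s: float = 6.0
) -> MVCResult:
    """MVC normalization constant from 2/6/2-protocol trials.

    The active window is located by the protocol timing (``rest_s`` seconds of
    rest, ``active_s`` seconds of contraction), not by thresholding.  The level
    is the maximum active-window RMS over trials, computed on the
    mean-subtracted trial.
    """
    if len(mvc_trials) < 1:
        raise ValueError("need at least one MVC trial")
    i0 = int(round(rest_s * cfg.fs))
    i1 = int(round((rest_s + active_s) * cfg.fs))
    values = []
    for trial in mvc_trials:
        x = _data(trial)
        if len(x) < i1:
            raise ValueError("MVC trial shorter than the 2/6/2 protocol window")
        x = x - x.mean()
        values.append(rms(x[i0:i1]))
    trial_rms = np.asarray(values)
    level = float(trial_rms.max())
    if level <= 0:
        raise ValueError("all-zero MVC trials: normalization level undefined")
    return MVCResult(mvc_level=level, trial_rms=trial_rms)


def mvc_normalize(
    signal: TimeSeries, mvc_trials, cfg: EMGConfig, channel: str | None = None
) -> TimeSeries:
    """Divide a signal by the MVC level of the given trials."""
    result = mvc_level(mvc_trials, cfg)
    x = _data(signal, channel) / result.mvc_level
    return _like(signal, x, "emg_norm")


def snr_db(signal, baseline) -> float:
    """Signal-to-noise ratio in dB, 20·log10(RMS_signal / RMS_baseline)."""
    rms_b = rms(_data(baseline))
    if rms_b == 0:
        raise ValueError("undefined SNR: baseline RMS is zero")
    return 20.0 * np.log10(rms(_data(signal)) / rms_b)
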