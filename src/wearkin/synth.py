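"""Seeded generators of synthetic sensor data with the structure the pipelines assume.

Every generator is a pure function of its configuration and seed, so tests and
acceptance runs are reproducible without hardware.  What is emulated:

* ``gen_shoulder`` — the two planar calibration movements (frontal abduction
  0–150°, sagittal flexion 0–120°) under a bi-articular ground truth: the
  gleno-humeral center travels along a configured elliptic arc in proportion to
  the scapular share of the elevation (constant-ratio scapulohumeral rhythm,
  60° of scapular rotation over a 150° abduction by default), while the strain
  channel is an affine function of the scapular angle.  IMU quaternion pairs
  are exactly consistent with the generating angles before noise injection;
  gold-standard positions are the exact trochlea trajectory.
* ``gen_emg`` — band-limited (20–250 Hz) Gaussian noise whose amplitude is
  stepped by a rest/burst schedule, with the ground-truth activation mask.
* ``gen_mvc_trial`` — a 2 s rest / 6 s contraction / 2 s rest trial whose
  active-window RMS is set exactly.
* ``gen_gait`` — periodic knee flexion (raised-cosine stride profile) with a
  thigh/shank IMU pair exactly consistent with the profile and a goniometer
  channel equal to the profile plus configurable bias and noise.
* ``gen_grasp`` — Gaussian samples around pose templates, including a pulp
  pinch / key pinch pair with identical angle means and distinct index-force
  means (the R³-vs-R⁴ contrast).
* ``gen_reach`` — aligned elevation / EMG-envelope / strain traces in the
  physiological, compensatory, or inactive pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy.spatial.transform import Rotation

from .shoulder import (
    ArmAngles,
    CalibrationMovement,
    EllipticArc,
    ShoulderModelParams,
    arm_direction,
    biarticular_position,
)
from .timeseries import OrientationStream, TimeSeries

__all__ = [
    "NoiseModel",
    "ShoulderScenario",
    "ShoulderMovement",
    "ShoulderDataset",
    "GaitDataset",
    "gen_shoulder",
    "gen_emg",
    "gen_mvc_trial",
    "gen_gait",
    "gen_grasp",
    "gen_reach",
    "default_pose_templates",
]


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise SDs per channel.

    Defaults reflect the bench-characterized hardware: sub-degree orientation
    noise for the IMUs, tens of Ω on the strain channel (a small fraction of
    its dynamic range), millimetric optical gold standard, sub-degree
    goniometer noise.
    """

    orient_deg: float = 0.5
    strain_ohm: float = 25.0
    gold_m: float = 0.001
    gonio_deg: float = 0.3
    gonio_bias_deg: float = 0.0
    emg_baseline: float = 0.01


@dataclass(frozen=True)
class ShoulderScenario:
    """Study conditions for the shoulder generator.

    ``rhythm_split`` is the fraction of total elevation contributed by the
    scapular path: 60°/150° = 0.4 for frontal abduction; the sagittal flexion
    split is 60°/120° = 0.5.  ``L`` is the trochlea distance (0.3 m; the full
    arm is ~0.8 m and reachable through the ``rescale`` model option).  Arc
    semi-axes place the humeral-head excursion at the few-centimetre scale of
    scapular sliding.  The strain channel gains ~85 Ω per scapular degree, the
    ΔR scale of the KPF characterization bench.
    """

    rhythm_split: float = 0.4
    flexion_split: float = 0.5
    max_abduction_deg: float = 150.0
    max_flexion_deg: float = 120.0
    L: float = 0.3
    p0: tuple[float, float, float] = (0.0, 0.20, 0.10)
    frontal_arc: tuple[float, float] = (0.05, 0.03)  # (a vertical, b lateral) m
    sagittal_arc: tuple[float, float] = (0.04, 0.025)
    s0_ohm: float = 1000.0
    strain_per_deg: float = 85.0
    duration_s: float = 6.0
    rate_hz: float = 100.0
    trunk_sway_deg: float = 0.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rhythm_split <= 1.0:
            raise ValueError("rhythm_split must lie in [0, 1]")

    def true_params(self) -> ShoulderModelParams:
        """The generating bi-articular parameters."""
        phi_f = self.rhythm_split * self.max_abduction_deg
        phi_s = self.flexion_split * self.max_flexion_deg
        return ShoulderModelParams(
            L=self.L,
            p0=np.asarray(self.p0, float),
            frontal_path=EllipticArc(*self.frontal_arc, phi_max_deg=phi_f),
            sagittal_path=EllipticArc(*self.sagittal_arc, phi_max_deg=phi_s),
            s0=self.s0_ohm,
            strain_gain=np.deg2rad(1.0) / self.strain_per_deg,
        )


@dataclass
class ShoulderMovement:
    """One planar movement: sensors, ground truth, and gold-standard positions."""

    name: str
    q_sternum: OrientationStream
    q_arm: OrientationStream
    strain: TimeSeries
    gold: np.ndarray  # sternum-frame trochlea positions (n, 3)
    gold_world: np.ndarray
    p_sternum: np.ndarray
    angles_true: ArmAngles

    def calibration(self) -> CalibrationMovement:
        return CalibrationMovement(
            angles=self.angles_true, strain=self.strain.single(), gold=self.gold
        )


@dataclass
class ShoulderDataset:
    frontal: ShoulderMovement
    sagittal: ShoulderMovement
    true_params: ShoulderModelParams


def _movement(
    scenario: ShoulderScenario,
    name: str,
    theta_deg: float,
    psi_max: float,
    split: float,
    rng: np.random.Generator,
) -> ShoulderMovement:
    n = int(round(scenario.duration_s * scenario.rate_hz)) + 1
    t = np.arange(n) / scenario.rate_hz
    # half-cosine ramp 0 → psi_max with zero end velocity
    psi = psi_max * 0.5 * (1.0 - np.cos(np.pi * t / scenario.duration_s))
    theta = np.full(n, theta_deg)

    params = scenario.true_params()
    strain_true = scenario.s0_ohm + split * psi * scenario.strain_per_deg
    angles = ArmAngles(t=t, theta_deg=theta, psi_deg=psi, rate_hz=scenario.rate_hz)
    gold = biarticular_position(angles, strain_true, params)

    # sternum orientation: identity or a small sway about the antero-posterior axis
    if scenario.trunk_sway_deg != 0.0:
        sway = scenario.trunk_sway_deg * np.sin(2.0 * np.pi * t / scenario.duration_s)
        r_st = Rotation.from_euler("x", sway[:, None], degrees=True)
    else:
        r_st = Rotation.identity(n)
    # relative arm rotation consistent with (theta, psi) by construction
    r_rel = Rotation.from_euler("z", -theta[:, None], degrees=True) * Rotation.from_euler(
        "x", psi[:, None], degrees=True
    )
    r_arm = r_st * r_rel

    nm = scenario.noise
    if nm.orient_deg > 0.0:
        wobble = Rotation.from_rotvec(
            np.deg2rad(nm.orient_deg) * rng.standard_normal((n, 3))
        )
        r_arm_obs = r_arm * wobble
    else:
        r_arm_obs = r_arm

    p_sternum = np.zeros((n, 3))
    gold_world = r_st.apply(gold) + p_sternum
    gold_obs = gold + nm.gold_m * rng.standard_normal((n, 3))
    strain_obs = strain_true + nm.strain_ohm * rng.standard_normal(n)

    return ShoulderMovement(
        name=name,
        q_sternum=OrientationStream.from_rotation(t, r_st, scenario.rate_hz, "sternum"),
        q_arm=OrientationStream.from_rotation(t, r_arm_obs, scenario.rate_hz, "upper_arm"),
        strain=TimeSeries(t=t, channels={"dR_ohm": strain_obs}, rate_hz=scenario.rate_hz),
        gold=gold_obs,
        gold_world=gold_world,
        p_sternum=p_sternum,
        angles_true=angles,
    )


def gen_shoulder(scenario: ShoulderScenario) -> ShoulderDataset:
    """Generate the two planar calibration movements under bi-articular truth."""
    rng = np.random.default_rng(scenario.seed)
    frontal = _movement(
        scenario, "abduction", 0.0, scenario.max_abduction_deg,
        scenario.rhythm_split, rng,
    )
    sagittal = _movement(
        scenario, "flexion", 90.0, scenario.max_flexion_deg,
        scenario.flexion_split, rng,
    )
    return ShoulderDataset(
        frontal=frontal, sagittal=sagittal, true_params=scenario.true_params()
    )


def _band_noise(n: int, fs: float, band: tuple[float, float], rng) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band`` Hz."""
    white = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    return x / np.sqrt(np.mean(x**2))


def gen_emg(
    duration_s: float,
    bursts,
    fs: float = 1000.0,
    baseline_sd: float = 0.01,
    band: tuple[float, float] = (20.0, 250.0),
    seed: int = 0,
) -> tuple[TimeSeries, np.ndarray]:
    """Raw surface-EMG-like trace plus its ground-truth activation mask.

    ``bursts`` is a list of ``(t_start, t_end, gain)`` tuples; within a burst
    the amplitude is ``gain × baseline_sd``.  Returns the trace and a boolean
    mask that is True inside bursts with gain > 1.
    """
    if fs < 1000.0:
        raise ValueError("EMG generation requires fs >= 1000 Hz")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    carrier = _band_noise(n, fs, band, rng)
    amp = np.full(n, baseline_sd)
    mask = np.zeros(n, dtype=bool)
    for t0, t1, gain in bursts:
        sel = (t >= t0) & (t < t1)
        amp[sel] = gain * baseline_sd
        if gain > 1.0:
            mask[sel] = True
    ts = TimeSeries(t=t, channels={"emg": carrier * amp}, rate_hz=fs)
    return ts, mask


def gen_mvc_trial(
    active_rms: float = 1.0,
    fs: float = 1000.0,
    baseline_sd: float = 0.01,
    band: tuple[float, float] = (20.0, 250.0),
    seed: int = 0,
) -> TimeSeries:
    """A 2/6/2 MVC trial whose 6-s active window has exactly the given RMS."""
    n = int(round(10.0 * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    x = _band_noise(n, fs, band, rng) * baseline_sd
    i0, i1 = int(round(2.0 * fs)), int(round(8.0 * fs))
    active = _band_noise(i1 - i0, fs, band, rng)
    x[i0:i1] = active * (active_rms / np.sqrt(np.mean(active**2)))
    return TimeSeries(t=t, channels={"emg": x}, rate_hz=fs)


@dataclass
class GaitDataset:
    q_thigh: OrientationStream
    q_shank: OrientationStream
    theta_g: TimeSeries
    theta_true: TimeSeries


def gen_gait(
    n_strides: int = 5,
    stride_period_s: float = 1.2,
    amplitude_deg: float = 60.0,
    rate_hz: float = 100.0,
    gonio_sd_deg: float = 0.0,
    gonio_bias_deg: float = 0.0,
    seed: int = 0,
) -> GaitDataset:
    """Periodic knee flexion with a consistent IMU pair and a noisy goniometer.

    The knee profile is ``amplitude·sin²(π t / T)`` per stride (0° at full
    extension).  The thigh stream is the identity; the shank rotates about the
    medio-lateral (y) axis by exactly the profile.  The goniometer channel is
    the profile plus ``gonio_bias_deg`` and iid Gaussian noise.
    """
    if not 0.0 < amplitude_deg < 90.0:
        raise ValueError("amplitude must lie in (0, 90) degrees")
    n = int(round(n_strides * stride_period_s * rate_hz))
    t = np.arange(n) / rate_hz
    theta = amplitude_deg * np.sin(np.pi * t / stride_period_s) ** 2
    rng = np.random.default_rng(seed)
    theta_g = theta + gonio_bias_deg + gonio_sd_deg * rng.standard_normal(n)
    r_thigh = Rotation.identity(n)
    r_shank = Rotation.from_euler("y", theta[:, None], degrees=True)
    return GaitDataset(
        q_thigh=OrientationStream.from_rotation(t, r_thigh, rate_hz, "thigh"),
        q_shank=OrientationStream.from_rotation(t, r_shank, rate_hz, "shank"),
        theta_g=TimeSeries(t=t, channels={"knee_deg": theta_g}, rate_hz=rate_hz),
        theta_true=TimeSeries(t=t, channels={"knee_deg": theta}, rate_hz=rate_hz),
    )


def default_pose_templates(dims: int = 3):
    """Templates for the eight functional grips in goniometer-angle space.

    Grips 2 (pulp pinch) and 7 (key pinch) share identical angle means — they
    are genuinely close in R³ — and differ only in the index-force dimension
    when ``dims=4``.
    """
    from .grasp import PoseTemplate

    angle_means = {
        1: (5.0, 5.0, 5.0),       # open hand
        2: (40.0, 45.0, 30.0),    # pulp pinch
        3: (60.0, 70.0, 65.0),
        4: (75.0, 85.0, 80.0),
        5: (20.0, 60.0, 58.0),
        6: (52.0, 48.0, 70.0),
        7: (40.0, 45.0, 30.0),    # key pinch: same angles as pulp pinch
        8: (30.0, 25.0, 50.0),
    }
    force_means = {1: 0.2, 2: 0.2, 3: 5.0, 4: 8.0, 5: 0.3, 6: 4.0, 7: 12.0, 8: 6.0}
    sd_angle, sd_force = 3.0, 0.15
    templates = []
    for pose_id, mean in angle_means.items():
        if dims == 3:
            templates.append(
                PoseTemplate(pose_id, np.array(mean), np.full(3, sd_angle))
            )
        elif dims == 4:
            templates.append(
                PoseTemplate(
                    pose_id,
                    np.array([*mean, force_means[pose_id]]),
                    np.array([sd_angle] * 3 + [sd_force]),
                )
            )
        else:
            raise ValueError("dims must be 3 or 4")
    return templates


def gen_grasp(templates, n_per_pose: int, seed: int = 0) -> dict[int, np.ndarray]:
    """Gaussian samples around each template, labelled by pose id.

    A 4th (force) dimension is clipped at zero: an FSR cannot read negative
    force.  Keep force SDs small relative to the means if exact Gaussian
    statistics matter.
    """
    rng = np.random.default_rng(seed)
    out: dict[int, np.ndarray] = {}
    for tp in templates:
        x = tp.mean + tp.sd * rng.standard_normal((n_per_pose, tp.dims))
        if tp.dims == 4:
            x[:, 3] = np.maximum(x[:, 3], 0.0)
        out[tp.pose_id] = x
    return out


def gen_reach(
    kind: str,
    duration_s: float = 8.0,
    rate_hz: float = 100.0,
    elevation_deg: float = 90.0,
    emg_burst: float = 0.5,
    strain_excursion_ohm: float = 500.0,
    seed: int = 0,
) -> tuple[ArmAngles, TimeSeries, TimeSeries]:
    """Aligned elevation / normalized-EMG-envelope / strain traces per pattern.

    ``kind`` is ``"physiological"`` (elevation + EMG burst + quiet strain),
    ``"compensatory"`` (elevation + quiet EMG + strain excursion) or
    ``"inactive"`` (everything flat).  The envelope is on the MVC-normalized
    scale; the strain is in Ω around a 1000 Ω baseline.
    """
    if kind not in ("physiological", "compensatory", "inactive"):
        raise ValueError("kind must be physiological, compensatory, or inactive")
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    rng = np.random.default_rng(seed)

    active = np.zeros(n)
    mid = (t >= duration_s / 4) & (t < 3 * duration_s / 4)
    ramp = np.sin(np.pi * (t[mid] - duration_s / 4) / (duration_s / 2)) ** 2
    active[mid] = ramp

    psi = elevation_deg * active if kind != "inactive" else np.zeros(n)
    env = 0.01 + 0.002 * np.abs(rng.standard_normal(n))
    strain = 1000.0 + 5.0 * rng.standard_normal(n)
    if kind == "physiological":
        env = env + emg_burst * active
    elif kind == "compensatory":
        strain = strain + strain_excursion_ohm * active

    angles = ArmAngles(t=t, theta_deg=np.zeros(n), psi_deg=psi, rate_hz=rate_hz)
    env_ts = TimeSeries(t=t, channels={"emg_env": env}, rate_hz=rate_hz)
    strain_ts = TimeSeries(t=t, channels={"dR_ohm": strain}, rate_hz=rate_hz)
    return angles, env_ts, strain_ts
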