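"""Shoulder reconstruction: socket-ball baseline, bi-articular strain-fused model,
parameter identification, trunk-motion removal, and physiological-vs-compensatory
reach discrimination.

Kinematic conventions (sternum frame, right-handed, z up = craniocaudal,
x = antero-posterior/forward, y = lateral):

* ``psi`` (abduction/elevation, deg) is the angle of the humerus axis from the
  downward craniocaudal axis: 0° with the arm hanging, 90° horizontal.
* ``theta`` (horizontal flexion, deg) is the azimuth of the humerus axis about
  the craniocaudal axis measured from the frontal plane: 0° is pure frontal
  abduction, 90° is sagittal flexion (arm forward).

The rest humerus axis in the arm-segment frame is −z, so the axis in the
sternum frame is ``R_rel·(0,0,−1)`` with ``R_rel = R_sternumᵀ·R_arm``.

Models
------
Socket-ball: the gleno-humeral (GH) center is fixed at ``p0``; the trochlea
(end effector) lies at distance L (humerus length) along the direction set by
(theta, psi).  This ignores the scapulo-thoracic joint and accumulates error at
high elevation, where a substantial share of the movement is scapular.

Bi-articular: the GH center itself travels along an elliptic arc anchored at
``p0`` — one identified arc for the frontal plane (abduction), one for the
sagittal plane (flexion), blended for intermediate azimuths by rotating the arc
plane about the craniocaudal axis and interpolating the arc geometry in
theta/90°.  The scapular strain channel drives the position along the arc:
``phi = g·(s − s0)`` clipped to the identified arc extent, so at the rest
strain reading the model coincides with the socket-ball map everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .timeseries import OrientationStream, TimeSeries

__all__ = [
    "ArmAngles",
    "EllipticArc",
    "ShoulderModelParams",
    "CalibrationMovement",
    "ReachConfig",
    "ReachClassification",
    "arm_direction",
    "extract_arm_angles",
    "socket_ball_position",
    "biarticular_position",
    "identify_parameters",
    "remove_trunk_motion",
    "classify_reach",
    "params_to_dict",
    "params_from_dict",
]

_REST_AXIS = np.array([0.0, 0.0, -1.0])
_ZHAT = np.array([0.0, 0.0, 1.0])


@dataclass
class ArmAngles:
    """Humerus orientation angles relative to the sternum frame (degrees)."""

    t: np.ndarray
    theta_deg: np.ndarray
    psi_deg: np.ndarray
    rate_hz: float = 1.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.theta_deg = np.asarray(self.theta_deg, float)
        self.psi_deg = np.asarray(self.psi_deg, float)
        if not (len(self.t) == len(self.theta_deg) == len(self.psi_deg)):
            raise ValueError("angle arrays must share the time-vector length")

    @property
    def n(self) -> int:
        return len(self.t)


def arm_direction(theta_deg, psi_deg) -> np.ndarray:
    """Unit humerus-axis direction(s) in the sternum frame, shape (..., 3)."""
    th = np.deg2rad(np.asarray(theta_deg, float))
    ps = np.deg2rad(np.asarray(psi_deg, float))
    d = np.stack(
        [np.sin(ps) * np.sin(th), np.sin(ps) * np.cos(th), -np.cos(ps)], axis=-1
    )
    return d


def extract_arm_angles(
    q_arm: OrientationStream, q_sternum: OrientationStream
) -> ArmAngles:
    """Arm angles from the upper-arm IMU relative to the sternum IMU.

    Computes ``R_rel = R_sternumᵀ·R_arm``, maps the rest humerus axis through
    it and reads (theta, psi) off the resulting direction.  theta is set to 0
    where psi vanishes (azimuth undefined at the pole).
    """
    if q_arm.n != q_sternum.n:
        raise ValueError("orientation streams have mismatched lengths")
    r_rel = q_sternum.as_rotation().inv() * q_arm.as_rotation()
    a = r_rel.apply(_REST_AXIS)
    psi = np.rad2deg(np.arccos(np.clip(-a[:, 2], -1.0, 1.0)))
    theta = np.rad2deg(np.arctan2(a[:, 0], a[:, 1]))
    theta = np.where(np.isclose(psi, 0.0, atol=1e-9), 0.0, theta)
    return ArmAngles(t=q_arm.t, theta_deg=theta, psi_deg=psi, rate_hz=q_arm.rate_hz)


def socket_ball_position(angles: ArmAngles, L: float, p0) -> np.ndarray:
    """Trochlea positions (n, 3) for a fixed-center ball joint: p0 + L·dir."""
    if L <= 0:
        raise ValueError("humerus length L must be > 0")
    p0 = np.asarray(p0, float)
    return p0 + L * arm_direction(angles.theta_deg, angles.psi_deg)


@dataclass(frozen=True)
class EllipticArc:
    """Planar elliptic arc anchored at the rest GH center.

    The arc point at phase phi (rad, 0 ≤ phi ≤ phi_max) is displaced from the
    anchor by ``b·(1 − cos phi)`` along the in-plane horizontal direction and
    ``a·sin phi`` along the craniocaudal axis.  ``a`` and ``b`` are *signed*
    semi-axes (m): negative values flip the travel direction.  phi = 0 is the
    rest pose, so the displacement vanishes there.
    """

    a: float
    b: float
    phi_max_deg: float

    def displacement(self, phi_rad, h_dir) -> np.ndarray:
        phi = np.asarray(phi_rad, float)[..., None]
        return self.b * (1.0 - np.cos(phi)) * np.asarray(h_dir, float) + (
            self.a * np.sin(phi)
        ) * _ZHAT

    def chord_length(self) -> float:
        """Straight-line distance between the arc endpoints."""
        phi = np.deg2rad(self.phi_max_deg)
        return float(
            np.hypot(self.b * (1.0 - np.cos(phi)), self.a * np.sin(phi))
        )


@dataclass
class ShoulderModelParams:
    """Identified parameters of the bi-articular shoulder map.

    ``strain_gain`` maps strain excess (s − s0, Ω) to arc phase in radians;
    the normalized arc position is phi / phi_max, clipped to [0, 1].
    """

    L: float
    p0: np.ndarray
    frontal_path: EllipticArc
    sagittal_path: EllipticArc
    s0: float
    strain_gain: float
    rescale: float = 1.0  # trochlea→hand scaling along the arm axis

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("humerus length L must be > 0")
        self.p0 = np.asarray(self.p0, float)


def _blended_geometry(theta_deg):
    """Blend weight w = clip(theta/90, 0, 1) and in-plane horizontal direction.

    The arc plane rotates about the craniocaudal axis from frontal (y) to
    sagittal (x) as the azimuth sweeps 0°→90°.
    """
    w = np.clip(np.asarray(theta_deg, float) / 90.0, 0.0, 1.0)
    az = w * (np.pi / 2.0)
    h_dir = np.stack([np.sin(az), np.cos(az), np.zeros_like(az)], axis=-1)
    return w, h_dir


def _arc_center(params: ShoulderModelParams, theta_deg, s) -> np.ndarray:
    w, h_dir = _blended_geometry(theta_deg)
    fa, sa = params.frontal_path, params.sagittal_path
    a = (1.0 - w) * fa.a + w * sa.a
    b = (1.0 - w) * fa.b + w * sa.b
    phi_max = np.deg2rad((1.0 - w) * fa.phi_max_deg + w * sa.phi_max_deg)
    phi = np.clip(params.strain_gain * (np.asarray(s, float) - params.s0), 0.0, phi_max)
    disp = (b * (1.0 - np.cos(phi)))[..., None] * h_dir + (
        a * np.sin(phi)
    )[..., None] * _ZHAT
    return params.p0 + disp


def biarticular_position(
    angles: ArmAngles, s, params: ShoulderModelParams
) -> np.ndarray:
    """Trochlea positions (n, 3) under the strain-fused bi-articular map.

    The GH center is placed on the blended elliptic arc at the phase the strain
    channel dictates; the trochlea then lies at distance L along the (theta,
    psi) direction.  At ``s = s0`` this reduces to the socket-ball map.
    """
    s = np.asarray(s, float)
    if s.shape != (angles.n,) and s.shape != ():
        raise ValueError("strain vector length must match the angle series")
    center = _arc_center(params, angles.theta_deg, s)
    return center + params.L * arm_direction(angles.theta_deg, angles.psi_deg)


@dataclass
class CalibrationMovement:
    """One planar calibration movement with gold-standard positions.

    ``gold`` holds optical-reference trochlea positions (n, 3) in the sternum
    frame; ``strain`` the scapular channel readings (Ω).
    """

    angles: ArmAngles
    strain: np.ndarray
    gold: np.ndarray

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, float)
        self.gold = np.asarray(self.gold, float)
        n = self.angles.n
        if self.strain.shape != (n,) or self.gold.shape != (n, 3):
            raise ValueError("calibration arrays must share the angle-series length")


def _socket_fit(dirs: np.ndarray, gold: np.ndarray) -> tuple[np.ndarray, float]:
    """Linear least-squares fit of p0 and L in gold ≈ p0 + L·dir."""
    n = len(dirs)
    a_mat = np.zeros((3 * n, 4))
    a_mat[0::3, 0] = 1.0
    a_mat[1::3, 1] = 1.0
    a_mat[2::3, 2] = 1.0
    a_mat[:, 3] = dirs.ravel()
    x, *_ = np.linalg.lstsq(a_mat, gold.ravel(), rcond=None)
    return x[:3], float(x[3])


def identify_parameters(
    frontal: CalibrationMovement,
    sagittal: CalibrationMovement,
    min_samples: int = 10,
) -> ShoulderModelParams:
    """Identify the bi-articular model from the two planar calibration movements.

    Joint nonlinear least squares over both movements with unknowns
    (L, p0, frontal arc a/b, sagittal arc a/b, strain gain, strain offset),
    initialised from the linear socket-ball fit.  The arc extents are set from
    the largest phase reached during calibration.  If the bi-articular fit does
    not improve on the socket-ball residual the data carry no scapular
    information: the arcs collapse to a point and the gain is zeroed, making
    the map coincide with the socket-ball model.
    """
    for mov in (frontal, sagittal):
        if mov.angles.n < min_samples:
            raise ValueError("insufficient calibration data: need >= 10 samples per movement")

    dirs_f = arm_direction(frontal.angles.theta_deg, frontal.angles.psi_deg)
    dirs_s = arm_direction(sagittal.angles.theta_deg, sagittal.angles.psi_deg)
    dirs = np.vstack([dirs_f, dirs_s])
    gold = np.vstack([frontal.gold, sagittal.gold])
    strain = np.concatenate([frontal.strain, sagittal.strain])
    n_f = frontal.angles.n

    p0_init, L_init = _socket_fit(dirs, gold)
    if L_init <= 0:
        raise ValueError("rank-deficient fit: non-positive humerus length")
    socket_resid = gold - (p0_init + L_init * dirs)
    rms_socket = float(np.sqrt(np.mean(socket_resid**2)))

    span = float(np.ptp(strain))
    scale = max(abs(L_init), 1e-6)
    if span == 0.0:
        return _degenerate_params(L_init, p0_init, float(strain.mean()))

    # rest reading: strain at the lowest-elevation samples of each movement
    psi_all = np.concatenate([frontal.angles.psi_deg, sagittal.angles.psi_deg])
    s0_init = float(strain[np.argmin(psi_all)])
    g_init = 1.0 / span

    h_f = np.array([0.0, 1.0, 0.0])
    h_s = np.array([1.0, 0.0, 0.0])

    def model(x: np.ndarray) -> np.ndarray:
        L, p0x, p0y, p0z, af, bf, asg, bsg, g, s0 = x
        p0 = np.array([p0x, p0y, p0z])
        phi = g * (strain - s0)
        phi_f, phi_s = phi[:n_f], phi[n_f:]
        disp_f = (
            bf * (1.0 - np.cos(phi_f))[:, None] * h_f
            + af * np.sin(phi_f)[:, None] * _ZHAT
        )
        disp_s = (
            bsg * (1.0 - np.cos(phi_s))[:, None] * h_s
            + asg * np.sin(phi_s)[:, None] * _ZHAT
        )
        centers = p0 + np.vstack([disp_f, disp_s])
        return centers + L * dirs

    def residuals(x: np.ndarray) -> np.ndarray:
        return (model(x) - gold).ravel()

    x0 = np.array(
        [L_init, *p0_init, 0.02 * scale, 0.02 * scale, 0.02 * scale, 0.02 * scale,
         g_init, s0_init]
    )
    x_scale = np.array(
        [scale, scale, scale, scale, scale, scale, scale, scale, g_init, max(span, 1.0)]
    )
    fit = least_squares(
        residuals, x0, x_scale=x_scale, xtol=1e-14, ftol=1e-14, gtol=1e-14,
        max_nfev=2000,
    )
    rms_biart = float(np.sqrt(np.mean(fit.fun**2)))
    if not np.isfinite(rms_biart) or rms_biart >= rms_socket * (1.0 - 1e-9):
        return _degenerate_params(L_init, p0_init, s0_init)

    L, p0x, p0y, p0z, af, bf, asg, bsg, g, s0 = fit.x
    if L <= 0:
        raise ValueError("rank-deficient fit: non-positive humerus length")
    phi = g * (strain - s0)
    phi_max_f = float(np.max(phi[:n_f], initial=0.0))
    phi_max_s = float(np.max(phi[n_f:], initial=0.0))
    if phi_max_f <= 0 and phi_max_s <= 0:
        return _degenerate_params(float(L), np.array([p0x, p0y, p0z]), float(s0))
    return ShoulderModelParams(
        L=float(L),
        p0=np.array([p0x, p0y, p0z]),
        frontal_path=EllipticArc(a=float(af), b=float(bf), phi_max_deg=np.rad2deg(phi_max_f)),
        sagittal_path=EllipticArc(a=float(asg), b=float(bsg), phi_max_deg=np.rad2deg(phi_max_s)),
        s0=float(s0),
        strain_gain=float(g),
    )


def _degenerate_params(L: float, p0: np.ndarray, s0: float) -> ShoulderModelParams:
    point = EllipticArc(a=0.0, b=0.0, phi_max_deg=0.0)
    return ShoulderModelParams(
        L=L, p0=np.asarray(p0, float), frontal_path=point, sagittal_path=point,
        s0=s0, strain_gain=0.0,
    )


def remove_trunk_motion(
    p_world: np.ndarray, q_sternum: OrientationStream, p_sternum
) -> np.ndarray:
    """Express world positions in the (moving) sternum frame.

    ``p_local = R_sternumᵀ·(p_world − p_sternum)``; removes thorax oscillations
    from end-effector trajectories.  ``p_sternum`` may be a single point or an
    (n, 3) trajectory.
    """
    p_world = np.asarray(p_world, float)
    if p_world.shape != (q_sternum.n, 3):
        raise ValueError("position/orientation length mismatch")
    p_st = np.broadcast_to(np.asarray(p_sternum, float), p_world.shape)
    return q_sternum.as_rotation().inv().apply(p_world - p_st)


@dataclass(frozen=True)
class ReachConfig:
    """Thresholds for the physiological/compensatory discrimination.

    ``emg_frac`` applies to an MVC-normalized envelope; ``strain_sd_mult``
    scales the out-of-epoch baseline SD of the scapular channel, with
    ``strain_floor_ohm`` as an absolute floor against a perfectly quiet
    baseline.
    """

    min_elevation_deg: float = 30.0
    min_duration_s: float = 0.5
    emg_frac: float = 0.10
    strain_sd_mult: float = 3.0
    strain_floor_ohm: float = 1.0


@dataclass
class ReachClassification:
    """Per-epoch discrimination outcome.

    physiological: elevation driven by the deltoid (EMG active); compensatory:
    elevation with scapular strain but no deltoid activity; inactive: neither,
    or no elevation epoch at all.
    """

    label: str
    emg_active: bool
    scapula_active: bool
    elevation_detected: bool
    t_start: float = 0.0
    t_end: float = 0.0


def _elevation_epochs(psi: np.ndarray, rate_hz: float, cfg: ReachConfig):
    above = psi >= cfg.min_elevation_deg
    min_len = max(1, int(round(cfg.min_duration_s * rate_hz)))
    epochs = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= min_len:
                epochs.append((i, j))
            i = j
        else:
            i += 1
    return epochs


def classify_reach(
    emg_env: TimeSeries,
    strain: TimeSeries,
    elevation: ArmAngles,
    cfg: ReachConfig = ReachConfig(),
) -> list[ReachClassification]:
    """Classify elevation epochs as physiological, compensatory, or inactive.

    Epochs are contiguous runs with psi above the elevation threshold for at
    least the minimum duration.  Within an epoch the EMG is *active* when the
    normalized envelope exceeds ``emg_frac`` of MVC, the scapula is *active*
    when the strain excursion from its out-of-epoch baseline exceeds the
    configured multiple of the baseline SD.  EMG activity wins: an epoch with
    both channels active is physiological (the deltoid drives the movement;
    some scapulohumeral rhythm may coexist).
    """
    env = emg_env.single()
    s = strain.single()
    psi = elevation.psi_deg
    if not (len(env) == len(s) == len(psi)):
        raise ValueError("classification inputs must be time-aligned")

    epochs = _elevation_epochs(psi, elevation.rate_hz, cfg)
    if not epochs:
        return [
            ReachClassification(
                label="inactive", emg_active=False, scapula_active=False,
                elevation_detected=False,
                t_start=float(elevation.t[0]), t_end=float(elevation.t[-1]),
            )
        ]

    outside = np.ones(len(s), dtype=bool)
    for i, j in epochs:
        outside[i:j] = False
    baseline = s[outside] if outside.any() else s
    base_med = float(np.median(baseline))
    thresh = max(cfg.strain_sd_mult * float(baseline.std()), cfg.strain_floor_ohm)

    out = []
    for i, j in epochs:
        emg_active = bool(np.max(env[i:j]) >= cfg.emg_frac)
        scap_active = bool(np.max(np.abs(s[i:j] - base_med)) > thresh)
        if emg_active:
            label = "physiological"
        elif scap_active:
            label = "compensatory"
        else:
            label = "inactive"
        out.append(
            ReachClassification(
                label=label, emg_active=emg_active, scapula_active=scap_active,
                elevation_detected=True,
                t_start=float(elevation.t[i]), t_end=float(elevation.t[j - 1]),
            )
        )
    return out


def params_to_dict(params: ShoulderModelParams) -> dict:
    """Plain-dict form of the model parameters (for YAML round-trips)."""
    def _arc(arc: EllipticArc) -> dict:
        return {"a": float(arc.a), "b": float(arc.b), "phi_max_deg": float(arc.phi_max_deg)}

    return {
        "L": float(params.L),
        "p0": [float(v) for v in params.p0],
        "frontal_path": _arc(params.frontal_path),
        "sagittal_path": _arc(params.sagittal_path),
        "s0": float(params.s0),
        "strain_gain": float(params.strain_gain),
        "rescale": float(params.rescale),
    }


def params_from_dict(d: dict) -> ShoulderModelParams:
    return ShoulderModelParams(
        L=float(d["L"]),
        p0=np.asarray(d["p0"], float),
        frontal_path=EllipticArc(**d["frontal_path"]),
        sagittal_path=EllipticArc(**d["sagittal_path"]),
        s0=float(d["s0"]),
        strain_gain=float(d["strain_gain"]),
        rescale=float(d.get("rescale", 1.0)),
    )
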