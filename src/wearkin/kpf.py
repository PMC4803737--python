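"""Knitted piezoresistive fabric (KPF) sensors: physics, calibration, characterization.

A KPF specimen is a strip of conductive knitted textile whose electrical
resistance depends on its stretched length and, weakly, on the bending angle
between its extremities.  For a specimen of rest volume V0 = l·d·h0 the
resistance of a single layer is

    R = l²·ρ / V0 − (ρ/d)·Δα

up to a second-order curvature term that is negligible for body-shape sensing.
Two nominally identical layers separated by an insulator form a *double-layer
goniometer*: the piezoresistive terms cancel in the layer resistance difference
ΔR, which is then an affine function of the bending angle,

    Δα = c1·ΔR + c2 ,

with (c1, c2) identified by a two-point calibration.

Characterization of either device follows the bench procedure: repeated
readings at a ladder of imposed stimulus levels (mm of elongation for the
strain sensor, degrees for the goniometer), per-level mean and population
standard deviation, a least-squares line through the level means giving the
sensitivity, and the worst-level SD converted to an equivalent angular error
for goniometers (sigma_max / sensitivity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KPFSpecimen",
    "GoniometerCalibration",
    "CharacterizationResult",
    "strain_resistance",
    "calibrate_two_point",
    "goniometer_angle",
    "characterize",
]


@dataclass(frozen=True)
class KPFSpecimen:
    """Geometry and material of a single-layer KPF strip.

    Parameters
    ----------
    l : float
        Actual (stretched) length, m.
    d : float
        Width, m.
    h0 : float
        Initial thickness, m.
    rho : float
        Resistivity, Ω·m.
    delta_alpha : float
        Bending angle between the tangent planes at the extremities, rad.
        Defaults to 0: for the scapular strain sensor the bending contribution
        is negligible in practice and only the piezoresistive term matters.
    """

    l: float
    d: float
    h0: float
    rho: float
    delta_alpha: float = 0.0

    def __post_init__(self) -> None:
        for name in ("l", "d", "h0", "rho"):
            if getattr(self, name) <= 0:
                raise ValueError(f"specimen field {name} must be > 0")

    @property
    def V0(self) -> float:
        """Rest volume l·d·h0, m³."""
        return self.l * self.d * self.h0


def strain_resistance(spec: KPFSpecimen) -> float:
    """Single-layer resistance in Ω: piezoresistive term minus bending term."""
    return spec.l**2 * spec.rho / spec.V0 - (spec.rho / spec.d) * spec.delta_alpha


@dataclass(frozen=True)
class GoniometerCalibration:
    """Affine ΔR→angle map of a double-layer goniometer.

    ``c1`` is the inverse sensitivity (degrees per Ω), ``c2`` the angular
    offset (degrees).  ``cal_points`` stores the two (angle_deg, dR_ohm) pairs
    the calibration was computed from; the map reproduces both exactly.
    """

    c1: float
    c2: float
    cal_points: tuple[tuple[float, float], tuple[float, float]] = field(
        default=((0.0, 0.0), (0.0, 0.0))
    )


def calibrate_two_point(
    a1: float, dR1: float, a2: float, dR2: float
) -> GoniometerCalibration:
    """Two-point goniometer calibration.

    Given resistance differences ``dR1``, ``dR2`` (Ω) read in two known angular
    positions ``a1``, ``a2`` (degrees):

        c1 = (a1 − a2) / (dR1 − dR2)
        c2 = (dR1·a2 − dR2·a1) / (dR1 − dR2)

    Raises ``ValueError("degenerate calibration")`` when dR1 == dR2 (no
    resistance contrast) or when the two angles coincide (c1 = 0, so the map
    cannot be inverted to measure angles).
    """
    if dR1 == dR2:
        raise ValueError("degenerate calibration: dR1 == dR2")
    c1 = (a1 - a2) / (dR1 - dR2)
    if c1 == 0.0:
        raise ValueError("degenerate calibration: zero sensitivity (a1 == a2)")
    c2 = (dR1 * a2 - dR2 * a1) / (dR1 - dR2)
    return GoniometerCalibration(c1=c1, c2=c2, cal_points=((a1, dR1), (a2, dR2)))


def goniometer_angle(dR, cal: GoniometerCalibration):
    """Angle in degrees from a resistance difference (scalar or array), c1·ΔR + c2."""
    return cal.c1 * np.asarray(dR, dtype=float) + cal.c2


@dataclass
class CharacterizationResult:
    """Electromechanical characterization of a KPF device.

    ``sensitivity`` is Ω per unit stimulus (Ω/mm for a strain sensor, Ω/° for
    a goniometer); ``offset`` is the intercept of the least-squares line
    through the per-level mean readings.  ``sigma_max`` is the worst per-level
    population SD; for angular stimuli ``angular_error_deg`` converts it to an
    equivalent angle, sigma_max / |sensitivity|.
    """

    levels: np.ndarray
    level_means: np.ndarray
    level_sds: np.ndarray
    sensitivity: float
    offset: float
    sigma_max: float
    angular_error_deg: float | None = None


def characterize(
    levels, trials, stimulus: str = "angle"
) -> CharacterizationResult:
    """Characterize a KPF device from repeated readings at stimulus levels.

    Parameters
    ----------
    levels : array of float
        Imposed stimulus values (≥ 2 distinct levels).
    trials : sequence of arrays
        ``trials[i]`` holds the repeated resistance readings (Ω) at
        ``levels[i]``; at least one reading per level.
    stimulus : {"angle", "strain"}
        With ``"angle"`` the worst-level SD is also expressed as an angular
        error in degrees.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.ndim != 1 or len(levels) < 2:
        raise ValueError("cannot fit line: need at least two stimulus levels")
    readings = [np.asarray(tr, dtype=float).ravel() for tr in trials]
    if len(readings) != len(levels):
        raise ValueError("trials must provide one reading set per level")
    if any(len(r) < 1 for r in readings):
        raise ValueError("each level needs at least one repetition")

    means = np.array([r.mean() for r in readings])
    # population SD (divisor P): the bench procedure averages over a fixed,
    # exhaustively repeated set of cycles, not a sample from a larger one
    sds = np.array([r.std(ddof=0) for r in readings])

    sensitivity, offset = np.polyfit(levels, means, 1)
    sigma_max = float(sds.max())
    angular_error = None
    if stimulus == "angle":
        if sensitivity == 0:
            raise ValueError("zero sensitivity: angular error undefined")
        angular_error = sigma_max / abs(float(sensitivity))
    return CharacterizationResult(
        levels=levels,
        level_means=means,
        level_sds=sds,
        sensitivity=float(sensitivity),
        offset=float(offset),
        sigma_max=sigma_max,
        angular_error_deg=angular_error,
    )
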