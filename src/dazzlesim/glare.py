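"""Disability-glare and laser-dazzle physics.

This module implements the human-eye glare model used throughout the
package: the CIE disability-glare kernel, the ambient-calibrated veiling
luminance produced by a laser at the cornea, Adrian-style threshold
contrast, and the derived dazzle/safety quantities

* ``dazzle_angle`` (U) -- angular extent around the glare source within
  which a target of given intrinsic contrast is masked,
* ``mde`` -- maximum dazzle exposure, the eye irradiance at which dazzle
  just reaches a given angle,
* ``nohd``/``nodd`` -- nominal ocular hazard / dazzle distances,
* ``mpe_visible_cw`` -- the visible-band CW aversion-response maximum
  permissible exposure.

Units follow the conventions of the laser-dazzle literature: angles in
degrees, luminances in cd/m^2, eye irradiance in mW/cm^2 at the module
interface (converted to W/m^2 internally), source power in mW, divergence
in mrad, distances in m.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .photometry import (
    LUMINOUS_EFFICACY_CONSTANT,
    illuminance_from_irradiance,
    photopic_efficiency,
)

logger = logging.getLogger(__name__)

MW_CM2_TO_W_M2 = 10.0  # 1 mW/cm^2 = 10 W/m^2


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObserverProfile:
    """An individual eye: observer age A (years) and iris pigmentation p.

    Pigmentation follows the CIE convention: 0 very dark, 0.5 dark,
    1.0 light, 1.2 very light eyes.
    """

    age: float
    pigmentation: float = 0.5

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if not (0.0 <= self.pigmentation <= 1.2):
            raise ValueError("pigmentation must lie in [0, 1.2]")


@dataclass(frozen=True)
class SceneConditions:
    """Ambient luminance L_b (cd/m^2), intrinsic target contrast C_orig,
    and target angular size (degrees, full subtense)."""

    ambient_luminance: float
    target_contrast: float
    target_angular_size: float

    def __post_init__(self) -> None:
        if self.ambient_luminance <= 0:
            raise ValueError("ambient_luminance must be positive")
        if not (0.0 < self.target_contrast <= 1.0):
            raise ValueError("target_contrast must lie in (0, 1]")
        if self.target_angular_size <= 0:
            raise ValueError("target_angular_size must be positive")


@dataclass(frozen=True)
class LaserExposure:
    """Laser light arriving at the eye plane.

    ``eye_irradiance`` is the radiant power density at the cornea in
    mW/cm^2; ``incidence_angle`` is the angle between the laser and the
    line of sight, degrees.
    """

    wavelength: float
    eye_irradiance: float
    incidence_angle: float = 0.5

    def __post_init__(self) -> None:
        if not (380.0 <= self.wavelength <= 780.0):
            raise ValueError("wavelength outside the photopic band [380, 780] nm")
        if self.eye_irradiance < 0:
            raise ValueError("eye_irradiance must be non-negative")
        if self.incidence_angle <= 0:
            raise ValueError("incidence_angle must be positive")


@dataclass(frozen=True)
class LaserSource:
    """CW laser source: power (mW), full-angle divergence (mrad),
    initial beam diameter d0 (m), and range L to the eye (m)."""

    power: float
    divergence: float
    initial_beam_diameter: float = 0.0
    distance: float = 0.0

    def __post_init__(self) -> None:
        if self.power <= 0:
            raise ValueError("power must be positive")
        if self.divergence <= 0:
            raise ValueError("divergence must be positive")
        if self.initial_beam_diameter < 0:
            raise ValueError("initial_beam_diameter must be non-negative")
        if self.distance < 0:
            raise ValueError("distance must be non-negative")


# ---------------------------------------------------------------------------
# Threshold-contrast calibration (Adrian visibility-model defaults)
# ---------------------------------------------------------------------------

def adrian_sqrt_phi(ambient_luminance: float) -> float:
    """sqrt(Phi) term of Adrian's visibility model (cd-based units).

    Piecewise over photopic / mesopic / scotopic adaptation regimes.
    """
    lb = float(ambient_luminance)
    if lb <= 0:
        raise ValueError("ambient luminance must be positive")
    if lb >= 0.6:
        return math.log10(4.1925 * lb**0.1556) + 0.1684 * lb**0.5867
    x = math.log10(lb)
    if lb >= 0.00418:
        return 10.0 ** (0.028 + 0.173 * x)
    return 10.0 ** (0.8559 + 0.3372 * x + 0.0866 * x * x)


def adrian_sqrt_l(ambient_luminance: float) -> float:
    """sqrt(L) term of Adrian's visibility model."""
    lb = float(ambient_luminance)
    if lb <= 0:
        raise ValueError("ambient luminance must be positive")
    if lb >= 0.6:
        return 0.05946 * lb**0.466
    x = math.log10(lb)
    if lb >= 0.00418:
        return 10.0 ** (-0.891 + 0.5275 * x + 0.0227 * x * x)
    return 10.0 ** (-1.256 + 0.319 * x)


@dataclass(frozen=True)
class GlareCalibration:
    """Empirical calibration of the veiling-luminance / threshold models.

    ``s1``/``t1`` scale the veil with ambient adaptation
    (f = S1 * Lb^T1 * g * E_v); ``sqrt_phi``/``sqrt_l`` are the
    luminance-dependent terms of the threshold-contrast calibration
    (Adrian-style defaults, pluggable).
    """

    s1: float = 0.9147
    t1: float = 0.1775
    luminous_efficacy_constant: float = LUMINOUS_EFFICACY_CONSTANT
    photopic_efficiency: Callable[[float], float] = field(default=photopic_efficiency)
    sqrt_phi: Callable[[float], float] = field(default=adrian_sqrt_phi)
    sqrt_l: Callable[[float], float] = field(default=adrian_sqrt_l)

    def __post_init__(self) -> None:
        if self.s1 <= 0:
            raise ValueError("s1 must be positive")
        if not (0.0 < self.t1 < 1.0):
            raise ValueError("t1 must lie in (0, 1)")
        if self.luminous_efficacy_constant != LUMINOUS_EFFICACY_CONSTANT:
            raise ValueError("luminous efficacy constant is fixed at 683 lm/W")


DEFAULT_CALIBRATION = GlareCalibration()


# ---------------------------------------------------------------------------
# Core physics
# ---------------------------------------------------------------------------

def glare_function(theta: float, observer: ObserverProfile) -> float:
    """CIE general disability-glare kernel g(theta, A, p).

    g = 10/theta^3 + [5/theta^2 + 0.1 p/theta] [1 + (A/62.5)^4] + 0.0025 p

    theta in degrees (> 0).  Strictly decreasing in theta.
    """
    if theta <= 0:
        raise ValueError("glare angle theta must be positive")
    a, p = observer.age, observer.pigmentation
    age_term = 1.0 + (a / 62.5) ** 4
    return 10.0 / theta**3 + (5.0 / theta**2 + 0.1 * p / theta) * age_term + 0.0025 * p


def age_factor(age: float) -> float:
    """Age factor AF of the threshold-contrast model.

    Quadratic in age with a steeper branch past 64 years; ages outside
    [19, 75] are clamped with a logged warning.
    """
    a = float(age)
    if a < 19.0 or a > 75.0:
        logger.warning("age %.1f outside supported range [19, 75]; clamping", a)
        a = min(max(a, 19.0), 75.0)
    if a <= 64.0:
        return (a - 19.0) ** 2 / 2160.0 + 0.99
    return (a - 56.6) ** 2 / 116.3 + 1.43


def visual_corneal_illuminance(
    exposure: LaserExposure, calib: GlareCalibration = DEFAULT_CALIBRATION
) -> float:
    """Photometric corneal illuminance (lm/m^2) of the laser exposure.

    E_v = 683 * V(lambda) * E_e, with the mW/cm^2 interface irradiance
    converted to W/m^2.
    """
    e_w_m2 = exposure.eye_irradiance * MW_CM2_TO_W_M2
    return calib.luminous_efficacy_constant * calib.photopic_efficiency(
        exposure.wavelength
    ) * e_w_m2


def veiling_luminance(
    theta: float,
    observer: ObserverProfile,
    scene: SceneConditions,
    exposure: LaserExposure,
    calib: GlareCalibration = DEFAULT_CALIBRATION,
) -> float:
    """Veiling luminance L_v (cd/m^2) at glare angle theta.

    L_v = S1 * Lb^T1 * g(theta, A, p) * E_v, linear in eye irradiance and
    strictly decreasing in theta.
    """
    return (
        calib.s1
        * scene.ambient_luminance**calib.t1
        * glare_function(theta, observer)
        * visual_corneal_illuminance(exposure, calib)
    )


def threshold_contrast(
    scene: SceneConditions,
    observer: ObserverProfile,
    calib: GlareCalibration = DEFAULT_CALIBRATION,
) -> float:
    """Threshold contrast C_thr for detecting the target without a laser.

    C_thr = Omega(Lb, a) * AF(A) with
    Omega = 2.6 (sqrt_phi(Lb)/(60 a) + sqrt_l(Lb))^2 / Lb,
    a the target's full angular subtense in degrees (60 a arcminutes).
    """
    lb = scene.ambient_luminance
    a = scene.target_angular_size
    if a <= 0:
        raise ValueError("target angular size must be positive")
    alpha_arcmin = 60.0 * a
    omega = 2.6 * (calib.sqrt_phi(lb) / alpha_arcmin + calib.sqrt_l(lb)) ** 2 / lb
    return omega * age_factor(observer.age)


def effective_contrast(scene: SceneConditions, veiling: float) -> float:
    """Target contrast under a veil: C_w = C_orig * Lb / (Lb + L_v)."""
    if veiling < 0:
        raise ValueError("veiling luminance must be non-negative")
    lb = scene.ambient_luminance
    return scene.target_contrast * lb / (lb + veiling)


# ---------------------------------------------------------------------------
# Dazzle quantities
# ---------------------------------------------------------------------------

_THETA_MIN = 0.01
_THETA_MAX = 90.0
_THETA_TOL = 1e-4


def _required_veil(
    scene: SceneConditions, observer: ObserverProfile, calib: GlareCalibration
) -> float:
    """Veiling luminance that drops the target contrast exactly to threshold.

    From C_orig * Lb / (Lb + L_v) = C_thr:  L_v = Lb (C_orig/C_thr - 1).
    Raises for degenerate scenes where the target is invisible even unlit.
    """
    c_thr = threshold_contrast(scene, observer, calib)
    if c_thr >= scene.target_contrast:
        raise ValueError(
            "degenerate scene: threshold contrast "
            f"{c_thr:.4g} >= intrinsic contrast {scene.target_contrast:.4g} "
            "(target invisible without a laser)"
        )
    return scene.ambient_luminance * (scene.target_contrast / c_thr - 1.0)


def dazzle_angle(
    observer: ObserverProfile,
    scene: SceneConditions,
    exposure: LaserExposure,
    calib: GlareCalibration = DEFAULT_CALIBRATION,
) -> float:
    """Dazzle (target-occlusion) angle U in degrees.

    The largest glare angle theta at which the veiled target contrast
    falls below threshold; 0 if the masking criterion is never met.
    Monotone non-decreasing in eye irradiance, non-increasing in ambient
    luminance.  Bisection on [0.01, 90] degrees to 1e-4 degrees (the veil
    is strictly decreasing in theta, so the root is unique).
    """
    if exposure.eye_irradiance == 0:
        return 0.0
    lv_req = _required_veil(scene, observer, calib)

    def veil(theta: float) -> float:
        return veiling_luminance(theta, observer, scene, exposure, calib)

    if veil(_THETA_MIN) <= lv_req:
        return 0.0
    if veil(_THETA_MAX) > lv_req:
        logger.warning(
            "masking criterion still met at %.0f deg; returning bracket bound",
            _THETA_MAX,
        )
        return _THETA_MAX
    lo, hi = _THETA_MIN, _THETA_MAX
    while hi - lo > _THETA_TOL:
        mid = 0.5 * (lo + hi)
        if veil(mid) > lv_req:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def mde(
    theta: float,
    observer: ObserverProfile,
    scene: SceneConditions,
    calib: GlareCalibration = DEFAULT_CALIBRATION,
    wavelength: float = 532.0,
) -> float:
    """Maximum dazzle exposure (mW/cm^2) at glare angle theta.

    Closed-form inversion of the masking criterion: the eye irradiance at
    which the veil at theta reduces the target contrast exactly to
    threshold.  Strictly increasing in theta.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    lv_req = _required_veil(scene, observer, calib)
    unit = LaserExposure(wavelength=wavelength, eye_irradiance=1.0,
                         incidence_angle=theta)
    lv_per_unit = veiling_luminance(theta, observer, scene, unit, calib)
    return lv_req / lv_per_unit


def eye_irradiance_at_distance(source: LaserSource) -> float:
    """Far-field eye irradiance (mW/cm^2) of a top-hat beam at range L.

    Beam diameter d0 + phi*L; irradiance P / (pi/4 d^2).
    """
    if source.distance <= 0:
        raise ValueError("distance must be positive")
    d = source.initial_beam_diameter + source.divergence * 1e-3 * source.distance
    area_m2 = math.pi / 4.0 * d * d
    if area_m2 == 0:
        raise ValueError("zero beam area")
    # mW / m^2 -> mW / cm^2
    return source.power / area_m2 / 1e4


def mpe_visible_cw(exposure_time: float = 0.25) -> float:
    """Visible-band CW aversion-response MPE (W/m^2): 18 t^0.75 / t.

    Valid for exposure times 0 < t <= 10 s in the visible band; other
    regimes require the full IEC 60825-1 treatment and are refused.
    """
    t = float(exposure_time)
    if not (0.0 < t <= 10.0):
        raise ValueError(
            "exposure time outside the supported visible-CW aversion regime "
            "(0, 10] s; consult IEC 60825-1 for other cases"
        )
    return 18.0 * t**0.75 / t


def nohd(source: LaserSource, mpe: float) -> float:
    """Nominal ocular hazard distance (m) for the given MPE (W/m^2).

    Distance at which the far-field irradiance falls to the MPE:
    (sqrt(4 P / (pi MPE)) - d0) / phi; 0 if already below MPE at source.
    """
    if mpe <= 0:
        raise ValueError("mpe must be positive")
    p_w = source.power * 1e-3
    d0 = source.initial_beam_diameter
    if d0 > 0 and p_w / (math.pi / 4.0 * d0 * d0) <= mpe:
        return 0.0  # already below MPE at the exit aperture
    d_at_mpe = math.sqrt(4.0 * p_w / (math.pi * mpe))
    dist = (d_at_mpe - source.initial_beam_diameter) / (source.divergence * 1e-3)
    return max(dist, 0.0)


def nodd(
    source: LaserSource,
    observer: ObserverProfile,
    scene: SceneConditions,
    calib: GlareCalibration = DEFAULT_CALIBRATION,
    wavelength: float = 532.0,
    reference_angle: float | None = None,
) -> float:
    """Nominal ocular dazzle distance (m).

    Distance at which the eye irradiance equals the maximum dazzle
    exposure at the reference angle (default: the target's angular
    half-extent).  Beyond this distance the dazzle criterion is not met.
    Returns 0 when the criterion is never met.
    """
    if reference_angle is None:
        reference_angle = scene.target_angular_size / 2.0
    try:
        e_mde = mde(reference_angle, observer, scene, calib, wavelength)
    except ValueError:
        logger.warning("dazzle criterion unattainable; NODD = 0")
        return 0.0
    if e_mde <= 0:
        return 0.0
    # mW/cm^2 -> W/m^2 for the beam-geometry inversion
    e_w_m2 = e_mde * MW_CM2_TO_W_M2
    return nohd(source, e_w_m2)
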