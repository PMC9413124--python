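"""Closed-form hemodynamic relations linking pulse timing to blood pressure.

All internal physics is SI (Pa, m, s, kg/m^3); pressures cross the public
interface in mmHg.  Two estimation arms are provided:

* a log-transit-time regression model ``P = K1 * ln(PTT) + K2``;
* a pressure--stiffness ("P-beta") model built on the Moens-Korteweg
  relation, yielding MAP and pulse pressure from wave speed and arterial
  geometry, with SBP/DBP tracked from MAP through a fixed coefficient ``k``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, InvalidInputError

#: Unit conversion factor: 1 mmHg in pascal.
MMHG_TO_PA = 133.322

#: Default whole-blood density, kg/m^3 (1.06 g/mL).
RHO_BLOOD = 1060.0

#: Default DBP/MAP tracking coefficient.
K_TRACKING = 0.76


@dataclass(frozen=True)
class ArterialState:
    """Geometry of one arterial segment.

    Parameters
    ----------
    dd : float
        End-diastolic lumen diameter, m.
    h : float
        Wall thickness (intima-media thickness), m.
    delta_d : float, optional
        Systolic diameter excursion ``Ds - Dd``, m.
    rho_blood : float, optional
        Whole-blood density, kg/m^3.
    d : float or None, optional
        Representative instantaneous diameter, m.  Defaults to ``dd``
        (systolic and diastolic diameters differ by <10% over a cycle).
    """

    dd: float
    h: float
    delta_d: float = 0.0
    rho_blood: float = RHO_BLOOD
    d: float | None = None

    def __post_init__(self) -> None:
        if self.dd <= 0:
            raise InvalidInputError(f"dd must be > 0, got {self.dd}")
        if self.h <= 0:
            raise InvalidInputError(f"h must be > 0, got {self.h}")
        if self.delta_d < 0:
            raise InvalidInputError(f"delta_d must be >= 0, got {self.delta_d}")
        if self.rho_blood <= 0:
            raise InvalidInputError("rho_blood must be > 0")
        if self.d is None:
            object.__setattr__(self, "d", self.dd)
        elif self.d <= 0:
            raise InvalidInputError(f"d must be > 0, got {self.d}")

    @property
    def ds(self) -> float:
        """Systolic diameter ``Dd + deltaD``, m."""
        return self.dd + self.delta_d


@dataclass(frozen=True)
class StiffnessParams:
    """Per-subject arterial stiffness constants.

    ``e0`` (Pa) and ``xi`` (1/mmHg) parameterise the exponential pressure
    dependence of Young's modulus; ``beta`` is the dimensionless local
    stiffness constant of the P-beta model; ``k`` maps MAP to DBP.
    """

    e0: float
    xi: float
    beta: float
    k: float = K_TRACKING

    def __post_init__(self) -> None:
        if self.e0 <= 0:
            raise InvalidInputError(f"e0 must be > 0, got {self.e0}")
        if self.beta <= 0:
            raise InvalidInputError(f"beta must be > 0, got {self.beta}")
        if not 0 < self.k <= 1:
            raise InvalidInputError(f"k must be in (0, 1], got {self.k}")


@dataclass(frozen=True)
class RegressionCoeffs:
    """Coefficients of the log-transit-time model ``P = K1*ln(PTT) + K2``."""

    k1: float
    k2: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.k1) and math.isfinite(self.k2)):
            raise InvalidInputError("regression coefficients must be finite")


@dataclass(frozen=True)
class BPEstimate:
    """One blood-pressure reading: SBP/DBP/MAP plus pulse pressure, mmHg.

    ``valid=False`` marks a reading rejected by quality gates; its pressure
    fields are NaN and the physiological invariants are not enforced.
    """

    sbp: float
    dbp: float
    map: float
    pp: float
    method: str
    valid: bool = True
    reason: str = ""

    def __post_init__(self) -> None:
        if not self.valid:
            return
        if not (self.sbp >= self.map >= self.dbp):
            raise InvalidInputError(
                f"require sbp >= map >= dbp, got {self.sbp}/{self.map}/{self.dbp}"
            )
        if self.pp < 0:
            raise InvalidInputError(f"pp must be >= 0, got {self.pp}")


def pwv_from_ptt(sensor_distance: float, ptt: float) -> float:
    """Wave speed (m/s) from the sensor separation (m) and transit time (s)."""
    if sensor_distance <= 0:
        raise InvalidInputError(f"sensor_distance must be > 0, got {sensor_distance}")
    if ptt <= 0:
        raise InvalidInputError(f"ptt must be > 0, got {ptt}")
    return sensor_distance / ptt


def mk_pwv(state: ArterialState, e: float) -> float:
    """Moens-Korteweg wave speed ``sqrt(E*h / (D*rho))`` in m/s."""
    if e <= 0:
        raise InvalidInputError(f"Young's modulus must be > 0, got {e}")
    return math.sqrt(e * state.h / (state.d * state.rho_blood))


def youngs_modulus(params: StiffnessParams, pressure: float) -> float:
    """Pressure-dependent Young's modulus ``E0 * exp(xi * P)`` in Pa.

    ``pressure`` is in mmHg, matching the 1/mmHg unit of ``xi``.
    """
    return params.e0 * math.exp(params.xi * pressure)


def mk_pressure(state: ArterialState, params: StiffnessParams, pwv: float) -> float:
    """Invert the Moens-Korteweg + exponential-modulus pair for pressure.

    Returns ``ln(pwv^2 * rho * D / (h * E0)) / xi`` in mmHg; this pressure
    approximates MAP.  Exact inverse of
    ``mk_pwv(state, youngs_modulus(params, P))``.
    """
    if pwv <= 0:
        raise InvalidInputError(f"pwv must be > 0, got {pwv}")
    if params.xi == 0:
        raise InvalidInputError("xi must be nonzero to invert the modulus law")
    arg = pwv**2 * state.rho_blood * state.d / (state.h * params.e0)
    if arg <= 0:
        raise InvalidInputError("log argument must be > 0")
    return math.log(arg) / params.xi


def regression_fit(pairs: list[tuple[float, float]]) -> RegressionCoeffs:
    """Ordinary least squares of BP (mmHg) on ln(PTT).

    ``pairs`` is a sequence of ``(ptt_seconds, bp_mmhg)``.  At least two
    pairs with distinct transit times are required.
    """
    if len(pairs) < 2:
        raise CalibrationError("need at least 2 (ptt, bp) pairs")
    ptt = np.asarray([p for p, _ in pairs], dtype=float)
    bp = np.asarray([b for _, b in pairs], dtype=float)
    if np.any(ptt <= 0):
        raise InvalidInputError("all ptt values must be > 0")
    if np.unique(ptt).size < 2:
        raise CalibrationError("need at least 2 distinct ptt values")
    k1, k2 = np.polyfit(np.log(ptt), bp, 1)
    return RegressionCoeffs(k1=float(k1), k2=float(k2))


def regression_predict(coeffs: RegressionCoeffs, ptt: float) -> float:
    """Evaluate ``K1 * ln(ptt) + K2`` (mmHg)."""
    if ptt <= 0:
        raise InvalidInputError(f"ptt must be > 0, got {ptt}")
    return coeffs.k1 * math.log(ptt) + coeffs.k2


def pulse_pressure(state: ArterialState, pwv: float) -> float:
    """Pulse pressure (mmHg) from wave speed and the diameter excursion.

    ``rho * pwv^2 * (2*dD/Dd + (dD/Dd)^2)``, converted Pa -> mmHg.
    """
    if pwv < 0:
        raise InvalidInputError(f"pwv must be >= 0, got {pwv}")
    x = state.delta_d / state.dd
    return state.rho_blood * pwv**2 * (2.0 * x + x**2) / MMHG_TO_PA


def map_p_beta(state: ArterialState, params: StiffnessParams, pwv: float) -> float:
    """Mean arterial pressure (mmHg) from the P-beta relation.

    ``2 * rho * pwv^2 * Dd / (beta * D)``, converted Pa -> mmHg.  With the
    default representative diameter ``D = Dd`` the geometric ratio is one.
    """
    if pwv < 0:
        raise InvalidInputError(f"pwv must be >= 0, got {pwv}")
    return 2.0 * state.rho_blood * pwv**2 * state.dd / (params.beta * state.d) / MMHG_TO_PA


def beta_calibrate(state: ArterialState, pwv_cal: float, map_ref: float) -> float:
    """One-point stiffness calibration: beta that reproduces ``map_ref``.

    Exact algebraic inverse of :func:`map_p_beta` in its ``beta`` argument.
    """
    if pwv_cal <= 0:
        raise CalibrationError(f"pwv_cal must be > 0, got {pwv_cal}")
    if map_ref <= 0:
        raise CalibrationError(f"map_ref must be > 0, got {map_ref}")
    return 2.0 * state.rho_blood * pwv_cal**2 * state.dd / (state.d * map_ref * MMHG_TO_PA)


def track_sbp_dbp(
    map_mmhg: float,
    pp: float = 0.0,
    k: float = K_TRACKING,
    method: str = "p_beta",
    tracking_variant: str = "printed",
) -> BPEstimate:
    """Track SBP/DBP from MAP through the coefficient ``k``.

    Default ("printed") form::

        DBP = MAP * k
        SBP = MAP + (1 - k) * DBP

    ``pp`` is carried in the returned estimate but not consumed by the
    default form.  ``tracking_variant="pp"`` is a non-default alternative
    substituting ``SBP = MAP + (1 - k) * PP``.
    """
    if map_mmhg <= 0:
        raise InvalidInputError(f"map must be > 0, got {map_mmhg}")
    if not 0 < k <= 1:
        raise InvalidInputError(f"k must be in (0, 1], got {k}")
    dbp = map_mmhg * k
    if tracking_variant == "printed":
        sbp = map_mmhg + (1.0 - k) * dbp
    elif tracking_variant == "pp":
        sbp = map_mmhg + (1.0 - k) * pp
    else:
        raise InvalidInputError(f"unknown tracking_variant {tracking_variant!r}")
    return BPEstimate(sbp=sbp, dbp=dbp, map=map_mmhg, pp=pp, method=method)
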