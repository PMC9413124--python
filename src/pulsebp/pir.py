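"""PPG intensity-ratio features and arterial-dimension estimation.

Per cardiac cycle the raw (DC-containing) PPG is reduced to its extremes
IH and IL; their ratio (PIR) maps to the diameter excursion through the
Beer-Lambert relation ``deltaD = ln(IH/IL) / alpha``.  A linear model on
the normalized PPG (``ln(AC)/ln(DC)``) estimates the end-diastolic
diameter against reference dimensions (an ultrasound-surrogate table).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .dsp import BeatFeatures, Signal
from .errors import CalibrationError, DataError

log = logging.getLogger(__name__)

#: Saturation rails of the 18-bit PPG ADC.
ADC_MAX = 2**18 - 1


@dataclass
class PIRMeasurement:
    """Per-beat and session-level PPG intensity features."""

    ih: np.ndarray
    il: np.ndarray
    pir: np.ndarray
    valid: np.ndarray
    pir_median: float
    ppg_norm: float
    delta_d_est: float | None = None
    dd_est: float | None = None

    @property
    def n_beats(self) -> int:
        return int(self.ih.size)


@dataclass(frozen=True)
class DiameterModel:
    """Linear map from normalized PPG to end-diastolic diameter (m)."""

    slope: float
    intercept: float
    alpha: float | None
    fit_r2: float
    norm_range: tuple[float, float]

    def predict_dd(self, ppg_norm: float) -> float:
        """Evaluate the fitted line; extrapolation outside the fitted
        ppg_norm range is allowed but logged."""
        lo, hi = self.norm_range
        if not lo <= ppg_norm <= hi:
            log.warning(
                "ppg_norm %.4f outside fitted range [%.4f, %.4f]; extrapolating",
                ppg_norm, lo, hi,
            )
        return self.slope * ppg_norm + self.intercept


def extract_ih_il(ppg: Signal, beats: BeatFeatures) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cycle (IH, IL) from the raw PPG.

    Cycle windows span consecutive beat foot times.  Cycles containing
    ADC-saturated samples (0 or full scale) are flagged invalid.
    Returns ``(ih, il, valid)``.
    """
    x = ppg.samples
    if np.any(x < 0):
        raise DataError("PPG contains negative intensities")
    feet = beats.foot_times
    if feet.size < 2:
        return np.empty(0), np.empty(0), np.empty(0, dtype=bool)
    ih, il, valid = [], [], []
    for t0, t1 in zip(feet[:-1], feet[1:]):
        i0 = max(0, int(math.floor(t0 * ppg.fs)))
        i1 = min(x.size, int(math.ceil(t1 * ppg.fs)))
        if i1 - i0 < 2:
            continue
        win = x[i0:i1]
        hi, lo = float(np.max(win)), float(np.min(win))
        saturated = (lo <= 0.0) or (hi >= ADC_MAX)
        ih.append(hi)
        il.append(lo)
        valid.append(not saturated and lo > 0)
    return np.asarray(ih), np.asarray(il), np.asarray(valid, dtype=bool)


def ppg_norm(ac_amplitude: float, dc_level: float) -> float:
    """Normalized PPG ``ln(AC) / ln(DC)`` (quotient-of-logs reading)."""
    if ac_amplitude <= 0:
        raise DataError(f"ac_amplitude must be > 0, got {ac_amplitude}")
    if dc_level <= 1:
        raise DataError(f"dc_level must be > 1, got {dc_level}")
    return math.log(ac_amplitude) / math.log(dc_level)


def ppg_norm_ratio(ac_amplitude: float, dc_level: float) -> float:
    """Alternative single-log reading ``ln(AC / DC)`` (non-default)."""
    if ac_amplitude <= 0 or dc_level <= 0:
        raise DataError("intensities must be > 0")
    return math.log(ac_amplitude / dc_level)


def session_pir(ppg: Signal, beats: BeatFeatures,
                eq12_reading: str = "quotient") -> PIRMeasurement:
    """Aggregate per-beat features into a session-level measurement.

    The session PIR is the median of per-beat IH/IL over valid cycles; AC
    is the median per-beat excursion and DC the median per-beat mean.
    """
    ih, il, valid = extract_ih_il(ppg, beats)
    if ih.size == 0 or not np.any(valid):
        raise DataError("no valid PPG cycles")
    ihv, ilv = ih[valid], il[valid]
    pir = ihv / ilv
    ac = float(np.median(ihv - ilv))
    x = ppg.samples
    feet = beats.foot_times
    means = []
    for t0, t1 in zip(feet[:-1], feet[1:]):
        i0 = max(0, int(math.floor(t0 * ppg.fs)))
        i1 = min(x.size, int(math.ceil(t1 * ppg.fs)))
        if i1 - i0 >= 2:
            means.append(float(np.mean(x[i0:i1])))
    dc = float(np.median(means))
    reading = ppg_norm if eq12_reading == "quotient" else ppg_norm_ratio
    return PIRMeasurement(
        ih=ih, il=il, pir=ih / np.where(il > 0, il, np.nan), valid=valid,
        pir_median=float(np.median(pir)),
        ppg_norm=reading(ac, dc),
    )


def delta_d_from_pir(pir_value: float, alpha: float) -> float:
    """Diameter excursion ``ln(PIR) / alpha`` in metres."""
    if pir_value < 1:
        raise DataError(f"pir must be >= 1, got {pir_value}")
    if alpha <= 0:
        raise DataError(f"alpha must be > 0, got {alpha}")
    return math.log(pir_value) / alpha


def alpha_calibrate(pir_cal: float, delta_d_ref: float) -> float:
    """Absorbance coefficient from one (PIR, reference deltaD) point."""
    if pir_cal <= 1:
        raise CalibrationError(f"pir_cal must be > 1, got {pir_cal}")
    if delta_d_ref <= 0:
        raise CalibrationError(f"delta_d_ref must be > 0, got {delta_d_ref}")
    return math.log(pir_cal) / delta_d_ref


def fit_diameter_model(observations: list[tuple[float, float]],
                       alpha: float | None = None) -> DiameterModel:
    """Least-squares line mapping ppg_norm to reference Dd (m)."""
    if len(observations) < 3:
        raise CalibrationError("need >= 3 (ppg_norm, dd) observations")
    x = np.asarray([o[0] for o in observations], dtype=float)
    y = np.asarray([o[1] for o in observations], dtype=float)
    if np.ptp(x) <= 0:
        raise CalibrationError("ppg_norm observations span a zero range")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return DiameterModel(
        slope=float(slope), intercept=float(intercept), alpha=alpha,
        fit_r2=r2, norm_range=(float(x.min()), float(x.max())),
    )
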