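"""Forward model of the analog front end applied to the piezo voltage.

Chain: parasitic-capacitance high-pass -> linear gain -> second-order
Sallen-Key low-pass -> half-supply DC offset -> clip to the rails.  Each
analog stage is discretized by the bilinear transform (no pre-warping:
cutoffs are far below fs/2 at the 5 kHz sensor rate, so warping error is
negligible and quantified in the tests).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .dsp import Signal
from .errors import ConfigError, InvalidInputError

log = logging.getLogger(__name__)

#: Default Sallen-Key low-pass cutoff target, Hz.
LPF_CUTOFF = 10.6


def _c_for_cutoff(r: float, fc: float) -> float:
    return 1.0 / (2.0 * math.pi * fc * r)


@dataclass(frozen=True)
class AFEParams:
    """Component values of the front end.

    Defaults hit the printed design targets (Cp = 8000 pF, R1 = R2 = 20 MOhm,
    gain 18x, low-pass cutoff 10.6 Hz); the remaining components are
    back-solved from those targets.  R5 = R6 and C2 = C3 by construction.
    """

    r1: float = 20e6
    r2: float = 20e6
    r3: float = 10e3
    r4: float = 170e3
    r5: float = 150e3
    r6: float = 150e3
    c1: float = 10e-6
    c2: float = _c_for_cutoff(150e3, LPF_CUTOFF)
    c3: float = _c_for_cutoff(150e3, LPF_CUTOFF)
    cp: float = 8e-9
    vcc: float = 3.3
    gain: float = 18.0

    def __post_init__(self) -> None:
        for name in ("r1", "r2", "r3", "r4", "r5", "r6", "c1", "c2", "c3",
                     "cp", "vcc", "gain"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")
        if not math.isclose(self.r5, self.r6, rel_tol=1e-9):
            raise InvalidInputError("R5 and R6 must be equal")
        if not math.isclose(self.c2, self.c3, rel_tol=1e-9):
            raise InvalidInputError("C2 and C3 must be equal")


def hp_cutoff(r1: float, cp: float) -> float:
    """High-pass cutoff of the parasitic-capacitance/load-resistor pair, Hz."""
    if r1 <= 0 or cp <= 0:
        raise InvalidInputError("r1 and cp must be > 0")
    return 1.0 / (2.0 * math.pi * r1 * cp)


def dc_offset(vp: Signal, vcc: float, r1: float, r2: float) -> Signal:
    """Add the resistor-divider DC level ``Vcc * R1 / (R1 + R2)``."""
    if r1 <= 0 or r2 <= 0:
        raise InvalidInputError("r1 and r2 must be > 0")
    offset = vcc * r1 / (r1 + r2)
    return Signal(vp.samples + offset, vp.fs, "V", vp.role, dict(vp.meta))


def sallen_key_cutoff(r5: float, r6: float, c2: float, c3: float) -> float:
    """Low-pass cutoff ``1 / (2*pi*sqrt(R5*C2*R6*C3))``, Hz."""
    if min(r5, r6, c2, c3) <= 0:
        raise InvalidInputError("all components must be > 0")
    return 1.0 / (2.0 * math.pi * math.sqrt(r5 * c2 * r6 * c3))


def sallen_key_analog_tf(params: AFEParams) -> tuple[list[float], list[float]]:
    """Analog (num, den) of the Sallen-Key stage in descending powers of s."""
    w0_sq = 1.0 / (params.r5 * params.c2 * params.r6 * params.c3)
    damp = 1.0 / (params.r6 * params.c2) + 1.0 / (params.r5 * params.c2)
    return [w0_sq], [1.0, damp, w0_sq]


def _bilinear_sos(b: list[float], a: list[float], fs: float) -> tuple[np.ndarray, np.ndarray]:
    bz, az = sps.bilinear(b, a, fs)
    return bz, az


def afe_apply(sig: Signal, params: AFEParams | None = None,
              fs: float | None = None) -> Signal:
    """Run the full front-end chain on a piezo voltage signal.

    Output is offset to ``Vcc * R1 / (R1 + R2)`` and clipped to [0, Vcc];
    clipping is logged as saturation.
    """
    if params is None:
        params = AFEParams()
    if fs is None:
        fs = sig.fs
    fc_lp = sallen_key_cutoff(params.r5, params.r6, params.c2, params.c3)
    if fs <= 4.0 * fc_lp:
        raise ConfigError(f"fs={fs} must exceed 4x the low-pass cutoff {fc_lp:.3g}")

    fc_hp = hp_cutoff(params.r1, params.cp)
    w_hp = 2.0 * math.pi * fc_hp
    bz, az = _bilinear_sos([1.0, 0.0], [1.0, w_hp], fs)
    y = sps.lfilter(bz, az, sig.samples)

    y = y * params.gain

    b_lp, a_lp = sallen_key_analog_tf(params)
    bz, az = _bilinear_sos(b_lp, a_lp, fs)
    y = sps.lfilter(bz, az, y)

    offset = params.vcc * params.r1 / (params.r1 + params.r2)
    y = y + offset
    n_clip = int(np.sum((y < 0) | (y > params.vcc)))
    if n_clip:
        log.warning("AFE saturation: %d samples clipped to the rails", n_clip)
    y = np.clip(y, 0.0, params.vcc)
    meta = dict(sig.meta)
    meta["afe_saturated_samples"] = n_clip
    return Signal(y, fs, "V", sig.role, meta)
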