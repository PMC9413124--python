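"""Physics-based synthetic signal generator with known ground truth.

Builds simulated subjects whose blood pressure, arterial geometry,
stiffness and optics are mutually consistent, then renders:

* two piezo-sensor voltage channels with a controlled transit delay
  (arterial displacement -> sealed-chamber pressure -> piezo voltage ->
  analog front end);
* a Beer-Lambert PPG intensity channel sharing the same cardiac cycle;
* additive white Gaussian noise at a configurable SNR.

Ground truth is chosen so that the package's own inverse models are
recoverable: DBP = k*MAP and SBP = MAP + (1-k)*DBP, and the wave speed
implied by the stiffness parameters at true MAP equals the wave speed
implied by the pressure-stiffness (beta) relation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import afe as afe_mod
from .dsp import Signal
from .errors import ConfigError, InvalidInputError, SimulationError
from .hemodynamics import (
    MMHG_TO_PA,
    ArterialState,
    StiffnessParams,
    mk_pwv,
    youngs_modulus,
)

#: Default membrane displacement amplitude driven by the pulse, m.
DISPLACEMENT_AMP = 5e-6

#: Piezo voltage per unit chamber pressure, V/Pa (millivolt-scale output).
PIEZO_SENSITIVITY = 1.8e-4

#: PPG source intensity (ADC-scale arbitrary units) and DC path length (m).
PPG_I0 = 6e5
PPG_D_DC = 0.02

#: ADC resolution of the PPG channel.
PPG_BITS = 18

# Beat template: systolic Gaussian + dicrotic reflection, in cycle fraction.
_SYS_CENTER, _SYS_WIDTH = 0.18, 0.055
_DIC_CENTER, _DIC_WIDTH, _DIC_AMP = 0.55, 0.09, 0.35


@dataclass(frozen=True)
class OpticsParams:
    """Beer-Lambert optics of the PPG site."""

    i0: float = PPG_I0
    alpha_dc: float = 60.0   # bulk absorbance epsilon*c, 1/m
    d_dc: float = PPG_D_DC   # DC photon path length, m
    alpha: float = 500.0     # arterial absorbance, 1/m

    def __post_init__(self) -> None:
        for name in ("i0", "alpha_dc", "d_dc", "alpha"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")

    @property
    def dc_intensity(self) -> float:
        """Intensity reaching the detector with the artery removed."""
        return self.i0 * math.exp(-self.alpha_dc * self.d_dc)


@dataclass(frozen=True)
class ChamberParams:
    """Sealed sensor chamber behind the contact membrane."""

    volume: float = 2e-7       # m^3
    area: float = 7.85e-5      # membrane cross-section, m^2
    gamma: float = 1.4         # ratio of specific heats (air)
    pa_internal: float = 101325.0  # internal chamber pressure, Pa
    rho_air: float = 1.204     # kg/m^3

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.area <= 0:
            raise InvalidInputError("volume and area must be > 0")


@dataclass(frozen=True)
class SubjectProfile:
    """Ground-truth description of one simulated subject."""

    subject_id: str
    true_sbp: float
    true_dbp: float
    true_map: float
    heart_rate: float
    arterial: ArterialState
    stiffness: StiffnessParams
    optics: OpticsParams
    seed: int

    def __post_init__(self) -> None:
        if not self.true_sbp > self.true_map > self.true_dbp > 0:
            raise InvalidInputError("require sbp > map > dbp > 0")
        if self.heart_rate <= 0:
            raise InvalidInputError("heart_rate must be > 0")

    @property
    def pwv(self) -> float:
        """Wave speed implied by the stiffness law at true MAP, m/s."""
        return mk_pwv(self.arterial, youngs_modulus(self.stiffness, self.true_map))

    def to_dict(self) -> dict:
        a, s, o = self.arterial, self.stiffness, self.optics
        return {
            "subject_id": self.subject_id,
            "true_sbp": self.true_sbp,
            "true_dbp": self.true_dbp,
            "true_map": self.true_map,
            "heart_rate": self.heart_rate,
            "arterial": {"dd": a.dd, "h": a.h, "delta_d": a.delta_d,
                         "rho_blood": a.rho_blood, "d": a.d},
            "stiffness": {"e0": s.e0, "xi": s.xi, "beta": s.beta, "k": s.k},
            "optics": {"i0": o.i0, "alpha_dc": o.alpha_dc, "d_dc": o.d_dc,
                       "alpha": o.alpha},
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectProfile":
        return cls(
            subject_id=d["subject_id"],
            true_sbp=d["true_sbp"],
            true_dbp=d["true_dbp"],
            true_map=d["true_map"],
            heart_rate=d["heart_rate"],
            arterial=ArterialState(**d["arterial"]),
            stiffness=StiffnessParams(**d["stiffness"]),
            optics=OpticsParams(**d["optics"]),
            seed=d["seed"],
        )


@dataclass(frozen=True)
class CohortRanges:
    """Uniform sampling ranges for :func:`make_cohort`."""

    map_mmhg: tuple[float, float] = (70.0, 120.0)
    hr_bpm: tuple[float, float] = (50.0, 100.0)
    dd_mm: tuple[float, float] = (2.0, 3.0)
    delta_d_ratio: tuple[float, float] = (0.03, 0.09)
    h_mm: tuple[float, float] = (0.2, 0.4)
    beta: tuple[float, float] = (3.0, 9.0)
    xi_per_mmhg: tuple[float, float] = (0.012, 0.020)
    alpha_per_m: tuple[float, float] = (400.0, 600.0)
    dc_absorbance: tuple[float, float] = (1.0, 1.4)
    k: float = 0.76
    rho_blood: float = 1060.0

    def __post_init__(self) -> None:
        for name in ("map_mmhg", "hr_bpm", "dd_mm", "delta_d_ratio", "h_mm",
                     "beta", "xi_per_mmhg", "alpha_per_m", "dc_absorbance"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigError(f"invalid range for {name}: ({lo}, {hi})")
        if not 0 < self.k <= 1:
            raise ConfigError(f"k must be in (0, 1], got {self.k}")


def make_cohort(n_subjects: int, seed: int,
                ranges: CohortRanges | None = None) -> list[SubjectProfile]:
    """Draw ``n_subjects`` internally consistent subjects, deterministically.

    MAP, heart rate, geometry, stiffness index and optics are uniform over
    the configured ranges.  E0 is back-solved so the exponential-modulus
    route and the beta route agree on the subject's wave speed at true MAP.
    """
    if n_subjects < 1:
        raise ConfigError("n_subjects must be >= 1")
    if ranges is None:
        ranges = CohortRanges()
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_subjects):
        u = lambda pair: float(rng.uniform(*pair))  # noqa: E731
        map_mmhg = u(ranges.map_mmhg)
        hr = u(ranges.hr_bpm)
        dd = u(ranges.dd_mm) * 1e-3
        ratio = u(ranges.delta_d_ratio)
        h = u(ranges.h_mm) * 1e-3
        beta = u(ranges.beta)
        xi = u(ranges.xi_per_mmhg)
        alpha = u(ranges.alpha_per_m)
        dc_abs = u(ranges.dc_absorbance)
        sub_seed = int(rng.integers(0, 2**31 - 1))

        k = ranges.k
        dbp = map_mmhg * k
        sbp = map_mmhg + (1.0 - k) * dbp
        arterial = ArterialState(dd=dd, h=h, delta_d=ratio * dd,
                                 rho_blood=ranges.rho_blood)
        # beta route: MAP_Pa = 2*rho*pwv^2*Dd/(beta*D); with D = Dd:
        pwv_sq = map_mmhg * MMHG_TO_PA * beta * arterial.d / (2.0 * ranges.rho_blood * dd)
        # modulus route back-solve: pwv^2 = E0*exp(xi*MAP)*h/(D*rho)
        e0 = pwv_sq * ranges.rho_blood * arterial.d / (h * math.exp(xi * map_mmhg))
        stiffness = StiffnessParams(e0=e0, xi=xi, beta=beta, k=k)
        optics = OpticsParams(i0=PPG_I0, alpha_dc=dc_abs / PPG_D_DC,
                              d_dc=PPG_D_DC, alpha=alpha)
        subjects.append(SubjectProfile(
            subject_id=f"sim{i:03d}",
            true_sbp=sbp, true_dbp=dbp, true_map=map_mmhg,
            heart_rate=hr, arterial=arterial, stiffness=stiffness,
            optics=optics, seed=sub_seed,
        ))
    return subjects


def _template(u: np.ndarray) -> np.ndarray:
    """Beat template over cycle fraction u (compactly supported in [0, 1])."""
    sys = np.exp(-((u - _SYS_CENTER) ** 2) / (2.0 * _SYS_WIDTH**2))
    dic = _DIC_AMP * np.exp(-((u - _DIC_CENTER) ** 2) / (2.0 * _DIC_WIDTH**2))
    return sys + dic


def template_fiducial_fraction() -> float:
    """Cycle fraction of the template's maximum upslope (foot fiducial)."""
    u = np.linspace(0.0, 0.4, 40001)
    d = np.gradient(_template(u), u)
    return float(u[int(np.argmax(d))])


def _beat_schedule(heart_rate: float, duration: float, seed: int,
                   jitter: float = 0.02) -> tuple[np.ndarray, np.ndarray]:
    """Beat onset times and per-beat cycle lengths with +/-jitter."""
    rng = np.random.default_rng(seed)
    t_mean = 60.0 / heart_rate
    onsets, periods = [], []
    t = -0.5 * t_mean  # start before zero so the first visible beat is whole
    while t < duration + t_mean:
        period = t_mean * (1.0 + rng.uniform(-jitter, jitter))
        onsets.append(t)
        periods.append(period)
        t += period
    return np.asarray(onsets), np.asarray(periods)


def _waveform(t: np.ndarray, onsets: np.ndarray, periods: np.ndarray) -> np.ndarray:
    """Evaluate the quasi-periodic pulse wave at arbitrary times."""
    out = np.zeros_like(t)
    for t0, period in zip(onsets, periods):
        # half-cycle margins: Gaussian tails are < 1e-20 at the window edges,
        # so adjacent beats sum without truncation steps
        lo = np.searchsorted(t, t0 - 0.5 * period)
        hi = np.searchsorted(t, t0 + 1.5 * period)
        if hi > lo:
            u = (t[lo:hi] - t0) / period
            out[lo:hi] += _template(u)
    return out


def chamber_response(displacement: Signal, params: ChamberParams | None = None) -> Signal:
    """Adiabatic chamber pressure from membrane displacement.

    ``Pa(t) = -gamma * PA * A * x(t) / V`` -- linear and memoryless; inward
    (negative) displacement raises the chamber pressure.
    """
    if params is None:
        params = ChamberParams()
    x = displacement.samples
    if np.max(np.abs(params.area * x)) >= params.volume:
        raise SimulationError("displaced volume A*x exceeds chamber volume")
    pa = -params.gamma * params.pa_internal * params.area * x / params.volume
    return Signal(pa, displacement.fs, "Pa", displacement.role,
                  dict(displacement.meta))


def gen_pulse_pair(
    profile: SubjectProfile,
    duration: float = 25.0,
    fs: float = 5000.0,
    sensor_distance: float = 0.02,
    apply_afe: bool = True,
    chamber: ChamberParams | None = None,
    afe_params: "afe_mod.AFEParams | None" = None,
    seed: int | None = None,
) -> tuple[Signal, Signal, float]:
    """Render the two piezo channels and return the true transit time.

    The distal channel is the proximal waveform evaluated at ``t - ptt``
    (exact continuous-time delay), where ``ptt = sensor_distance / PWV`` and
    PWV follows from the subject's stiffness law at true MAP.
    """
    if duration < 5.0:
        raise ConfigError("duration must be >= 5 s")
    if fs < 500.0:
        raise ConfigError("fs must be >= 500 Hz")
    if sensor_distance < 0:
        raise ConfigError("sensor_distance must be >= 0")
    pwv = profile.pwv
    true_ptt = sensor_distance / pwv
    if 0 < true_ptt < 2.0 / fs:
        raise ConfigError(
            f"true_ptt {true_ptt:.2e} s unresolvable: below 2 sample periods at fs={fs}"
        )
    if seed is None:
        seed = profile.seed
    onsets, periods = _beat_schedule(profile.heart_rate, duration, seed)
    t = np.arange(int(round(duration * fs))) / fs
    frac = template_fiducial_fraction()
    meta = {
        "true_ptt": true_ptt,
        "true_pwv": pwv,
        "beat_onsets": onsets.tolist(),
        "beat_fiducials": (onsets + frac * periods).tolist(),
        "subject_id": profile.subject_id,
    }

    chans = []
    for role, delay in (("piezo_proximal", 0.0), ("piezo_distal", true_ptt)):
        w = _waveform(t - delay, onsets, periods)
        disp = Signal(-DISPLACEMENT_AMP * w, fs, "m", role, dict(meta))
        pressure = chamber_response(disp, chamber)
        volts = Signal(PIEZO_SENSITIVITY * pressure.samples, fs, "V", role,
                       dict(meta))
        if apply_afe:
            volts = afe_mod.afe_apply(volts, afe_params)
        chans.append(volts)
    return chans[0], chans[1], true_ptt


def gen_ppg(
    profile: SubjectProfile,
    duration: float = 25.0,
    fs: float = 100.0,
    quantize: bool = True,
    seed: int | None = None,
) -> Signal:
    """Render the Beer-Lambert PPG intensity channel.

    Per beat the received intensity swings between
    ``IH = I0 * exp(-aDC*dDC) * exp(-alpha*Dd)`` (diastole) and
    ``IL = I0 * exp(-aDC*dDC) * exp(-alpha*Ds)`` (systole), following the
    shared beat template phase; optionally quantized to the 18-bit ADC grid.
    """
    if fs < 50.0:
        raise ConfigError("fs must be >= 50 Hz")
    o = profile.optics
    a = profile.arterial
    ih = o.dc_intensity * math.exp(-o.alpha * a.dd)
    il = o.dc_intensity * math.exp(-o.alpha * a.ds)
    if not 0 < il <= ih < 2**PPG_BITS:
        raise ConfigError(
            f"optics produce intensities outside the ADC range: IH={ih:.1f}, IL={il:.1f}"
        )
    if seed is None:
        seed = profile.seed
    onsets, periods = _beat_schedule(profile.heart_rate, duration, seed)
    t = np.arange(int(round(duration * fs))) / fs
    w = _waveform(t, onsets, periods)
    w = w / _template(np.asarray([_SYS_CENTER]))[0]  # normalize systolic peak to 1
    d_t = a.dd + a.delta_d * np.clip(w, 0.0, 1.0)
    intensity = o.dc_intensity * np.exp(-o.alpha * d_t)
    sig = Signal(intensity, fs, "counts", "ppg",
                 {"true_ih": ih, "true_il": il, "beat_onsets": onsets.tolist(),
                  "subject_id": profile.subject_id})
    if quantize:
        sig = quantize_adc(sig, PPG_BITS)
    return sig


def quantize_adc(sig: Signal, bits: int = PPG_BITS) -> Signal:
    """Round to integer counts and clip to the [0, 2^bits - 1] ADC range."""
    q = np.clip(np.round(sig.samples), 0, 2**bits - 1)
    return Signal(q, sig.fs, sig.unit, sig.role, dict(sig.meta))


def add_noise(sig: Signal, snr_db: float | None, seed: int) -> Signal:
    """Additive white Gaussian noise at the requested SNR (dB).

    SNR is defined on the AC (mean-removed) signal power.  ``None`` or
    ``inf`` returns an unchanged copy.  Deterministic given ``seed``.
    """
    if snr_db is None or math.isinf(snr_db):
        return Signal(sig.samples.copy(), sig.fs, sig.unit, sig.role,
                      dict(sig.meta))
    if not math.isfinite(snr_db):
        raise ConfigError("snr_db must be finite, None or +inf")
    ac = sig.samples - np.mean(sig.samples)
    p_signal = float(np.mean(ac**2))
    sigma = math.sqrt(p_signal) * 10.0 ** (-snr_db / 20.0)
    rng = np.random.default_rng(seed)
    noisy = sig.samples + rng.normal(0.0, sigma, sig.samples.size)
    meta = dict(sig.meta)
    meta["snr_db"] = snr_db
    return Signal(noisy, sig.fs, sig.unit, sig.role, meta)
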