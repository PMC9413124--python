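"""Schema-validated pipeline configuration.

Every default that has a printed design target elsewhere in the package
(band edges 0.7/9.5 Hz, blood density 1.06 g/mL, tracking coefficient
0.76, parasitic capacitance 8000 pF, low-pass cutoff 10.6 Hz, gain 18x,
5 kHz piezo / 100 Hz PPG sampling, 18-bit PPG ADC) is reproduced here so
the zero-config path matches those targets.  Unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal

from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import ConfigError


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AFEConfig(_Block):
    enabled: bool = True
    r1: float = 20e6
    r2: float = 20e6
    r3: float = 10e3
    r4: float = 170e3
    r5: float = 150e3
    c1: float = 10e-6
    cp: float = 8e-9
    vcc: float = 3.3
    gain: float = 18.0
    lpf_cutoff_hz: float = 10.6

    def to_params(self):
        from .afe import AFEParams, _c_for_cutoff

        c = _c_for_cutoff(self.r5, self.lpf_cutoff_hz)
        return AFEParams(r1=self.r1, r2=self.r2, r3=self.r3, r4=self.r4,
                         r5=self.r5, r6=self.r5, c1=self.c1, c2=c, c3=c,
                         cp=self.cp, vcc=self.vcc, gain=self.gain)


class DSPConfig(_Block):
    fs_work: float = 200.0
    f_hp: float = 0.7
    f_lp: float = 9.5
    decay_tau_s: float = 2.0
    threshold_frac: float = 0.5
    refractory_s: float = 0.3
    deriv_smooth_s: float = 0.06
    edge_guard_s: float | None = 2.0
    pair_window_s: float = 0.15


class PIRConfig(_Block):
    eq12_reading: Literal["quotient", "ratio"] = "quotient"


class RangesConfig(_Block):
    map_mmhg: tuple[float, float] = (70.0, 120.0)
    hr_bpm: tuple[float, float] = (50.0, 100.0)
    dd_mm: tuple[float, float] = (2.0, 3.0)
    delta_d_ratio: tuple[float, float] = (0.03, 0.09)
    h_mm: tuple[float, float] = (0.2, 0.4)
    beta: tuple[float, float] = (3.0, 9.0)
    xi_per_mmhg: tuple[float, float] = (0.012, 0.020)
    alpha_per_m: tuple[float, float] = (400.0, 600.0)
    dc_absorbance: tuple[float, float] = (1.0, 1.4)


class SimulationConfig(_Block):
    n_subjects: int = 20
    n_sessions: int = 3
    duration_s: float = 25.0
    fs_piezo: float = 5000.0
    fs_ppg: float = 100.0
    snr_db: float | None = 20.0
    quantize_bits: int = 18
    ranges: RangesConfig = RangesConfig()

    def to_ranges(self, k: float, rho_blood: float):
        from .sensor_sim import CohortRanges

        return CohortRanges(**self.ranges.model_dump(), k=k, rho_blood=rho_blood)


class ValidationConfig(_Block):
    c1_mean_bound: float = 5.0
    c1_sd_bound: float = 8.0


class PipelineConfig(_Block):
    seed: int = 0
    sensor_distance_m: float = 0.02
    rho_blood: float = 1060.0
    k: float = 0.76
    tracking_variant: Literal["printed", "pp"] = "printed"
    afe: AFEConfig = AFEConfig()
    dsp: DSPConfig = DSPConfig()
    pir: PIRConfig = PIRConfig()
    simulation: SimulationConfig = SimulationConfig()
    validation: ValidationConfig = ValidationConfig()

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        try:
            return cls.model_validate(raw)
        except ValidationError as exc:
            raise ConfigError(str(exc)) from exc

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
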