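# pulsebp

Cuffless blood-pressure estimation from dual-site arterial pulse waves and a
photoplethysmography (PPG) channel, with a physics-based synthetic signal
generator so every stage is testable without recorded human data.

Two estimation arms are implemented and compared:

* **regression** — `P = K1·ln(PTT) + K2`, fitted on calibration anchors
  pooled across subjects;
* **P–β** — a hemodynamic model: pulse wave velocity (PWV) from the pulse
  transit time (PTT) between two piezo sensors, arterial diameter change
  from the PPG intensity ratio (PIR) via Beer–Lambert absorption, mean
  arterial pressure from a one-point-calibrated stiffness constant β, pulse
  pressure from the diameter excursion, and SBP/DBP tracked from MAP with a
  fixed coefficient `k = 0.76`.

Cohort agreement is scored with Bland–Altman statistics, Pearson
correlation and the ANSI/AAMI/ISO 81060-2 criterion 1/2 bounds.

## Layout

| Module | Role |
| --- | --- |
| `pulsebp.hemodynamics` | closed-form relations: Moens–Korteweg, exponential Young's modulus, log-PTT regression, pulse pressure, P–β MAP, SBP/DBP tracking |
| `pulsebp.sensor_sim` | synthetic subjects and signals: chamber physics, Beer–Lambert PPG, controlled inter-channel delay, noise |
| `pulsebp.afe` | analog-front-end forward model: parasitic-capacitance high-pass, gain, Sallen–Key low-pass, rails |
| `pulsebp.dsp` | decimation, FIR band-pass (0.7–9.5 Hz), dynamic-threshold beat detection, sub-sample foot fiducials, PTT/PWV |
| `pulsebp.pir` | per-beat IH/IL, PIR, normalized PPG, diameter-excursion estimation and the diameter regression model |
| `pulsebp.pipeline` | per-subject calibration, per-session estimation, cohort orchestration |
| `pulsebp.validation` | Bland–Altman, Pearson, ISO 81060-2 criterion 1 and 2 |
| `pulsebp.io_cli` | session CSV dialect, cohort manifests, configuration, CLI |

## CLI

```bash
pulsebp simulate --n 20 --sessions 3 --seed 42 --out cohortdir/
pulsebp calibrate --session cohortdir/sim000_s0.csv \
    --manifest cohortdir/manifest.json --out cal.json
pulsebp estimate --session cohortdir/sim000_s1.csv --cal cal.json \
    --method p_beta
pulsebp cohort --seed 42 --out cohort.csv      # full synthetic run, both arms
pulsebp validate --cohort cohort.csv --method p_beta --out report.json
```

Signal files are long-format CSV (`time_s,channel,value,unit`, channels
`piezo_proximal`/`piezo_distal`/`ppg`) with a JSON sidecar carrying the
per-channel sampling rates, subject id and sensor separation.  All
configuration lives in one JSON document (see `pulsebp.config`); defaults
reproduce the printed design targets (0.7/9.5 Hz band, 1.06 g/mL blood
density, k = 0.76, 8000 pF, 10.6 Hz low-pass, 18× gain, 5 kHz / 100 Hz
sampling, 18-bit PPG ADC).

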