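# ettnir

Simulation and estimation toolkit for **optical monitoring of endotracheal-tube
(ETT) displacement**. An ETT secured in the trachea can still migrate with head
movement; a displacement of even a few millimetres matters in neonates. One
monitoring approach attaches a side-firing optical fiber to the tube, drives it
with 810 nm near-infrared light (near the hemoglobin isosbestic point, where
tissue absorption is low and insensitive to oxygenation), and tapes a small
board of five phototransistors to the chest skin. As the tube tip moves, the
spot of diffusely transmitted light on the skin moves with it, and the tube
displacement can be recovered from the sensor voltages.

This package implements the complete computational chain for such a device,
for researchers in biomedical optics who want to study or extend the method
without bench hardware:

* **`ettnir.tissue` / `ettnir.montecarlo`** — a layered-slab Monte Carlo model
  of NIR photon transport from the tracheal lumen to the skin (five-layer
  tracheal tissue stack, 16 mm total; Henyey–Greenstein scattering, Fresnel
  boundaries, Russian roulette), producing skin exitance profiles and
  simulated ratio curves in planar (2-D) and full 3-D geometry.
* **`ettnir.electronics`** — the detector-board forward model: sensors P1–P3
  spaced 10 mm along the tube axis, P4/P5 offset ±3.5 mm for rotation
  monitoring, linear-with-saturation phototransistor response off a 5 V rail,
  the 9.7 Hz RC output filter, 250 Hz sampling and 14-bit quantization.
* **`ettnir.calibration`** — the estimation algorithm, packaged as a
  scikit-learn regressor (`DisplacementEstimator`).
* **`ettnir.synthetic`** — a seeded generator of calibration logs and sweep
  sessions with the structure of the animal protocol (±15 mm range, ~1 mm
  steps, multiple cycles, ±40° rotations, hand-jitter vs linear-stage modes).
* **`ettnir.agreement`** — method-comparison statistics: OLS of estimate on
  reference, Bland–Altman limits of agreement with constant or
  regression-estimated bias, and cross-cycle interpolation summaries.

## The estimator

Voltages `VP1, VP2, VP3` give two ratios

```
r12 = VP1 / VP2        r32 = VP3 / VP2
```

which are gain- and coupling-invariant (common factors cancel). Calibration
measures the ratios at five displacements d ∈ {−10, −5, 0, +5, +10} mm against
a reference position sensor and fits four interpolating quadratics r = f(d):
`f12High` and `f32Low` on the negative half-range, `f32High` and `f12Low` on
the positive half-range. At run time, `r12(d)/r12(0) > 1` classifies the move
as outward (d < 0), `< 1` as inward; each branch quadratic is inverted on its
monotone half-range, and the final estimate fuses the high- and low-signal
branch inversions

```
d_final = w · d_high + (1 − w) · d_low ,   w = 0.95,
```

weighting the larger ratio (better SNR) almost exclusively.

## Worked example

```python
import numpy as np
from ettnir import (SpotProfileParams, MotionProtocol, NoiseSpec, ElectronicsSpec,
                    make_forward_curves, generate_calibration_log, generate_session,
                    fit_calibration, track_series, bland_altman)
from ettnir.calibration import calibration_set_from_log

curves = make_forward_curves(SpotProfileParams())       # synthetic light spot
electronics = ElectronicsSpec()

cal = calibration_set_from_log(generate_calibration_log(curves, electronics))
model = fit_calibration(cal, weight_w=0.95)
print("r12 at calibration nodes:", np.round(cal.r12, 3))

session, _ = generate_session(
    curves,
    MotionProtocol(n_cycles=5, seed=42, rotation_schedule_deg=(0.0,)),
    NoiseSpec(voltage_sd_v=0.01),
    electronics,
)
estimates = track_series(session, model)
ok = np.isfinite(estimates.d_final_mm)
report = bland_altman(estimates.d_final_mm[ok].to_numpy(),
                      estimates.ref_mm[ok].to_numpy(), bias_model="regression")
print(f"n = {report.n} frames")
print(f"R^2 = {report.r_squared:.3f}")
print(f"bias(mean) = {report.bias_intercept:+.3f} {report.bias_slope:+.4f} * mean  (mm)")
print(f"95% limits of agreement: +/- {report.loa_halfwidth_mm:.2f} mm")
```

prints

```
r12 at calibration nodes: [2.774 1.    0.36  0.13  0.047]
n = 30500 frames
R^2 = 0.979
bias(mean) = -0.000 -0.1536 * mean  (mm)
95% limits of agreement: +/- 2.29 mm
```

The ratio falls monotonically from 2.77 at −10 mm to 0.05 at +10 mm — the
negative branch where `r12` is the high-signal channel. Over five ±15 mm sweep
cycles with 10 mV voltage noise, the estimates track the reference with
R² ≈ 0.98; the negative bias slope reflects the quadratic model's
underestimation beyond the ±10 mm calibration range, and 95% of frame-wise
differences fall within ±2.3 mm.

The same pipeline is scriptable from the shell:

```bash
ettnir synth --seed 3 --out session
ettnir calibrate --log session.cal.csv --out model.json
ettnir estimate --log session.csv --model model.json --out estimates.csv
ettnir validate --estimates estimates.csv --out report.json --plot report
ettnir simulate --mode 2d --packets 2000000 --seed 1 --out sim
```

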