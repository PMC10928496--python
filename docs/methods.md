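# Methods

## Photon transport model

Tissue between the tracheal lumen and the chest skin is a stack of
plane-parallel homogeneous layers; the default is a five-layer tracheal model
(lumen → skin: mucosal/submucosal/glandular tissue 1.5 mm, cartilage 1.0 mm,
adipose-rich 6.5 mm, muscle-rich 6.5 mm, skin 0.5 mm; 16 mm total) with
810 nm absorption and scattering coefficients, anisotropy and refractive
index per layer. Curvature of the trachea is neglected (slab approximation),
layers are uniform, and transport is steady-state, unpolarized and
monochromatic.

The kernel is a classic photon-packet random walk: free paths are sampled
exponentially against μt = μa + μs of the current layer (dimensionless step
carried across interfaces), each interaction deposits the weight fraction
μa/μt and scatters the remainder, and packets below weight 10⁻⁴ play Russian
roulette with survival probability 0.1 (survivors boosted ×10, keeping the
expectation unbiased). Every layer interface and both outer surfaces apply
unpolarized Fresnel reflection/refraction; the outer half-spaces are air
(n = 1.0). Packets wandering beyond a configurable lateral half-width
(default 40 mm) are tallied as lateral escape. The tally (absorbed + skin
exitance + lumen reflectance + lateral escape = launched) balances to ~10⁻⁶
relative in practice; the suite enforces ≤10⁻³.

The source models a side-firing fiber tip pressed to the lumen wall: a point
emitter with either a pencil beam or a Lambertian (cosine) lobe about the
inward normal, optionally tilted to emulate tube rotation (in-plane for 2-D,
in the perpendicular plane for 3-D, matching rotation of the tube about its
own axis).

Two geometries:

* **planar2D** — true planar transport: position and direction live in the
  x–z plane and the scattering deflection is a single signed angle drawn from
  the wrapped-Cauchy density, the exact planar analogue of Henyey–Greenstein:
  its mean deflection cosine equals g and its inverse CDF is closed-form.
* **slab3D** — standard 3-D transport with Henyey–Greenstein inverse-CDF
  polar sampling and uniform azimuth; skin exitance is tallied on an (x, y)
  map.

Skin exitance is binned at 0.5 mm (default) and normalized to 1 W launched.
Profiles are smoothed with a 6-bin centered moving average (edges use the
available shorter window); per-bin Monte Carlo standard errors
(√Σw² / N, propagated through smoothing) drive the statistical tolerances in
the tests. On the default stack a 2×10⁶-packet planar run gives a
half-intensity half-width of ≈7.5 mm; this run size (rather than tens of
millions of packets) keeps a full run to roughly two minutes on one core
while leaving the half-width estimate's Monte Carlo scatter well inside the
±1.5 mm acceptance band. Ratio curves for the sensors are derived from a
single centered run: displacing the tube by d shifts the skin spot to x = d,
so sensors sample the same profile at x_i − d.

In 3-D runs the ratios r12/r32 are computed from the x-marginal of the
exitance map (for a separable spot I(x,y) ≈ f(x)g(y) the marginal gives the
same ratios as a center strip, at far lower variance), while P4/P5 are read
from strips at their true ±3.5 mm offsets.

Deliberate differences from a mesh-based finite-element transport code: no
mesh (layered slab only), and the planar mode is genuine 2-D transport rather
than a slice of 3-D. The lateral domain size, outer media and bin width are
package choices — a half-width tolerance of ±1.5 mm absorbs these modeling
degrees of freedom.

## Sensor and electronics model

Sensor i collects the exitance integrated over
[x_i − d − a, x_i − d + a] with aperture half-width a = 0.5 mm (one bin;
point sampling is the a → 0 limit). Board coordinates: P1 at −10 mm
(proximal), P2 at 0, P3 at +10 mm; positive displacement (tube pushed in)
moves the spot toward P3, which makes r12 the high-signal ratio for negative
displacements. In planar mode P4/P5 are the P2 channel scaled by a
configurable attenuation (default 0.8, matching their lower peaks 3.5 mm off
the spot track); 3-D runs compute them from the exitance map.

The phototransistor is modeled linear-with-saturation,
V = min(V_supply, k_i · I), since no transfer curve is available for the
device; per-sensor responsivities k_i default to 1 and are randomizable to
emulate gain heterogeneity. The RC output filter (200 kΩ, 82 nF → 9.7 Hz) is
a single-pole discrete filter with the exact pole exp(−2π f_c / f_s) at
f_s = 250 Hz and DC gain exactly 1, state-initialized at the first sample.
The ADC rounds to 2¹⁴ uniform levels over [0, 5 V], rounding the level index
half away from zero (ties are measure-zero under Gaussian noise).

## Calibration and estimation

Each branch quadratic interpolates its three calibration nodes exactly
(3-point Vandermonde solve, not least squares — three points determine the
parabola; dwell samples are averaged before fitting, discarding the first 25%
of each dwell for filter settling). A fitted branch whose vertex falls inside
its half-range is flagged non-monotone. Inversion solves the quadratic on the
half-range; a ratio with no in-range root clamps to the range end with the
nearest fitted ratio and sets an `out_of_range` flag rather than
extrapolating, because extrapolation beyond the ±10 mm calibration range is
the dominant source of outliers. A near-degenerate branch (curvature and
slope both ~0) raises. Exactly-baseline ratios return d = 0 directly (the
direction rule does not assign a branch at r12 = r12(0)); a configurable
deadband (default 0, i.e. the strict sign rule) is available for noisy
streams. The signal floor on VP2 defaults to 0.02 V (~65 ADC levels) to guard
against ratio blow-up when the board decouples. The rotation alert flags
frames whose VP4/VP2 or VP5/VP2 deviates more than a preset fraction
(default 0.30) from the calibration-time baseline; it never feeds back into
the displacement estimate.

The fusion weight w = 0.95 is exposed as `weight_high` and not optimized.
`DisplacementEstimator` follows scikit-learn conventions (`fit(X, y)` on the
five ratio pairs, `predict`, `get_params`/`set_params`, trailing-underscore
fitted attributes), so it clones and composes with sklearn tooling; the
spec-level operations (`fit_calibration`, `estimate_displacement`,
`invert_branch`, `track_series`, ...) are thin functional wrappers.

## Synthetic sessions

The generator emulates the measurement protocol: a calibration log of five
dwells at −10…+10 mm, then back-and-forth sweep cycles 0 → +15 → −15 → 0 mm
in 1 mm steps with a dwell (default 0.4 s at 250 Hz) per step; the first
rotation-schedule entry (0°) runs `n_cycles`, additional entries (±40°
default) one cycle each. The default spot is a closed-form pseudo-Gaussian
(σ = 7 mm, whose half-intensity half-width σ√(2 ln 2) ≈ 8.2 mm is slightly
broader than the simulated profile, as measured curves are), with per-sensor
gains, a broadening factor, an optional peak offset, and a rotation model
that shifts the spot perpendicular to the sensor axis by 0.08 mm/deg
(≈ r·sinθ for a tip riding a ~5 mm-radius tracheal wall) — a common-mode
factor for P1–P3 that cancels in the ratios, and an antisymmetric one for
P4/P5. An MC-driven mode replaces the closed form with a transport run for
end-to-end physics realism.

Noise model (defaults are package choices for sensitivity studies — the
device's noise was never characterized quantitatively): additive voltage
noise (default 10 mV), optional multiplicative (fractional) noise, optional
per-cycle gain drift. `linear_stage` mode hits the commanded positions
exactly; `manual` mode adds per-step position jitter (0.3 mm SD; the
reference column records the jittered truth, as a reference sensor would)
**and** per-step per-sensor coupling fluctuations (5% SD) emulating the tube
rotations, tilting and hand tremor of direct manipulation — disturbances the
reference sensor cannot see, which is what makes hand-maneuvered sessions
agree less well than stage-driven ones. The generated sessions do not model
breathing or cardiac motion, ambient light, or contact-pressure drift, so
passing tests bound algorithmic error under the stated noise, not in vivo
performance.

## Agreement statistics

OLS of estimate on reference (R² is the squared Pearson correlation,
identical to 1 − SSR/SST for simple OLS). Bland–Altman supports a constant
bias (mean difference, limits ±1.96·SD of differences) and a regression bias
(OLS of difference on pair mean, limits ±1.96·SD of residuals about the
line) for the case of differences trending with magnitude; the residual SD
is homoscedastic — no variance-regression model is fitted. Sample SDs use
the n−1 denominator throughout. Cycle summaries split a session into maximal
monotone sweeps of the truth displacement, average dwell plateaus, linearly
interpolate each sweep onto a uniform grid (default 1 mm), and report the
cross-sweep mean and 1.96·SD band; grid points covered by fewer than two
sweeps get a NaN band, and the turning sample is shared by adjacent sweeps.

## Limitations

* The slab kernel ignores tracheal curvature and intra-layer heterogeneity;
  absolute exitance levels are therefore indicative only, though ratio
  *trends* are robust to uniform property errors.
* Planar (2-D) transport is not a slice of 3-D transport; widths agree only
  to within the modeling tolerance discussed above.
* The pseudo-Gaussian session generator is a statistical stand-in for animal
  data; agreement numbers computed on it characterize the pipeline, not the
  device.
* Estimates clamp at the calibration range ends; sustained operation beyond
  ±10 mm degrades gracefully but systematically underestimates.
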