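"""Synthetic measurement sessions emulating the animal experiment protocol.

Real sessions move the tube back and forth over +/-15 mm in roughly 1 mm
steps for several cycles (with a reference position sensor logging the true
displacement), after a five-point calibration run, sometimes with the tube
rotated +/-40 deg.  This module generates voltage logs with that structure
so every downstream stage is testable without hardware: a forward model
maps displacement to the five sensor voltages (either a closed-form
pseudo-Gaussian light spot or a Monte Carlo exitance profile), a motion
protocol drives the commanded positions, and a noise model plus the
electronics chain (saturation, RC filter, quantization) produce the log.

The pseudo-Gaussian spot reproduces the qualitative features of in vivo
curves — per-sensor gain heterogeneity, lower P4/P5 peaks (3.5 mm off the
spot track), broadening relative to simulation, optional peak offset — but
not tissue heterogeneity or contact-pressure drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .electronics import (
    VOLTAGE_COLUMNS,
    ElectronicsSpec,
    SensorGeometry,
    VoltageSeries,
    apply_lowpass,
    quantize_and_noise,
    sensor_intensities,
)
from .montecarlo import SourceSpec, run_mc, smooth_profile
from .tissue import TissueStack

__all__ = [
    "SpotProfileParams",
    "MotionProtocol",
    "NoiseSpec",
    "ForwardCurves",
    "make_forward_curves",
    "generate_session",
    "generate_calibration_log",
]


@dataclass(frozen=True)
class SpotProfileParams:
    """Parametric model of the skin light spot seen by the sensors.

    ``width_sigma_mm`` is the Gaussian sigma of the spot (default 7 mm, whose
    half-intensity half-width sigma*sqrt(2 ln 2) ~ 8.2 mm matches the breadth
    of measured in vivo curves, slightly wider than simulation);
    ``broadening_factor`` scales it further.  ``peak_offset_mm`` shifts the
    spot center off d = 0, as seen on heterogeneous tissue.
    """

    shape: Literal["pseudo_gaussian", "mc_profile"] = "pseudo_gaussian"
    width_sigma_mm: float = 7.0
    peak_voltage_v: float = 3.0
    per_sensor_gain: tuple[float, float, float, float, float] = (1.0, 1.0, 1.0, 1.0, 1.0)
    broadening_factor: float = 1.0
    peak_offset_mm: float = 0.0
    #: lateral spot shift per degree of tube rotation; ~r*sin(theta)/theta for
    #: a fiber tip riding on a ~5 mm radius tracheal wall
    rotation_shift_mm_per_deg: float = 0.08

    def __post_init__(self) -> None:
        if self.width_sigma_mm <= 0:
            raise ValueError("width_sigma_mm must be > 0")
        if self.broadening_factor < 1:
            raise ValueError("broadening_factor must be >= 1")
        if len(self.per_sensor_gain) != 5 or any(g <= 0 for g in self.per_sensor_gain):
            raise ValueError("per_sensor_gain needs five positive factors")
        if self.shape not in ("pseudo_gaussian", "mc_profile"):
            raise ValueError(f"unknown spot shape {self.shape!r}")


@dataclass(frozen=True)
class MotionProtocol:
    """Back-and-forth sweep protocol: 0 -> +range -> -range -> 0 per cycle."""

    range_mm: float = 15.0
    step_mm: float = 1.0
    n_cycles: int = 5
    dwell_s: float = 0.4
    #: rotation angles; the first entry runs n_cycles, the rest one cycle each
    rotation_schedule_deg: tuple[float, ...] = (0.0, 40.0, -40.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.range_mm <= 0 or self.step_mm <= 0:
            raise ValueError("range_mm and step_mm must be > 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.dwell_s <= 0:
            raise ValueError("dwell_s must be > 0")

    def cycle_positions(self) -> np.ndarray:
        r, s = self.range_mm, self.step_mm
        up1 = np.arange(0.0, r + s / 2, s)
        down = np.arange(r - s, -r - s / 2, -s)
        up2 = np.arange(-r + s, s / 2, s)
        return np.concatenate((up1, down, up2))


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model.

    ``linear_stage`` mode moves the tube exactly to the commanded positions;
    ``manual`` mode adds Gaussian jitter (hand positioning) to each step —
    the reference sensor still reads the true (jittered) position — and,
    crucially, per-step per-sensor coupling fluctuations
    (``manual_disturbance_sd``, fractional) emulating the tube rotations,
    tilting and hand tremor of direct manipulation, which perturb the
    voltage ratios without being visible to the reference sensor.
    Magnitudes are package defaults for sensitivity studies, not device
    characterizations.
    """

    voltage_sd_v: float = 0.01
    multiplicative_sd: float = 0.0
    gain_drift_sd_per_cycle: float = 0.0
    step_jitter_sd_mm: float = 0.3
    manual_disturbance_sd: float = 0.05
    mode: Literal["linear_stage", "manual"] = "linear_stage"

    def __post_init__(self) -> None:
        for name in (
            "voltage_sd_v",
            "multiplicative_sd",
            "gain_drift_sd_per_cycle",
            "step_jitter_sd_mm",
            "manual_disturbance_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mode not in ("linear_stage", "manual"):
            raise ValueError(f"unknown noise mode {self.mode!r}")
        if self.mode == "manual" and self.step_jitter_sd_mm <= 0:
            raise ValueError("manual mode requires step_jitter_sd_mm > 0")

    @classmethod
    def noiseless(cls) -> "NoiseSpec":
        return cls(voltage_sd_v=0.0, multiplicative_sd=0.0, gain_drift_sd_per_cycle=0.0)


@dataclass(frozen=True)
class ForwardCurves:
    """Displacement -> five-sensor voltage map (noise-free)."""

    params: SpotProfileParams
    geometry: SensorGeometry
    grid_mm: np.ndarray
    voltages_v: np.ndarray  # (n_grid, 5) at rotation 0

    def voltage_at(self, d_mm, rotation_deg: float = 0.0) -> np.ndarray:
        """Voltages at displacement(s) d; returns shape (..., 5).

        For the pseudo-Gaussian spot the closed form is evaluated exactly
        (including the rotation-induced perpendicular spot shift); the MC
        mode interpolates the precomputed grid, with rotation applied as a
        common attenuation that cancels in the ratios.
        """
        d = np.atleast_1d(np.asarray(d_mm, dtype=float))
        p = self.params
        if p.shape == "pseudo_gaussian":
            v = _pseudo_gaussian_voltages(d, p, self.geometry, rotation_deg)
        else:
            v = np.empty((len(d), 5))
            for i in range(5):
                v[:, i] = np.interp(d, self.grid_mm, self.voltages_v[:, i])
            if rotation_deg != 0.0:
                y0 = p.rotation_shift_mm_per_deg * rotation_deg
                sigma = p.width_sigma_mm * p.broadening_factor
                v = v * np.exp(-(y0**2) / (2.0 * sigma**2))
        return v[0] if np.isscalar(d_mm) or np.asarray(d_mm).ndim == 0 else v

    def ratios_at(self, d_mm, rotation_deg: float = 0.0) -> np.ndarray:
        v = np.atleast_2d(self.voltage_at(np.atleast_1d(d_mm), rotation_deg))
        return np.column_stack((v[:, 0] / v[:, 1], v[:, 2] / v[:, 1]))


def _pseudo_gaussian_voltages(
    d: np.ndarray, p: SpotProfileParams, geom: SensorGeometry, rotation_deg: float
) -> np.ndarray:
    sigma = p.width_sigma_mm * p.broadening_factor
    x_spot = d + p.peak_offset_mm
    y0 = p.rotation_shift_mm_per_deg * rotation_deg
    v = np.empty((len(d), 5))
    common_y = np.exp(-(y0**2) / (2.0 * sigma**2))
    for i, x_i in enumerate(geom.axial_positions_mm):
        v[:, i] = (
            p.per_sensor_gain[i]
            * p.peak_voltage_v
            * np.exp(-((x_i - x_spot) ** 2) / (2.0 * sigma**2))
            * common_y
        )
    for j, y_off in enumerate(geom.lateral_offsets_mm):
        v[:, 3 + j] = (
            p.per_sensor_gain[3 + j]
            * p.peak_voltage_v
            * np.exp(-(x_spot**2) / (2.0 * sigma**2))
            * np.exp(-((y_off - y0) ** 2) / (2.0 * sigma**2))
        )
    return v


def make_forward_curves(
    params: SpotProfileParams,
    geometry: SensorGeometry | None = None,
    stack: TissueStack | None = None,
    grid_mm: np.ndarray | None = None,
    source: SourceSpec | None = None,
    smoothing_window: int = 6,
) -> ForwardCurves:
    """Build the displacement -> voltage forward model.

    ``pseudo_gaussian`` mode is closed-form and fast; ``mc_profile`` mode
    runs the layered-slab Monte Carlo on ``stack`` and reads the sensors off
    the (smoothed) exitance profile, scaled so the center-channel peak
    reaches ``params.peak_voltage_v``.
    """
    geometry = geometry or SensorGeometry()
    if grid_mm is None:
        grid_mm = np.arange(-18.0, 18.0 + 0.25, 0.5)
    grid_mm = np.asarray(grid_mm, dtype=float)
    if params.shape == "pseudo_gaussian":
        v = _pseudo_gaussian_voltages(grid_mm, params, geometry, 0.0)
        return ForwardCurves(params, geometry, grid_mm, v)
    if stack is None:
        raise ValueError("mc_profile mode needs a tissue stack")
    source = source or SourceSpec(n_packets=2_000_000, seed=7)
    profile, _ = run_mc(stack, source, dimensionality="planar2D")
    if smoothing_window > 1:
        profile = smooth_profile(profile, smoothing_window)
    raw = np.array([sensor_intensities(profile, geometry, d) for d in grid_mm])
    scale = params.peak_voltage_v / raw[:, 1].max()
    v = raw * scale * np.asarray(params.per_sensor_gain)
    return ForwardCurves(params, geometry, grid_mm, v)


def _apply_electronics(
    frame: pd.DataFrame,
    electronics: ElectronicsSpec,
    sampling_rate: float,
    metadata: dict,
) -> VoltageSeries:
    series = VoltageSeries(frame, sampling_rate, metadata)
    v = np.clip(series.voltages(), 0.0, electronics.supply_voltage_v)
    series = series.with_voltages(v)
    series = apply_lowpass(series, electronics.cutoff_hz)
    # noise is injected before the filter by the generator; here only quantize
    series = quantize_and_noise(series, electronics, noise_sd_v=0.0, seed=0)
    return series


def generate_session(
    curves: ForwardCurves,
    protocol: MotionProtocol,
    noise: NoiseSpec,
    electronics: ElectronicsSpec | None = None,
    seed: int | None = None,
) -> tuple[VoltageSeries, np.ndarray]:
    """Generate a seeded voltage log for the sweep protocol.

    Returns the series (with ``ref_mm`` truth, ``rot_deg`` and ``cycle``
    columns) and the truth displacement per frame.  With ``electronics``
    given, voltages pass the saturation clamp, RC low-pass and ADC
    quantization; with ``electronics=None`` the raw noisy forward-model
    voltages are returned (plateaus then equal the forward curves exactly
    in the noiseless case).
    """
    rng = np.random.default_rng(protocol.seed if seed is None else seed)
    fs = (electronics or ElectronicsSpec()).sampling_rate_hz
    n_dwell = max(1, int(round(protocol.dwell_s * fs)))
    base_positions = protocol.cycle_positions()

    rows_truth = []
    rows_rot = []
    rows_cycle = []
    volts = []
    gains = np.ones(5)
    cycle_id = 0
    for k_rot, rot in enumerate(protocol.rotation_schedule_deg):
        n_cyc = protocol.n_cycles if k_rot == 0 else 1
        for _ in range(n_cyc):
            if noise.gain_drift_sd_per_cycle > 0:
                gains = gains * (1.0 + rng.normal(0.0, noise.gain_drift_sd_per_cycle, size=5))
                gains = np.clip(gains, 0.1, None)
            pos = base_positions.copy()
            if noise.mode == "manual":
                pos = pos + rng.normal(0.0, noise.step_jitter_sd_mm, size=pos.shape)
            v_plateau = np.atleast_2d(curves.voltage_at(pos, rotation_deg=rot)) * gains
            if noise.mode == "manual" and noise.manual_disturbance_sd > 0:
                v_plateau = v_plateau * (
                    1.0 + rng.normal(0.0, noise.manual_disturbance_sd, size=v_plateau.shape)
                )
            for p_i, v_i in zip(pos, v_plateau):
                v_frames = np.tile(v_i, (n_dwell, 1))
                if noise.multiplicative_sd > 0:
                    v_frames = v_frames * (
                        1.0 + rng.normal(0.0, noise.multiplicative_sd, size=v_frames.shape)
                    )
                if noise.voltage_sd_v > 0:
                    v_frames = v_frames + rng.normal(0.0, noise.voltage_sd_v, size=v_frames.shape)
                volts.append(v_frames)
                rows_truth.append(np.full(n_dwell, p_i))
                rows_rot.append(np.full(n_dwell, rot))
                rows_cycle.append(np.full(n_dwell, cycle_id, dtype=int))
            cycle_id += 1
    v = np.vstack(volts)
    truth = np.concatenate(rows_truth)
    n = len(truth)
    frame = pd.DataFrame(v, columns=list(VOLTAGE_COLUMNS))
    frame.insert(0, "time_s", np.arange(n) / fs)
    frame["ref_mm"] = truth
    frame["rot_deg"] = np.concatenate(rows_rot)
    frame["cycle"] = np.concatenate(rows_cycle)
    metadata = {
        "kind": "session",
        "seed": int(protocol.seed if seed is None else seed),
        "protocol": {
            "range_mm": protocol.range_mm,
            "step_mm": protocol.step_mm,
            "n_cycles": protocol.n_cycles,
            "dwell_s": protocol.dwell_s,
            "rotation_schedule_deg": list(protocol.rotation_schedule_deg),
        },
        "noise": {
            "voltage_sd_v": noise.voltage_sd_v,
            "multiplicative_sd": noise.multiplicative_sd,
            "gain_drift_sd_per_cycle": noise.gain_drift_sd_per_cycle,
            "step_jitter_sd_mm": noise.step_jitter_sd_mm,
            "mode": noise.mode,
        },
    }
    if electronics is None:
        series = VoltageSeries(frame, fs, metadata)
    else:
        series = _apply_electronics(frame, electronics, fs, metadata)
    return series, truth


def generate_calibration_log(
    curves: ForwardCurves,
    electronics: ElectronicsSpec | None = None,
    dwell_s: float = 2.0,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    nodes_mm: tuple[float, ...] = (-10.0, -5.0, 0.0, 5.0, 10.0),
) -> VoltageSeries:
    """Five-dwell calibration log at the prescribed displacements.

    Each node appears exactly once as a contiguous dwell tagged in
    ``ref_mm``, ready for :func:`ettnir.calibration.calibration_set_from_log`.
    """
    noise = noise or NoiseSpec.noiseless()
    rng = np.random.default_rng(seed)
    fs = (electronics or ElectronicsSpec()).sampling_rate_hz
    n_dwell = max(1, int(round(dwell_s * fs)))
    volts = []
    truth = []
    for node in nodes_mm:
        v_i = curves.voltage_at(float(node))
        v_frames = np.tile(v_i, (n_dwell, 1))
        if noise.multiplicative_sd > 0:
            v_frames = v_frames * (1.0 + rng.normal(0.0, noise.multiplicative_sd, v_frames.shape))
        if noise.voltage_sd_v > 0:
            v_frames = v_frames + rng.normal(0.0, noise.voltage_sd_v, v_frames.shape)
        volts.append(v_frames)
        truth.append(np.full(n_dwell, float(node)))
    v = np.vstack(volts)
    truth = np.concatenate(truth)
    frame = pd.DataFrame(v, columns=list(VOLTAGE_COLUMNS))
    frame.insert(0, "time_s", np.arange(len(truth)) / fs)
    frame["ref_mm"] = truth
    metadata = {"kind": "calibration", "seed": int(seed), "nodes_mm": list(nodes_mm)}
    if electronics is None:
        return VoltageSeries(frame, fs, metadata)
    return _apply_electronics(frame, electronics, fs, metadata)
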