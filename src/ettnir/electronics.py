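"""Forward model of the five-phototransistor detector board.

The board carries phototransistors P1, P2, P3 spaced 10 mm apart along the
tube axis (for longitudinal displacement) and P4, P5 offset 3.5 mm to either
side of P2 perpendicular to the axis (for tube-rotation monitoring).  Each
phototransistor sits in a common-collector stage off a 5 V rail with a
430 kOhm emitter resistor setting the gain, followed by a single-pole RC
low-pass (200 kOhm, 82 nF -> 9.7 Hz) and a 250 Hz, 14-bit acquisition.

The chain modeled here: collected skin exitance -> linear-with-saturation
voltage -> RC low-pass -> additive noise, rail clamping and quantization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .montecarlo import ExitanceProfile

__all__ = [
    "SensorGeometry",
    "ElectronicsSpec",
    "VoltageSeries",
    "sensor_intensities",
    "intensity_to_voltage",
    "rc_cutoff_frequency",
    "apply_lowpass",
    "quantize_and_noise",
]

VOLTAGE_COLUMNS = ("vp1_v", "vp2_v", "vp3_v", "vp4_v", "vp5_v")


@dataclass(frozen=True)
class SensorGeometry:
    """Sensor positions in board coordinates.

    The board axis runs along the tube with P1 at -10 mm (proximal / mouth
    side), P2 at 0 and P3 at +10 mm; the light-spot center sits at x = d for
    tube displacement d (positive = pushed inward, spot toward P3).  P4/P5
    share P2's axial position with perpendicular offsets of -3.5/+3.5 mm.
    """

    axial_positions_mm: tuple[float, float, float] = (-10.0, 0.0, 10.0)
    lateral_offsets_mm: tuple[float, float] = (-3.5, 3.5)
    aperture_mm: float = 0.5
    p45_attenuation: float = 0.8

    def __post_init__(self) -> None:
        if self.aperture_mm <= 0:
            raise ValueError("aperture_mm must be > 0")
        if not 0 < self.p45_attenuation <= 1:
            raise ValueError("p45_attenuation must be in (0, 1]")


@dataclass(frozen=True)
class ElectronicsSpec:
    supply_voltage_v: float = 5.0
    emitter_resistance_ohm: float = 430e3
    filter_resistance_ohm: float = 200e3
    filter_capacitance_f: float = 82e-9
    sampling_rate_hz: float = 250.0
    adc_bits: int = 14
    responsivity: tuple[float, float, float, float, float] = (1.0, 1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        for name in (
            "supply_voltage_v",
            "emitter_resistance_ohm",
            "filter_resistance_ohm",
            "filter_capacitance_f",
            "sampling_rate_hz",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.adc_bits < 1:
            raise ValueError("adc_bits must be >= 1")
        if len(self.responsivity) != 5 or any(r <= 0 for r in self.responsivity):
            raise ValueError("responsivity needs five positive per-sensor gains")

    @property
    def cutoff_hz(self) -> float:
        return rc_cutoff_frequency(self.filter_resistance_ohm, self.filter_capacitance_f)


class VoltageSeries:
    """Uniformly sampled five-channel voltage log with optional reference.

    Thin wrapper over a DataFrame with columns ``time_s, vp1_v..vp5_v`` and
    optionally ``ref_mm`` (reference-sensor displacement) plus extras such as
    ``rot_deg``; carries the sampling rate and a metadata dict (session id,
    seed, protocol...).
    """

    def __init__(self, frame: pd.DataFrame, sampling_rate_hz: float, metadata: dict | None = None):
        missing = [c for c in ("time_s", *VOLTAGE_COLUMNS) if c not in frame.columns]
        if missing:
            raise ValueError(f"voltage series missing columns {missing}")
        t = frame["time_s"].to_numpy()
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0) or not np.allclose(dt, 1.0 / sampling_rate_hz, rtol=1e-6, atol=1e-9):
                raise ValueError("time_s must increase uniformly at 1/sampling_rate spacing")
        self.frame = frame.reset_index(drop=True)
        self.sampling_rate_hz = float(sampling_rate_hz)
        self.metadata = dict(metadata or {})

    def __len__(self) -> int:
        return len(self.frame)

    def voltages(self) -> np.ndarray:
        """(n, 5) array of the five channels."""
        return self.frame.loc[:, list(VOLTAGE_COLUMNS)].to_numpy(dtype=float)

    def with_voltages(self, v: np.ndarray) -> "VoltageSeries":
        frame = self.frame.copy()
        frame.loc[:, list(VOLTAGE_COLUMNS)] = v
        return VoltageSeries(frame, self.sampling_rate_hz, self.metadata)


def _profile_cumulative(profile: ExitanceProfile):
    """Cumulative power from the left domain edge, defined at bin edges."""
    c = np.asarray(profile.bin_centers_mm, dtype=float)
    w = profile.bin_width_mm
    edges = np.concatenate((c - w / 2.0, [c[-1] + w / 2.0]))
    cum = np.concatenate(([0.0], np.cumsum(profile.intensity)))
    return edges, cum


def _integrate_profile(profile: ExitanceProfile, lo: float, hi: float) -> float:
    edges, cum = _profile_cumulative(profile)
    if lo < edges[0] - 1e-9 or hi > edges[-1] + 1e-9:
        raise ValueError(
            f"collection window [{lo:.2f}, {hi:.2f}] mm outside the binned domain "
            f"[{edges[0]:.2f}, {edges[-1]:.2f}] mm"
        )
    a, b = np.interp([lo, hi], edges, cum)
    return float(b - a)


def sensor_intensities(
    profile: ExitanceProfile, geometry: SensorGeometry, displacement_mm: float
) -> np.ndarray:
    """Collected power at P1..P5 for a tube displacement ``displacement_mm``.

    Sensor i collects the exitance integrated over
    ``[x_i - d - a, x_i - d + a]`` where ``a`` is the aperture half-width:
    moving the tube by d shifts the light spot under the fixed board.  With a
    1-D (planar) profile P4/P5 are approximated as the P2 channel scaled by
    ``geometry.p45_attenuation``; with a 3-D run's (x, y) map they are read
    at their true perpendicular offsets.
    """
    d = float(displacement_mm)
    a = geometry.aperture_mm
    out = np.empty(5)
    for i, x_i in enumerate(geometry.axial_positions_mm):
        out[i] = _integrate_profile(profile, x_i - d - a, x_i - d + a)
    if profile.xy_map is not None:
        m = profile.xy_map
        ycen = m.y_centers_mm
        dens = m.intensity  # (nx, ny) W per bin
        for j, y_off in enumerate(geometry.lateral_offsets_mm):
            ysel = np.abs(ycen - y_off) <= a
            if not np.any(ysel):
                ysel = np.abs(ycen - y_off) <= m.bin_width_mm
            strip = dens[:, ysel].sum(axis=1)
            strip_profile = ExitanceProfile(
                bin_centers_mm=m.x_centers_mm,
                intensity=strip,
                bin_width_mm=m.bin_width_mm,
                dimensionality="slab3D",
                smoothing_window=profile.smoothing_window,
            )
            out[3 + j] = _integrate_profile(strip_profile, -d - a, -d + a)
    else:
        p2 = out[1]
        out[3] = geometry.p45_attenuation * p2
        out[4] = geometry.p45_attenuation * p2
    return out


def intensity_to_voltage(intensity: float, spec: ElectronicsSpec, sensor_index: int) -> float:
    """Linear-with-saturation phototransistor response, clamped at the rail."""
    if intensity < 0:
        raise ValueError("intensity must be >= 0")
    v = spec.responsivity[sensor_index] * intensity
    return min(spec.supply_voltage_v, v)


def rc_cutoff_frequency(resistance_ohm: float, capacitance_f: float) -> float:
    """First-order RC low-pass cutoff, 1 / (2 pi R C), in Hz."""
    if resistance_ohm <= 0 or capacitance_f <= 0:
        raise ValueError("resistance and capacitance must be > 0")
    return 1.0 / (2.0 * math.pi * resistance_ohm * capacitance_f)


def apply_lowpass(series: VoltageSeries, cutoff_hz: float) -> VoltageSeries:
    """Single-pole discrete filter matched to the analog RC (DC gain 1).

    Uses the exact zero-order-hold pole ``exp(-2 pi fc / fs)``; the state is
    initialized at the first sample so a constant input passes unchanged.
    """
    fs = series.sampling_rate_hz
    if cutoff_hz >= fs / 2.0:
        raise ValueError("cutoff must lie below the Nyquist frequency")
    alpha = 1.0 - math.exp(-2.0 * math.pi * cutoff_hz / fs)
    v = series.voltages()
    out = np.empty_like(v)
    state = v[0].copy()
    for k in range(v.shape[0]):
        state = state + alpha * (v[k] - state)
        out[k] = state
    return series.with_voltages(out)


def quantize_and_noise(
    series: VoltageSeries,
    spec: ElectronicsSpec,
    noise_sd_v: float,
    seed: int,
) -> VoltageSeries:
    """Add Gaussian noise, clamp to [0, supply] and quantize to the ADC grid.

    Quantization rounds the level index half away from zero (ties are
    measure-zero for Gaussian noise).  Fully deterministic for a fixed seed.
    """
    if noise_sd_v < 0:
        raise ValueError("noise_sd_v must be >= 0")
    rng = np.random.default_rng(seed)
    v = series.voltages()
    if noise_sd_v > 0:
        v = v + rng.normal(0.0, noise_sd_v, size=v.shape)
    v = np.clip(v, 0.0, spec.supply_voltage_v)
    lsb = spec.supply_voltage_v / (2**spec.adc_bits)
    v = np.floor(v / lsb + 0.5) * lsb
    v = np.minimum(v, spec.supply_voltage_v)
    return series.with_voltages(v)
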