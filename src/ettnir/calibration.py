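"""Ratio-based polynomial calibration and displacement estimation.

The tube displacement is estimated from the voltage ratios
``r12 = VP1/VP2`` and ``r32 = VP3/VP2``.  Calibration measures the ratios at
five displacements (-10, -5, 0, +5, +10 mm against a reference position
sensor) and fits four quadratics of ratio on displacement, one
high-signal and one low-signal branch per direction:

* negative range (tube pulled out): ``f12_high`` and ``f32_low`` each
  interpolate their ratios at (-10, -5, 0) mm;
* positive range (tube pushed in): ``f32_high`` and ``f12_low`` each
  interpolate their ratios at (0, +5, +10) mm.

At run time the movement direction follows from ``r12/r12(0)`` (> 1 means
outward, < 1 inward); the branch quadratics are inverted on their monotone
half-ranges, and the two branch estimates are fused as
``d_final = w * d_high + (1 - w) * d_low`` — the larger of the two ratios has
the better signal-to-noise ratio and carries the weight ``w`` (default 0.95).

:class:`DisplacementEstimator` packages this as a scikit-learn regressor
(``fit`` on the five calibration ratio pairs, ``predict`` displacement from
ratio pairs); the module-level functions are thin wrappers over it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "LowSignalError",
    "RatioPair",
    "CalibrationSet",
    "DisplacementEstimate",
    "RotationAlert",
    "DisplacementEstimator",
    "compute_ratios",
    "fit_calibration",
    "classify_direction",
    "invert_branch",
    "estimate_displacement",
    "rotation_alert",
    "track_series",
    "calibration_set_from_log",
    "save_model",
    "load_model",
]

CALIBRATION_DISPLACEMENTS = (-10.0, -5.0, 0.0, 5.0, 10.0)
DEFAULT_SIGNAL_FLOOR_V = 0.02


class LowSignalError(ValueError):
    """Center-sensor voltage below the signal floor; ratios are unreliable."""


class RatioPair(NamedTuple):
    r12: float
    r32: float


@dataclass(frozen=True)
class CalibrationSet:
    """Time-averaged ratio pairs at the five calibration displacements."""

    displacements_mm: tuple[float, ...]
    r12: tuple[float, ...]
    r32: tuple[float, ...]
    #: optional rotation-channel baselines VP4/VP2, VP5/VP2 at d = 0
    r42_zero: float | None = None
    r52_zero: float | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.displacements_mm, dtype=float)
        if len(d) != 5 or len(set(d.tolist())) != 5:
            raise ValueError("calibration needs exactly five distinct displacements")
        if 0.0 not in d or (d < 0).sum() != 2 or (d > 0).sum() != 2:
            raise ValueError("calibration displacements must be two negative, zero, two positive")
        for name, vals in (("r12", self.r12), ("r32", self.r32)):
            v = np.asarray(vals, dtype=float)
            if len(v) != 5 or not np.all(np.isfinite(v)) or np.any(v <= 0):
                raise ValueError(f"{name} must hold five finite positive ratios")


@dataclass(frozen=True)
class DisplacementEstimate:
    d_final_mm: float
    d_high_mm: float
    d_low_mm: float
    direction: str  # "negative" | "positive" | "zero"
    out_of_range: bool = False
    low_signal: bool = False


@dataclass(frozen=True)
class RotationAlert:
    ratio_p4: float
    ratio_p5: float
    threshold: float
    flagged: bool


# ---------------------------------------------------------------------------
# elementary operations


def compute_ratios(frame, floor_v: float = DEFAULT_SIGNAL_FLOOR_V) -> RatioPair:
    """Voltage ratios (VP1/VP2, VP3/VP2) with a low-signal guard on VP2.

    ``frame`` may be a mapping/Series with ``vp1_v..vp3_v`` keys or a
    sequence ordered VP1, VP2, VP3[, VP4, VP5].
    """
    if hasattr(frame, "__getitem__") and not isinstance(frame, (list, tuple, np.ndarray)):
        try:
            v1, v2, v3 = frame["vp1_v"], frame["vp2_v"], frame["vp3_v"]
        except (KeyError, IndexError):
            v1, v2, v3 = frame[0], frame[1], frame[2]
    else:
        v1, v2, v3 = frame[0], frame[1], frame[2]
    if v2 <= floor_v:
        raise LowSignalError(
            f"VP2 = {v2:.4f} V is at or below the {floor_v} V floor; "
            "possible decoupling or extreme displacement"
        )
    return RatioPair(float(v1) / float(v2), float(v3) / float(v2))


def _interpolating_quadratic(d: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Coefficients (a, b, c) of the quadratic through three (d, r) nodes."""
    vander = np.column_stack((d**2, d, np.ones_like(d)))
    return np.linalg.solve(vander, r)


def _vertex_in_open_interval(coeffs: np.ndarray, lo: float, hi: float) -> bool:
    a, b, _ = coeffs
    if abs(a) < 1e-14:
        return False
    v = -b / (2.0 * a)
    return bool(lo < v < hi)


def classify_direction(ratios: RatioPair, r12_zero: float, deadband: float = 0.0) -> str:
    """Movement direction from r12 relative to its d = 0 baseline.

    ``r12/r12(0) > 1`` means the spot moved toward P1, i.e. the tube moved
    outward (negative displacement); ``< 1`` means inward (positive).
    """
    rel = ratios.r12 / r12_zero
    if rel > 1.0 + deadband:
        return "negative"
    if rel < 1.0 - deadband:
        return "positive"
    return "zero"


def invert_branch(
    coeffs: Sequence[float],
    ratio_value: float,
    applicable_range: tuple[float, float],
) -> tuple[float, bool]:
    """Solve ``f(d) = ratio_value`` for d on the branch's half-range.

    Returns ``(d_mm, out_of_range)``.  Ratios with no in-range root clamp to
    the range end whose fitted ratio is closest, with the flag set — the
    quadratics are only trusted inside the calibrated range.
    """
    a, b, c = (float(v) for v in coeffs)
    lo, hi = applicable_range
    eps = 1e-9 * max(1.0, hi - lo)
    if abs(a) < 1e-12:
        if abs(b) < 1e-12:
            raise ValueError("degenerate branch: near-zero curvature and slope")
        d = (ratio_value - c) / b
        if lo - eps <= d <= hi + eps:
            return float(np.clip(d, lo, hi)), False
    else:
        disc = b * b - 4.0 * a * (c - ratio_value)
        if disc >= 0.0:
            sq = np.sqrt(disc)
            roots = [(-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)]
            in_range = [d for d in roots if lo - eps <= d <= hi + eps]
            if len(in_range) == 2 and abs(in_range[0] - in_range[1]) > 2 * eps:
                raise ValueError(
                    "both quadratic roots fall in the applicable range; "
                    "the branch is not monotone there"
                )
            if in_range:
                return float(np.clip(in_range[0], lo, hi)), False
    # no usable in-range root: clamp to the end whose fitted ratio is nearest
    f_lo = a * lo * lo + b * lo + c
    f_hi = a * hi * hi + b * hi + c
    d = lo if abs(f_lo - ratio_value) <= abs(f_hi - ratio_value) else hi
    return float(d), True


# ---------------------------------------------------------------------------
# the estimator


class DisplacementEstimator(RegressorMixin, BaseEstimator):
    """Five-point branch-quadratic calibration as a scikit-learn regressor.

    ``fit(X, y)`` takes the calibration ratio pairs ``X`` of shape (5, 2)
    (columns r12, r32) and the commanded displacements ``y`` in mm (two
    negative, zero, two positive; nominally -10, -5, 0, +5, +10).
    ``predict(X)`` maps ratio pairs to fused displacement estimates.

    Parameters
    ----------
    weight_high : float
        Fusion weight ``w`` on the high-signal branch estimate, in [0, 1].
    deadband : float
        Relative half-width of the direction dead zone around
        ``r12/r12(0) = 1``; 0 applies the strict sign rule.

    Attributes
    ----------
    f12_high_, f32_low_, f32_high_, f12_low_ : ndarray, shape (3,)
        Quadratic coefficients (a, b, c) of each branch, ratio = f(d).
    r12_zero_, r32_zero_ : float
        Baseline ratios at d = 0.
    monotone_flags_ : dict
        Branch name -> True when the fitted quadratic has its vertex inside
        the branch's half-range (non-monotone fit; inversion may clamp).
    valid_range_ : tuple
        (min, max) calibrated displacement.
    """

    def __init__(self, weight_high: float = 0.95, deadband: float = 0.0):
        self.weight_high = weight_high
        self.deadband = deadband

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y):
        if not 0.0 <= self.weight_high <= 1.0:
            raise ValueError("weight_high must be in [0, 1]")
        if self.deadband < 0:
            raise ValueError("deadband must be >= 0")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have shape (5, 2) with columns (r12, r32)")
        cal = CalibrationSet(
            displacements_mm=tuple(y.tolist()),
            r12=tuple(X[:, 0].tolist()),
            r32=tuple(X[:, 1].tolist()),
        )
        order = np.argsort(y)
        d = y[order]
        r12 = X[order, 0]
        r32 = X[order, 1]
        neg = slice(0, 3)  # d_min, d_mid<0, 0
        pos = slice(2, 5)  # 0, d_mid>0, d_max
        self.f12_high_ = _interpolating_quadratic(d[neg], r12[neg])
        self.f32_low_ = _interpolating_quadratic(d[neg], r32[neg])
        self.f32_high_ = _interpolating_quadratic(d[pos], r32[pos])
        self.f12_low_ = _interpolating_quadratic(d[pos], r12[pos])
        self.r12_zero_ = float(r12[2])
        self.r32_zero_ = float(r32[2])
        self.valid_range_ = (float(d[0]), float(d[4]))
        self.monotone_flags_ = {
            "f12_high": _vertex_in_open_interval(self.f12_high_, d[0], 0.0),
            "f32_low": _vertex_in_open_interval(self.f32_low_, d[0], 0.0),
            "f32_high": _vertex_in_open_interval(self.f32_high_, 0.0, d[4]),
            "f12_low": _vertex_in_open_interval(self.f12_low_, 0.0, d[4]),
        }
        self.calibration_ = cal
        self.n_features_in_ = 2
        return self

    # -- prediction ---------------------------------------------------------

    def _estimate_one(self, r12: float, r32: float) -> DisplacementEstimate:
        ratios = RatioPair(r12, r32)
        direction = classify_direction(ratios, self.r12_zero_, self.deadband)
        w = self.weight_high
        if direction == "zero":
            return DisplacementEstimate(0.0, 0.0, 0.0, direction)
        lo, hi = self.valid_range_
        if direction == "negative":
            d_high, oor_h = invert_branch(self.f12_high_, r12, (lo, 0.0))
            d_low, oor_l = invert_branch(self.f32_low_, r32, (lo, 0.0))
        else:
            d_high, oor_h = invert_branch(self.f32_high_, r32, (0.0, hi))
            d_low, oor_l = invert_branch(self.f12_low_, r12, (0.0, hi))
        d_final = w * d_high + (1.0 - w) * d_low
        return DisplacementEstimate(d_final, d_high, d_low, direction, out_of_range=oor_h or oor_l)

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "f12_high_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != 2:
            raise ValueError("X must have two columns (r12, r32)")
        return np.array([self._estimate_one(r12, r32).d_final_mm for r12, r32 in X])

    def predict_detail(self, X) -> pd.DataFrame:
        """Per-row branch estimates, direction and quality flags."""
        check_is_fitted(self, "f12_high_")
        X = np.asarray(X, dtype=float).reshape(-1, 2)
        rows = [self._estimate_one(r12, r32) for r12, r32 in X]
        return pd.DataFrame(
            {
                "d_final_mm": [e.d_final_mm for e in rows],
                "d_high_mm": [e.d_high_mm for e in rows],
                "d_low_mm": [e.d_low_mm for e in rows],
                "direction": [e.direction for e in rows],
                "out_of_range": [e.out_of_range for e in rows],
            }
        )

    # -- persistence ----------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "f12_high_")
        cal = self.calibration_
        return {
            "schema": "ettnir-calibration-1",
            "weight_high": self.weight_high,
            "deadband": self.deadband,
            "displacements_mm": list(cal.displacements_mm),
            "r12": list(cal.r12),
            "r32": list(cal.r32),
            "r42_zero": cal.r42_zero,
            "r52_zero": cal.r52_zero,
            "coefficients": {
                "f12_high": self.f12_high_.tolist(),
                "f32_low": self.f32_low_.tolist(),
                "f32_high": self.f32_high_.tolist(),
                "f12_low": self.f12_low_.tolist(),
            },
            "r12_zero": self.r12_zero_,
            "r32_zero": self.r32_zero_,
            "valid_range_mm": list(self.valid_range_),
            "monotone_flags": self.monotone_flags_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DisplacementEstimator":
        if d.get("schema") != "ettnir-calibration-1":
            raise ValueError(f"unrecognized calibration schema {d.get('schema')!r}")
        est = cls(weight_high=d["weight_high"], deadband=d["deadband"])
        est.calibration_ = CalibrationSet(
            displacements_mm=tuple(d["displacements_mm"]),
            r12=tuple(d["r12"]),
            r32=tuple(d["r32"]),
            r42_zero=d.get("r42_zero"),
            r52_zero=d.get("r52_zero"),
        )
        co = d["coefficients"]
        est.f12_high_ = np.array(co["f12_high"])
        est.f32_low_ = np.array(co["f32_low"])
        est.f32_high_ = np.array(co["f32_high"])
        est.f12_low_ = np.array(co["f12_low"])
        est.r12_zero_ = float(d["r12_zero"])
        est.r32_zero_ = float(d["r32_zero"])
        est.valid_range_ = tuple(d["valid_range_mm"])
        est.monotone_flags_ = dict(d["monotone_flags"])
        est.n_features_in_ = 2
        return est


def save_model(est: DisplacementEstimator, path: str | Path) -> None:
    Path(path).write_text(json.dumps(est.to_dict(), indent=2))


def load_model(path: str | Path) -> DisplacementEstimator:
    return DisplacementEstimator.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# functional wrappers and batch processing


def fit_calibration(cal: CalibrationSet, weight_w: float = 0.95) -> DisplacementEstimator:
    """Fit the four branch quadratics from a calibration set."""
    X = np.column_stack((cal.r12, cal.r32))
    y = np.asarray(cal.displacements_mm, dtype=float)
    est = DisplacementEstimator(weight_high=weight_w).fit(X, y)
    est.calibration_ = cal  # keep rotation baselines if present
    return est


def estimate_displacement(ratios: RatioPair, model: DisplacementEstimator) -> DisplacementEstimate:
    return model._estimate_one(ratios.r12, ratios.r32)


def rotation_alert(
    frame,
    baselines: tuple[float, float],
    threshold: float = 0.30,
    floor_v: float = DEFAULT_SIGNAL_FLOOR_V,
) -> RotationAlert:
    """Flag tube rotation when VP4/VP2 or VP5/VP2 drifts off its baseline.

    ``threshold`` is the fractional deviation tolerated relative to the
    calibration-time baselines (default 0.30).
    """
    try:
        v2 = frame["vp2_v"]
        v4 = frame["vp4_v"]
        v5 = frame["vp5_v"]
    except (KeyError, IndexError, TypeError):
        v2, v4, v5 = frame[1], frame[3], frame[4]
    if v2 <= floor_v:
        raise LowSignalError(f"VP2 = {v2:.4f} V below floor; rotation check unreliable")
    r4 = float(v4) / float(v2)
    r5 = float(v5) / float(v2)
    b4, b5 = baselines
    flagged = abs(r4 / b4 - 1.0) > threshold or abs(r5 / b5 - 1.0) > threshold
    return RotationAlert(r4, r5, threshold, flagged)


def track_series(
    series,
    model: DisplacementEstimator,
    floor_v: float = DEFAULT_SIGNAL_FLOOR_V,
    rotation_threshold: float = 0.30,
) -> pd.DataFrame:
    """Per-frame displacement estimates (and rotation alerts) for a log.

    Frames whose VP2 falls below the floor yield NaN estimates with a reason;
    all other frames are unaffected.  Rotation alerts require the model's
    calibration to carry the P4/P5 baselines.
    """
    frame = series.frame
    v = series.voltages()
    cal = getattr(model, "calibration_", None)
    have_rot = cal is not None and cal.r42_zero is not None and cal.r52_zero is not None
    n = len(frame)
    out = {
        "time_s": frame["time_s"].to_numpy(),
        "d_final_mm": np.full(n, np.nan),
        "d_high_mm": np.full(n, np.nan),
        "d_low_mm": np.full(n, np.nan),
        "direction": np.array([""] * n, dtype=object),
        "out_of_range": np.zeros(n, dtype=bool),
        "low_signal": np.zeros(n, dtype=bool),
        "rotation_flagged": np.zeros(n, dtype=bool),
    }
    for k in range(n):
        try:
            ratios = compute_ratios(v[k], floor_v=floor_v)
        except LowSignalError:
            out["low_signal"][k] = True
            continue
        est = model._estimate_one(ratios.r12, ratios.r32)
        out["d_final_mm"][k] = est.d_final_mm
        out["d_high_mm"][k] = est.d_high_mm
        out["d_low_mm"][k] = est.d_low_mm
        out["direction"][k] = est.direction
        out["out_of_range"][k] = est.out_of_range
        if have_rot:
            alert = rotation_alert(
                v[k], (cal.r42_zero, cal.r52_zero), rotation_threshold, floor_v
            )
            out["rotation_flagged"][k] = alert.flagged
    result = pd.DataFrame(out)
    if "ref_mm" in frame.columns:
        result["ref_mm"] = frame["ref_mm"].to_numpy()
    return result


def calibration_set_from_log(
    series,
    nodes_mm: Sequence[float] = CALIBRATION_DISPLACEMENTS,
    dwell_trim: float = 0.25,
    floor_v: float = DEFAULT_SIGNAL_FLOOR_V,
) -> CalibrationSet:
    """Build a :class:`CalibrationSet` from a dwell-tagged calibration log.

    The log's ``ref_mm`` column marks the commanded node for each frame.
    For each node the first ``dwell_trim`` fraction of its frames (filter
    settling) is discarded, the remaining voltages are averaged, and the
    ratios are computed from the averages.  P4/P5 baselines come from the
    d = 0 dwell.
    """
    frame = series.frame
    if "ref_mm" not in frame.columns:
        raise ValueError("calibration log needs a ref_mm column tagging the dwells")
    ref = frame["ref_mm"].to_numpy(dtype=float)
    nodes = np.asarray(nodes_mm, dtype=float)
    tol = 0.25 * np.min(np.diff(np.sort(nodes)))
    v = series.voltages()
    mean_v = {}
    for node in nodes:
        sel = np.flatnonzero(np.abs(ref - node) <= tol)
        if sel.size == 0:
            raise ValueError(f"calibration log is missing the {node:+.0f} mm dwell")
        keep = sel[int(np.floor(dwell_trim * sel.size)):]
        mean_v[node] = v[keep].mean(axis=0)
    r12, r32 = [], []
    for node in nodes:
        pair = compute_ratios(mean_v[node], floor_v=floor_v)
        r12.append(pair.r12)
        r32.append(pair.r32)
    v0 = mean_v[0.0]
    return CalibrationSet(
        displacements_mm=tuple(nodes.tolist()),
        r12=tuple(r12),
        r32=tuple(r32),
        r42_zero=float(v0[3] / v0[1]),
        r52_zero=float(v0[4] / v0[1]),
    )
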