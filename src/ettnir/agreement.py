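"""Agreement analysis between estimated and reference displacements.

Two complementary views, matching standard method-comparison practice:

* ordinary least squares of estimated on reference with the coefficient of
  determination (scatter against the perfect-agreement line);
* Bland-Altman analysis of the paired differences against the paired means,
  with either a constant bias (mean difference) or, when the differences
  trend with the mean, a regression-estimated bias line; the 95% limits of
  agreement are the bias (line) +/- 1.96 times the sample standard
  deviation of the differences (residuals in regression mode).

Sample statistics use the n-1 denominator throughout.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import stats

__all__ = [
    "AgreementReport",
    "CycleSummary",
    "linear_agreement",
    "bland_altman",
    "summarize_cycles",
]


@dataclass(frozen=True)
class AgreementReport:
    """Regression and Bland-Altman summary for one paired series."""

    slope: float
    intercept: float
    r_squared: float
    bias_model: str  # "constant" | "regression"
    bias_slope: float
    bias_intercept: float
    loa_halfwidth_mm: float
    n: int

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.loa_halfwidth_mm < 0:
            raise ValueError("loa_halfwidth_mm must be >= 0")

    def bias_at(self, mean_mm: float) -> float:
        return self.bias_intercept + self.bias_slope * mean_mm

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {"schema": "ettnir-agreement-1", **asdict(self)}
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AgreementReport":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        if d.pop("schema", None) != "ettnir-agreement-1":
            raise ValueError("unrecognized agreement report schema")
        return cls(**d)


@dataclass(frozen=True)
class CycleSummary:
    """Cross-sweep mean and 1.96*SD band of a signal on a displacement grid."""

    grid_mm: np.ndarray
    mean: np.ndarray
    band: np.ndarray  # 1.96 * sample SD; NaN where fewer than 2 sweeps cover
    n_sweeps: np.ndarray


def _clean_pairs(estimated, reference) -> tuple[np.ndarray, np.ndarray]:
    est = np.asarray(estimated, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape or est.ndim != 1:
        raise ValueError("estimated and reference must be equal-length 1-D arrays")
    keep = np.isfinite(est) & np.isfinite(ref)
    est, ref = est[keep], ref[keep]
    if len(est) < 3:
        raise ValueError("need at least 3 finite pairs")
    return est, ref


def linear_agreement(estimated, reference) -> tuple[float, float, float]:
    """OLS of estimated on reference: returns (slope, intercept, R^2)."""
    est, ref = _clean_pairs(estimated, reference)
    if np.ptp(ref) == 0:
        raise ValueError("reference is constant; the regression slope is undefined")
    res = stats.linregress(ref, est)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def bland_altman(
    estimated,
    reference,
    bias_model: Literal["constant", "regression"] = "regression",
) -> AgreementReport:
    """Bland-Altman agreement of two displacement measurements.

    ``constant`` mode: bias = mean difference, limits = bias +/- 1.96 * SD of
    the differences.  ``regression`` mode (for non-constant variance /
    trending differences): bias is the OLS line of difference on mean,
    limits = bias line +/- 1.96 * SD of the residuals about it.
    """
    est, ref = _clean_pairs(estimated, reference)
    slope, intercept, r2 = linear_agreement(est, ref)
    diff = est - ref
    mean = 0.5 * (est + ref)
    if bias_model == "constant":
        bias_slope = 0.0
        bias_intercept = float(np.mean(diff))
        resid = diff - bias_intercept
    elif bias_model == "regression":
        if np.ptp(mean) == 0:
            raise ValueError("pair means are constant; regression bias is undefined")
        res = stats.linregress(mean, diff)
        bias_slope = float(res.slope)
        bias_intercept = float(res.intercept)
        resid = diff - (bias_intercept + bias_slope * mean)
    else:
        raise ValueError(f"unknown bias model {bias_model!r}")
    sd = float(np.std(resid, ddof=1))
    return AgreementReport(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        bias_model=bias_model,
        bias_slope=bias_slope,
        bias_intercept=bias_intercept,
        loa_halfwidth_mm=1.96 * sd,
        n=len(est),
    )


def _monotone_sweeps(d: np.ndarray) -> list[np.ndarray]:
    """Index groups of maximal monotone runs of the step positions."""
    # compress dwell plateaus to step transitions, keep frame indices per step
    change = np.flatnonzero(np.diff(d) != 0)
    starts = np.concatenate(([0], change + 1))
    step_d = d[starts]
    if len(step_d) < 2:
        return [np.arange(len(d))]
    sgn = np.sign(np.diff(step_d))
    sweeps = []
    run_start = 0
    cur = sgn[0]
    for k in range(1, len(sgn)):
        if sgn[k] != 0 and cur != 0 and sgn[k] != cur:
            sweeps.append((run_start, k))
            run_start = k
            cur = sgn[k]
        elif cur == 0:
            cur = sgn[k]
    sweeps.append((run_start, len(step_d) - 1))
    out = []
    ends = np.concatenate((starts[1:], [len(d)]))
    for a, b in sweeps:
        out.append(np.arange(starts[a], ends[b]))
    return out


def summarize_cycles(
    truth_mm,
    values,
    grid_interval_mm: float = 1.0,
) -> CycleSummary:
    """Per-sweep linear interpolation onto a uniform displacement grid.

    The series is split into maximal monotone sweeps of the truth
    displacement (each half of a back-and-forth cycle), each sweep is
    linearly interpolated onto the grid, and the cross-sweep mean and
    1.96 * sample SD are reported per grid point.  Grid points covered by a
    single sweep carry the sweep value with a NaN band.
    """
    if grid_interval_mm <= 0:
        raise ValueError("grid_interval_mm must be > 0")
    d = np.asarray(truth_mm, dtype=float)
    v = np.asarray(values, dtype=float)
    if d.shape != v.shape or d.ndim != 1:
        raise ValueError("truth and values must be equal-length 1-D arrays")
    sweeps = _monotone_sweeps(d)
    lo = np.ceil(d.min() / grid_interval_mm) * grid_interval_mm
    hi = np.floor(d.max() / grid_interval_mm) * grid_interval_mm
    grid = np.arange(lo, hi + grid_interval_mm / 2, grid_interval_mm)
    samples = np.full((len(sweeps), len(grid)), np.nan)
    for i, idx in enumerate(sweeps):
        dd, vv = d[idx], v[idx]
        if np.ptp(dd) < grid_interval_mm:
            continue  # sweep shorter than one grid step
        order = np.argsort(dd, kind="stable")
        dd, vv = dd[order], vv[order]
        # average duplicate displacements (dwell frames) before interpolation
        uniq, inv = np.unique(dd, return_inverse=True)
        acc = np.zeros(len(uniq))
        cnt = np.zeros(len(uniq))
        np.add.at(acc, inv, vv)
        np.add.at(cnt, inv, 1)
        prof = acc / cnt
        inside = (grid >= uniq[0]) & (grid <= uniq[-1])
        samples[i, inside] = np.interp(grid[inside], uniq, prof)
    n_sweeps = np.sum(np.isfinite(samples), axis=0)
    if np.all(n_sweeps < 2):
        if len(sweeps) < 2:
            # single sweep: mean equals the sweep, band undefined
            pass
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(samples, axis=0)
        band = np.full(len(grid), np.nan)
        ok = n_sweeps >= 2
        if np.any(ok):
            band[ok] = 1.96 * np.nanstd(samples[:, ok], axis=0, ddof=1)
    return CycleSummary(grid_mm=grid, mean=mean, band=band, n_sweeps=n_sweeps)
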