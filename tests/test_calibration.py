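import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from ettnir import (
    CalibrationSet,
    DisplacementEstimator,
    compute_ratios,
    estimate_displacement,
    fit_calibration,
    load_model,
    rotation_alert,
    save_model,
    track_series,
)
from ettnir.calibration import (
    LowSignalError,
    RatioPair,
    classify_direction,
    invert_branch,
)
from ettnir.electronics import VOLTAGE_COLUMNS, VoltageSeries


def _cal_set(r12=None, r32=None):
    d = (-10.0, -5.0, 0.0, 5.0, 10.0)
    r12 = r12 or (2.0, 1.4, 1.0, 0.7, 0.5)
    r32 = r32 or (0.5, 0.7, 1.0, 1.4, 2.0)
    return CalibrationSet(displacements_mm=d, r12=r12, r32=r32)


def _series_from_voltages(v, fs=250.0):
    frame = pd.DataFrame(np.atleast_2d(v), columns=list(VOLTAGE_COLUMNS))
    frame.insert(0, "time_s", np.arange(len(frame)) / fs)
    return VoltageSeries(frame, fs)


# ------------------------------------------------------------- ratios


def test_ratio_arithmetic():
    assert compute_ratios([1.0, 1.0, 1.0]) == (1.0, 1.0)
    assert compute_ratios([3.0, 2.0, 1.0]) == (1.5, 0.5)


def test_low_center_voltage_raises():
    with pytest.raises(LowSignalError):
        compute_ratios([1.0, 0.001, 1.0])


# ------------------------------------------------------------- fitting


def test_branches_interpolate_their_nodes_exactly():
    model = fit_calibration(_cal_set())
    a, b, c = model.f12_high_
    for d, r in [(-10.0, 2.0), (-5.0, 1.4), (0.0, 1.0)]:
        assert a * d * d + b * d + c == pytest.approx(r, rel=1e-9)
    a, b, c = model.f32_high_
    for d, r in [(0.0, 1.0), (5.0, 1.4), (10.0, 2.0)]:
        assert a * d * d + b * d + c == pytest.approx(r, rel=1e-9)


def test_exact_quadratic_is_recovered():
    f = lambda d: 1.0 + 0.01 * d + 0.002 * d * d
    d = np.array([-10.0, -5.0, 0.0, 5.0, 10.0])
    cal = CalibrationSet(tuple(d), tuple(f(d)), tuple(f(-d)))
    model = fit_calibration(cal)
    # the negative-direction r12 branch sees the same quadratic
    assert np.allclose(model.f12_high_, [0.002, 0.01, 1.0], atol=1e-10)


def test_non_monotone_branch_is_flagged():
    """Nodes (0, 1), (5, 1.2), (10, 1.1) put the fitted vertex inside (0, 10)."""
    model = fit_calibration(_cal_set(r32=(0.5, 0.7, 1.0, 1.2, 1.1)))
    assert model.monotone_flags_["f32_high"] is True
    a, b, _ = model.f32_high_
    assert -b / (2 * a) == pytest.approx(35.0 / 6.0, rel=1e-9)  # vertex at 5.83 mm
    clean = fit_calibration(_cal_set())
    assert not any(clean.monotone_flags_.values())


def test_duplicate_displacements_rejected():
    with pytest.raises(ValueError):
        CalibrationSet((-10.0, -5.0, 0.0, 5.0, 5.0), (2, 1.4, 1, 0.7, 0.5), (0.5, 0.7, 1, 1.4, 2))


# ------------------------------------------------------------- direction


def test_direction_rule():
    assert classify_direction(RatioPair(1.2, 0.9), r12_zero=1.0) == "negative"
    assert classify_direction(RatioPair(0.8, 1.1), r12_zero=1.0) == "positive"
    assert classify_direction(RatioPair(1.0, 1.0), r12_zero=1.0) == "zero"


def test_direction_deadband():
    assert classify_direction(RatioPair(1.05, 1.0), 1.0, deadband=0.1) == "zero"
    assert classify_direction(RatioPair(1.15, 1.0), 1.0, deadband=0.1) == "negative"


# ------------------------------------------------------------- inversion


def test_invert_recovers_node():
    model = fit_calibration(_cal_set())
    d, oor = invert_branch(model.f12_high_, 1.4, (-10.0, 0.0))
    assert d == pytest.approx(-5.0, abs=1e-9)
    assert not oor


def test_invert_linear_branch():
    d, oor = invert_branch((0.0, -0.05, 1.0), 0.75, (0.0, 10.0))
    assert d == pytest.approx(5.0)
    assert not oor


def test_invert_quadratic_at_range_end():
    # quadratic through (0, 1.0), (5, 1.5), (10, 2.2) is 0.004 d^2 + 0.08 d + 1
    coeffs = (0.004, 0.08, 1.0)
    d, oor = invert_branch(coeffs, 2.2, (0.0, 10.0))
    assert d == pytest.approx(10.0, abs=1e-9)
    assert not oor


def test_invert_clamps_out_of_range_ratio():
    d, oor = invert_branch((0.004, 0.08, 1.0), 3.0, (0.0, 10.0))
    assert d == 10.0
    assert oor
    d, oor = invert_branch((0.004, 0.08, 1.0), 0.5, (0.0, 10.0))
    assert d == 0.0
    assert oor


def test_invert_rejects_two_in_range_roots():
    # non-monotone quadratic -0.006 d^2 + 0.07 d + 1 crosses 1.15 twice in (0, 10)
    with pytest.raises(ValueError, match="monotone"):
        invert_branch((-0.006, 0.07, 1.0), 1.15, (0.0, 10.0))


def test_invert_rejects_degenerate_branch():
    with pytest.raises(ValueError, match="degenerate"):
        invert_branch((0.0, 0.0, 1.0), 1.2, (0.0, 10.0))


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    slope=st.floats(0.02, 0.2),
    curv=st.floats(-0.0009, 0.004),
    d_true=st.floats(0.0, 10.0),
)
def test_invert_is_inverse_of_evaluation_on_monotone_branches(slope, curv, d_true):
    """f monotone increasing on (0, 10) implies invert(f(d)) == d."""
    coeffs = (curv, slope, 1.0)  # f'(d) = 2 curv d + slope > 0 on [0, 10]
    value = coeffs[0] * d_true**2 + coeffs[1] * d_true + coeffs[2]
    d, oor = invert_branch(coeffs, value, (0.0, 10.0))
    assert not oor
    assert d == pytest.approx(d_true, abs=1e-6)


# ------------------------------------------------------------- estimation


def test_estimates_recover_all_calibration_nodes():
    cal = _cal_set()
    model = fit_calibration(cal)
    X = np.column_stack((cal.r12, cal.r32))
    pred = model.predict(X)
    assert np.allclose(pred, cal.displacements_mm, atol=1e-6)


def test_weighted_fusion_identity():
    model = fit_calibration(_cal_set(), weight_w=0.95)
    detail = model.predict_detail([[1.7, 0.6], [0.6, 1.7], [1.1, 0.93]])
    recomputed = 0.95 * detail.d_high_mm + (1 - 0.95) * detail.d_low_mm
    assert np.all(detail.d_final_mm.to_numpy() == recomputed.to_numpy())


def test_weight_example():
    est = estimate_displacement(RatioPair(2.0, 0.5), fit_calibration(_cal_set(), weight_w=0.95))
    # both branches recover -10 exactly here; check the fused form explicitly
    assert est.d_final_mm == pytest.approx(0.95 * est.d_high_mm + 0.05 * est.d_low_mm)
    assert est.direction == "negative"


def test_baseline_ratios_give_zero():
    model = fit_calibration(_cal_set())
    est = estimate_displacement(RatioPair(1.0, 1.0), model)
    assert est.d_final_mm == 0.0
    assert est.direction == "zero"


@settings(derandomize=True, max_examples=50, deadline=None)
@given(scale=st.floats(0.05, 1.5))
def test_common_voltage_scaling_leaves_estimate_unchanged(scale):
    model = fit_calibration(_cal_set())
    v = np.array([1.4, 1.0, 0.7, 0.8, 0.8])
    base = model.predict([compute_ratios(v)])[0]
    scaled = model.predict([compute_ratios(v * scale)])[0]
    assert scaled == pytest.approx(base, abs=1e-9)


def test_monotone_tracking_of_monotone_forward_curves(pseudo_curves, fitted_model):
    d = np.arange(-10.0, 10.01, 0.5)
    pred = fitted_model.predict(pseudo_curves.ratios_at(d))
    assert np.all(np.diff(pred) >= -1e-9)


def test_direction_always_correct_beyond_one_millimetre(pseudo_curves, fitted_model):
    d = np.concatenate((np.arange(-10, 0.0, 0.5), np.arange(1.0, 10.5, 0.5)))
    detail = fitted_model.predict_detail(pseudo_curves.ratios_at(d))
    expected = np.where(d < 0, "negative", "positive")
    assert np.all(detail.direction.to_numpy() == expected)


def test_noiseless_grid_recovery_within_band(pseudo_curves, fitted_model):
    d = np.arange(-10.0, 10.01, 1.0)
    pred = fitted_model.predict(pseudo_curves.ratios_at(d))
    assert np.max(np.abs(pred - d)) <= 1.5


# ------------------------------------------------------------- rotation alert


def test_rotation_alert_thresholds():
    frame = {"vp2_v": 2.0, "vp4_v": 1.6, "vp5_v": 1.6}
    ok = rotation_alert(frame, baselines=(0.8, 0.8), threshold=0.30)
    assert not ok.flagged
    hot = rotation_alert({"vp2_v": 2.0, "vp4_v": 2.4, "vp5_v": 1.6}, (0.8, 0.8), 0.30)
    assert hot.flagged  # VP4/VP2 = 1.5x baseline
    strict = rotation_alert({"vp2_v": 2.0, "vp4_v": 1.601, "vp5_v": 1.6}, (0.8, 0.8), 0.0)
    assert strict.flagged


# ------------------------------------------------------------- tracking


def test_constant_frames_give_constant_stream():
    cal = _cal_set()
    model = fit_calibration(cal)
    v2 = 2.0
    v = np.tile([cal.r12[3] * v2, v2, cal.r32[3] * v2, 0.8 * v2, 0.8 * v2], (40, 1))
    out = track_series(_series_from_voltages(v), model)
    assert np.allclose(out.d_final_mm, 5.0, atol=1e-6)


def test_center_dropout_isolates_one_frame():
    cal = _cal_set()
    model = fit_calibration(cal)
    v = np.tile([1.0, 1.0, 1.0, 0.8, 0.8], (5, 1))
    v[2, 1] = 0.0  # VP2 dropout
    out = track_series(_series_from_voltages(v), model)
    assert out.low_signal.tolist() == [False, False, True, False, False]
    assert np.isnan(out.d_final_mm[2])
    assert np.allclose(out.d_final_mm.drop(index=2), 0.0)


# ------------------------------------------------------------- persistence


def test_model_json_round_trip_is_exact(tmp_path, fitted_model):
    path = tmp_path / "model.json"
    save_model(fitted_model, path)
    loaded = load_model(path)
    for attr in ("f12_high_", "f32_low_", "f32_high_", "f12_low_"):
        assert np.array_equal(getattr(loaded, attr), getattr(fitted_model, attr))
    assert loaded.r12_zero_ == fitted_model.r12_zero_
    assert loaded.r32_zero_ == fitted_model.r32_zero_
    X = [[1.3, 0.8], [0.7, 1.4]]
    assert np.array_equal(loaded.predict(X), fitted_model.predict(X))


# ------------------------------------------------------------- sklearn API


def test_estimator_follows_sklearn_conventions():
    est = DisplacementEstimator(weight_high=0.9, deadband=0.01)
    assert est.get_params() == {"weight_high": 0.9, "deadband": 0.01}
    cloned = clone(est)
    assert cloned.get_params() == est.get_params()
    cal = _cal_set()
    X = np.column_stack((cal.r12, cal.r32))
    y = np.array(cal.displacements_mm)
    cloned.set_params(weight_high=1.0).fit(X, y)
    detail = cloned.predict_detail([[2.0, 0.5]])
    # with w = 1 the estimate depends on the high branch only
    assert detail.d_final_mm[0] == detail.d_high_mm[0]
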