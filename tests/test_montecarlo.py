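import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ettnir import (
    ExitanceProfile,
    build_tissue_stack,
    fresnel_interface,
    half_intensity_halfwidth,
    run_mc,
    sample_hg_cosine,
    sample_planar_deflection,
    simulate_ratio_curves,
    smooth_profile,
)
from ettnir.montecarlo import SourceSpec


def _profile(x, y, width):
    return ExitanceProfile(bin_centers_mm=x, intensity=y, bin_width_mm=width)


# ---------------------------------------------------------------- samplers


def test_hg_isotropic_midpoint():
    assert sample_hg_cosine(0.0, 0.5) == pytest.approx(0.0)


def test_hg_forward_peaked_limit():
    assert sample_hg_cosine(0.9, 1.0 - 1e-12) == pytest.approx(1.0, abs=1e-6)


@pytest.mark.parametrize("g", [0.0, 0.79, 0.9, 0.95])
def test_hg_mean_cosine_matches_anisotropy(g):
    """E[cos(theta)] of Henyey-Greenstein sampling equals g (3-sigma check)."""
    rng = np.random.default_rng(12345)
    c = sample_hg_cosine(g, rng.random(1_000_000))
    se = c.std(ddof=1) / math.sqrt(len(c))
    assert abs(c.mean() - g) < 3 * se + 1e-12
    assert np.all((c >= -1) & (c <= 1))


@pytest.mark.parametrize("g", [0.0, 0.79, 0.95])
def test_planar_deflection_mean_cosine_matches_anisotropy(g):
    """The wrapped-Cauchy planar deflection also has mean cosine g."""
    rng = np.random.default_rng(54321)
    th = sample_planar_deflection(g, rng.random(1_000_000))
    c = np.cos(th)
    se = c.std(ddof=1) / math.sqrt(len(c))
    assert abs(c.mean() - g) < 3 * se + 1e-12


@settings(derandomize=True, max_examples=100, deadline=None)
@given(g=st.floats(-0.99, 0.99), u=st.floats(0.0, 1.0, exclude_max=True))
def test_hg_cosine_always_in_unit_interval(g, u):
    assert -1.0 <= sample_hg_cosine(g, u) <= 1.0


# ---------------------------------------------------------------- Fresnel


def test_fresnel_matched_indices_pass_through():
    r, ct = fresnel_interface(1.4, 1.4, 0.3)
    assert r == 0.0
    assert ct == pytest.approx(0.3)


def test_fresnel_normal_incidence_closed_form():
    r, ct = fresnel_interface(1.0, 1.4, 1.0)
    assert r == pytest.approx((0.4 / 2.4) ** 2, rel=1e-12)
    assert ct == pytest.approx(1.0)


def test_fresnel_total_internal_reflection():
    # grazing incidence from 1.45 into 1.40, beyond the critical angle
    cos_crit = math.sqrt(1.0 - (1.40 / 1.45) ** 2)
    r, ct = fresnel_interface(1.45, 1.40, 0.5 * cos_crit)
    assert r == 1.0
    assert math.isnan(ct)


# ---------------------------------------------------------------- transport


def test_beer_lambert_limit():
    """mu_s = 0, matched indices, pencil beam: transmission is exp(-mu_a t)."""
    stack = build_tissue_stack(
        [{"name": "ab", "thickness_mm": 10.0, "mu_a_per_cm": 1.0, "mu_s_per_cm": 0.0, "g": 0.0, "n": 1.0}]
    )
    n = 200_000
    src = SourceSpec(angular_model="pencil", n_packets=n, seed=4)
    _, tally = run_mc(stack, src, n_outside=1.0)
    expected = math.exp(-1.0)
    se = math.sqrt(expected * (1 - expected) / n)
    assert abs(tally.skin_exitance_weight - expected) < 3 * se


def test_energy_conservation(mc_profile):
    _, tally = mc_profile
    assert tally.balance_error <= 1e-3


def test_all_tallies_nonnegative(mc_profile):
    _, t = mc_profile
    assert min(t.absorbed_weight, t.skin_exitance_weight,
               t.lumen_reflectance_weight, t.lateral_escape_weight) >= 0.0


def test_fixed_seed_runs_are_bit_identical(stack):
    src = SourceSpec(n_packets=50_000, seed=77)
    p1, t1 = run_mc(stack, src)
    p2, t2 = run_mc(stack, src)
    assert np.array_equal(p1.intensity, p2.intensity)
    assert t1 == t2


def test_centered_source_profile_is_symmetric(mc_profile):
    """|I(x) - I(-x)| within 4 combined MC standard errors per bin pair."""
    profile, _ = mc_profile
    y = profile.intensity
    se = profile.intensity_se
    y_r = y[::-1]
    se_r = se[::-1]
    tol = 4.0 * np.sqrt(se**2 + se_r**2) + 1e-12
    assert np.all(np.abs(y - y_r) <= tol)


def test_profile_flanks_decrease_monotonically(mc_profile):
    """Smoothed exitance decays beyond +/-2 mm of the peak, up to MC noise."""
    profile, _ = mc_profile
    x = profile.bin_centers_mm
    y = profile.intensity
    se = profile.intensity_se
    peak = x[np.argmax(y)]
    for sel, flip in (((x > peak + 2) & (x < 20), 1), ((x < peak - 2) & (x > -20), -1)):
        yy = y[sel][::flip]
        ss = se[sel][::flip]
        rises = np.diff(yy)
        tol = 3.0 * np.sqrt(ss[:-1] ** 2 + ss[1:] ** 2)
        assert np.all(rises <= tol)


def test_small_packet_count_warns(stack):
    with pytest.warns(UserWarning, match="small"):
        run_mc(stack, SourceSpec(n_packets=1_000, seed=1))


def test_unknown_dimensionality_rejected(stack):
    with pytest.raises(ValueError, match="dimensionality"):
        run_mc(stack, SourceSpec(n_packets=10_000, seed=1), dimensionality="4d")


# ---------------------------------------------------------------- smoothing


def test_smoothing_window_one_is_identity(mc_profile):
    profile, _ = mc_profile
    out = smooth_profile(profile, 1)
    assert np.array_equal(out.intensity, profile.intensity)
    assert out.smoothing_window == 1


def test_smoothing_preserves_constant():
    x = np.arange(-5.0, 5.5, 0.5)
    p = _profile(x, np.full_like(x, 2.0), 0.5)
    out = smooth_profile(p, 6)
    assert np.allclose(out.intensity, 2.0)


def test_smoothing_spreads_impulse_to_plateau():
    x = np.arange(-10.0, 10.5, 0.5)
    y = np.zeros_like(x)
    y[len(x) // 2] = 3.0
    out = smooth_profile(_profile(x, y, 0.5), 6)
    interior = out.intensity[np.abs(out.intensity) > 1e-15]
    assert len(interior) == 6
    assert np.allclose(interior, 3.0 / 6.0)


def test_smoothing_window_larger_than_profile_rejected():
    x = np.arange(-1.0, 1.5, 0.5)
    with pytest.raises(ValueError, match="window"):
        smooth_profile(_profile(x, np.ones_like(x), 0.5), 10)


# ---------------------------------------------------------------- half-width


def test_halfwidth_of_triangle_profile():
    x = np.arange(-12.0, 12.5, 0.5)
    y = np.clip(1.0 - np.abs(x) / 10.0, 0.0, None)
    assert half_intensity_halfwidth(_profile(x, y, 0.5)) == pytest.approx(5.0)


def test_halfwidth_of_gaussian_profile():
    sigma = 5.0
    x = np.arange(-25.0, 25.05, 0.1)
    y = np.exp(-(x**2) / (2 * sigma**2))
    expected = sigma * math.sqrt(2 * math.log(2))  # 5.887 mm
    assert half_intensity_halfwidth(_profile(x, y, 0.1)) == pytest.approx(expected, abs=0.05)


def test_halfwidth_requires_crossing():
    x = np.arange(-2.0, 2.5, 0.5)
    y = 1.0 - 0.01 * x**2  # never reaches half within the window
    with pytest.raises(ValueError, match="crossing|edge"):
        half_intensity_halfwidth(_profile(x, y, 0.5))


# ---------------------------------------------------------------- ratio curves


def test_simulated_ratio_curves_branch_structure(stack, geometry):
    """r12 and r32 cross at d = 0 and dominate on opposite sides."""
    curves = simulate_ratio_curves(
        stack, SourceSpec(n_packets=300_000, seed=2), geometry, [-10.0, 0.0, 10.0]
    )
    r = curves.set_index("d_mm")
    assert r.loc[-10.0, "r12"] > r.loc[-10.0, "r32"]
    assert r.loc[10.0, "r12"] < r.loc[10.0, "r32"]
    # mirror symmetry at the centered position, within MC noise
    assert r.loc[0.0, "r12"] == pytest.approx(r.loc[0.0, "r32"], rel=0.25)


def test_rotated_source_leaves_ratio_curves_unchanged(stack, geometry):
    """Tilting the source +/-40 deg (3-D) barely moves the ratio curves."""
    d = [-10.0, -5.0, 0.0, 5.0, 10.0]
    c0 = simulate_ratio_curves(
        stack, SourceSpec(n_packets=400_000, seed=5), geometry, d, dimensionality="slab3D"
    )
    c40 = simulate_ratio_curves(
        stack,
        SourceSpec(n_packets=400_000, seed=6, tilt_angle_deg=40.0),
        geometry,
        d,
        dimensionality="slab3D",
    )
    assert np.all(np.abs(c40.r12 / c0.r12 - 1.0) < 0.25)
    assert np.all(np.abs(c40.r32 / c0.r32 - 1.0) < 0.25)
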