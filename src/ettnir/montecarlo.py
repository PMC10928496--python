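"""Layered-slab Monte Carlo transport of NIR photon packets.

Classic packet-transport kernel for plane-parallel tissue: exponential free
paths against ``mu_t = mu_a + mu_s``, weight-fraction absorption
``mu_a/mu_t`` per interaction, Henyey-Greenstein scattering, unpolarized
Fresnel reflection/refraction at every refractive-index mismatch (including
the outer air boundaries), and Russian-roulette termination of low-weight
packets.  Two geometries are provided:

* ``planar2D`` — true planar transport: positions and directions confined to
  the x-z plane; the scattering deflection is a single signed angle drawn
  from the wrapped-Cauchy density, the exact planar analogue of
  Henyey-Greenstein (mean cosine equals ``g``, closed-form inverse CDF).
* ``slab3D`` — full 3-D transport with the standard Henyey-Greenstein
  inverse-CDF polar sampling and uniform azimuth; the skin exitance is
  tallied on an (x, y) map.

The source models a side-firing fiber tip pressed against the lumen wall:
a point source at z = 0 emitting into the tissue, either a Lambertian
(cosine-lobe) emitter or a pencil beam, optionally tilted to emulate tube
rotation.  The launched power is normalized to 1 W.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from numba import njit

from .tissue import TissueStack

__all__ = [
    "SourceSpec",
    "ExitanceProfile",
    "ExitanceMap",
    "TransportTally",
    "sample_hg_cosine",
    "sample_planar_deflection",
    "fresnel_interface",
    "run_mc",
    "smooth_profile",
    "half_intensity_halfwidth",
    "simulate_ratio_curves",
]

#: packet weight below which Russian roulette is played
ROULETTE_THRESHOLD = 1e-4
#: survival probability in Russian roulette (survivors boosted by 1/p)
ROULETTE_SURVIVE = 0.1


@dataclass(frozen=True)
class SourceSpec:
    """Side-firing fiber tip modeled as a surface point source.

    ``tilt_angle_deg`` rotates the emission lobe away from the inward surface
    normal (in the transport plane for 2D, in the y-z plane for 3D, matching
    rotation of the tube about its own axis).
    """

    lateral_position_mm: float = 0.0
    angular_model: Literal["cosine_lobe", "pencil"] = "cosine_lobe"
    tilt_angle_deg: float = 0.0
    n_packets: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_packets < 1:
            raise ValueError("n_packets must be >= 1")
        if not -90.0 <= self.tilt_angle_deg <= 90.0:
            raise ValueError("tilt_angle_deg must be within [-90, 90]")
        if self.angular_model not in ("cosine_lobe", "pencil"):
            raise ValueError(f"unknown angular_model {self.angular_model!r}")


@dataclass(frozen=True)
class TransportTally:
    """Energy bookkeeping for one run (all in W, launched power = 1)."""

    launched_weight: float
    absorbed_weight: float
    skin_exitance_weight: float
    lumen_reflectance_weight: float
    lateral_escape_weight: float

    @property
    def balance_error(self) -> float:
        """Relative deviation of the tally sum from the launched power."""
        total = (
            self.absorbed_weight
            + self.skin_exitance_weight
            + self.lumen_reflectance_weight
            + self.lateral_escape_weight
        )
        return abs(total - self.launched_weight) / self.launched_weight


@dataclass(frozen=True)
class ExitanceMap:
    """2-D skin exitance tally (W per bin) on an (x, y) grid, 3-D runs only."""

    x_centers_mm: np.ndarray
    y_centers_mm: np.ndarray
    intensity: np.ndarray  # shape (nx, ny)
    bin_width_mm: float


@dataclass(frozen=True)
class ExitanceProfile:
    """Lateral profile of diffusely transmitted power at the skin surface.

    ``intensity`` holds power per bin (W) normalized to 1 W launched;
    ``intensity_se`` the per-bin Monte Carlo standard error.
    """

    bin_centers_mm: np.ndarray
    intensity: np.ndarray
    bin_width_mm: float
    dimensionality: Literal["planar2D", "slab3D"] = "planar2D"
    smoothing_window: int = 0
    intensity_se: np.ndarray | None = None
    xy_map: ExitanceMap | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.bin_centers_mm, dtype=float)
        if c.ndim != 1 or len(c) < 2:
            raise ValueError("bin_centers_mm must be a 1-D array with >= 2 bins")
        d = np.diff(c)
        if not (np.all(d > 0) and np.allclose(d, d[0], rtol=1e-9)):
            raise ValueError("bin_centers_mm must be strictly increasing and uniform")
        if np.any(np.asarray(self.intensity) < 0):
            raise ValueError("intensity must be non-negative everywhere")


# ---------------------------------------------------------------------------
# elementary samplers / optics, shared by the python API and the jit kernels


@njit(cache=True)
def _hg_cosine_nb(g: float, u: float) -> float:
    if abs(g) < 1e-7:
        return 2.0 * u - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - t * t) / (2.0 * g)
    return min(1.0, max(-1.0, c))


@njit(cache=True)
def _planar_deflection_nb(g: float, u: float) -> float:
    # wrapped-Cauchy inverse CDF; E[cos(theta)] = g exactly
    if abs(g) < 1e-7:
        return math.pi * (2.0 * u - 1.0)
    return 2.0 * math.atan(((1.0 - g) / (1.0 + g)) * math.tan(math.pi * (u - 0.5)))


@njit(cache=True)
def _fresnel_nb(n_from: float, n_to: float, ci: float):
    """Unpolarized Fresnel reflectance and transmitted |cos| for ci = |cos(inc)|."""
    if n_from == n_to:
        return 0.0, ci
    si2 = 1.0 - ci * ci
    if si2 < 0.0:
        si2 = 0.0
    st2 = (n_from / n_to) * (n_from / n_to) * si2
    if st2 >= 1.0:
        return 1.0, 0.0  # total internal reflection
    ct = math.sqrt(1.0 - st2)
    rs = (n_from * ci - n_to * ct) / (n_from * ci + n_to * ct)
    rp = (n_from * ct - n_to * ci) / (n_from * ct + n_to * ci)
    return 0.5 * (rs * rs + rp * rp), ct


def sample_hg_cosine(g: float, u: float | np.ndarray) -> float | np.ndarray:
    """Henyey-Greenstein inverse-CDF sample of cos(theta); isotropic at g = 0."""
    u = np.asarray(u, dtype=float)
    if abs(g) < 1e-7:
        out = 2.0 * u - 1.0
    else:
        t = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        out = np.clip((1.0 + g * g - t * t) / (2.0 * g), -1.0, 1.0)
    return float(out) if out.ndim == 0 else out


def sample_planar_deflection(g: float, u: float | np.ndarray) -> float | np.ndarray:
    """Signed planar deflection angle from the wrapped-Cauchy density.

    This is the planar analogue of Henyey-Greenstein scattering: the mean
    cosine of the deflection equals ``g`` and the inverse CDF is closed-form.
    """
    u = np.asarray(u, dtype=float)
    if abs(g) < 1e-7:
        out = np.pi * (2.0 * u - 1.0)
    else:
        out = 2.0 * np.arctan(((1.0 - g) / (1.0 + g)) * np.tan(np.pi * (u - 0.5)))
    return float(out) if out.ndim == 0 else out


def fresnel_interface(n_from: float, n_to: float, cos_incident: float) -> tuple[float, float]:
    """Unpolarized Fresnel reflectance and refracted direction cosine.

    Returns ``(reflect_probability, cos_transmitted)``; beyond the critical
    angle the probability is 1 and the refracted cosine is NaN.
    """
    if n_from < 1 or n_to < 1:
        raise ValueError("refractive indices must be >= 1")
    if abs(cos_incident) > 1:
        raise ValueError("|cos_incident| must be <= 1")
    r, ct = _fresnel_nb(n_from, n_to, abs(cos_incident))
    if r == 1.0 and n_from != n_to:
        return 1.0, float("nan")
    # preserve the travel direction sign
    return r, math.copysign(ct, cos_incident) if cos_incident != 0 else ct


# ---------------------------------------------------------------------------
# transport kernels


@njit(cache=True)
def _transport_2d(
    seed,
    n_packets,
    zb,
    mua,
    mus,
    g,
    nidx,
    n_out,
    src_x,
    tilt_rad,
    pencil,
    half_dom,
    nbins,
    bin_w,
    w_min,
    p_surv,
):
    np.random.seed(seed)
    nlay = mua.shape[0]
    bins = np.zeros(nbins)
    bins_sq = np.zeros(nbins)
    absorbed = 0.0
    refl = 0.0
    lateral = 0.0
    trans = 0.0
    for _ in range(n_packets):
        if pencil:
            ang = tilt_rad
        else:
            ang = math.asin(2.0 * np.random.random() - 1.0) + tilt_rad
        ux = math.sin(ang)
        uz = math.cos(ang)
        if uz <= 0.0:
            refl += 1.0  # tilted lobe pointing out of the tissue
            continue
        x = src_x
        z = 0.0
        layer = 0
        w = 1.0
        alive = True
        while alive:
            s = -math.log(np.random.random() + 1e-300)
            while True:
                mt = mua[layer] + mus[layer]
                step = s / mt
                if uz > 0.0:
                    db = (zb[layer + 1] - z) / uz
                elif uz < 0.0:
                    db = (zb[layer] - z) / uz
                else:
                    db = 1e30
                if db <= step:
                    x += ux * db
                    z += uz * db
                    s -= db * mt
                    if abs(x) > half_dom:
                        lateral += w
                        alive = False
                        break
                    up = uz > 0.0
                    ni = nidx[layer]
                    if up:
                        nt = n_out if layer == nlay - 1 else nidx[layer + 1]
                    else:
                        nt = n_out if layer == 0 else nidx[layer - 1]
                    r, ct = _fresnel_nb(ni, nt, abs(uz))
                    if np.random.random() < r:
                        uz = -uz
                        z = zb[layer + 1] if up else zb[layer]
                    else:
                        sx = ux * ni / nt
                        ux = sx
                        uz = ct if up else -ct
                        nrm = math.sqrt(ux * ux + uz * uz)
                        ux /= nrm
                        uz /= nrm
                        if up and layer == nlay - 1:
                            trans += w
                            ib = int((x + half_dom) / bin_w)
                            if 0 <= ib < nbins:
                                bins[ib] += w
                                bins_sq[ib] += w * w
                            alive = False
                            break
                        if (not up) and layer == 0:
                            refl += w
                            alive = False
                            break
                        if up:
                            layer += 1
                            z = zb[layer]
                        else:
                            z = zb[layer]
                            layer -= 1
                else:
                    x += ux * step
                    z += uz * step
                    if abs(x) > half_dom:
                        lateral += w
                        alive = False
                        break
                    absorbed += w * mua[layer] / mt
                    w *= mus[layer] / mt
                    if w <= 0.0:
                        alive = False
                        break
                    th = _planar_deflection_nb(g[layer], np.random.random())
                    cth = math.cos(th)
                    sth = math.sin(th)
                    ux, uz = ux * cth - uz * sth, ux * sth + uz * cth
                    if w < w_min:
                        if np.random.random() < p_surv:
                            w /= p_surv
                        else:
                            absorbed += w
                            alive = False
                    break
    return bins, bins_sq, absorbed, refl, trans, lateral


@njit(cache=True)
def _transport_3d(
    seed,
    n_packets,
    zb,
    mua,
    mus,
    g,
    nidx,
    n_out,
    src_x,
    tilt_rad,
    pencil,
    half_dom,
    nbins,
    bin_w,
    w_min,
    p_surv,
):
    np.random.seed(seed)
    nlay = mua.shape[0]
    xymap = np.zeros((nbins, nbins))
    xbins_sq = np.zeros(nbins)
    absorbed = 0.0
    refl = 0.0
    lateral = 0.0
    trans = 0.0
    st_t = math.sin(tilt_rad)
    ct_t = math.cos(tilt_rad)
    for _ in range(n_packets):
        if pencil:
            dx = 0.0
            dy = st_t
            dz = ct_t
        else:
            # cosine lobe about +z, then rotate the lobe axis by tilt about x
            czl = math.sqrt(np.random.random())
            szl = math.sqrt(max(0.0, 1.0 - czl * czl))
            phi = 2.0 * math.pi * np.random.random()
            lx = szl * math.cos(phi)
            ly = szl * math.sin(phi)
            dx = lx
            dy = ly * ct_t + czl * st_t
            dz = -ly * st_t + czl * ct_t
        if dz <= 0.0:
            refl += 1.0
            continue
        ux, uy, uz = dx, dy, dz
        x = src_x
        y = 0.0
        z = 0.0
        layer = 0
        w = 1.0
        alive = True
        while alive:
            s = -math.log(np.random.random() + 1e-300)
            while True:
                mt = mua[layer] + mus[layer]
                step = s / mt
                if uz > 0.0:
                    db = (zb[layer + 1] - z) / uz
                elif uz < 0.0:
                    db = (zb[layer] - z) / uz
                else:
                    db = 1e30
                if db <= step:
                    x += ux * db
                    y += uy * db
                    z += uz * db
                    s -= db * mt
                    if abs(x) > half_dom or abs(y) > half_dom:
                        lateral += w
                        alive = False
                        break
                    up = uz > 0.0
                    ni = nidx[layer]
                    if up:
                        nt = n_out if layer == nlay - 1 else nidx[layer + 1]
                    else:
                        nt = n_out if layer == 0 else nidx[layer - 1]
                    r, ct = _fresnel_nb(ni, nt, abs(uz))
                    if np.random.random() < r:
                        uz = -uz
                        z = zb[layer + 1] if up else zb[layer]
                    else:
                        scale = ni / nt
                        ux *= scale
                        uy *= scale
                        uz = ct if up else -ct
                        nrm = math.sqrt(ux * ux + uy * uy + uz * uz)
                        ux /= nrm
                        uy /= nrm
                        uz /= nrm
                        if up and layer == nlay - 1:
                            trans += w
                            ix = int((x + half_dom) / bin_w)
                            iy = int((y + half_dom) / bin_w)
                            if 0 <= ix < nbins and 0 <= iy < nbins:
                                xymap[ix, iy] += w
                                xbins_sq[ix] += w * w
                            alive = False
                            break
                        if (not up) and layer == 0:
                            refl += w
                            alive = False
                            break
                        if up:
                            layer += 1
                            z = zb[layer]
                        else:
                            z = zb[layer]
                            layer -= 1
                else:
                    x += ux * step
                    y += uy * step
                    z += uz * step
                    if abs(x) > half_dom or abs(y) > half_dom:
                        lateral += w
                        alive = False
                        break
                    absorbed += w * mua[layer] / mt
                    w *= mus[layer] / mt
                    if w <= 0.0:
                        alive = False
                        break
                    cth = _hg_cosine_nb(g[layer], np.random.random())
                    sth = math.sqrt(max(0.0, 1.0 - cth * cth))
                    phi = 2.0 * math.pi * np.random.random()
                    cph = math.cos(phi)
                    sph = math.sin(phi)
                    if abs(uz) > 0.99999:
                        ux = sth * cph
                        uy = sth * sph
                        uz = cth if uz > 0 else -cth
                    else:
                        den = math.sqrt(1.0 - uz * uz)
                        nx = sth * (ux * uz * cph - uy * sph) / den + ux * cth
                        ny = sth * (uy * uz * cph + ux * sph) / den + uy * cth
                        nz = -sth * cph * den + uz * cth
                        ux, uy, uz = nx, ny, nz
                    if w < w_min:
                        if np.random.random() < p_surv:
                            w /= p_surv
                        else:
                            absorbed += w
                            alive = False
                    break
    return xymap, xbins_sq, absorbed, refl, trans, lateral


def run_mc(
    stack: TissueStack,
    source: SourceSpec,
    dimensionality: Literal["planar2D", "slab3D"] = "planar2D",
    bin_width_mm: float = 0.5,
    domain_halfwidth_mm: float = 40.0,
    n_outside: float = 1.0,
) -> tuple[ExitanceProfile, TransportTally]:
    """Run the layered-slab Monte Carlo and tally skin exitance.

    Photons launch at the lumen surface (z = 0) and the skin surface sits at
    ``z = stack.total_thickness_mm``; both outer half-spaces are air
    (``n_outside``).  Packets wandering beyond ``domain_halfwidth_mm``
    laterally are tallied as lateral escape.  Results are bit-reproducible
    for a fixed ``(stack, source, binning)``.
    """
    if dimensionality not in ("planar2D", "slab3D"):
        raise ValueError(f"unknown dimensionality {dimensionality!r}")
    if bin_width_mm <= 0:
        raise ValueError("bin_width_mm must be > 0")
    if source.n_packets < 10_000:
        warnings.warn(
            f"n_packets = {source.n_packets} is small; exitance profiles will be noisy",
            stacklevel=2,
        )
    arrays = stack.as_arrays()
    nbins = int(round(2.0 * domain_halfwidth_mm / bin_width_mm))
    half_dom = nbins * bin_width_mm / 2.0
    args = (
        np.int64(source.seed % (2**31)),
        np.int64(source.n_packets),
        arrays["boundaries_mm"],
        arrays["mu_a_per_mm"],
        arrays["mu_s_per_mm"],
        arrays["g"],
        arrays["n"],
        float(n_outside),
        float(source.lateral_position_mm),
        math.radians(source.tilt_angle_deg),
        source.angular_model == "pencil",
        half_dom,
        nbins,
        float(bin_width_mm),
        ROULETTE_THRESHOLD,
        ROULETTE_SURVIVE,
    )
    if dimensionality == "planar2D":
        bins, bins_sq, absorbed, refl, trans, lateral = _transport_2d(*args)
        xy_map = None
    else:
        xymap, bins_sq, absorbed, refl, trans, lateral = _transport_3d(*args)
        bins = xymap.sum(axis=1)
        centers = -half_dom + (np.arange(nbins) + 0.5) * bin_width_mm
        xy_map = ExitanceMap(
            x_centers_mm=centers,
            y_centers_mm=centers.copy(),
            intensity=xymap / source.n_packets,
            bin_width_mm=float(bin_width_mm),
        )
    npk = float(source.n_packets)
    centers = -half_dom + (np.arange(nbins) + 0.5) * bin_width_mm
    profile = ExitanceProfile(
        bin_centers_mm=centers,
        intensity=bins / npk,
        bin_width_mm=float(bin_width_mm),
        dimensionality=dimensionality,
        smoothing_window=0,
        intensity_se=np.sqrt(bins_sq) / npk,
        xy_map=xy_map,
    )
    tally = TransportTally(
        launched_weight=1.0,
        absorbed_weight=absorbed / npk,
        skin_exitance_weight=trans / npk,
        lumen_reflectance_weight=refl / npk,
        lateral_escape_weight=lateral / npk,
    )
    return profile, tally


# ---------------------------------------------------------------------------
# profile post-processing


def smooth_profile(profile: ExitanceProfile, window: int) -> ExitanceProfile:
    """Centered moving average over ``window`` bins; edges use what is available."""
    n = len(profile.bin_centers_mm)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > n:
        raise ValueError(f"window {window} exceeds the bin count {n}")
    if window == 1:
        return replace(profile, smoothing_window=1)
    kernel = np.ones(window)
    counts = np.convolve(np.ones(n), kernel, mode="same")
    smoothed = np.convolve(np.asarray(profile.intensity, dtype=float), kernel, mode="same") / counts
    se = profile.intensity_se
    if se is not None:
        se = np.sqrt(np.convolve(np.asarray(se) ** 2, kernel, mode="same")) / counts
    return replace(profile, intensity=smoothed, intensity_se=se, smoothing_window=window)


def half_intensity_halfwidth(profile: ExitanceProfile) -> float:
    """Mean lateral distance from the peak to the half-peak crossings.

    Linearly interpolates the first crossing of half the peak intensity on
    each side of the (unique interior) maximum and averages the left and
    right distances.
    """
    x = np.asarray(profile.bin_centers_mm, dtype=float)
    y = np.asarray(profile.intensity, dtype=float)
    k = int(np.argmax(y))
    if k == 0 or k == len(y) - 1:
        raise ValueError("profile maximum lies on the domain edge")
    half = y[k] / 2.0

    def _cross(idx_range) -> float:
        prev = k
        for i in idx_range:
            if y[i] <= half:
                # linear interpolation between prev (above) and i (at/below)
                frac = (y[prev] - half) / (y[prev] - y[i])
                return abs((x[prev] + frac * (x[i] - x[prev])) - x[k])
            prev = i
        raise ValueError("no half-peak crossing found; domain too narrow")

    left = _cross(range(k - 1, -1, -1))
    right = _cross(range(k + 1, len(y)))
    return 0.5 * (left + right)


def simulate_ratio_curves(
    stack: TissueStack,
    source: SourceSpec,
    geometry,
    displacements_mm,
    dimensionality: Literal["planar2D", "slab3D"] = "planar2D",
    bin_width_mm: float = 0.5,
    domain_halfwidth_mm: float = 40.0,
    smoothing_window: int = 6,
):
    """Simulated voltage-ratio curves r12(d), r32(d) from one transport run.

    A single run with the spot centered at the source position is reused for
    all displacements: moving the tube by ``d`` shifts the skin light spot to
    x = d, so the sensors sample the profile at their positions minus ``d``.

    Returns a pandas DataFrame with columns ``d_mm, r12, r32``.
    """
    import pandas as pd

    from .electronics import sensor_intensities

    profile, _ = run_mc(
        stack,
        source,
        dimensionality=dimensionality,
        bin_width_mm=bin_width_mm,
        domain_halfwidth_mm=domain_halfwidth_mm,
    )
    if smoothing_window > 1:
        profile = smooth_profile(profile, smoothing_window)
    rows = []
    for d in np.asarray(displacements_mm, dtype=float):
        i1, i2, i3, _, _ = sensor_intensities(profile, geometry, d)
        if i2 <= 0:
            raise ValueError(f"zero center-sensor intensity at d = {d} mm")
        rows.append({"d_mm": d, "r12": i1 / i2, "r32": i3 / i2})
    return pd.DataFrame(rows)
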