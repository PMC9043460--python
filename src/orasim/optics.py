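"""Geometric-optics model of the ORA applanation detector.

A parallel beam (3 mm diameter, 3000 rays by default) leaves a transmitter
at 45 deg incidence, reflects specularly off the anterior corneal surface
and is tested against a co-sized receiver placed at the mirror-image
position; transmitter and receiver sit on the plane 11 cm above the corneal
apex, i.e. at a slant distance of 11*sqrt(2) cm along the beam.  The
normalized light intensity is the received ray fraction, and its variation
over the deformation history is the applanation curve: the signal peaks at
the two instants the central cornea is flat.

Diffuse reflection, tear-film effects and corneal refraction are ignored.
Rays are laid out on a deterministic sunflower pattern over the beam disc
so results are reproducible without Monte-Carlo noise, and each 2D profile
is revolved into a 3D surface because the oblique beam breaks the optical
axisymmetry even though the surface itself is axisymmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .units import mm_to_m

__all__ = [
    "OpticalConfig",
    "ApplanationCurve",
    "ProfileSurface",
    "RayTraceResult",
    "surface_normal",
    "trace_rays",
    "applanation_curve",
    "sunflower_disc",
]

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


def _lerp_uniform(x, table, x_max, out=None):
    """Linear interpolation on a uniform [0, x_max] grid (x pre-clipped)."""
    n = table.shape[0]
    pos = x * ((n - 1) / x_max)
    i0 = np.minimum(pos.astype(np.intp), n - 2)
    frac = pos - i0
    lo = table[i0]
    return lo + (table[i0 + 1] - lo) * frac


@dataclass(frozen=True)
class OpticalConfig:
    """Transmitter/receiver geometry and ray-sampling parameters."""

    plane_distance_cm: float = 11.0
    incidence_angle_deg: float = 45.0
    beam_diameter_mm: float = 3.0
    receiver_diameter_mm: float = 3.0
    n_rays: int = 3000
    n_levels: int = 64          # coarse bracketing levels along each ray
    bisect_iters: int = 42
    smoothing_lam: float | None = 0.0  # spline penalty; None = GCV choice

    def __post_init__(self):
        if min(self.plane_distance_cm, self.beam_diameter_mm,
               self.receiver_diameter_mm) <= 0:
            raise ValueError("optical dimensions must be positive")
        if not 0 < self.incidence_angle_deg < 90:
            raise ValueError("incidence angle must lie in (0, 90) deg")
        if self.n_rays < 100:
            raise ValueError("need at least 100 rays")


@dataclass
class ApplanationCurve:
    """Normalized light intensity versus time."""

    times_s: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.times_s.shape != self.intensity.shape:
            raise ValueError("times and intensity must have equal length")

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.times_s, self.intensity]),
                   delimiter=",", header="time_s,intensity", comments="")

    @classmethod
    def from_csv(cls, path) -> "ApplanationCurve":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(times_s=arr[:, 0], intensity=arr[:, 1])


def sunflower_disc(n: int, radius: float) -> np.ndarray:
    """Deterministic quasi-uniform covering of a disc (Vogel spiral)."""
    k = np.arange(n, dtype=float)
    r = radius * np.sqrt((k + 0.5) / n)
    th = k * _GOLDEN_ANGLE
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


class ProfileSurface:
    """Smooth surface of revolution built from a 2D anterior profile.

    The profile (x >= 0, in mm) is mirrored about the axis and fitted with a
    cubic smoothing spline, which enforces a symmetric, differentiable crest
    at x = 0.  Heights and slopes are evaluated in metres; extrapolation
    beyond the profile support is forbidden.
    """

    def __init__(self, profile_mm: np.ndarray, lam: float | None = 0.0):
        prof = np.asarray(profile_mm, dtype=float)
        if prof.ndim != 2 or prof.shape[1] != 2 or prof.shape[0] < 4:
            raise ValueError("profile must be an (n>=4, 2) array of (x, y) mm")
        order = np.argsort(prof[:, 0])
        x = mm_to_m(prof[order, 0])
        y = mm_to_m(prof[order, 1])
        if x[0] < 0:
            raise ValueError("profile x-coordinates must be nonnegative")
        xs = np.concatenate([-x[:0:-1], x]) if x[0] == 0.0 else np.concatenate([-x[::-1], x])
        ys = np.concatenate([y[:0:-1], y]) if x[0] == 0.0 else np.concatenate([y[::-1], y])
        self._spl = make_smoothing_spline(xs, ys, lam=lam)
        self._dspl = self._spl.derivative()
        self.rho_max_m = float(x[-1])
        self.y_min_m = float(y.min())
        self.y_max_m = float(y.max())

    def height(self, rho_m):
        rho = np.asarray(rho_m, dtype=float)
        if np.any(rho > self.rho_max_m * (1 + 1e-12)) or np.any(rho < 0):
            raise ValueError("rho outside the profile support")
        return self._spl(rho)

    def slope(self, rho_m):
        rho = np.asarray(rho_m, dtype=float)
        if np.any(rho > self.rho_max_m * (1 + 1e-12)) or np.any(rho < 0):
            raise ValueError("rho outside the profile support")
        return self._dspl(rho)


def surface_normal(profile_mm: np.ndarray, x_mm, lam: float | None = 0.0):
    """Outward (upward) unit normal of the profile at radial position x (mm).

    ``x`` may be negative; the revolved surface is even in x, so the normal's
    radial component flips sign under mirroring.
    """
    surf = ProfileSurface(profile_mm, lam=lam)
    x = np.asarray(x_mm, dtype=float)
    sl = np.sign(x) * np.asarray(surf.slope(np.abs(mm_to_m(x))))
    norm = np.hypot(sl, 1.0)
    n = np.stack([-sl / norm, np.ones_like(sl) / norm], axis=-1)
    return n[()] if np.isscalar(x_mm) else n


@dataclass
class RayTraceResult:
    """Per-ray diagnostics of one trace (all 3D vectors in metres)."""

    intensity: float
    n_received: int
    n_missed_surface: int
    n_off_receiver: int
    origins: np.ndarray | None = None
    directions: np.ndarray | None = None
    hit_points: np.ndarray | None = None
    normals: np.ndarray | None = None
    reflected: np.ndarray | None = None
    received: np.ndarray | None = None
    hit_mask: np.ndarray | None = None


def _device_frame(config: OpticalConfig, anchor_y_m: float):
    """Transmitter/receiver placement anchored at the (initial) apex."""
    th = math.radians(config.incidence_angle_deg)
    d = np.array([math.sin(th), -math.cos(th), 0.0])
    r0 = np.array([math.sin(th), math.cos(th), 0.0])  # chief reflected ray
    L = config.plane_distance_cm * 1e-2 / math.cos(th)
    apex = np.array([0.0, anchor_y_m, 0.0])
    src = apex - L * d
    rcv = apex + L * r0
    e1 = np.array([-math.cos(th), -math.sin(th), 0.0])  # in-plane, ⟂ d
    e2 = np.array([0.0, 0.0, 1.0])
    return d, r0, src, rcv, e1, e2


def trace_rays(
    profile_mm: np.ndarray,
    config: OpticalConfig,
    anchor_y_mm: float | None = None,
    return_rays: bool = False,
):
    """Received fraction of the beam reflected off one surface profile.

    ``anchor_y_mm`` fixes the device relative to a reference apex height
    (the undeformed apex when tracing a deformation history); by default
    the device is anchored at the profile's own apex.  Rays that miss the
    surface are counted, not raised.
    """
    surf = ProfileSurface(profile_mm, lam=config.smoothing_lam)
    anchor = surf.height(0.0) if anchor_y_mm is None else mm_to_m(anchor_y_mm)
    d, r0, src, rcv_c, e1, e2 = _device_frame(config, float(anchor))
    n = config.n_rays
    offs = sunflower_disc(n, mm_to_m(config.beam_diameter_mm) / 2.0)
    origins = src[None, :] + offs[:, 0:1] * e1[None, :] + offs[:, 1:2] * e2[None, :]

    cth = -d[1]  # cos(incidence angle); d_y = -cos(theta)
    pad = 1e-4   # 0.1 mm margin above/below the surface band

    # dense height table for cheap, accurate intersection bracketing; the
    # exact spline is still used for the normals at the hit points
    rho_grid = np.linspace(0.0, surf.rho_max_m, 4096)
    y_tab = surf._spl(rho_grid)

    y_levels = np.linspace(surf.y_max_m + pad, surf.y_min_m - pad,
                           config.n_levels)
    # distance along each ray to reach a given height
    t_lev = (origins[:, 1:2] - y_levels[None, :]) / cth      # (n, L)
    px = origins[:, 0:1] + t_lev * d[0]
    pz = origins[:, 2:3] + t_lev * d[2]
    rho = np.hypot(px, pz)
    valid = rho <= surf.rho_max_m
    phi = np.where(valid,
                   y_levels[None, :]
                   - _lerp_uniform(np.minimum(rho, surf.rho_max_m), y_tab,
                                   surf.rho_max_m),
                   np.nan)
    crossing = (phi[:, :-1] > 0) & (phi[:, 1:] <= 0) & valid[:, :-1] & valid[:, 1:]
    has_hit = crossing.any(axis=1)
    first = np.argmax(crossing, axis=1)

    t_lo = np.take_along_axis(t_lev, first[:, None], axis=1)[:, 0]
    t_hi = np.take_along_axis(t_lev, first[:, None] + 1, axis=1)[:, 0]
    for _ in range(config.bisect_iters):
        tm = 0.5 * (t_lo + t_hi)
        pmx = origins[:, 0] + tm * d[0]
        pmz = origins[:, 2] + tm * d[2]
        rm = np.minimum(np.hypot(pmx, pmz), surf.rho_max_m)
        fm = origins[:, 1] - tm * cth - _lerp_uniform(rm, y_tab, surf.rho_max_m)
        above = fm > 0
        t_lo = np.where(above, tm, t_lo)
        t_hi = np.where(above, t_hi, tm)
    t_hit = 0.5 * (t_lo + t_hi)
    P = origins + t_hit[:, None] * d[None, :]
    rho_hit = np.clip(np.hypot(P[:, 0], P[:, 2]), 0.0, surf.rho_max_m)
    sl = surf._dspl(rho_hit)
    safe_rho = np.where(rho_hit > 1e-12, rho_hit, 1.0)
    nx = np.where(rho_hit > 1e-12, -sl * P[:, 0] / safe_rho, 0.0)
    nz = np.where(rho_hit > 1e-12, -sl * P[:, 2] / safe_rho, 0.0)
    ny = np.ones_like(nx)
    nn = np.sqrt(nx * nx + ny * ny + nz * nz)
    N = np.column_stack([nx / nn, ny / nn, nz / nn])
    dn = N @ d
    refl = d[None, :] - 2.0 * dn[:, None] * N

    m = r0
    denom = refl @ m
    tr = ((rcv_c[None, :] - P) @ m) / np.where(np.abs(denom) > 1e-14, denom, np.nan)
    hit_plane = np.isfinite(tr) & (tr > 0)
    Q = P + tr[:, None] * refl
    dist = np.linalg.norm(Q - rcv_c[None, :], axis=1)
    received = has_hit & hit_plane & (dist <= mm_to_m(config.receiver_diameter_mm) / 2.0)

    n_recv = int(received.sum())
    n_miss = int((~has_hit).sum())
    n_off = n - n_recv - n_miss
    res = RayTraceResult(intensity=n_recv / n, n_received=n_recv,
                         n_missed_surface=n_miss, n_off_receiver=n_off)
    if return_rays:
        res.origins = origins
        res.directions = np.broadcast_to(d, origins.shape).copy()
        res.hit_points = P
        res.normals = N
        res.reflected = refl
        res.received = received
        res.hit_mask = has_hit
        return res
    return res.intensity


def applanation_curve(history, config: OpticalConfig) -> ApplanationCurve:
    """Normalized applanation curve of a deformation history.

    The optical bench is anchored at the frame-0 (undeformed) apex and does
    not track the moving cornea.
    """
    if history.n_frames == 0:
        raise ValueError("empty deformation history")
    anchor = float(history.anterior_profiles_mm[0, 0, 1])
    vals = np.empty(history.n_frames)
    for f in range(history.n_frames):
        vals[f] = trace_rays(history.anterior_profiles_mm[f], config,
                             anchor_y_mm=anchor)
    return ApplanationCurve(times_s=history.times_s.copy(), intensity=vals)
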