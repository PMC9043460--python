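"""Synthetic fixtures: two-peak curves and closed-form reference reflectors.

Everything here is generated programmatically — the package ships no data
files.  The synthetic applanation curve emulates the two-peak shape of a
real measurement with known Gaussian peaks, so feature extraction can be
checked against closed forms; the reference reflectors (plane, spheres,
paraboloid) have analytic normals for validating the ray tracer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .optics import ApplanationCurve

__all__ = ["make_synthetic_curve", "make_reference_reflectors", "ReferenceReflector"]


def make_synthetic_curve(
    peak_times_s: tuple[float, float] = (0.008, 0.017),
    peak_sigmas_ms: tuple[float, float] = (1.0, 1.0),
    heights: tuple[float, float] = (0.9, 0.6),
    frame_spacing_ms: float = 25.0 / 400.0,
    duration_s: float = 0.025,
) -> ApplanationCurve:
    """Sum of two Gaussian peaks sampled on a uniform frame grid.

    The 50%-height width of an isolated Gaussian peak with scale sigma is
    ``2 sigma sqrt(ln 2)``.  Heavily overlapping peaks trigger a warning
    because the closed forms then stop being exact.
    """
    t1, t2 = peak_times_s
    if not 0.0 < t1 < t2 < duration_s:
        raise ValueError("peak times must satisfy 0 < t1 < t2 < duration")
    s1, s2 = (s * 1e-3 for s in peak_sigmas_ms)
    if min(s1, s2) <= 0:
        raise ValueError("peak sigmas must be positive")
    if (t2 - t1) < 3.0 * max(s1, s2):
        warnings.warn("applanation peaks overlap (|t2 - t1| < 3 max sigma); "
                      "widths will deviate from the isolated-peak closed form")
    n = int(round(duration_s / (frame_spacing_ms * 1e-3))) + 1
    t = np.linspace(0.0, duration_s, n)
    y = (heights[0] * np.exp(-(((t - t1) / s1) ** 2))
         + heights[1] * np.exp(-(((t - t2) / s2) ** 2)))
    return ApplanationCurve(times_s=t, intensity=np.clip(y, 0.0, 1.0))


@dataclass(frozen=True)
class ReferenceReflector:
    """A surface profile with closed-form normals for oracle comparisons."""

    name: str
    profile_mm: np.ndarray                      # (n, 2), x >= 0
    normal: Callable[[float], tuple[float, float]]  # outward unit normal at x (mm)
    description: str


def _sphere_profile(R_mm: float, x_max_mm: float, n: int) -> np.ndarray:
    x = np.linspace(0.0, x_max_mm, n)
    return np.column_stack([x, np.sqrt(R_mm ** 2 - x ** 2)])


def make_reference_reflectors(n_points: int = 121) -> dict[str, ReferenceReflector]:
    """Flat plane, spheres (R = 6, 7, 8 mm) and an apex-matched paraboloid."""
    out: dict[str, ReferenceReflector] = {}
    x_flat = np.linspace(0.0, 6.0, n_points)
    out["flat"] = ReferenceReflector(
        name="flat",
        profile_mm=np.column_stack([x_flat, np.zeros_like(x_flat)]),
        normal=lambda x: (0.0, 1.0),
        description="plane mirror at the apex plane; received fraction is 1",
    )
    for R in (6.0, 7.0, 8.0):
        def nrm(x, R=R):
            y = np.sqrt(R ** 2 - x ** 2)
            return (x / R, y / R)
        out[f"sphere_{R:g}"] = ReferenceReflector(
            name=f"sphere_{R:g}",
            profile_mm=_sphere_profile(R, 0.75 * R, n_points),
            normal=nrm,
            description=f"sphere of radius {R:g} mm centred on the axis",
        )
    R = 7.0
    x_par = np.linspace(0.0, 0.75 * R, n_points)
    def par_nrm(x, R=R):
        sl = -x / R
        nl = float(np.hypot(sl, 1.0))
        return (-sl / nl, 1.0 / nl)
    out["paraboloid_7"] = ReferenceReflector(
        name="paraboloid_7",
        profile_mm=np.column_stack([x_par, R - x_par ** 2 / (2.0 * R)]),
        normal=par_nrm,
        description="paraboloid osculating the 7 mm sphere at the apex",
    )
    return out
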