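"""Extraction of ORA output parameters from a normalized applanation curve.

The applanation curve has one intensity peak while the cornea flattens
inward (time ``t1``) and one while it recovers (``t2``).  The device-style
outputs are the two applanation times, the widths of the two peaks at 50%
of their height (``w1``, ``w2``) and the puff pressures at the applanation
instants (``p1``, ``p2``), read off the temporal load profile.  Peak
partitioning uses the mechanics-side time of maximum apex indentation,
which is robust when the concave phase produces spurious micro-peaks in
the optical signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ApplanationError
from .mechanics import AirPuff, airpuff_temporal
from .optics import ApplanationCurve

__all__ = [
    "OraFeatures",
    "find_applanation_peaks",
    "peak_width_50",
    "applanation_pressures",
    "extract_features",
]

#: default conversion from milliseconds to ORA's unitless width scale:
#: one unit per 25/400 ms sample of the device waveform.
DEFAULT_WIDTH_SCALE_PER_MS = 400.0 / 25.0


@dataclass(frozen=True)
class OraFeatures:
    """ORA output parameters of one simulated (or synthetic) measurement."""

    t1_s: float
    t2_s: float
    w1_ms: float
    w2_ms: float
    w1: float          # widths on the ORA unitless scale
    w2: float
    p1_mmHg: float
    p2_mmHg: float

    def __post_init__(self):
        if not self.t1_s < self.t2_s:
            raise ValueError("first applanation must precede the second")
        if min(self.w1_ms, self.w2_ms) <= 0:
            raise ValueError("peak widths must be positive")


def _refine_peak(t: np.ndarray, y: np.ndarray, k: int) -> tuple[float, float]:
    """Sub-frame peak location/height by a 3-point parabola around index k."""
    y0, y1, y2 = y[k - 1], y[k], y[k + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:
        return float(t[k]), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    h = t[k + 1] - t[k] if delta >= 0 else t[k] - t[k - 1]
    t_pk = float(t[k] + delta * abs(h))
    y_pk = float(y1 - 0.25 * (y0 - y2) * delta)
    return t_pk, y_pk


def _side_peak(t: np.ndarray, y: np.ndarray, lo: int, hi: int) -> int:
    """Index of the maximum in [lo, hi) that is a strict local maximum."""
    if hi - lo < 1:
        raise ApplanationError("no applanation detected: empty window")
    k = lo + int(np.argmax(y[lo:hi]))
    if k == 0 or k == y.size - 1 or not (y[k] > y[k - 1] and y[k] >= y[k + 1]):
        raise ApplanationError("no applanation detected: no interior local maximum")
    return k


def find_applanation_peaks(curve: ApplanationCurve, split_time_s: float):
    """Applanation times ``(t1, t2)`` and peak heights from the curve.

    ``split_time_s`` partitions the curve at the instant of maximum apex
    indentation; the loading peak is searched before it, the unloading peak
    after.  Peak times are refined to sub-frame accuracy with a 3-point
    parabola.  Raises :class:`ApplanationError` when either side has no
    interior local maximum (e.g. a monotone curve).
    """
    t, y = curve.times_s, curve.intensity
    if t.size < 10:
        raise ValueError("curve too short for peak detection")
    n_left = int(np.searchsorted(t, split_time_s, side="right"))
    k1 = _side_peak(t, y, 0, max(n_left, 1))
    k2 = _side_peak(t, y, min(n_left, t.size - 1), t.size)
    t1, h1 = _refine_peak(t, y, k1)
    t2, h2 = _refine_peak(t, y, k2)
    if not t1 < t2:
        raise ApplanationError("applanation peaks are not ordered")
    return t1, t2, (h1, h2)


def peak_width_50(curve: ApplanationCurve, t_peak_s: float) -> float:
    """Width (ms) of the peak at ``t_peak_s`` at 50% of its height.

    The two crossings of half the (parabola-refined) peak height that
    bracket the peak are located by linear interpolation between frames.
    Raises :class:`ApplanationError` when a crossing is not bracketed
    inside the curve support.
    """
    t, y = curve.times_s, curve.intensity
    k = int(np.argmin(np.abs(t - t_peak_s)))
    k = max(1, min(k, t.size - 2))
    _, height = _refine_peak(t, y, k)
    half = 0.5 * height

    i = k
    while i > 0 and y[i] >= half:
        i -= 1
    if y[i] >= half:
        raise ApplanationError("left half-height crossing not bracketed")
    tl = t[i] + (t[i + 1] - t[i]) * (half - y[i]) / (y[i + 1] - y[i])

    j = k
    while j < t.size - 1 and y[j] >= half:
        j += 1
    if y[j] >= half:
        raise ApplanationError("right half-height crossing not bracketed")
    tr = t[j - 1] + (t[j] - t[j - 1]) * (half - y[j - 1]) / (y[j] - y[j - 1])
    return float((tr - tl) * 1.0e3)


def applanation_pressures(puff: AirPuff, t1_s: float, t2_s: float):
    """Puff pressures (mmHg) at the two applanation times."""
    if not 0.0 <= t1_s < t2_s <= puff.duration_s:
        raise ValueError("applanation times must satisfy 0 <= t1 < t2 <= duration")
    p1 = puff.P_max_mmHg * airpuff_temporal(puff, t1_s)
    p2 = puff.P_max_mmHg * airpuff_temporal(puff, t2_s)
    return float(p1), float(p2)


def extract_features(
    curve: ApplanationCurve,
    history=None,
    puff: AirPuff | None = None,
    split_time_s: float | None = None,
    width_scale_per_ms: float = DEFAULT_WIDTH_SCALE_PER_MS,
) -> OraFeatures:
    """All six ORA output parameters from one applanation curve.

    The peak split point comes from ``history`` (time of maximum apex
    indentation) or an explicit ``split_time_s`` for synthetic curves.
    Widths are reported both in ms and on the ORA unitless scale via the
    configurable proportionality constant.
    """
    if puff is None:
        puff = AirPuff()
    if split_time_s is None:
        if history is None:
            raise ValueError("need either a deformation history or a split time")
        split_time_s = history.max_indentation_time_s
    t1, t2, _ = find_applanation_peaks(curve, split_time_s)
    w1_ms = peak_width_50(curve, t1)
    w2_ms = peak_width_50(curve, t2)
    p1, p2 = applanation_pressures(puff, t1, t2)
    return OraFeatures(
        t1_s=t1, t2_s=t2,
        w1_ms=w1_ms, w2_ms=w2_ms,
        w1=w1_ms * width_scale_per_ms, w2=w2_ms * width_scale_per_ms,
        p1_mmHg=p1, p2_mmHg=p2,
    )
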