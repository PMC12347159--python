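"""Rugosity: deviation of the density map from rotational symmetry.

Circular density profiles around the CDC are smoothed, their peaks and
troughs located, and each extremum assigned an angular width spanning the
half-height crossings on its two flanks (half-height = midpoint between
the neighbouring peak and trough values).  Peak and trough widths tile
the circle; rugosity is the combined trough/peak width ratio, with values
above one indicating a horizontal ridge of elevated density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .profiles import CircularProfile

__all__ = [
    "RugosityResult",
    "smooth_circular",
    "detect_peaks_troughs",
    "half_height_widths",
    "rugosity",
    "analyze_circular_profile",
    "DEFAULT_RUGOSITY_ECCENTRICITIES",
]

#: Default analysis eccentricities (µm) for circular profiles.
DEFAULT_RUGOSITY_ECCENTRICITIES = (15, 40, 65, 90, 115, 140, 165, 190, 215, 240)


@dataclass
class RugosityResult:
    """Peak/trough decomposition of one circular profile.

    ``flat`` marks profiles with < 1% angular variation, for which no
    extrema (and no rugosity) are defined.
    """

    eccentricity: float
    peak_positions: np.ndarray
    trough_positions: np.ndarray
    peak_widths: np.ndarray
    trough_widths: np.ndarray
    rugosity: Optional[float]
    flat: bool = False

    def as_dict(self) -> dict:
        return {
            "eccentricity_um": self.eccentricity,
            "peak_positions_deg": list(map(float, self.peak_positions)),
            "trough_positions_deg": list(map(float, self.trough_positions)),
            "peak_widths_deg": list(map(float, self.peak_widths)),
            "trough_widths_deg": list(map(float, self.trough_widths)),
            "rugosity": self.rugosity,
            "flat": self.flat,
        }


def smooth_circular(values: np.ndarray, window_samples: int) -> np.ndarray:
    """Circular (wrap-around) moving mean with an odd window length."""
    window_samples = max(1, int(window_samples) | 1)
    kernel = np.ones(window_samples) / window_samples
    padded = np.concatenate([values[-(window_samples // 2):], values,
                             values[: window_samples // 2]])
    return np.convolve(padded, kernel, mode="valid")


def _circular_extrema(values: np.ndarray):
    """Indices of strict local maxima/minima on a periodic series."""
    prev = np.roll(values, 1)
    nxt = np.roll(values, -1)
    peaks = np.nonzero((values > prev) & (values >= nxt))[0]
    troughs = np.nonzero((values < prev) & (values <= nxt))[0]
    return peaks, troughs


def _enforce_alternation(theta, values, peaks, troughs):
    """Drop the lesser of adjacent same-type extrema until they alternate."""
    marks = [(int(i), +1) for i in peaks] + [(int(i), -1) for i in troughs]
    marks.sort()
    changed = True
    while changed and len(marks) > 1:
        changed = False
        out = []
        k = 0
        while k < len(marks):
            i, kind = marks[k]
            run = [marks[k]]
            while k + 1 < len(marks) and marks[k + 1][1] == kind:
                run.append(marks[k + 1])
                k += 1
            # wrap-around: same-type run may continue at the list head
            if k == len(marks) - 1 and out and out[0][1] == kind:
                run.extend(o for o in out if o[1] == kind)
                out = [o for o in out if o[1] != kind]
                changed = True
            if len(run) > 1:
                best = max(run, key=lambda m: kind * values[m[0]])
                out.append(best)
                changed = True
            else:
                out.append(run[0])
            k += 1
        marks = sorted(out)
    peaks = np.array([i for i, kind in marks if kind == +1], dtype=int)
    troughs = np.array([i for i, kind in marks if kind == -1], dtype=int)
    return peaks, troughs


def detect_peaks_troughs(
    profile: CircularProfile,
    smooth_window_deg: float = 11.0,
    flat_cv: float = 0.01,
):
    """Peak and trough positions (retinal degrees) of a circular profile.

    The profile is smoothed by a circular moving mean (11° default)
    before extrema detection; adjacent same-type extrema are reduced to
    the strongest so peaks and troughs alternate.  Profiles with angular
    CV below 1% are declared flat (returns ``(None, None)``).
    """
    theta = profile.theta
    step = np.median(np.diff(theta))
    smoothed = smooth_circular(profile.density, int(round(smooth_window_deg / step)))
    cv = smoothed.std() / smoothed.mean()
    if cv < flat_cv:
        return None, None
    peaks, troughs = _circular_extrema(smoothed)
    if peaks.size == 0 or troughs.size == 0:
        return None, None
    peaks, troughs = _enforce_alternation(theta, smoothed, peaks, troughs)
    return theta[peaks], theta[troughs]


def _crossing(theta, values, i_from: int, i_to: int, level: float, direction: int):
    """Half-height crossing angle walking from index i_from toward i_to."""
    n = values.size
    i = i_from
    while i != i_to:
        j = (i + direction) % n
        v0, v1 = values[i], values[j]
        if (v0 - level) * (v1 - level) <= 0 and v0 != v1:
            t0 = theta[i]
            t1 = theta[j]
            if direction > 0 and t1 < t0:
                t1 += 360.0
            if direction < 0 and t1 > t0:
                t1 -= 360.0
            frac = (level - v0) / (v1 - v0)
            return (t0 + frac * (t1 - t0)) % 360.0
        i = j
    return theta[i_to] % 360.0


def half_height_widths(
    profile: CircularProfile,
    peak_positions: Sequence[float],
    trough_positions: Sequence[float],
    smooth_window_deg: float = 11.0,
):
    """Angular widths of peaks and troughs from half-height crossings.

    For each flank between a peak and its adjacent trough, the crossing
    is where the (smoothed) profile passes the mean of the two extremum
    values; an extremum's width spans its two flank crossings.  Peak and
    trough widths tile the full circle.
    """
    theta = profile.theta
    step = np.median(np.diff(theta))
    values = smooth_circular(profile.density, int(round(smooth_window_deg / step)))

    marks = [(float(p), +1) for p in peak_positions] + [
        (float(t), -1) for t in trough_positions
    ]
    marks.sort()
    kinds = [kind for _, kind in marks]
    if any(kinds[i] == kinds[(i + 1) % len(kinds)] for i in range(len(kinds))):
        raise ValueError("peaks and troughs must alternate around the circle")

    idx = [int(np.argmin(np.abs((theta - pos + 180) % 360 - 180))) for pos, _ in marks]
    m = len(marks)
    crossings = np.empty(m)  # crossing on the flank from marks[k] to marks[k+1]
    for k in range(m):
        k2 = (k + 1) % m
        level = (values[idx[k]] + values[idx[k2]]) / 2.0
        crossings[k] = _crossing(theta, values, idx[k], idx[k2], level, +1)

    widths = np.empty(m)
    for k in range(m):
        left = crossings[(k - 1) % m]
        right = crossings[k]
        widths[k] = (right - left) % 360.0
    peak_w = np.array([w for w, (_, kind) in zip(widths, marks) if kind == +1])
    trough_w = np.array([w for w, (_, kind) in zip(widths, marks) if kind == -1])
    return peak_w, trough_w


def rugosity(peak_widths: Sequence[float], trough_widths: Sequence[float]) -> float:
    """Combined trough/peak width ratio, Σ(trough widths) / Σ(peak widths)."""
    peak_widths = np.asarray(peak_widths, dtype=float)
    trough_widths = np.asarray(trough_widths, dtype=float)
    if peak_widths.size == 0 or trough_widths.size == 0:
        raise ValueError("need at least one peak and one trough")
    return float(trough_widths.sum() / peak_widths.sum())


def analyze_circular_profile(
    profile: CircularProfile, smooth_window_deg: float = 11.0
) -> RugosityResult:
    """Full rugosity decomposition of one circular profile."""
    peaks, troughs = detect_peaks_troughs(profile, smooth_window_deg)
    if peaks is None:
        return RugosityResult(
            eccentricity=profile.eccentricity,
            peak_positions=np.array([]), trough_positions=np.array([]),
            peak_widths=np.array([]), trough_widths=np.array([]),
            rugosity=None, flat=True,
        )
    peak_w, trough_w = half_height_widths(profile, peaks, troughs, smooth_window_deg)
    return RugosityResult(
        eccentricity=profile.eccentricity,
        peak_positions=np.sort(np.asarray(peaks, float) % 360.0),
        trough_positions=np.sort(np.asarray(troughs, float) % 360.0),
        peak_widths=peak_w,
        trough_widths=trough_w,
        rugosity=rugosity(peak_w, trough_w),
    )
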