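"""Per-pixel fiber orientation by weighted vector summation.

For each pixel, vectors are drawn from the centre of an odd window (default
7×7, giving 48 vectors) to every other pixel in the window.  Each vector v
gets two weights: F1 = 1/|v| (short vectors count more) and

    F2 = √(1/3) − √((1/2)·Σ_{i=1..3}(I_i − Ī)²),

where I_1..I_3 are three intensities sampled along the vector (at its start,
midpoint and end, bilinearly) on the [0, 1]-normalised image — F2 is maximal
(√(1/3) ≈ 0.577) when intensity is uniform along the vector, i.e. the vector
runs along a fiber.  The weighted vectors are summed in doubled-angle space
(orientation is axial: θ and θ+180° are the same fiber), and the half-angle
of the resultant gives θ ∈ [0°, 180°).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

__all__ = [
    "OrientationField",
    "orientation_field",
    "orientation_histogram",
    "peak_spacing_deg",
    "track_theta",
]

F2_MAX = np.sqrt(1.0 / 3.0)


@dataclass
class OrientationField:
    """Per-pixel orientation θ in degrees [0, 180), with confidence weights."""

    theta_deg: np.ndarray
    weight: np.ndarray
    valid: np.ndarray
    window_px: int


def _window_offsets(window_px: int) -> np.ndarray:
    """All (dy, dx) offsets from the window centre, excluding (0, 0)."""
    h = window_px // 2
    offs = [
        (dy, dx)
        for dy in range(-h, h + 1)
        for dx in range(-h, h + 1)
        if not (dy == 0 and dx == 0)
    ]
    return np.asarray(offs, dtype=float)


def orientation_field(
    image: np.ndarray,
    window_px: int = 7,
    intensity_threshold: float = 0.1,
    combine: str = "sum",
) -> OrientationField:
    """Estimate the per-pixel orientation of fibrous structures.

    ``intensity_threshold`` (on the internally [0, 1]-normalised image)
    marks pixels too dim to carry an orientation as invalid.  ``combine``
    selects how the two weight factors merge: ``sum`` (F1 + F2, clipped at
    zero) or ``product`` (F1·max(F2, 0)) for sensitivity analysis.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("orientation_field expects a 2-D image")
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError(f"window_px must be odd and >= 3; got {window_px}")
    if combine not in ("sum", "product"):
        raise ValueError("combine must be 'sum' or 'product'")
    peak = image.max()
    norm = image / peak if peak > 0 else image
    ny, nx = norm.shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)

    offsets = _window_offsets(window_px)
    sum_cos = np.zeros((ny, nx))
    sum_sin = np.zeros((ny, nx))
    for dy, dx in offsets:
        length = np.hypot(dy, dx)
        f1 = 1.0 / length
        # three samples along the vector at fractional positions 0, 1/2, 1
        samples = [norm]
        for t in (0.5, 1.0):
            samples.append(
                ndimage.map_coordinates(
                    norm, [yy + t * dy, xx + t * dx], order=1, mode="nearest"
                )
            )
        s = np.stack(samples)
        var_term = 0.5 * ((s - s.mean(axis=0)) ** 2).sum(axis=0)
        f2 = F2_MAX - np.sqrt(var_term)
        if combine == "sum":
            w = np.clip(f1 + f2, 0.0, None)
        else:
            w = f1 * np.clip(f2, 0.0, None)
        alpha = np.arctan2(dy, dx)
        sum_cos += w * np.cos(2.0 * alpha)
        sum_sin += w * np.sin(2.0 * alpha)

    theta = np.mod(0.5 * np.degrees(np.arctan2(sum_sin, sum_cos)), 180.0)
    weight = np.hypot(sum_cos, sum_sin)
    valid = norm >= intensity_threshold
    return OrientationField(theta, weight, valid, window_px)


def orientation_histogram(
    field: OrientationField,
    bins: int = 180,
    prominence_frac: float = 0.2,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Weight-weighted histogram of θ over [0°, 180°).

    Returns ``(bin_centers_deg, frequency, peaks_deg)`` with frequencies
    summing to 1 and peaks (circular local maxima whose prominence exceeds
    ``prominence_frac`` × the tallest bin) sorted by decreasing height.
    Raises ``ValueError`` when the field has no valid pixels.
    """
    sel = field.valid
    if not np.any(sel):
        raise ValueError("orientation field has no valid pixels")
    theta = field.theta_deg[sel]
    w = field.weight[sel]
    freq, edges = np.histogram(theta, bins=bins, range=(0.0, 180.0), weights=w)
    total = freq.sum()
    if total > 0:
        freq = freq / total
    centers = 0.5 * (edges[:-1] + edges[1:])

    # circular peak finding: tile the histogram to avoid seam artefacts
    tiled = np.concatenate([freq, freq, freq])
    pk, props = find_peaks(tiled, prominence=prominence_frac * freq.max())
    pk = pk[(pk >= bins) & (pk < 2 * bins)] - bins
    order = np.argsort(freq[pk])[::-1]
    peaks = [float(centers[i]) for i in pk[order]]
    return centers, freq, peaks


def peak_spacing_deg(peaks: list[float]) -> float:
    """Axial angular spacing between the two dominant peaks, folded to [0°, 90°]."""
    if len(peaks) < 2:
        raise ValueError("need at least two peaks")
    d = abs(peaks[0] - peaks[1]) % 180.0
    return min(d, 180.0 - d)


def track_theta(
    fields: list[OrientationField],
    region: np.ndarray,
    bins: int = 180,
) -> np.ndarray:
    """Dominant θ of a region through time, unwrapped across the 0/180 seam.

    Returns an array of shape (n_frames,): per frame, the tallest histogram
    peak of the region's valid pixels, then shifted by multiples of 180° so
    consecutive values stay within ±90° of each other.
    """
    region = np.asarray(region, dtype=bool)
    if not np.any(region):
        raise ValueError("empty region")
    series = []
    for f in fields:
        sel = region & f.valid
        if not np.any(sel):
            raise ValueError("region has no valid pixels in one frame")
        freq, edges = np.histogram(
            f.theta_deg[sel], bins=bins, range=(0.0, 180.0), weights=f.weight[sel]
        )
        centers = 0.5 * (edges[:-1] + edges[1:])
        series.append(float(centers[int(np.argmax(freq))]))
    out = [series[0]]
    for theta in series[1:]:
        prev = out[-1]
        # representative of {theta + 180k} within ±90° of the previous value
        out.append(prev + ((theta - prev + 90.0) % 180.0) - 90.0)
    return np.asarray(out)
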