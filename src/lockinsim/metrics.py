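"""Quantitative image-quality metrics.

Signal-to-background ratio (SBR) in dB,

    SBR = 10·log10((max(signal) − mean(background)) / sd(background)),

where background is every pixel without structural signal; plus sliding-
window local SBR maps, FWHM-based resolution measurement on point-like
objects, azimuthally averaged log-amplitude spectra with a noise-floor
cutoff estimate, and bilinear line profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "SBRReport",
    "sbr",
    "local_sbr",
    "fwhm",
    "radial_spectrum",
    "RadialSpectrum",
    "intensity_profile",
]


@dataclass
class SBRReport:
    """SBR in dB plus the ingredients needed to recompute it."""

    sbr_db: float
    signal_max: float
    background_mean: float
    background_sd: float
    mask_mode: str
    n_background_px: int
    degenerate: bool = False  # numerator <= 0 → sbr_db is -inf, flagged here


def _auto_mask(image: np.ndarray, smooth_sigma: float = 1.0) -> np.ndarray:
    """Otsu threshold on a lightly smoothed copy; True = structural signal."""
    sm = ndimage.gaussian_filter(image, smooth_sigma)
    if np.ptp(sm) == 0:
        return np.zeros(image.shape, dtype=bool)
    return sm > threshold_otsu(sm)


def sbr(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    mask_mode: str = "auto_otsu",
    percentile: float = 99.0,
    robust_max: bool = False,
) -> SBRReport:
    """Signal-to-background ratio of an image in dB.

    ``mask`` (True = signal) overrides automatic segmentation; otherwise
    ``mask_mode`` is ``auto_otsu`` (Otsu on a σ=1 px smoothed copy) or
    ``percentile`` (top ``percentile`` of intensities).  ``robust_max``
    replaces the literal signal maximum with the 99.9th percentile.

    Raises ``ValueError`` when fewer than 100 background pixels remain or
    the background is degenerate (zero spread); a non-positive numerator is
    reported as −inf with ``degenerate=True`` rather than raised.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        mode = "user"
    elif mask_mode == "auto_otsu":
        mask = _auto_mask(image)
        mode = "auto_otsu"
    elif mask_mode == "percentile":
        mask = image > np.percentile(image, percentile)
        mode = "percentile"
    else:
        raise ValueError("mask_mode must be 'auto_otsu' or 'percentile'")
    background = image[~mask]
    if background.size < 100:
        raise ValueError(f"only {background.size} background pixels (< 100)")
    signal = image[mask]
    if signal.size == 0:
        raise ValueError("mask selects no signal pixels")
    sig_max = float(np.percentile(signal, 99.9)) if robust_max else float(signal.max())
    bg_mean = float(background.mean())
    bg_sd = float(background.std())
    if bg_sd == 0:
        raise ValueError("degenerate background: zero standard deviation")
    numerator = sig_max - bg_mean
    if numerator <= 0:
        return SBRReport(float("-inf"), sig_max, bg_mean, bg_sd, mode,
                         int(background.size), degenerate=True)
    return SBRReport(10.0 * np.log10(numerator / bg_sd), sig_max, bg_mean, bg_sd,
                     mode, int(background.size))


def local_sbr(
    image: np.ndarray, window_px: int, stride: int | None = None
) -> np.ndarray:
    """SBR evaluated per sliding window (auto mask per window).

    Returns a map of shape (n_windows_y, n_windows_x); windows where the
    metric is undefined (too little background, degenerate spread) are NaN.
    """
    image = np.asarray(image, dtype=float)
    if window_px < 16:
        raise ValueError("window_px must be >= 16")
    ny, nx = image.shape
    if window_px > min(ny, nx):
        raise ValueError("window larger than image")
    stride = stride or window_px
    ys = range(0, ny - window_px + 1, stride)
    xs = range(0, nx - window_px + 1, stride)
    out = np.full((len(ys), len(xs)), np.nan)
    for i, y in enumerate(ys):
        for j, x in enumerate(xs):
            tile = image[y:y + window_px, x:x + window_px]
            try:
                out[i, j] = sbr(tile).sbr_db
            except ValueError:
                pass  # invalid window stays NaN
    return out


def _refine_peak(image: np.ndarray, center: tuple[float, float], radius: int = 4):
    """Snap ``center`` to the local maximum within ``radius`` pixels."""
    cy, cx = int(round(center[0])), int(round(center[1]))
    ny, nx = image.shape
    y0, y1 = max(cy - radius, 0), min(cy + radius + 1, ny)
    x0, x1 = max(cx - radius, 0), min(cx + radius + 1, nx)
    sub = image[y0:y1, x0:x1]
    iy, ix = np.unravel_index(np.argmax(sub), sub.shape)
    return float(y0 + iy), float(x0 + ix)


def fwhm(
    image: np.ndarray,
    center: tuple[float, float],
    direction_deg: float,
    pixel_nm: float,
    half_length_px: float = 15.0,
    step_px: float = 0.05,
) -> float:
    """Full width at half maximum of a point-like object, in nanometres.

    Samples a bilinear profile through the local maximum near ``center``
    along ``direction_deg``, subtracts the profile-edge median as local
    background, and locates the two half-maximum crossings by linear
    interpolation.  Raises ``ValueError`` when no two crossings exist.
    """
    image = np.asarray(image, dtype=float)
    cy, cx = _refine_peak(image, center)
    theta = np.deg2rad(direction_deg)
    t = np.arange(-half_length_px, half_length_px + step_px / 2, step_px)
    ys = cy + t * np.sin(theta)
    xs = cx + t * np.cos(theta)
    prof = ndimage.map_coordinates(image, [ys, xs], order=1, mode="nearest")
    n_edge = max(3, int(0.1 * prof.size))
    background = float(np.median(np.concatenate([prof[:n_edge], prof[-n_edge:]])))
    prof = prof - background
    ipk = int(np.argmax(prof))
    half = prof[ipk] / 2.0
    if prof[ipk] <= 0:
        raise ValueError("no peak above local background near center")
    # walk outward from the peak to find the half-max crossings
    left = None
    for i in range(ipk, 0, -1):
        if prof[i - 1] < half <= prof[i]:
            frac = (prof[i] - half) / (prof[i] - prof[i - 1])
            left = i - frac
            break
    right = None
    for i in range(ipk, prof.size - 1):
        if prof[i + 1] < half <= prof[i]:
            frac = (prof[i] - half) / (prof[i] - prof[i + 1])
            right = i + frac
            break
    if left is None or right is None:
        raise ValueError("profile has no two half-maximum crossings")
    return float((right - left) * step_px * pixel_nm)


@dataclass
class RadialSpectrum:
    """Azimuthally averaged log10 amplitude spectrum."""

    k: np.ndarray              # annulus centres, cycles/px
    log_amplitude: np.ndarray  # mean log10 |FT| per annulus
    noise_floor: float         # median log-amplitude of the outer 10% annuli
    cutoff: float              # first k where the profile sinks to the floor


def radial_spectrum(image: np.ndarray, floor_margin: float = 0.15) -> RadialSpectrum:
    """Azimuthal average of log10 |FT| over annuli one grid step wide.

    The noise floor is the median log-amplitude over the outermost 10% of
    annuli; the estimated cutoff is the first annulus (scanning outward from
    DC) whose amplitude drops to within ``floor_margin`` log10 units
    (≈3 dB in power) of that floor.  Annuli are lower-edge binned: annulus b
    covers radial frequencies [b, b+1) grid steps and is reported as k = b/n.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    ny, nx = image.shape
    amp = np.abs(np.fft.fftshift(np.fft.fft2(image)))
    ky = (np.arange(ny) - ny // 2)[:, None] / ny
    kx = (np.arange(nx) - nx // 2)[None, :] / nx
    kr = np.hypot(ky, kx)
    n = min(ny, nx)
    idx = np.floor(kr * n).astype(int)
    nbins = idx.max() + 1
    log_amp = np.full(nbins, np.nan)
    with np.errstate(divide="ignore"):
        la = np.log10(amp + 1e-30)
    for b in range(nbins):
        sel = idx == b
        if np.any(sel):
            log_amp[b] = la[sel].mean()
    k = np.arange(nbins) / n
    outer = max(1, int(0.1 * nbins))
    floor = float(np.nanmedian(log_amp[-outer:]))
    cutoff = k[-1]
    for b in range(1, nbins):
        if np.isfinite(log_amp[b]) and log_amp[b] <= floor + floor_margin:
            cutoff = k[b]
            break
    return RadialSpectrum(k, log_amp, floor, float(cutoff))


def intensity_profile(
    image: np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
    n_samples: int,
    pixel_nm: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear line profile between two (y, x) points.

    Returns ``(distance_nm, intensity)`` with ``n_samples`` equally spaced
    samples from ``p0`` to ``p1`` inclusive.  Raises on a zero-length
    segment or endpoints outside the image.
    """
    image = np.asarray(image, dtype=float)
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    ny, nx = image.shape
    for p in (p0, p1):
        if not (0 <= p[0] <= ny - 1 and 0 <= p[1] <= nx - 1):
            raise ValueError(f"endpoint {tuple(p)} outside image")
    length_px = float(np.hypot(*(p1 - p0)))
    if length_px == 0:
        raise ValueError("zero-length segment")
    t = np.linspace(0.0, 1.0, n_samples)
    ys = p0[0] + t * (p1[0] - p0[0])
    xs = p0[1] + t * (p1[1] - p0[1])
    vals = ndimage.map_coordinates(image, [ys, xs], order=1, mode="nearest")
    return t * length_px * pixel_nm, vals
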