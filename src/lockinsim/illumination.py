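"""Illumination-pattern parameter estimation.

Each orientation of a two-beam SIM acquisition is a sinusoidal stripe pattern
``1 + m·cos(2π k0·r + φ_j)``.  Reconstruction needs the pattern wave vector
``k0`` (cycles/pixel), the three phases ``φ_j`` and the modulation depth
``m``.  They are recovered from the raw frames themselves:

* ``k0`` — coarse peak of the cross-correlation between the separated zeroth
  and first-order bands, refined to subpixel precision by maximising the
  continuous-frequency (DTFT) correlation magnitude.
* ``φ_j`` — complex argument of each frame's first-order component at ``k0``
  after removing the phase-mean (widefield) term; non-iterative.
* ``m`` — least-squares amplitude ratio of the OTF-compensated first-order
  band to the shifted zeroth-order band over their spectral overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .optics import OpticalModel

__all__ = [
    "IlluminationParams",
    "PatternNotDetectedError",
    "estimate_k0",
    "estimate_phases_and_modulation",
    "estimate_parameters",
    "default_illumination",
]

EQUISPACED_3 = np.array([0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0])


class PatternNotDetectedError(RuntimeError):
    """No illumination-pattern peak above the noise floor."""


@dataclass
class IlluminationParams:
    """Per-orientation pattern parameters.

    ``k0`` has shape (n_angles, 2) in (ky, kx) cycles/pixel; ``phases`` has
    shape (n_angles, n_phases) in radians (reported modulo 2π); ``m`` and
    ``quality`` have shape (n_angles,).
    """

    k0: np.ndarray
    phases: np.ndarray
    m: np.ndarray
    quality: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.k0 = np.atleast_2d(np.asarray(self.k0, dtype=float))
        self.phases = np.mod(np.atleast_2d(np.asarray(self.phases, dtype=float)), 2 * np.pi)
        self.m = np.atleast_1d(np.asarray(self.m, dtype=float))
        if self.quality is None:
            self.quality = np.zeros(len(self.m))
        self.quality = np.atleast_1d(np.asarray(self.quality, dtype=float))
        if np.any(self.m < 0) or np.any(self.m > 1):
            raise ValueError("modulation depth m must lie in [0, 1]")

    @property
    def n_angles(self) -> int:
        return self.k0.shape[0]

    @property
    def n_phases(self) -> int:
        return self.phases.shape[1]

    def phase_spacing_deviation(self, d: int) -> float:
        """Max deviation (radians) of orientation ``d`` phases from an
        equispaced design — reported rather than silently assumed."""
        ph = np.sort(np.mod(self.phases[d] - self.phases[d][0], 2 * np.pi))
        nominal = np.arange(self.n_phases) * 2 * np.pi / self.n_phases
        dev = np.angle(np.exp(1j * (ph - nominal)))
        return float(np.max(np.abs(dev)))

    def to_dict(self) -> dict:
        return {
            "k0": self.k0.tolist(),
            "phases": self.phases.tolist(),
            "m": self.m.tolist(),
            "quality": self.quality.tolist(),
        }

    @staticmethod
    def from_dict(d: dict) -> "IlluminationParams":
        return IlluminationParams(
            np.asarray(d["k0"]), np.asarray(d["phases"]),
            np.asarray(d["m"]), np.asarray(d.get("quality")),
        )


def default_illumination(
    optical: OpticalModel,
    n_angles: int = 3,
    k_frac: float = 0.8,
    m: float = 0.9,
    angle0_deg: float = 0.0,
) -> IlluminationParams:
    """Nominal pattern parameters: |k0| = ``k_frac``·k_cutoff, orientations
    spaced 180°/n_angles apart, three equispaced phases per orientation."""
    kmag = k_frac * optical.k_cutoff
    angs = np.deg2rad(angle0_deg + np.arange(n_angles) * 180.0 / n_angles)
    k0 = np.stack([kmag * np.sin(angs), kmag * np.cos(angs)], axis=1)
    phases = np.tile(EQUISPACED_3, (n_angles, 1))
    return IlluminationParams(k0, phases, np.full(n_angles, m), np.ones(n_angles))


# ---------------------------------------------------------------------------
# Estimation


def _separate_nominal(frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Zeroth and +1 order spectra under the nominal equispaced 3-phase design."""
    phases = EQUISPACED_3
    M = np.exp(1j * np.outer(phases, np.array([-1, 0, 1])))
    Minv = np.linalg.inv(M)
    fts = np.fft.fft2(frames)
    bands = np.tensordot(Minv, fts, axes=(1, 0))
    return bands[1], bands[2]  # order 0, order +1


def _dtft_mag(p: np.ndarray, k: np.ndarray) -> float:
    """|Σ_r p(r)·exp(−2πi k·r)| evaluated at continuous k (cycles/px)."""
    ny, nx = p.shape
    ey = np.exp(-2j * np.pi * k[0] * np.arange(ny))
    ex = np.exp(-2j * np.pi * k[1] * np.arange(nx))
    return abs(ey @ p @ ex)


def estimate_k0(
    frames: np.ndarray,
    optical: OpticalModel,
    dc_exclude_frac: float = 0.1,
    noise_floor_factor: float = 5.0,
) -> tuple[np.ndarray, float]:
    """Estimate the pattern wave vector from 3 phase frames of one orientation.

    Returns ``(k0, quality)`` with ``k0`` in (ky, kx) cycles/pixel,
    canonicalised to the half-plane ky > 0 (ky = 0 → kx > 0); ``quality`` is
    the normalised correlation-peak magnitude in [0, 1].

    Raises :class:`PatternNotDetectedError` when the correlation peak does
    not exceed ``noise_floor_factor`` × the median off-peak magnitude.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.shape[0] != 3:
        raise ValueError("estimate_k0 expects exactly 3 phase frames")
    if np.ptp(frames) == 0:
        raise PatternNotDetectedError("frames are constant; pattern not detected")
    b0, b1 = _separate_nominal(frames)
    e0 = np.sum(np.abs(b0) ** 2)
    e1 = np.sum(np.abs(b1) ** 2)
    if e0 == 0 or e1 < 1e-12 * e0:
        raise PatternNotDetectedError(
            "pattern not detected: first-order band energy is negligible "
            "(unmodulated input)"
        )
    c0 = np.fft.ifft2(b0)
    c1 = np.fft.ifft2(b1)
    p = c1 * np.conj(c0)
    P = np.fft.fft2(p)
    mag = np.abs(P)

    ny, nx = frames.shape[1:]
    ky = np.fft.fftfreq(ny)[:, None]
    kx = np.fft.fftfreq(nx)[None, :]
    kr = np.hypot(ky, kx)
    exclude = max(dc_exclude_frac * optical.k_cutoff, 2.0 / max(ny, nx))
    search = (kr >= exclude) & (kr <= optical.k_cutoff)
    if not np.any(search):
        raise PatternNotDetectedError("no admissible frequencies in search annulus")
    masked = np.where(search, mag, 0.0)
    iy, ix = np.unravel_index(np.argmax(masked), masked.shape)
    peak = masked[iy, ix]
    floor = float(np.median(mag[search]))
    if floor > 0 and peak < noise_floor_factor * floor:
        raise PatternNotDetectedError(
            f"pattern not detected: correlation peak {peak:.3g} below "
            f"{noise_floor_factor:g}x the median magnitude {floor:.3g}"
        )

    k_coarse = np.array([ky[iy, 0], kx[0, ix]])
    res = minimize(
        lambda k: -_dtft_mag(p, k),
        k_coarse,
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 400},
    )
    k0 = res.x
    # sign is a gauge freedom (k0 and -k0 describe the same stripes);
    # canonicalise to ky > 0 with a tolerance band so near-horizontal
    # patterns (ky ~ 0) resolve by the sign of kx
    tol = 1e-3
    if k0[0] < -tol or (abs(k0[0]) <= tol and k0[1] < 0):
        k0 = -k0
    norm = np.sqrt(np.sum(np.abs(c0) ** 2) * np.sum(np.abs(c1) ** 2))
    quality = float(_dtft_mag(p, k0) / norm) if norm > 0 else 0.0
    return k0, quality


def estimate_phases_and_modulation(
    frames: np.ndarray,
    k0: np.ndarray,
    optical: OpticalModel,
    otf_floor: float = 0.05,
) -> tuple[np.ndarray, float]:
    """Recover the three pattern phases and the modulation depth given ``k0``.

    Phases come from the complex argument of each widefield-subtracted
    frame's spectrum at the continuous frequency ``k0``; ``m`` is twice the
    magnitude of the complex least-squares factor matching the
    OTF-compensated first order to the shifted zeroth order over the band
    overlap.  Raises ``ValueError`` if the bands do not overlap on the grid.
    """
    frames = np.asarray(frames, dtype=float)
    ny, nx = frames.shape[1:]
    if np.hypot(*k0) >= 2.0 * optical.k_cutoff:
        raise ValueError("band overlap region empty: |k0| >= 2 k_cutoff")

    # each frame's first-order component evaluated at the continuous pattern
    # frequency (DTFT); subtracting the phase-mean (widefield) first removes
    # the zeroth-order term that would otherwise bias the argument
    widefield = frames.mean(axis=0)
    ey = np.exp(-2j * np.pi * k0[0] * np.arange(ny))
    ex = np.exp(-2j * np.pi * k0[1] * np.arange(nx))
    phases = np.array([np.angle(ey @ (f - widefield) @ ex) for f in frames])

    # band separation with the recovered phases
    M = np.exp(1j * np.outer(phases, np.array([-1, 0, 1])))
    if np.linalg.cond(M) > 1e8:
        raise ValueError("phase design matrix singular; phases too close")
    bands = np.tensordot(np.linalg.inv(M), np.fft.fft2(frames), axes=(1, 0))
    b0, b1 = bands[1], bands[2]

    ky = np.fft.fftfreq(ny)[:, None]
    kx = np.fft.fftfreq(nx)[None, :]
    otf_here = optical.otf_at(ky, kx)                 # H(k)
    otf_shift = optical.otf_at(ky - k0[0], kx - k0[1])  # H(k - k0)
    overlap = (otf_here > otf_floor) & (otf_shift > otf_floor)
    if not np.any(overlap):
        raise ValueError("band overlap region empty on this grid")

    # b0 translated by +k0 so it aligns with b1's sample content
    yy = np.arange(ny)[:, None]
    xx = np.arange(nx)[None, :]
    ramp = np.exp(2j * np.pi * (k0[0] * yy + k0[1] * xx))
    b0_shift = np.fft.fft2(np.fft.ifft2(b0) * ramp)

    x = b1[overlap] / otf_here[overlap]
    y = b0_shift[overlap] / otf_shift[overlap]
    w = (otf_here[overlap] * otf_shift[overlap])
    denom = np.sum(w * np.abs(y) ** 2)
    if denom == 0:
        raise ValueError("degenerate overlap; cannot estimate modulation")
    factor = np.sum(w * x * np.conj(y)) / denom
    m = float(np.clip(2.0 * np.abs(factor), 1e-6, 1.0))
    return np.mod(phases, 2 * np.pi), m


def estimate_parameters(plane: np.ndarray, optical: OpticalModel) -> IlluminationParams:
    """Estimate k0, phases and m for every orientation of a (angle, phase, y, x)
    plane of raw frames."""
    n_angles = plane.shape[0]
    k0s, phs, ms, qs = [], [], [], []
    for d in range(n_angles):
        k0, q = estimate_k0(plane[d], optical)
        ph, m = estimate_phases_and_modulation(plane[d], k0, optical)
        k0s.append(k0)
        phs.append(ph)
        ms.append(m)
        qs.append(q)
    return IlluminationParams(np.array(k0s), np.array(phs), np.array(ms), np.array(qs))
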