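"""Three-phase lock-in demodulation and background removal.

A raw two-beam SIM frame splits into a modulation-independent (DC) part —
out-of-focus haze plus the unmodulated fraction of the in-focus signal —
and a modulation-dependent (AC) part that only in-focus structure
contributes to.  Because each orientation is sampled at three pattern
phases, every pixel carries three samples of a sinusoid
``I_j = C + A·cos(φ_j − ψ)``: solving for (C, A) per pixel is a homodyne
(lock-in) measurement.  ``C − A`` isolates the DC background, which is
low-pass filtered (background varies slowly across the field) and
subtracted from every raw frame before reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .illumination import IlluminationParams
from .optics import SIMRawStack

__all__ = [
    "LockinSettings",
    "DemodulationResult",
    "demodulate_three_phase",
    "estimate_dc",
    "filter_dc",
    "remove_background",
]


@dataclass
class LockinSettings:
    """Background-removal knobs.

    ``sigma_px`` — Gaussian width for smoothing the DC map; ``None`` uses one
    pattern period (1/|k0|) per orientation.  ``combine`` — ``per_orientation``
    subtracts each orientation's own DC map; ``median`` replaces them with
    their pixel-wise median across orientations (robust when one pattern is
    degraded).  ``clip`` — clamp negative residuals after subtraction.

    ``equalize_otf`` — the raw lock-in amplitude is the in-focus signal seen
    through the *shifted* OTF ``H(k+k0)``, which attenuates it relative to
    the ``m·(O_in*H)`` term that the phase-mean contains; the plain
    ``C − A`` estimator therefore counts part of the unmodulated in-focus
    intensity as background (maximally aggressive suppression, the default).
    Enabling ``equalize_otf`` re-maps the complex envelope onto the
    zeroth-band OTF with a regularised spectral filter (``equalize_eps``)
    before the subtraction, preserving the widefield component of in-focus
    structure at the cost of leaving in-focus PSF tails in place.
    """

    sigma_px: float | None = None
    combine: str = "per_orientation"
    clip: bool = True
    equalize_otf: bool = False
    equalize_eps: float = 0.05

    def __post_init__(self) -> None:
        if self.combine not in ("per_orientation", "median"):
            raise ValueError("combine must be 'per_orientation' or 'median'")
        if self.sigma_px is not None and self.sigma_px < 0:
            raise ValueError("sigma_px must be >= 0")
        if self.equalize_eps <= 0:
            raise ValueError("equalize_eps must be > 0")

    def to_dict(self) -> dict:
        return {
            "sigma_px": self.sigma_px,
            "combine": self.combine,
            "clip": self.clip,
            "equalize_otf": self.equalize_otf,
            "equalize_eps": self.equalize_eps,
        }


@dataclass
class DemodulationResult:
    """Outputs of background removal on a full stack.

    ``dc_map`` has axes (c, t, z, angle, y, x); ``amplitude_map`` likewise;
    ``ac`` is the background-subtracted stack with the raw stack's axes.
    ``clipped_mass`` is the total intensity removed by negative clipping,
    logged for diagnostics.
    """

    dc_map: np.ndarray
    amplitude_map: np.ndarray
    ac: SIMRawStack
    settings: LockinSettings
    clipped_mass: float = 0.0


def _solve_three_phase(frames: np.ndarray, phases: np.ndarray):
    """Per-pixel solve of I_j = C + a·cos φ_j + b·sin φ_j; returns (C, a, b)."""
    frames = np.asarray(frames, dtype=float)
    phases = np.asarray(phases, dtype=float)
    if frames.shape[0] != 3 or phases.shape != (3,):
        raise ValueError("three-phase demodulation expects 3 frames and 3 phases")
    design = np.stack([np.ones(3), np.cos(phases), np.sin(phases)], axis=1)
    if np.linalg.cond(design) > 1e10:
        raise ValueError("phase design matrix singular (phases not distinct mod 2π)")
    coeff = np.linalg.inv(design) @ frames.reshape(3, -1)
    shape = frames.shape[1:]
    return coeff[0].reshape(shape), coeff[1].reshape(shape), coeff[2].reshape(shape)


def demodulate_three_phase(
    frames: np.ndarray, phases: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel homodyne solve of ``I_j = C + a·cos φ_j + b·sin φ_j``.

    Returns ``(mean_map, amplitude_map, phase_map)`` = (C, √(a²+b²),
    atan2(b, a)).  For exactly equispaced phases this reduces to the
    classical root-mean-square optical-sectioning formulas
    C = (I₁+I₂+I₃)/3 and A = (√2/3)·√((I₁−I₂)²+(I₂−I₃)²+(I₃−I₁)²).
    Raises ``ValueError`` when the phase design matrix is singular.
    """
    c, a, b = _solve_three_phase(frames, phases)
    return c, np.hypot(a, b), np.arctan2(b, a)


def _equalized_amplitude(
    frames: np.ndarray,
    phases: np.ndarray,
    k0: np.ndarray,
    optical,
    eps: float = 0.05,
) -> np.ndarray:
    """Estimate the ``m·(O_in*H)`` map from the complex lock-in envelope.

    The per-pixel envelope ``a − i·b`` carries the in-focus structure through
    the shifted OTF ``H(k+k0)``; shifting it to baseband and applying the
    regularised transfer ``H(k)·H(k+k0)/(H(k+k0)² + eps²)`` re-expresses it
    through the zeroth-band OTF, which is what the phase-mean contains.
    """
    _, a, b = _solve_three_phase(frames, phases)
    ny, nx = a.shape
    yy = np.arange(ny)[:, None]
    xx = np.arange(nx)[None, :]
    baseband = (a - 1j * b) * np.exp(-2j * np.pi * (k0[0] * yy + k0[1] * xx))
    spec = np.fft.fft2(baseband)
    ky = np.fft.fftfreq(ny)[:, None]
    kx = np.fft.fftfreq(nx)[None, :]
    h0 = optical.otf_at(ky, kx)
    hs = optical.otf_at(ky + k0[0], kx + k0[1])
    return np.abs(np.fft.ifft2(spec * h0 * hs / (hs**2 + eps**2)))


def estimate_dc(frames: np.ndarray, phases: np.ndarray) -> np.ndarray:
    """Raw (unsmoothed) DC background map of one orientation.

    The phase-mean C of the three frames contains the background plus the
    unmodulated in-focus mean, while the lock-in amplitude A estimates the
    modulated in-focus contribution; their clipped difference
    ``max(C − A, 0)`` isolates the modulation-independent background.
    """
    c, amp, _ = demodulate_three_phase(frames, phases)
    return np.clip(c - amp, 0.0, None)


def filter_dc(dc_raw: np.ndarray, sigma_px: float) -> np.ndarray:
    """Gaussian low-pass of the DC map (σ in pixels; σ = 0 is the identity).

    Backgrounds vary slowly across the field, so smoothing prevents the DC
    estimate from carrying — and subtracting — residual in-focus texture.
    """
    if sigma_px < 0:
        raise ValueError("sigma_px must be >= 0")
    if sigma_px == 0:
        return np.asarray(dc_raw, dtype=float)
    return ndimage.gaussian_filter(np.asarray(dc_raw, dtype=float), sigma_px)


def remove_background(
    raw: SIMRawStack,
    params: IlluminationParams,
    settings: LockinSettings | None = None,
) -> DemodulationResult:
    """Strip the DC background from every frame of a raw stack.

    Per orientation (and independently per channel/time/z): the phase-mean C
    and the lock-in amplitude A are demodulated, the DC background
    ``max(C − A, 0)`` is smoothed with ``filter_dc`` and subtracted:
    ``ac_j = max(raw_j − dc, 0)``.  With ``settings.equalize_otf`` (default)
    A is the OTF-equalised amplitude so in-focus structure is not counted as
    background; with ``combine='median'`` the per-orientation DC maps are
    replaced by their pixel-wise median before subtraction.  Raises
    ``ValueError`` for incomplete 3-phase groups.
    """
    settings = settings or LockinSettings()
    if raw.n_phases != 3:
        raise ValueError(
            f"lock-in demodulation needs 3 phases per orientation; got {raw.n_phases}"
        )
    if params.n_angles != raw.n_angles:
        raise ValueError(
            f"params cover {params.n_angles} orientations, stack has {raw.n_angles}"
        )
    nc, nt, nz, na, nph, ny, nx = raw.data.shape
    dc_all = np.zeros((nc, nt, nz, na, ny, nx))
    amp_all = np.zeros_like(dc_all)
    ac = np.empty_like(raw.data)
    clipped = 0.0
    for (c, t, z), plane in raw.iter_planes():
        dc_maps = np.empty((na, ny, nx))
        for d in range(na):
            kmag = np.hypot(*params.k0[d])
            sigma = settings.sigma_px if settings.sigma_px is not None else (
                1.0 / kmag if kmag > 0 else 0.0
            )
            c_map, amp, _ = demodulate_three_phase(plane[d], params.phases[d])
            if settings.equalize_otf:
                if raw.optical is None:
                    raise ValueError(
                        "equalize_otf needs the stack's OpticalModel; attach one "
                        "or set equalize_otf=False"
                    )
                amp = _equalized_amplitude(
                    plane[d], params.phases[d], params.k0[d], raw.optical,
                    eps=settings.equalize_eps,
                )
            dc_maps[d] = filter_dc(np.clip(c_map - amp, 0.0, None), sigma)
            amp_all[c, t, z, d] = amp
        if settings.combine == "median":
            dc_maps = np.broadcast_to(
                np.median(dc_maps, axis=0), dc_maps.shape
            ).copy()
        dc_all[c, t, z] = dc_maps
        for d in range(na):
            resid = plane[d] - dc_maps[d][None]
            if settings.clip:
                clipped += float(-resid[resid < 0].sum())
                resid = np.clip(resid, 0.0, None)
            ac[c, t, z, d] = resid
    ac_stack = SIMRawStack(np.clip(ac, 0.0, None), optical=raw.optical,
                           tags={**raw.tags, "lockin": settings.to_dict()})
    return DemodulationResult(dc_all, amp_all, ac_stack, settings, clipped)
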