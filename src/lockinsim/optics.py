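"""Optical primitives shared across the package.

Frequency convention: all spatial frequencies are in *cycles per pixel* on the
FFT grid (``numpy.fft.fftfreq`` ordering); conversion to physical units
(µm⁻¹) happens only at reporting boundaries.  The incoherent OTF is the
diffraction-limited scalar model — the normalised autocorrelation of a
circular pupil — with support radius ``k_cutoff = 2·NA/λ``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticalModel",
    "AcquisitionGeometry",
    "SIMRawStack",
    "NyquistError",
    "build_optical_model",
    "frames_per_plane",
    "speedup_ratio",
    "diffraction_otf",
]


class NyquistError(ValueError):
    """Pixel size too coarse to sample the OTF support."""


def _freq_grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """FFT-ordered frequency grids (ky, kx) in cycles/pixel."""
    ny, nx = shape
    ky = np.fft.fftfreq(ny)[:, None]
    kx = np.fft.fftfreq(nx)[None, :]
    return ky, kx


def diffraction_otf(kr: np.ndarray, k_cutoff: float) -> np.ndarray:
    """Diffraction-limited incoherent 2-D OTF at radial frequency ``kr``.

    Normalised pupil autocorrelation: (2/π)(arccos ρ − ρ√(1−ρ²)) with
    ρ = kr/k_cutoff, zero outside the cutoff.
    """
    rho = np.clip(np.asarray(kr, dtype=float) / k_cutoff, 0.0, None)
    inside = rho < 1.0
    r = np.where(inside, rho, 0.0)
    otf = np.where(inside, (2.0 / np.pi) * (np.arccos(r) - r * np.sqrt(1.0 - r * r)), 0.0)
    return otf


def gaussian_otf(kr: np.ndarray, k_cutoff: float) -> np.ndarray:
    """Gaussian OTF approximation with the same hard support bound.

    σ_k is set so the Gaussian reaches ~1% at the cutoff; useful as a smooth
    stand-in when ringing from the hard-edged pupil is undesirable.
    """
    sigma_k = k_cutoff / 3.0
    otf = np.exp(-0.5 * (np.asarray(kr, dtype=float) / sigma_k) ** 2)
    otf[np.asarray(kr) >= k_cutoff] = 0.0
    return otf


@dataclass(frozen=True)
class OpticalModel:
    """Acquisition optics: wavelength/NA/pixel geometry plus OTF/PSF grids.

    ``otf`` lives on the FFT-ordered frequency grid of ``shape``; ``psf`` is
    its centred inverse transform, non-negative and normalised to unit sum.
    """

    wavelength_nm: float
    na: float
    pixel_nm: float
    shape: tuple[int, int]
    otf: np.ndarray = field(repr=False)
    psf: np.ndarray = field(repr=False)
    otf_model: str = "diffraction"

    @property
    def k_cutoff(self) -> float:
        """OTF support radius 2·NA/λ in cycles per pixel."""
        return 2.0 * self.na / self.wavelength_nm * self.pixel_nm

    @property
    def k_cutoff_per_um(self) -> float:
        """OTF support radius in µm⁻¹."""
        return 2.0 * self.na / self.wavelength_nm * 1000.0

    def otf_at(self, ky: np.ndarray, kx: np.ndarray) -> np.ndarray:
        """Evaluate the analytic OTF at arbitrary frequencies (cycles/px)."""
        kr = np.hypot(ky, kx)
        if self.otf_model == "gaussian":
            return gaussian_otf(kr, self.k_cutoff)
        return diffraction_otf(kr, self.k_cutoff)

    def to_dict(self) -> dict:
        return {
            "wavelength_nm": self.wavelength_nm,
            "na": self.na,
            "pixel_nm": self.pixel_nm,
            "shape": list(self.shape),
            "otf_model": self.otf_model,
        }

    @staticmethod
    def from_dict(d: dict) -> "OpticalModel":
        return build_optical_model(
            d["wavelength_nm"], d["na"], d["pixel_nm"], tuple(d["shape"]),
            otf_model=d.get("otf_model", "diffraction"),
        )


def build_optical_model(
    wavelength_nm: float,
    na: float,
    pixel_nm: float,
    shape: tuple[int, int],
    otf_model: str = "diffraction",
) -> OpticalModel:
    """Build an :class:`OpticalModel` with analytic OTF and derived PSF.

    Raises :class:`NyquistError` when the pixel is too large for the OTF
    support (k_cutoff must stay below the grid Nyquist of 0.5 cycles/px).
    """
    if wavelength_nm <= 0 or na <= 0 or pixel_nm <= 0:
        raise ValueError("wavelength_nm, na and pixel_nm must be positive")
    ny, nx = shape
    if ny < 8 or nx < 8:
        raise ValueError("grid must be at least 8x8")
    k_cutoff = 2.0 * na / wavelength_nm * pixel_nm
    if k_cutoff >= 0.5:
        max_pixel = wavelength_nm / (4.0 * na)
        raise NyquistError(
            f"pixel size {pixel_nm:g} nm undersamples the OTF support "
            f"(k_cutoff = {k_cutoff:.3f} cycles/px >= Nyquist 0.5); "
            f"maximum admissible pixel is {max_pixel:.1f} nm"
        )
    ky, kx = _freq_grid(shape)
    kr = np.hypot(ky, kx)
    if otf_model == "diffraction":
        otf = diffraction_otf(kr, k_cutoff)
    elif otf_model == "gaussian":
        otf = gaussian_otf(kr, k_cutoff)
    else:
        raise ValueError(f"unknown otf_model {otf_model!r}; use 'diffraction' or 'gaussian'")
    psf = np.fft.fftshift(np.fft.ifft2(otf).real)
    psf = np.clip(psf, 0.0, None)
    psf /= psf.sum()
    return OpticalModel(
        wavelength_nm=float(wavelength_nm),
        na=float(na),
        pixel_nm=float(pixel_nm),
        shape=(ny, nx),
        otf=otf,
        psf=psf,
        otf_model=otf_model,
    )


# ---------------------------------------------------------------------------
# Acquisition geometry


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Frames-per-plane bookkeeping for an illumination modality.

    ``z_sampling_relative`` is the relative axial sampling density a modality
    needs per unit depth (three-beam SIM requires twice the z density of a
    two-beam optically-sectioned acquisition).
    """

    modality: str
    angles: int
    phases: int
    z_sampling_relative: float

    def __post_init__(self) -> None:
        if self.modality not in ("two_beam_2d", "three_beam_3d"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.angles < 1 or self.phases < 1:
            raise ValueError("angles and phases must be >= 1")
        if self.z_sampling_relative <= 0:
            raise ValueError("z_sampling_relative must be positive")

    @staticmethod
    def two_beam_2d(angles: int = 3, phases: int = 3, z_sampling_relative: float = 1.0):
        return AcquisitionGeometry("two_beam_2d", angles, phases, z_sampling_relative)

    @staticmethod
    def three_beam_3d(angles: int = 3, phases: int = 5, z_sampling_relative: float = 2.0):
        return AcquisitionGeometry("three_beam_3d", angles, phases, z_sampling_relative)


def frames_per_plane(geom: AcquisitionGeometry) -> int:
    """Raw exposures needed per focal plane: angles × phases."""
    return geom.angles * geom.phases


def speedup_ratio(reference: AcquisitionGeometry, candidate: AcquisitionGeometry) -> float:
    """Acquisition speed-up of ``candidate`` over ``reference`` for one volume.

    Exposures per unit depth are frames_per_plane × relative z density; the
    ratio reference/candidate is the fold improvement (e.g. two-beam
    sectioning at 9 frames and single z density vs three-beam at 15 frames
    and doubled z density gives 30/9 ≈ 3.3-fold).
    """
    ref = frames_per_plane(reference) * reference.z_sampling_relative
    cand = frames_per_plane(candidate) * candidate.z_sampling_relative
    return ref / cand


# ---------------------------------------------------------------------------
# Raw stack container


@dataclass
class SIMRawStack:
    """Raw SIM frames with canonical axes (channel, time, z, angle, phase, y, x)."""

    data: np.ndarray
    optical: OpticalModel | None = None
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 7:
            raise ValueError(
                f"stack must have 7 axes (c,t,z,angle,phase,y,x); got {self.data.ndim}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite intensities")
        if np.any(self.data < 0):
            raise ValueError("stack contains negative intensities")

    @property
    def n_angles(self) -> int:
        return self.data.shape[3]

    @property
    def n_phases(self) -> int:
        return self.data.shape[4]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[5], self.data.shape[6]

    def plane(self, c: int = 0, t: int = 0, z: int = 0) -> np.ndarray:
        """The (angle, phase, y, x) block for one channel/time/z."""
        return self.data[c, t, z]

    def iter_planes(self):
        nc, nt, nz = self.data.shape[:3]
        for c in range(nc):
            for t in range(nt):
                for z in range(nz):
                    yield (c, t, z), self.data[c, t, z]
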