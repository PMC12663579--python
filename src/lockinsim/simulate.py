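"""Synthetic scene and raw SIM stack generation.

The renderer follows the forward model of two-beam SIM: the ground-truth
fluorophore density is multiplied by the sinusoidal illumination pattern,
convolved with the PSF, and corrupted with additive Gaussian noise.
Out-of-focus haze is emulated by superimposing a blurred (unmodulated) copy
of the widefield image at a chosen level, and a volumetric variant sums
depth-weighted contributions whose pattern contrast and PSF degrade away
from the focal plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .illumination import IlluminationParams, default_illumination
from .optics import OpticalModel, SIMRawStack

__all__ = [
    "SyntheticScene",
    "SimulationRecipe",
    "make_scene",
    "render_sim_raw",
    "inject_background",
    "render_volume_stack",
]

SCENE_KINDS = ("beads", "crossed_filaments", "radial_lines", "volume_filaments")


@dataclass
class SyntheticScene:
    """Ground-truth fluorophore map (2-D, or 3-D for volume scenes)."""

    kind: str
    truth: np.ndarray
    params: dict
    seed: int
    pixel_nm: float = 65.0
    z_step_um: float | None = None  # slice spacing for 3-D scenes


@dataclass
class SimulationRecipe:
    """Everything needed to render a raw stack from a scene, reproducibly."""

    optical: OpticalModel
    illum: IlluminationParams | None = None
    noise_sd: float = 0.0
    contrast_level: float = 1.0
    background_level: float = 0.0
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 < self.contrast_level <= 1.0):
            raise ValueError("contrast_level must lie in (0, 1]")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")

    def resolved_illum(self) -> IlluminationParams:
        return self.illum if self.illum is not None else default_illumination(self.optical)


# ---------------------------------------------------------------------------
# Scenes


def _draw_segment(canvas: np.ndarray, p0, p1, width_px: float) -> None:
    """Accumulate a line segment with a Gaussian cross-section."""
    ny, nx = canvas.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    p0 = np.asarray(p0, float)
    d = np.asarray(p1, float) - p0
    L2 = d @ d
    if L2 == 0:
        return
    t = ((yy - p0[0]) * d[0] + (xx - p0[1]) * d[1]) / L2
    t = np.clip(t, 0.0, 1.0)
    dist2 = (yy - (p0[0] + t * d[0])) ** 2 + (xx - (p0[1] + t * d[1])) ** 2
    canvas += np.exp(-dist2 / (2.0 * width_px**2))


def _beads(shape, rng, n, diameter_nm, pixel_nm):
    ny, nx = shape
    radius = diameter_nm / pixel_nm / 2.0
    canvas = np.zeros(shape)
    yy, xx = np.mgrid[0:ny, 0:nx]
    margin = max(4.0, 2 * radius)
    centers = rng.uniform([margin, margin], [ny - margin, nx - margin], size=(n, 2))
    for cy, cx in centers:
        # area-weighted antialiasing: coverage ramps over one pixel at the rim
        dist = np.hypot(yy - cy, xx - cx)
        canvas += np.clip(radius + 0.5 - dist, 0.0, 1.0)
    return canvas, {"centers": centers.tolist(), "radius_px": radius}


def _crossed_filaments(shape, rng, n, width_px):
    ny, nx = shape
    canvas = np.zeros(shape)
    for _ in range(n):
        side = rng.integers(0, 2)
        if side == 0:  # left-to-right
            p0 = (rng.uniform(0, ny), 0.0)
            p1 = (rng.uniform(0, ny), nx - 1.0)
        else:  # top-to-bottom
            p0 = (0.0, rng.uniform(0, nx))
            p1 = (ny - 1.0, rng.uniform(0, nx))
        _draw_segment(canvas, p0, p1, width_px)
    return canvas, {}


def _radial_lines(shape, rng, n_spokes, width_px, inner_frac):
    ny, nx = shape
    canvas = np.zeros(shape)
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    r_out = 0.48 * min(ny, nx)
    r_in = inner_frac * r_out
    angles = np.arange(n_spokes) * (360.0 / n_spokes)
    for a in np.deg2rad(angles):
        p0 = (cy + r_in * np.sin(a), cx + r_in * np.cos(a))
        p1 = (cy + r_out * np.sin(a), cx + r_out * np.cos(a))
        _draw_segment(canvas, p0, p1, width_px)
    return canvas, {"angles_deg": angles.tolist()}


def make_scene(
    kind: str,
    params: dict | None = None,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    pixel_nm: float = 65.0,
) -> SyntheticScene:
    """Render a deterministic ground-truth scene, peak-normalised to 1.

    Kinds: ``beads`` (antialiased disks; params n, diameter_nm),
    ``crossed_filaments`` (params n, width_px), ``radial_lines`` (params
    n_spokes, width_px, inner_frac) and ``volume_filaments`` (params
    n_planes, n_per_plane, width_px, z_step_um; truth is 3-D).
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "beads":
        n = int(params.get("n", 50))
        diameter_nm = float(params.get("diameter_nm", 100.0))
        if diameter_nm <= 0:
            raise ValueError("bead diameter must be positive")
        truth, extra = _beads(shape, rng, n, diameter_nm, pixel_nm)
        params.update(extra)
    elif kind == "crossed_filaments":
        n = int(params.get("n", 12))
        truth, extra = _crossed_filaments(shape, rng, n, float(params.get("width_px", 1.0)))
    elif kind == "radial_lines":
        n_spokes = int(params.get("n_spokes", 36))
        if n_spokes < 1:
            raise ValueError("need at least one spoke")
        truth, extra = _radial_lines(
            shape, rng, n_spokes,
            float(params.get("width_px", 1.0)), float(params.get("inner_frac", 0.08)),
        )
        params.update(extra)
    elif kind == "volume_filaments":
        n_planes = int(params.get("n_planes", 2))
        n_per = int(params.get("n_per_plane", 6))
        width_px = float(params.get("width_px", 1.0))
        z_step = float(params.get("z_step_um", 0.5))
        planes = []
        for _ in range(n_planes):
            t, _e = _crossed_filaments(shape, rng, n_per, width_px)
            planes.append(t)
        truth = np.stack(planes)
        scene = SyntheticScene(kind, truth, params, seed, pixel_nm, z_step_um=z_step)
        _normalise(scene)
        return scene
    else:
        raise ValueError(f"unknown scene kind {kind!r}; valid kinds: {SCENE_KINDS}")
    scene = SyntheticScene(kind, truth, params, seed, pixel_nm)
    _normalise(scene)
    return scene


def _normalise(scene: SyntheticScene) -> None:
    peak = scene.truth.max()
    if peak > 0:
        scene.truth = scene.truth / peak


# ---------------------------------------------------------------------------
# Raw stack rendering


def _convolve_otf(img: np.ndarray, otf: np.ndarray) -> np.ndarray:
    return np.fft.ifft2(np.fft.fft2(img) * otf).real


def _pattern(shape, k0, phase, m):
    yy = np.arange(shape[0])[:, None]
    xx = np.arange(shape[1])[None, :]
    return 1.0 + m * np.cos(2.0 * np.pi * (k0[0] * yy + k0[1] * xx) + phase)


def render_sim_raw(
    scene: SyntheticScene, recipe: SimulationRecipe
) -> tuple[SIMRawStack, np.ndarray]:
    """Render the raw frames of one focal plane plus the widefield image.

    Each frame is ``{[1 + m·cos(2π k0·r + φ_j)]·truth} * PSF`` plus Gaussian
    noise of ``recipe.noise_sd``; ``contrast_level`` scales m; a background
    of ``background_level`` × blur(widefield) is superimposed when requested.
    Frames are clipped at zero after noise (fluorescence non-negativity).
    """
    if scene.truth.ndim != 2:
        raise ValueError("render_sim_raw needs a 2-D scene; use render_volume_stack")
    optical = recipe.optical
    if scene.truth.shape != optical.shape:
        raise ValueError("scene shape does not match optical model grid")
    illum = recipe.resolved_illum()
    if np.any(np.hypot(illum.k0[:, 0], illum.k0[:, 1]) >= 0.5):
        raise ValueError("pattern |k0| beyond the grid Nyquist (0.5 cycles/px)")
    rng = np.random.default_rng(recipe.seed)
    widefield = _convolve_otf(scene.truth, optical.otf)

    n_angles, n_phases = illum.n_angles, illum.n_phases
    ny, nx = optical.shape
    frames = np.empty((n_angles, n_phases, ny, nx))
    for d in range(n_angles):
        m_eff = illum.m[d] * recipe.contrast_level
        for j in range(n_phases):
            pat = _pattern(optical.shape, illum.k0[d], illum.phases[d, j], m_eff)
            frames[d, j] = _convolve_otf(pat * scene.truth, optical.otf)
    if recipe.background_level > 0:
        frames += recipe.background_level * _convolve_otf(widefield, optical.otf)
    if recipe.noise_sd > 0:
        frames += rng.normal(0.0, recipe.noise_sd, size=frames.shape)
    frames = np.clip(frames, 0.0, None)
    stack = SIMRawStack(frames[None, None, None], optical=optical,
                        tags={"scene": scene.kind, "seed": recipe.seed})
    return stack, widefield


def inject_background(
    raw: SIMRawStack,
    widefield: np.ndarray,
    level: float,
    optical: OpticalModel | None = None,
    blur_sigma_px: float | None = None,
) -> SIMRawStack:
    """Superimpose an unmodulated, smooth background on every raw frame.

    The added term is ``level × blur(widefield)``; by default the blur
    re-applies the PSF once (requires ``optical`` or ``raw.optical``), or a
    Gaussian of ``blur_sigma_px`` when given.  ``level = 0`` is the identity.
    """
    if level < 0:
        raise ValueError("background level must be >= 0")
    if widefield.shape != raw.frame_shape:
        raise ValueError("widefield shape does not match raw frames")
    if blur_sigma_px is not None:
        bg = ndimage.gaussian_filter(widefield, blur_sigma_px)
    else:
        opt = optical or raw.optical
        if opt is None:
            raise ValueError("need an OpticalModel (or blur_sigma_px) to blur the background")
        bg = _convolve_otf(widefield, opt.otf)
    data = raw.data + level * bg
    return SIMRawStack(np.clip(data, 0.0, None), optical=raw.optical,
                       tags={**raw.tags, "background_level": level})


# ---------------------------------------------------------------------------
# Volumetric rendering for optical-sectioning tests


def render_volume_stack(
    scene3d: SyntheticScene,
    recipe: SimulationRecipe,
    z_planes_um: list[float],
    z_m_um: float = 0.6,
    z_r_um: float = 0.4,
    sigma0_px: float = 2.0,
) -> list[tuple[SIMRawStack, float]]:
    """Render raw stacks focused at each requested z plane of a 3-D scene.

    A slice at defocus Δz contributes with pattern contrast
    ``m·exp(−(Δz/z_m)²)`` (stripe visibility dies off axially) and a PSF
    widened to total Gaussian width ``σ0·√(1+(Δz/z_r)²)`` — implemented as an
    extra blur of ``σ0·|Δz|/z_r`` on top of the in-focus PSF, so the in-focus
    slice is rendered exactly as in :func:`render_sim_raw`.
    """
    if scene3d.truth.ndim != 3:
        raise ValueError("render_volume_stack needs a 3-D scene")
    if len(z_planes_um) == 0:
        raise ValueError("z_planes_um must name at least one focal plane")
    if scene3d.z_step_um is None:
        raise ValueError("scene z_step_um missing")
    optical = recipe.optical
    illum = recipe.resolved_illum()
    rng = np.random.default_rng(recipe.seed)
    nz = scene3d.truth.shape[0]
    slice_z = np.arange(nz) * scene3d.z_step_um
    ny, nx = optical.shape

    out = []
    for z0 in z_planes_um:
        frames = np.zeros((illum.n_angles, illum.n_phases, ny, nx))
        widefield = np.zeros((ny, nx))
        for iz in range(nz):
            dz = slice_z[iz] - z0
            sigma_extra = sigma0_px * abs(dz) / z_r_um
            otf_dz = optical.otf
            if sigma_extra > 0:
                ky = np.fft.fftfreq(ny)[:, None]
                kx = np.fft.fftfreq(nx)[None, :]
                otf_dz = otf_dz * np.exp(-2.0 * (np.pi * sigma_extra) ** 2 * (ky**2 + kx**2))
            m_dz = np.exp(-((dz / z_m_um) ** 2))
            truth_z = scene3d.truth[iz]
            widefield += _convolve_otf(truth_z, otf_dz)
            for d in range(illum.n_angles):
                m_eff = illum.m[d] * recipe.contrast_level * m_dz
                for j in range(illum.n_phases):
                    pat = _pattern(optical.shape, illum.k0[d], illum.phases[d, j], m_eff)
                    frames[d, j] += _convolve_otf(pat * truth_z, otf_dz)
        if recipe.noise_sd > 0:
            frames += rng.normal(0.0, recipe.noise_sd, size=frames.shape)
        frames = np.clip(frames, 0.0, None)
        stack = SIMRawStack(frames[None, None, None], optical=optical,
                            tags={"scene": scene3d.kind, "focus_um": z0})
        out.append((stack, z0))
    return out
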