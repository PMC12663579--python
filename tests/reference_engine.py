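"""Literal, slow reference implementation of the Wiener-SIM engine.

Everything is done with explicit DFT matrices, explicit index arithmetic for
the spectrum padding, and per-band loops — no FFTs, no shared plumbing with
the package's engine beyond the analytic OTF (which is the model, not the
pipeline).  Used as an independent oracle on small grids.
"""

import numpy as np


def dft_matrix(n: int) -> np.ndarray:
    j = np.arange(n)
    return np.exp(-2j * np.pi * np.outer(j, j) / n)


def dft2(x: np.ndarray) -> np.ndarray:
    ny, nx = x.shape
    return dft_matrix(ny) @ x @ dft_matrix(nx).T


def idft2(X: np.ndarray) -> np.ndarray:
    ny, nx = X.shape
    return (np.conj(dft_matrix(ny)) @ X @ np.conj(dft_matrix(nx)).T) / (ny * nx)


def fft_order_freqs(n: int, scale: float = 1.0) -> np.ndarray:
    """FFT-ordered frequencies by modular index arithmetic (cycles/px·scale)."""
    k = np.arange(n, dtype=float)
    k[k >= (n + 1) // 2] -= n
    return k / n * scale


def pad_spectrum(band: np.ndarray, u: int) -> np.ndarray:
    """Centre-embed an FFT-ordered N-grid spectrum into a u·N grid, index by index."""
    n = band.shape[0]
    un = n * u
    out = np.zeros((un, un), dtype=complex)
    for iy in range(n):
        fy = iy if iy < (n + 1) // 2 else iy - n  # signed frequency index
        ty = fy % un
        for ix in range(n):
            fx = ix if ix < (n + 1) // 2 else ix - n
            out[ty, fx % un] = band[iy, ix]
    return out * (u**2)


def reference_reconstruct(plane, params, optical, wiener_w=0.15,
                          apodization="triangular", upsample=2):
    """Direct-DFT two-beam reconstruction of one (angle, phase, y, x) plane."""
    n_angles = plane.shape[0]
    n = plane.shape[-1]
    un = n * upsample
    ky = fft_order_freqs(un, upsample)[:, None]
    kx = fft_order_freqs(un, upsample)[None, :]
    yy = np.arange(un)[:, None] / upsample
    xx = np.arange(un)[None, :] / upsample

    num = np.zeros((un, un), dtype=complex)
    den = np.zeros((un, un))
    max_k0 = 0.0
    for d in range(n_angles):
        phases = params.phases[d]
        k0 = params.k0[d]
        m = float(params.m[d])
        max_k0 = max(max_k0, float(np.hypot(*k0)))
        M = np.array([[np.exp(1j * nn * p) for nn in (-1, 0, 1)] for p in phases])
        Minv = np.linalg.inv(M)
        spectra = [dft2(plane[d, j]) for j in range(3)]
        for bi, order in enumerate((-1, 0, 1)):
            band = sum(Minv[bi, j] * spectra[j] for j in range(3))
            padded = pad_spectrum(band, upsample)
            shift = -order * k0
            if order != 0:
                field = idft2(padded)
                field = field * np.exp(2j * np.pi * (shift[0] * yy + shift[1] * xx))
                padded = dft2(field)
            g = 1.0 if order == 0 else m / 2.0
            otf_n = optical.otf_at(ky + order * k0[0], kx + order * k0[1])
            num = num + g * otf_n * padded
            den = den + (g * otf_n) ** 2
    sr = num / (den + wiener_w**2)
    if apodization == "triangular":
        kr = np.hypot(ky, kx)
        sr = sr * np.clip(1.0 - kr / (optical.k_cutoff + max_k0), 0.0, None)
    return np.clip(idft2(sr).real, 0.0, None)
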