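# lockinsim

Background-free super-resolution reconstruction for two-beam 2D structured
illumination microscopy (SIM).

SIM doubles lateral resolution by illuminating the sample with sinusoidal
stripe patterns and computationally demodulating the frequency-shifted
bands, but as a widefield technique it collects out-of-focus light that
buries fine structure in haze.  `lockinsim` exploits the fact that only
in-focus structure is modulated by the stripes: the three phase-shifted
frames of each pattern orientation are a per-pixel homodyne (lock-in)
measurement of a sinusoid

    I_j(r) = C(r) + A(r)·cos(φ_j − ψ(r)),

whose offset-minus-amplitude `C − A` isolates the modulation-independent
background `I_dc = [O_out + (1 − m)·O_in] * H`.  That background is mapped,
low-pass filtered and subtracted from every raw frame, and a standard
Wiener-SIM engine (band separation via the phase mixing matrix, subpixel
band shifting, generalized Wiener combination with triangular apodization)
reconstructs the background-free frames.  The package targets microscopists
and method developers who want a transparent, fully scriptable SIM stack:
a forward simulator, pattern-parameter estimation, plain Wiener and
lock-in reconstruction, SBR/FWHM/spectral metrics, fiber-orientation
mapping, and optical-sectioning utilities for z/t stacks — everything
importable from Python, plus a thin `lockinsim` CLI.

Because the nine-frame two-beam acquisition sections optically without the
fifteen frames and doubled z-sampling a three-beam 3D acquisition needs,
volumetric imaging speeds up by (15×2)/(9×1) ≈ 3.3-fold.

## Worked example

```python
import numpy as np
import lockinsim as L

optical = L.build_optical_model(wavelength_nm=488, na=1.49, pixel_nm=65,
                                shape=(256, 256))
illum = L.default_illumination(optical, m=0.9)   # |k0| = 0.8 k_cutoff

scene = L.make_scene("crossed_filaments", {"n": 10}, seed=1, shape=(256, 256))
raw, widefield = L.render_sim_raw(
    scene, L.SimulationRecipe(optical=optical, illum=illum, seed=1))
hazy = L.inject_background(raw, widefield, level=1.0, optical=optical)

wiener = L.reconstruct_wiener(hazy, optical, params=illum)
lockin = L.reconstruct_lockin(hazy, optical, params=illum)

mask = np.kron(widefield > 0.1 * widefield.max(), np.ones((2, 2), dtype=bool))
print(L.sbr(wiener.sr_image, mask=mask).sbr_db)
print(L.sbr(lockin.sr_image, mask=mask).sbr_db)
```

prints

```
17.42...
25.96...
```

— the same scene with the same injected haze gains +8.5 dB of
signal-to-background ratio (SBR = 10·log10((max signal − mean background) /
sd background)) when the lock-in step removes the background before
reconstruction.  The `examples/` directory holds one short script per
capability (`background_removal.py`, `resolution_doubling.py`,
`optical_sectioning.py`, `orientation_mapping.py`,
`estimate_pattern_parameters.py`); each builds a small input, runs the
method and explains the numbers it prints.  `resolution_doubling.py`, for
instance, measures a 100-nm bead shrinking from 186 nm to 112 nm FWHM
(0.60×, ideal 1/1.8 ≈ 0.56×).

The CLI mirrors the library:

```bash
lockinsim simulate --kind crossed_filaments --size 256 --out scratch/sim
lockinsim reconstruct scratch/sim_raw.tif --mode lockin --out scratch/sr
lockinsim metrics scratch/sr.tif --out scratch/report.json
```

## Documentation

`docs/methods.md` describes the image-formation model, every estimator and
its defaults, the known biases (shifted-OTF attenuation of the lock-in
amplitude and the equalisation flag), the simulator's scope, and numerical
edge-case behaviour.
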