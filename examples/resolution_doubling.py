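"""Measure the resolution gain of SIM reconstruction on 100 nm beads.

Renders fluorescent microspheres, reconstructs them, and compares the full
width at half maximum (FWHM) of a bead in the widefield and super-resolved
images.  At pattern frequency 0.8x the OTF cutoff the passband extends 1.8x,
so the bead image should shrink to roughly 0.56x (untapered).
"""

import numpy as np

import lockinsim as L

optical = L.build_optical_model(488, 1.49, 65, (256, 256))
illum = L.default_illumination(optical, m=0.9)  # |k0| = 0.8 k_cutoff

scene = L.make_scene("beads", {"n": 25, "diameter_nm": 100}, seed=3, shape=(256, 256))
raw, widefield = L.render_sim_raw(
    scene, L.SimulationRecipe(optical=optical, illum=illum, seed=3)
)
result = L.reconstruct_wiener(
    raw, optical, params=illum, settings=L.ReconSettings(apodization="none")
)

center = np.asarray(scene.params["centers"][0])
fwhm_wf = L.fwhm(widefield, tuple(center), direction_deg=0, pixel_nm=65.0)
fwhm_sr = L.fwhm(result.sr_image, tuple(2 * center), direction_deg=0,
                 pixel_nm=result.pixel_nm)

print(f"widefield bead FWHM:     {fwhm_wf:6.1f} nm")
print(f"reconstructed bead FWHM: {fwhm_sr:6.1f} nm")
print(f"shrink factor:           {fwhm_sr / fwhm_wf:.2f}  (ideal 1/(1+0.8) = 0.56)")

default = L.reconstruct_wiener(raw, optical, params=illum)  # tapered passband
spec_wf = L.radial_spectrum(widefield)
spec_sr = L.radial_spectrum(default.sr_image)
u = default.settings.upsample
print(f"spectral cutoff: widefield {spec_wf.cutoff:.3f} cycles/px, "
      f"SIM {spec_sr.cutoff * u:.3f} cycles/px (same pixel scale)")
print("The SIM spectrum carries real signal beyond the widefield OTF support —")
print("that extension is the resolution doubling.")
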