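"""Remove out-of-focus background from a raw SIM stack by lock-in demodulation.

Simulates a crossed-filament scene, superimposes an unmodulated background
(emulating out-of-focus haze), reconstructs with plain Wiener-SIM and with
Lock-in-SIM, and compares the signal-to-background ratio of the two results.
"""

import numpy as np

import lockinsim as L

optical = L.build_optical_model(wavelength_nm=488, na=1.49, pixel_nm=65, shape=(256, 256))
illum = L.default_illumination(optical, m=0.9)

scene = L.make_scene("crossed_filaments", {"n": 10}, seed=1, shape=(256, 256))
raw, widefield = L.render_sim_raw(
    scene, L.SimulationRecipe(optical=optical, illum=illum, noise_sd=0.0, seed=1)
)
hazy = L.inject_background(raw, widefield, level=1.0, optical=optical)

wiener = L.reconstruct_wiener(hazy, optical, params=illum)
lockin = L.reconstruct_lockin(hazy, optical, params=illum)

# same structure mask (from the known ground truth) for both reconstructions
mask = np.kron(widefield > 0.1 * widefield.max(), np.ones((2, 2), dtype=bool))
sbr_w = L.sbr(wiener.sr_image, mask=mask)
sbr_l = L.sbr(lockin.sr_image, mask=mask)

print(f"Wiener-SIM   SBR: {sbr_w.sbr_db:6.2f} dB")
print(f"Lock-in-SIM  SBR: {sbr_l.sbr_db:6.2f} dB")
print(f"improvement:      {sbr_l.sbr_db - sbr_w.sbr_db:+.2f} dB")
print()
print("SBR = 10*log10((max(signal) - mean(background)) / sd(background));")
print("the gain is the background haze the lock-in step mapped and removed.")
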