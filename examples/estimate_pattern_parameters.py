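"""Recover illumination-pattern parameters from raw frames alone.

Simulates an acquisition with known pattern wave vectors, phases and
modulation depth, then estimates them back from the 9 raw frames — the
step every SIM reconstruction depends on.
"""

import numpy as np

import lockinsim as L

optical = L.build_optical_model(488, 1.49, 65, (256, 256))
truth = L.default_illumination(optical, m=0.9, angle0_deg=10.0)

scene = L.make_scene("crossed_filaments", {"n": 10}, seed=1, shape=(256, 256))
raw, _ = L.render_sim_raw(scene, L.SimulationRecipe(optical=optical, illum=truth, seed=1))

estimated = L.estimate_parameters(raw.plane(), optical)

for d in range(3):
    k_err = np.abs(estimated.k0[d] - truth.k0[d]).max()
    print(f"orientation {d}: |k0| = {np.hypot(*estimated.k0[d]):.4f} cycles/px "
          f"(error {k_err:.1e}), m = {estimated.m[d]:.3f} (true 0.900), "
          f"quality = {estimated.quality[d]:.2f}")
print()
print("k0 errors of ~1e-4 cycles/px keep band-shifting artifacts far below the")
print("noise floor; m calibrates the Wiener weights of the shifted bands.")
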