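"""Optical sectioning of a two-plane volume with per-plane Lock-in-SIM.

Renders a 3-D filament scene whose two slices are 1.8 um apart, acquires a
9-frame SIM stack focused at each plane, reconstructs with background
removal, and shows that each filament set lands in its true plane.  A
depth-coded projection summarises the volume in one image.
"""

import numpy as np

import lockinsim as L

optical = L.build_optical_model(488, 1.49, 65, (128, 128))
illum = L.default_illumination(optical, m=0.9)

scene3d = L.make_scene(
    "volume_filaments",
    {"n_planes": 2, "n_per_plane": 5, "z_step_um": 1.8},
    seed=4, shape=(128, 128),
)
volume = L.render_volume_stack(
    scene3d, L.SimulationRecipe(optical=optical, illum=illum, seed=4),
    z_planes_um=[0.0, 1.8],
)

sr_planes = []
for i, (stack, z) in enumerate(volume):
    result = L.reconstruct_lockin(stack, optical, params=illum)
    sr_planes.append(result.sr_image)
    in_plane = np.kron(scene3d.truth[i] > 0.3, np.ones((2, 2), dtype=bool))
    out_plane = np.kron(scene3d.truth[1 - i] > 0.3, np.ones((2, 2), dtype=bool)) & ~in_plane
    ratio = result.sr_image[in_plane].mean() / result.sr_image[out_plane].mean()
    print(f"focus {z:.1f} um: in-plane/out-of-plane intensity ratio = {ratio:.1f}")

rgb, depth = L.depth_code_projection(np.stack(sr_planes))
structure = np.max(np.stack(sr_planes), axis=0) > 0.1 * np.max(sr_planes)
truth_plane = np.argmax(
    np.stack([np.kron(scene3d.truth[i], np.ones((2, 2))) for i in range(2)]), axis=0
)
accuracy = (depth[structure] == truth_plane[structure]).mean()
print(f"depth-coded projection: {100 * accuracy:.1f}% of structure pixels "
      "assigned to their true plane")
print("Ratios well above 1 mean out-of-focus filaments are rejected — the")
print("optical sectioning that lock-in background removal provides.")
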