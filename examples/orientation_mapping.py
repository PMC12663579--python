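"""Map per-pixel fiber orientation with the weighted vector summation method.

Builds two orthogonal families of synthetic fibers, estimates the per-pixel
orientation field (7x7 window, 48 vectors per pixel), and reads the dominant
directions off the weighted orientation histogram.
"""

import numpy as np

import lockinsim as L
from lockinsim.simulate import _draw_segment


def fiber(angle_deg, shape=(96, 96)):
    img = np.zeros(shape)
    c = (shape[0] - 1) / 2
    a = np.deg2rad(angle_deg)
    r = 0.45 * shape[0]
    _draw_segment(img, (c - r * np.sin(a), c - r * np.cos(a)),
                  (c + r * np.sin(a), c + r * np.cos(a)), width_px=1.0)
    return img


image = fiber(30.0) + fiber(120.0)
field = L.orientation_field(image, window_px=7, intensity_threshold=0.4)
centers, freq, peaks = L.orientation_histogram(field)

print(f"valid pixels: {int(field.valid.sum())}")
print(f"dominant orientations: {peaks[0]:.1f} deg and {peaks[1]:.1f} deg")
print(f"angular spacing: {L.peak_spacing_deg(peaks):.1f} deg (constructed: 90)")
print()
print("theta is axial (0..180 deg); each peak marks one fiber family, and the")
print("weights favour vectors along which intensity stays uniform (the")
print("uniformity weight peaks at sqrt(1/3) for a perfectly flat profile).")
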