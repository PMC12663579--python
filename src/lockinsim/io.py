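"""File I/O: multi-page TIFF stacks with axis-layout strings, provenance
sidecars, and depth-coded projections.

Raw SIM data arrives as flat multi-page TIFFs whose page order depends on
the acquisition software.  A :class:`LayoutSpec` names that order with a
permutation string over the axes ``c`` (channel), ``t`` (time), ``z``
(focus), ``a`` (pattern angle) and ``p`` (pattern phase), fastest-varying
last, e.g. ``"zap"`` for z-major, phase-fastest.  Internally everything is
canonical ``(c, t, z, a, p, y, x)`` with phase fastest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .optics import OpticalModel, SIMRawStack

__all__ = [
    "LayoutSpec",
    "read_stack",
    "write_stack",
    "write_outputs",
    "depth_code_projection",
]

CANONICAL = "ctzap"


@dataclass(frozen=True)
class LayoutSpec:
    """Page ordering of a flat TIFF: axis permutation + per-axis counts.

    ``axis_order`` lists the non-trivial axes from slowest to fastest
    varying; omitted axes have count 1.
    """

    axis_order: str
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        order = self.axis_order
        if len(set(order)) != len(order):
            raise ValueError(f"axis repeated in layout {order!r}")
        if any(ax not in CANONICAL for ax in order):
            raise ValueError(f"layout axes must come from '{CANONICAL}'; got {order!r}")
        if len(self.counts) != len(order):
            raise ValueError("one count per axis required")
        if any(n < 1 for n in self.counts):
            raise ValueError("axis counts must be >= 1")

    @property
    def n_pages(self) -> int:
        return int(np.prod(self.counts)) if self.counts else 1

    def count(self, axis: str) -> int:
        return self.counts[self.axis_order.index(axis)] if axis in self.axis_order else 1


def read_stack(
    path: str | Path,
    layout: LayoutSpec,
    optical: OpticalModel | None = None,
) -> SIMRawStack:
    """Read a grayscale multi-page TIFF into a canonical raw stack.

    Pages are validated against the layout's expected count, reordered to
    (c, t, z, a, p, y, x), converted to float, and checked finite; small
    negative values (float inputs) are clipped at zero.
    """
    with tifffile.TiffFile(str(path)) as tf:
        if tf.pages[0].samplesperpixel != 1:
            raise ValueError(
                "RGB/multisample TIFFs are not supported; expected grayscale pages"
            )
        pages = tf.asarray()
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(
            f"expected grayscale pages; got array with {pages.ndim} axes"
        )
    n_found = pages.shape[0]
    if n_found != layout.n_pages:
        raise ValueError(
            f"page-count mismatch: layout expects {layout.n_pages} pages, file has {n_found}"
        )
    ny, nx = pages.shape[1:]
    data = np.asarray(pages, dtype=float).reshape(*layout.counts, ny, nx)
    # expand omitted axes, then permute into canonical order
    full_order = layout.axis_order
    for ax in CANONICAL:
        if ax not in full_order:
            data = data[None]
            full_order = ax + full_order
    perm = [full_order.index(ax) for ax in CANONICAL] + [5, 6]
    data = np.transpose(data, perm)
    if not np.all(np.isfinite(data)):
        raise ValueError("stack contains non-finite values")
    return SIMRawStack(np.clip(data, 0.0, None), optical=optical)


def write_stack(stack: SIMRawStack, path: str | Path) -> None:
    """Write a canonical stack as a flat float32 TIFF (canonical page order)."""
    ny, nx = stack.frame_shape
    pages = stack.data.reshape(-1, ny, nx).astype(np.float32)
    tifffile.imwrite(str(path), pages)


def write_outputs(result, path_prefix: str | Path) -> dict[str, Path]:
    """Write a reconstruction as TIFF + JSON provenance sidecar.

    The TIFF carries the effective pixel size in its resolution tags
    (pixels per centimetre); the sidecar stores every parameter needed to
    reproduce the reconstruction bit-for-bit.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tif_path = prefix.with_suffix(".tif")
    json_path = prefix.with_suffix(".json")
    px_cm = 1e7 / result.pixel_nm  # pixels per centimetre
    tifffile.imwrite(
        str(tif_path),
        result.sr_image.astype(np.float32),
        resolution=(px_cm, px_cm),
        resolutionunit="CENTIMETER",
    )
    sidecar = {
        "pixel_nm": result.pixel_nm,
        "algorithm": result.algorithm,
        "clipped_mass": result.clipped_mass,
        "provenance": result.provenance,
    }
    json_path.write_text(json.dumps(sidecar, indent=2))
    return {"image": tif_path, "provenance": json_path}


def depth_code_projection(
    sr_stack: np.ndarray,
    colormap: str = "turbo",
) -> tuple[np.ndarray, np.ndarray]:
    """Depth-coded maximum intensity projection of a (z, y, x) stack.

    Per pixel, hue encodes the z index of the intensity maximum and
    brightness the normalised maximum itself.  Returns ``(rgb, depth)``
    where ``rgb`` is (y, x, 3) in [0, 1] and ``depth`` the argmax z map.
    Raises for fewer than two planes (use a plain projection instead).
    """
    sr_stack = np.asarray(sr_stack, dtype=float)
    if sr_stack.ndim != 3 or sr_stack.shape[0] < 2:
        raise ValueError(
            "depth coding needs a (z, y, x) stack with >= 2 planes; "
            "for a single plane use the image directly"
        )
    import matplotlib

    nz = sr_stack.shape[0]
    depth = np.argmax(sr_stack, axis=0)
    peak = np.max(sr_stack, axis=0)
    vmax = peak.max()
    value = peak / vmax if vmax > 0 else peak
    cmap = matplotlib.colormaps[colormap]
    rgb = cmap(depth / (nz - 1))[..., :3] * value[..., None]
    return rgb, depth
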