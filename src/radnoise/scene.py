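"""Synthetic chest scene: lung fields, rib bands and a liver block.

The scene stands in for an anthropomorphic chest phantom imaged in the AP
projection.  "Level" means detector signal, so transmissive regions are
bright: lungs are the brightest, the liver (thick soft tissue) the darkest,
and ribs sit between the two where they cross the lung fields.  Region edges
are smoothed with a Gaussian of ``edge_blur`` pixels so that line-profile edge
metrics see a finite-width transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .radiograph import InvalidArgumentError


@dataclass(frozen=True)
class ChestSceneSpec:
    """Geometry and signal levels of the synthetic chest scene.

    Levels are detector units at the reference mAs.  ``lung_ellipses`` are
    ``(row, col, semi_row, semi_col)`` in pixels; rib bands span
    ``rib_col_range`` horizontally but are painted only inside the lung
    fields; ``liver_box`` is ``(row0, col0, height, width)``.
    """

    shape: tuple[int, int] = (512, 512)
    background_level: float = 1000.0
    lung_level: float = 2800.0
    rib_level: float = 1600.0
    liver_level: float = 700.0
    lung_ellipses: tuple[tuple[float, float, float, float], ...] = (
        (220.0, 150.0, 140.0, 90.0),
        (220.0, 362.0, 140.0, 90.0),
    )
    rib_rows: tuple[float, ...] = (90.0, 160.0, 230.0, 300.0)
    rib_height: float = 20.0
    rib_col_range: tuple[float, float] = (36.0, 476.0)
    liver_box: tuple[float, float, float, float] = (380.0, 60.0, 120.0, 392.0)
    edge_blur: float = 2.0

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if rows < 1 or cols < 1:
            raise InvalidArgumentError("scene shape must be positive")
        for name in ("background_level", "lung_level", "rib_level", "liver_level"):
            if not getattr(self, name) > 0:
                raise InvalidArgumentError(f"{name} must be > 0")
        if not self.lung_level > self.rib_level:
            raise InvalidArgumentError("lung_level must exceed rib_level (lungs transmit more)")
        if not self.lung_level > self.liver_level:
            raise InvalidArgumentError("lung_level must exceed liver_level")
        if self.edge_blur < 0:
            raise InvalidArgumentError("edge_blur must be >= 0")
        for (r, c, sr, sc) in self.lung_ellipses:
            if sr <= 0 or sc <= 0:
                raise InvalidArgumentError("lung ellipse semi-axes must be > 0")
            if r - sr < 0 or r + sr > rows or c - sc < 0 or c + sc > cols:
                raise InvalidArgumentError("lung ellipse out of image bounds")
        for r0 in self.rib_rows:
            if r0 < 0 or r0 + self.rib_height > rows:
                raise InvalidArgumentError("rib band out of image bounds")
        c0, c1 = self.rib_col_range
        if not (0 <= c0 < c1 <= cols):
            raise InvalidArgumentError("rib column range out of image bounds")
        lr0, lc0, lh, lw = self.liver_box
        if lr0 < 0 or lc0 < 0 or lr0 + lh > rows or lc0 + lw > cols or lh <= 0 or lw <= 0:
            raise InvalidArgumentError("liver box out of image bounds")


def render_chest_scene(spec: ChestSceneSpec, mas: float, ref_mas: float) -> np.ndarray:
    """Noiseless chest scene scaled to ``mas`` by exposure reciprocity.

    Signal is linear in mAs through the reference: every level is multiplied
    by ``mas / ref_mas``.  Returned as a float64 array of ``spec.shape``.
    """
    if not mas > 0 or not ref_mas > 0:
        raise InvalidArgumentError("mas and ref_mas must be > 0")
    rows, cols = spec.shape
    rr, cc = np.mgrid[0:rows, 0:cols].astype(np.float64)

    img = np.full(spec.shape, spec.background_level, dtype=np.float64)

    lung_mask = np.zeros(spec.shape, dtype=bool)
    for (r, c, sr, sc) in spec.lung_ellipses:
        lung_mask |= ((rr - r) / sr) ** 2 + ((cc - c) / sc) ** 2 <= 1.0
    img[lung_mask] = spec.lung_level

    c0, c1 = spec.rib_col_range
    rib_mask = np.zeros(spec.shape, dtype=bool)
    for r0 in spec.rib_rows:
        rib_mask |= (rr >= r0) & (rr < r0 + spec.rib_height) & (cc >= c0) & (cc < c1)
    img[rib_mask & lung_mask] = spec.rib_level

    lr0, lc0, lh, lw = spec.liver_box
    liver_mask = (rr >= lr0) & (rr < lr0 + lh) & (cc >= lc0) & (cc < lc0 + lw)
    img[liver_mask] = spec.liver_level

    if spec.edge_blur > 0:
        img = gaussian_filter(img, spec.edge_blur)
    return img * (mas / ref_mas)
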