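"""Noise-only subtraction metrics, line profiles and exposure bookkeeping.

Implements the chest-phantom analyses: repeat-subtraction noise-only images,
per-ROI standard deviations and noise-reduction percentages, width-averaged
line profiles with a 10-90% rise-distance edge metric, pixel-identity
detection for collapsing redundant parameter settings, and the deviation
index DI = 10*log10(EI / EI_target).

Conventions: coordinates are 0-based, row-major, half-open; geometry is in
pixel units and converted to mm only in outputs; ROI statistics use the
sample (n-1) standard deviation; noise reduction is reported positive when
noise decreases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .radiograph import InvalidArgumentError, Radiograph


class BoundsError(InvalidArgumentError):
    """An ROI or sampling band exits the image."""


class NoEdgeError(ValueError):
    """A line profile has no detectable plateau-to-plateau edge."""


@dataclass(frozen=True)
class ROISpec:
    """Rectangular region of interest: rows [row0, row0+height), cols likewise."""

    label: str
    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 2 or self.width < 2:
            raise InvalidArgumentError("ROI height and width must be >= 2")
        if self.row0 < 0 or self.col0 < 0:
            raise InvalidArgumentError("ROI corner must be non-negative")

    def extract(self, img: Radiograph) -> np.ndarray:
        rows, cols = img.shape
        if self.row0 + self.height > rows or self.col0 + self.width > cols:
            raise BoundsError(
                f"ROI {self.label!r} ({self.row0}:{self.row0 + self.height}, "
                f"{self.col0}:{self.col0 + self.width}) exceeds image {img.shape}"
            )
        return img.pixels[self.row0:self.row0 + self.height, self.col0:self.col0 + self.width]


@dataclass(frozen=True)
class NoiseReductionResult:
    """Per-ROI noise reduction of a processed image relative to baseline."""

    roi: str
    sd_baseline: float
    sd_processed: float

    @property
    def reduction_percent(self) -> float:
        return noise_reduction_percent(self.sd_baseline, self.sd_processed)


@dataclass(frozen=True)
class LineProfile:
    """Width-averaged intensity profile along a segment.

    ``positions`` are mm along the segment (strictly increasing, uniform);
    ``values`` the averaged intensities; ``width_pixels`` the number of
    perpendicular unit-spaced samples averaged at each position.
    """

    positions: np.ndarray
    values: np.ndarray
    width_pixels: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=np.float64))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))
        if self.positions.shape != self.values.shape or self.positions.ndim != 1:
            raise InvalidArgumentError("positions and values must be 1D of equal length")
        d = np.diff(self.positions)
        if len(d) and (np.any(d <= 0) or not np.allclose(d, d[0])):
            raise InvalidArgumentError("positions must be strictly increasing and uniform")


def subtract_repeats(a: Radiograph, b: Radiograph) -> Radiograph:
    """Pixel-wise a - b: the noise-only image of a repeated pair.

    No variance rescaling is applied here; consumers account for the sqrt(2)
    factor (or the factor 2 in power) where needed.
    """
    if a.shape != b.shape:
        raise InvalidArgumentError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.pixel_pitch != b.pixel_pitch:
        raise InvalidArgumentError("pixel pitch mismatch")
    return a.with_pixels(a.pixels - b.pixels, label=f"{a.label}_subtraction")


def roi_sd(img: Radiograph, roi: ROISpec) -> float:
    """Sample standard deviation (n-1 denominator) of the ROI pixels."""
    return float(np.std(roi.extract(img), ddof=1))


def noise_reduction_percent(sd_baseline: float, sd_processed: float) -> float:
    """100 * (sd_baseline - sd_processed) / sd_baseline.

    Positive when noise is reduced; negative values (amplification) are
    reported as-is, never clipped.
    """
    if not sd_baseline > 0:
        raise InvalidArgumentError("sd_baseline must be > 0")
    if sd_processed < 0:
        raise InvalidArgumentError("sd_processed must be >= 0")
    return 100.0 * (sd_baseline - sd_processed) / sd_baseline


def extract_line_profile(
    img: Radiograph,
    start: tuple[float, float],
    end: tuple[float, float],
    width_pixels: int = 1,
    samples: int = 100,
) -> LineProfile:
    """Bilinear line profile from ``start`` to ``end`` (row, col) in pixels.

    ``samples`` uniform points on the segment, each averaged over
    ``width_pixels`` (odd) perpendicular offsets at unit-pixel spacing.
    Positions are mm from ``start`` via the pixel pitch.
    """
    if samples < 2:
        raise InvalidArgumentError("samples must be >= 2")
    if width_pixels < 1 or width_pixels % 2 == 0:
        raise InvalidArgumentError("width_pixels must be odd and >= 1")
    r0, c0 = float(start[0]), float(start[1])
    r1, c1 = float(end[0]), float(end[1])
    length = float(np.hypot(r1 - r0, c1 - c0))
    if length == 0:
        raise InvalidArgumentError("start and end coincide")
    t = np.linspace(0.0, 1.0, samples)
    rr = r0 + t * (r1 - r0)
    cc = c0 + t * (c1 - c0)
    # unit perpendicular
    pr, pc = -(c1 - c0) / length, (r1 - r0) / length
    half = width_pixels // 2
    offsets = np.arange(-half, half + 1, dtype=np.float64)
    sample_r = rr[None, :] + offsets[:, None] * pr
    sample_c = cc[None, :] + offsets[:, None] * pc
    rows, cols = img.shape
    if (sample_r.min() < 0 or sample_c.min() < 0
            or sample_r.max() > rows - 1 or sample_c.max() > cols - 1):
        raise BoundsError("profile band exits the image")
    vals = map_coordinates(img.pixels, [sample_r.ravel(), sample_c.ravel()], order=1)
    values = vals.reshape(sample_r.shape).mean(axis=0)
    positions = t * length * img.pixel_pitch
    return LineProfile(positions, values, width_pixels)


def edge_rise_distance(profile: LineProfile) -> float:
    """10-90% rise distance (mm) of a plateau-to-plateau edge profile.

    Plateau levels are the 10th and 90th percentiles of the pooled first and
    last quartile of samples (robust to noise); the 10% and 90% crossings of
    the span are located by linear interpolation.  For a step blurred by a
    Gaussian of standard deviation sigma the distance is 2*z_0.9*sigma =
    2.5631*sigma.  Invariant to intensity offset and positive rescaling.

    Raises :class:`NoEdgeError` when the plateau span is below 5x the plateau
    noise standard deviation.
    """
    v = profile.values
    pos = profile.positions
    n = len(v)
    q = max(2, n // 4)
    head, tail = v[:q], v[-q:]
    pooled = np.concatenate([head, tail])
    low = float(np.percentile(pooled, 10))
    high = float(np.percentile(pooled, 90))
    span = high - low
    noise_sd = float(np.sqrt((np.var(head, ddof=1) + np.var(tail, ddof=1)) / 2.0))
    if span < 5.0 * noise_sd or span <= 0:
        raise NoEdgeError("plateau span below 5x profile noise SD: no detectable edge")
    rising = float(np.mean(tail)) > float(np.mean(head))
    w = v if rising else v[::-1]
    p = pos if rising else (pos[-1] - pos[::-1])

    def _crossing(level: float) -> float:
        above = np.nonzero(w >= level)[0]
        if len(above) == 0 or above[0] == 0:
            return float(p[0]) if len(above) else float(p[-1])
        i = above[0]
        frac = (level - w[i - 1]) / (w[i] - w[i - 1])
        return float(p[i - 1] + frac * (p[i] - p[i - 1]))

    x10 = _crossing(low + 0.1 * span)
    x90 = _crossing(low + 0.9 * span)
    return abs(x90 - x10)


def options_identical(a: Radiograph, b: Radiograph, quantization_step: float = 0.0) -> bool:
    """True iff two processed images are pixel-identical.

    With ``quantization_step == 0`` this is exact float equality.  With a
    positive step it is true when the maximum absolute difference does not
    exceed half a step — i.e. the images cannot be told apart in the
    quantized output representation.
    """
    if a.shape != b.shape:
        raise InvalidArgumentError(f"shape mismatch: {a.shape} vs {b.shape}")
    if quantization_step < 0:
        raise InvalidArgumentError("quantization_step must be >= 0")
    if quantization_step == 0:
        return bool(np.array_equal(a.pixels, b.pixels))
    return bool(np.max(np.abs(a.pixels - b.pixels)) <= quantization_step / 2.0)


def quantize(pixels: np.ndarray, step: float) -> np.ndarray:
    """Round pixel values to the nearest multiple of ``step`` (as integers)."""
    if not step > 0:
        raise InvalidArgumentError("step must be > 0")
    return np.round(np.asarray(pixels, dtype=np.float64) / step).astype(np.int64)


def group_identical(
    images: dict[str, Radiograph], quantization_step: float = 0.0
) -> list[list[str]]:
    """Partition labelled images into pixel-identical equivalence classes.

    Classes are the transitive closure of pairwise :func:`options_identical`;
    on denoiser outputs the within-class differences are orders of magnitude
    below the step and between-class differences orders above it, so the
    closure coincides with the pairwise relation.  Class members are sorted,
    classes ordered by first appearance.
    """
    names = list(images)
    parent = {n: n for n in names}

    def find(n: str) -> str:
        while parent[n] != n:
            parent[n] = parent[parent[n]]
            n = parent[n]
        return n

    for i, ni in enumerate(names):
        for nj in names[i + 1:]:
            if find(ni) != find(nj) and options_identical(images[ni], images[nj], quantization_step):
                parent[find(nj)] = find(ni)

    classes: dict[str, list[str]] = {}
    order: list[str] = []
    for n in names:
        root = find(n)
        if root not in classes:
            classes[root] = []
            order.append(root)
        classes[root].append(n)
    return [sorted(classes[r]) for r in order]


def deviation_index(ei: float, target_ei: float) -> float:
    """DI = 10 * log10(EI / EI_target); 0 at target exposure."""
    if not ei > 0 or not target_ei > 0:
        raise InvalidArgumentError("exposure indices must be > 0")
    return float(10.0 * np.log10(ei / target_ei))


def synthetic_exposure_index(mas: float, ref_mas: float, target_ei: float = 625.0) -> float:
    """Linear-in-mAs synthetic exposure index, equal to the target at ref_mas."""
    if not mas > 0 or not ref_mas > 0 or not target_ei > 0:
        raise InvalidArgumentError("mas, ref_mas and target_ei must be > 0")
    return target_ei * mas / ref_mas
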