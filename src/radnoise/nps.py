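"""Noise power spectrum estimation with circularly arranged ROIs.

The NPS of a noise image is estimated from n (default 10) square ROIs
(default 128 x 128 px) whose centers lie on a circle (default diameter
600 px) around the image center.  Each ROI is detrended (mean or
least-squares plane), no taper window is applied, and

    NPS_roi = pitch**2 / (Nr * Nc) * |DFT2(roi)|**2

is averaged over ROIs.  When the input is a repeat-subtraction (noise-only)
image the result is divided by 2, since differencing two equal-noise images
doubles the variance.  Frequency axes are DC-centered in cycles/mm; the
Nyquist frequency is 1/(2*pitch).  The integral of the 2D NPS over frequency
equals the mean detrended ROI variance (Parseval; exact for mean
detrending).

The radial average assigns every off-DC 2D bin to the radial bin of its
frequency magnitude (default bin width = the ROI frequency resolution
1/(roi_size*pitch)); empty bins are NaN, never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .radiograph import InvalidArgumentError, Radiograph
from .metrics import subtract_repeats


class GeometryError(InvalidArgumentError):
    """The image cannot hold the requested ROI arrangement."""


class NoPeakError(ValueError):
    """A radial profile has no identifiable spectral peak (all zero)."""


@dataclass(frozen=True)
class NPSGeometry:
    """Circular ROI arrangement for NPS estimation.

    ``n_rois`` ROI centers at angles 2*pi*k/n_rois on a circle of
    ``circle_diameter`` px around ``center`` (image center when None),
    rounded to the nearest pixel.  The image must be at least
    ``circle_diameter + roi_size`` on each side.
    """

    n_rois: int = 10
    roi_size: int = 128
    circle_diameter: float = 600.0
    center: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.n_rois < 1:
            raise InvalidArgumentError("n_rois must be >= 1")
        if self.roi_size < 16 or self.roi_size % 2 != 0:
            raise InvalidArgumentError("roi_size must be even and >= 16")
        if self.circle_diameter < 0:
            raise InvalidArgumentError("circle_diameter must be >= 0")

    @property
    def min_side(self) -> int:
        return int(np.ceil(self.circle_diameter)) + self.roi_size


@dataclass
class NPSResult:
    """2D NPS with frequency axes plus its radial average and summary metrics.

    ``nps2d`` in detector-units^2 * mm^2 on DC-centered axes ``fu`` (rows) and
    ``fv`` (columns), cycles/mm.  ``freq`` / ``nps1d`` / ``counts`` hold the
    radial average (NaN where a radial bin received no samples).
    ``variance_integral`` is sum(nps2d) * du * dv.  ``peak_frequency`` is None
    until the radial profile is computed, or for an all-zero spectrum.
    """

    nps2d: np.ndarray
    fu: np.ndarray
    fv: np.ndarray
    pitch: float
    n_rois_used: int
    variance_integral: float
    freq: np.ndarray | None = None
    nps1d: np.ndarray | None = None
    counts: np.ndarray | None = None
    peak_frequency: float | None = None

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.pitch)


def extract_circular_rois(img: Radiograph, geom: NPSGeometry = NPSGeometry()) -> list[np.ndarray]:
    """ROI pixel blocks at centers on the configured circle.

    Center k sits at ``center + (R*sin(theta_k), R*cos(theta_k))``,
    theta_k = 2*pi*k/n_rois, rounded to the nearest pixel.  Neighboring ROIs
    may overlap.
    """
    rows, cols = img.shape
    if rows < geom.min_side or cols < geom.min_side:
        raise GeometryError(
            f"image {img.shape} too small for NPS geometry: each side must be "
            f">= circle_diameter + roi_size = {geom.min_side}"
        )
    cr, cc = geom.center if geom.center is not None else (rows // 2, cols // 2)
    radius = geom.circle_diameter / 2.0
    half = geom.roi_size // 2
    blocks = []
    for k in range(geom.n_rois):
        theta = 2.0 * np.pi * k / geom.n_rois
        r = int(round(cr + radius * np.sin(theta)))
        c = int(round(cc + radius * np.cos(theta)))
        r0, c0 = r - half, c - half
        if r0 < 0 or c0 < 0 or r0 + geom.roi_size > rows or c0 + geom.roi_size > cols:
            raise GeometryError(
                f"ROI {k} at center ({r}, {c}) exceeds image {img.shape}; "
                f"minimum side is {geom.min_side}"
            )
        blocks.append(img.pixels[r0:r0 + geom.roi_size, c0:c0 + geom.roi_size])
    return blocks


def _detrend(block: np.ndarray, mode: str) -> np.ndarray:
    if mode == "mean":
        return block - block.mean()
    if mode == "plane":
        nr, nc = block.shape
        rr, cc = np.mgrid[0:nr, 0:nc]
        design = np.column_stack([np.ones(block.size), rr.ravel(), cc.ravel()])
        coef, *_ = np.linalg.lstsq(design, block.ravel(), rcond=None)
        return block - (design @ coef).reshape(block.shape)
    raise InvalidArgumentError(f"detrend must be 'mean' or 'plane', got {mode!r}")


def nps_2d(
    blocks: list[np.ndarray],
    pitch: float,
    detrend: str = "plane",
    pair_subtraction: bool = False,
) -> NPSResult:
    """Average 2D NPS of ROI blocks (no taper window).

    ``pair_subtraction=True`` halves the spectrum, converting the NPS of a
    repeat-subtraction image into that of a single acquisition.
    """
    if not blocks:
        raise InvalidArgumentError("at least one block required")
    if not pitch > 0:
        raise InvalidArgumentError("pitch must be > 0")
    shape = np.asarray(blocks[0]).shape
    if any(np.asarray(b).shape != shape for b in blocks):
        raise InvalidArgumentError("all blocks must have identical shape")
    nr, nc = shape
    acc = np.zeros(shape, dtype=np.float64)
    for b in blocks:
        d = _detrend(np.asarray(b, dtype=np.float64), detrend)
        acc += np.abs(np.fft.fft2(d)) ** 2
    nps = (pitch ** 2) / (nr * nc) * acc / len(blocks)
    if pair_subtraction:
        nps = nps / 2.0
    nps = np.fft.fftshift(nps)
    fu = np.fft.fftshift(np.fft.fftfreq(nr, d=pitch))
    fv = np.fft.fftshift(np.fft.fftfreq(nc, d=pitch))
    du, dv = 1.0 / (nr * pitch), 1.0 / (nc * pitch)
    return NPSResult(
        nps2d=nps, fu=fu, fv=fv, pitch=pitch, n_rois_used=len(blocks),
        variance_integral=float(nps.sum() * du * dv),
    )


def radial_average(result: NPSResult, bin_width: float | None = None) -> NPSResult:
    """Fill in the radially averaged 1D NPS (and peak frequency) of a result.

    Default bin width is the ROI frequency resolution.  The DC sample is
    excluded; empty bins are NaN.  Returns the same result object, updated.
    """
    nr = result.nps2d.shape[0]
    if bin_width is None:
        bin_width = 1.0 / (nr * result.pitch)
    if not bin_width > 0:
        raise InvalidArgumentError("bin_width must be > 0")
    uu, vv = np.meshgrid(result.fu, result.fv, indexing="ij")
    radius = np.hypot(uu, vv)
    mask = radius > 0  # exclude DC
    idx = np.floor(radius[mask] / bin_width).astype(np.int64)
    vals = result.nps2d[mask]
    nbins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=nbins)
    sums = np.bincount(idx, weights=vals, minlength=nbins)
    with np.errstate(invalid="ignore"):
        profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    freq = (np.arange(nbins) + 0.5) * bin_width
    result.freq = freq
    result.nps1d = profile
    result.counts = counts
    try:
        result.peak_frequency = peak_frequency(freq, profile)
    except NoPeakError:
        result.peak_frequency = None
    return result


def peak_frequency(freq: np.ndarray, nps1d: np.ndarray) -> float:
    """Frequency of the radial-profile maximum after 3-bin smoothing.

    NaN (empty) bins are dropped first; ties break toward the lower
    frequency.  Raises :class:`NoPeakError` for an all-zero profile.
    """
    freq = np.asarray(freq, dtype=np.float64)
    vals = np.asarray(nps1d, dtype=np.float64)
    keep = np.isfinite(vals)
    freq, vals = freq[keep], vals[keep]
    if len(vals) < 3:
        raise InvalidArgumentError("need at least 3 radial bins")
    if np.all(vals == 0):
        raise NoPeakError("all-zero radial profile has no peak")
    kernel = np.ones(3)
    smooth = np.convolve(vals, kernel, mode="same") / np.convolve(np.ones_like(vals), kernel, mode="same")
    return float(freq[int(np.argmax(smooth))])  # argmax takes first (lowest) on ties


def texture_nps(
    processed: Radiograph,
    baseline: Radiograph,
    geom: NPSGeometry = NPSGeometry(),
    detrend: str = "plane",
) -> NPSResult:
    """NPS of processed - baseline: the spectrum of what processing changed.

    No pair-subtraction halving: the difference image itself is the object of
    interest, not an estimate of acquisition noise.
    """
    diff = subtract_repeats(processed, baseline)
    blocks = extract_circular_rois(diff, geom)
    return radial_average(nps_2d(blocks, diff.pixel_pitch, detrend=detrend, pair_subtraction=False))


def repeat_subtraction_nps(
    a: Radiograph,
    b: Radiograph,
    geom: NPSGeometry = NPSGeometry(),
    detrend: str = "plane",
) -> NPSResult:
    """Single-acquisition NPS estimated from a repeated pair (a - b, halved)."""
    diff = subtract_repeats(a, b)
    blocks = extract_circular_rois(diff, geom)
    return radial_average(nps_2d(blocks, diff.pixel_pitch, detrend=detrend, pair_subtraction=True))


def high_frequency_index(result: NPSResult, cutoff_fraction: float = 0.5) -> float:
    """Integrated NPS above ``cutoff_fraction`` of Nyquist (detector-units^2).

    Measures high-frequency texture content; 0 for an identity processing's
    texture NPS, and approaching the full variance integral as the cutoff
    fraction approaches 0.
    """
    if not 0.0 < cutoff_fraction < 1.0:
        raise InvalidArgumentError("cutoff_fraction must be in (0, 1)")
    uu, vv = np.meshgrid(result.fu, result.fv, indexing="ij")
    radius = np.hypot(uu, vv)
    nr, nc = result.nps2d.shape
    du, dv = 1.0 / (nr * result.pitch), 1.0 / (nc * result.pitch)
    sel = radius > cutoff_fraction * result.nyquist
    return float(result.nps2d[sel].sum() * du * dv)
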