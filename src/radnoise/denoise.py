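"""Surrogate of the vendor's four-parameter multi-band noise reduction (FNC).

The true algorithm is proprietary; this surrogate reproduces its documented
*behaviors* with fully specified math so that every downstream analysis is
exercisable.  An image is decomposed into a Gaussian band-pass stack (four
octave bands plus a low-pass residual, an exact decomposition), and each band
is attenuated by a factor

    s = enhancement * w_band(balance) * d(filter_control, mas/ref_mas)
        * rho(density_type, local mean)

clipped to [0, 1], gated off near strong edges.  The four parameters mirror
the vendor semantics:

* ``filter_control`` — C: dose-independent, d = 1; F: granularity-oriented,
  d = min(cap, r**-alpha) with r = mas/ref_mas, so suppression strictly
  increases as dose decreases.
* ``balance`` — per-band weight vector over spatial-frequency bands
  (G uniform; A/C/E progressively low/mid/high-frequency weighted).
* ``density_type`` — A: constant in density; B: suppression ramps down above
  the reference density (bright regions protected); C: ramps down below it
  (dark regions protected).  The reference density is the image median and
  the local density is a heavily smoothed mean, so on a flat-field image all
  three types coincide to within a fraction of a quantization step — the
  redundancy observed on uniform phantoms.
* ``enhancement`` — overall amount in [0, 1]; 0 is a bit-identical
  passthrough.

Edge protection: band attenuation is multiplied by
``exp(-(|grad| / tau)**4)`` where ``tau`` scales with a robust estimate of
the noise-induced gradient magnitude, so noise is smoothed while resolved
edges (gradient well above the noise floor) pass through unfiltered.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .radiograph import InvalidArgumentError, Radiograph

#: Band-pass stack scales in pixels, finest to coarsest.
BAND_SIGMAS: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)

#: Per-band weights (finest band first) for each balance option.
BALANCE_WEIGHTS: dict[str, tuple[float, ...]] = {
    "G": (1.0, 1.0, 1.0, 1.0),
    "A": (0.4, 0.7, 0.9, 1.0),   # low-frequency weighted
    "C": (0.7, 1.0, 1.0, 0.7),   # mid-frequency weighted
    "E": (1.0, 0.9, 0.7, 0.4),   # high-frequency weighted
}

FILTER_CONTROLS = ("C", "F")
DENSITY_TYPES = ("A", "B", "C")

#: Dose-adaptivity exponent and cap for filter control F.
DOSE_ALPHA = 0.5
DOSE_CAP = 2.0

#: Density ramp: depth of suppression loss and ramp width as fraction of the
#: reference density.
DENSITY_DEPTH = 0.8
DENSITY_WIDTH_FRAC = 0.5
#: Smoothing scale (pixels) of the local-density map.
DENSITY_SIGMA = 32.0

#: Edge gate: gradient scale multiplier over the noise gradient floor.
EDGE_K = 5.0
EDGE_POWER = 4
GRAD_SIGMA = 1.5

_CODE_RE = re.compile(r"^([CF])([ACEG])([ABC])(\d(?:\.\d+)?)$")


@dataclass(frozen=True)
class DenoiserParams:
    """Four-parameter setting of the surrogate denoiser.

    The compact code string concatenates the options, e.g. ``"FGA0.5"`` =
    filter control F, balance G, density type A, enhancement 0.5.
    """

    filter_control: str
    balance: str
    density_type: str
    enhancement: float

    def __post_init__(self) -> None:
        if self.filter_control not in FILTER_CONTROLS:
            raise InvalidArgumentError(f"filter_control must be one of {FILTER_CONTROLS}")
        if self.balance not in BALANCE_WEIGHTS:
            raise InvalidArgumentError(f"balance must be one of {tuple(BALANCE_WEIGHTS)}")
        if self.density_type not in DENSITY_TYPES:
            raise InvalidArgumentError(f"density_type must be one of {DENSITY_TYPES}")
        if not 0.0 <= self.enhancement <= 1.0:
            raise InvalidArgumentError("enhancement must be in [0, 1]")

    @property
    def code(self) -> str:
        e = self.enhancement
        text = f"{e:g}" if e != int(e) else f"{e:.1f}"
        return f"{self.filter_control}{self.balance}{self.density_type}{text}"

    @classmethod
    def from_code(cls, code: str) -> "DenoiserParams":
        m = _CODE_RE.match(code.strip())
        if m is None:
            raise InvalidArgumentError(f"cannot parse denoiser code {code!r}")
        return cls(m.group(1), m.group(2), m.group(3), float(m.group(4)))


def band_decompose(pixels: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
    """Gaussian band-pass stack: returns (bands finest→coarsest, low-pass).

    The decomposition is exact: ``sum(bands) + low == pixels``.
    """
    smoothed = [np.asarray(pixels, dtype=np.float64)]
    for sigma in BAND_SIGMAS:
        smoothed.append(gaussian_filter(smoothed[0], sigma))
    bands = [smoothed[i] - smoothed[i + 1] for i in range(len(BAND_SIGMAS))]
    return bands, smoothed[-1]


def dose_factor(filter_control: str, mas_ratio: float) -> float:
    """d(FFC, r): 1 for C; min(cap, r**-alpha) for F (stronger at low dose)."""
    if not mas_ratio > 0:
        raise InvalidArgumentError("mas ratio must be > 0")
    if filter_control == "C":
        return 1.0
    return float(min(DOSE_CAP, mas_ratio ** (-DOSE_ALPHA)))


def density_factor(density_type: str, local_mean: np.ndarray, ref_level: float) -> np.ndarray:
    """rho(FNT, v): one-sided ramps around the reference density.

    A is identically 1; B decreases linearly from 1 to 1-depth as the local
    mean rises from the reference to reference*(1+width); C mirrors it below
    the reference.  Both are 1 *at* the reference, so on a uniform image all
    density types act identically.
    """
    if density_type == "A":
        return np.ones_like(local_mean)
    width = DENSITY_WIDTH_FRAC * ref_level
    if density_type == "B":
        t = np.clip((local_mean - ref_level) / width, 0.0, 1.0)
    else:  # "C"
        t = np.clip((ref_level - local_mean) / width, 0.0, 1.0)
    return 1.0 - DENSITY_DEPTH * t


def edge_gate(pixels: np.ndarray) -> np.ndarray:
    """Attenuation gate in [0, 1]: 1 in noise-like areas, → 0 at strong edges.

    The gradient magnitude of a lightly smoothed image is compared with a
    robust (median-based) estimate of its noise floor; gradients several
    times the floor are treated as resolved structure and protected.
    """
    sm = gaussian_filter(pixels, GRAD_SIGMA)
    gr, gc = np.gradient(sm)
    gmag = np.hypot(gr, gc)
    floor = float(np.median(gmag))
    tau = EDGE_K * floor + 1e-9
    with np.errstate(over="ignore"):
        return np.exp(-((gmag / tau) ** EDGE_POWER))


def apply_surrogate_denoiser(img: Radiograph, params: DenoiserParams, ref_mas: float) -> Radiograph:
    """Apply the surrogate multi-band denoiser to a radiograph.

    ``ref_mas`` anchors the dose-adaptivity of filter control F (the station
    at which d = 1).  ``enhancement == 0`` returns a bit-identical copy.
    """
    if not ref_mas > 0:
        raise InvalidArgumentError("ref_mas must be > 0")
    if params.enhancement == 0.0:
        return img.with_pixels(img.pixels.copy(), label=f"{img.label}+{params.code}")

    x = img.pixels
    bands, low = band_decompose(x)
    d = dose_factor(params.filter_control, img.mas / ref_mas)
    local_mean = gaussian_filter(x, DENSITY_SIGMA)
    rho = density_factor(params.density_type, local_mean, float(np.median(x)))
    gate = edge_gate(x)

    out = low.copy()
    weights = BALANCE_WEIGHTS[params.balance]
    for band, w in zip(bands, weights):
        s = np.clip(params.enhancement * w * d * rho, 0.0, 1.0) * gate
        out += band * (1.0 - s)
    return img.with_pixels(out, label=f"{img.label}+{params.code}")
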