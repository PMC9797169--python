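"""Core container types: radiographs and the detector noise model.

A :class:`Radiograph` is a 2D grayscale image in arbitrary detector units with
the physical pixel pitch (mm) and the acquisition factors (mAs, kVp) attached.
Pixel values may be signed: repeat-subtraction "noise-only" images live in the
same container as acquisitions.

:class:`NoiseModel` describes the second-order statistics of detector noise:
signal-dependent (quantum) variance ``gain * mean`` plus a signal-independent
electronic floor, an optional pre-sampling blur that correlates the quantum
noise, and an optional unsharp-mask term standing in for the detail-enhancement
stage of a clinical processing chain (it gives the measured noise power
spectrum its characteristic mid-frequency peak).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter


class InvalidArgumentError(ValueError):
    """Raised when an operation receives arguments violating its contract."""


@dataclass
class Radiograph:
    """A 2D grayscale radiograph with physical metadata.

    Parameters
    ----------
    pixels
        2D array of intensities in arbitrary detector units.  Stored as
        float64; all values must be finite.
    pixel_pitch
        Detector pixel pitch in mm per pixel (default 0.15, a typical
        portable flat-panel pitch).
    mas
        Tube current-time product in mAs.
    kvp
        Tube potential in kV (informational).
    label
        Free-text description, e.g. ``"solid_water_10cm"`` or ``"chest"``.
    """

    pixels: np.ndarray
    pixel_pitch: float = 0.15
    mas: float = 1.0
    kvp: float = 85.0
    label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise InvalidArgumentError("pixels must be a non-empty 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise InvalidArgumentError("pixels must be finite")
        if not self.pixel_pitch > 0:
            raise InvalidArgumentError(f"pixel_pitch must be > 0, got {self.pixel_pitch}")
        if not self.mas > 0:
            raise InvalidArgumentError(f"mas must be > 0, got {self.mas}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def nyquist(self) -> float:
        """Nyquist frequency in cycles/mm: 1 / (2 * pixel pitch)."""
        return 1.0 / (2.0 * self.pixel_pitch)

    def with_pixels(self, pixels: np.ndarray, label: str | None = None) -> "Radiograph":
        """Copy of this radiograph with new pixel data (metadata inherited)."""
        return replace(self, pixels=pixels, label=self.label if label is None else label)


@dataclass(frozen=True)
class NoiseModel:
    """Second-order detector noise description.

    In a uniform region of mean signal ``m`` the generated per-pixel variance
    is ``gain * m + electronic_sd**2`` before any spatial correlation.
    ``blur_sigma`` (pixels) low-pass filters the quantum noise (pre-sampling
    blur); ``sharpen_amount``/``sharpen_sigma`` apply an unsharp mask
    ``q + a * (q - G_sigma(q))`` to the quantum noise afterwards, emulating the
    detail enhancement of a clinical processing chain.  Both correlation terms
    default to off, in which case the variance identity is exact.
    """

    gain: float = 1.0
    electronic_sd: float = 0.0
    blur_sigma: float = 0.0
    sharpen_amount: float = 0.0
    sharpen_sigma: float = 1.5

    def __post_init__(self) -> None:
        if self.gain < 0 or self.electronic_sd < 0 or self.blur_sigma < 0:
            raise InvalidArgumentError("gain, electronic_sd and blur_sigma must be >= 0")
        if self.sharpen_amount < 0 or self.sharpen_sigma <= 0:
            raise InvalidArgumentError("sharpen_amount >= 0 and sharpen_sigma > 0 required")

    def realize(self, scene: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """One noisy realization of ``scene`` under this model."""
        scene = np.asarray(scene, dtype=np.float64)
        quantum_sd = np.sqrt(self.gain * np.clip(scene, 0.0, None))
        noise = rng.standard_normal(scene.shape) * quantum_sd
        if self.blur_sigma > 0:
            noise = gaussian_filter(noise, self.blur_sigma)
        if self.sharpen_amount > 0:
            noise = noise + self.sharpen_amount * (noise - gaussian_filter(noise, self.sharpen_sigma))
        if self.electronic_sd > 0:
            noise = noise + rng.standard_normal(scene.shape) * self.electronic_sd
        return scene + noise
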