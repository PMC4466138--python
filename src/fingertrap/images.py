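"""Synthetic end-on particle images.

Emulates negatively stained end-on views of a hollow cylindrical
particle: an annular intensity ring of chosen radius over a flat
background plus Gaussian noise, with filled-disk and pure-noise control
shapes.  Default polarity is stain-high (negative stain): the annular
signal is bright.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ParticleImage:
    """2-D grayscale particle image with physical pixel size (Å/px)."""

    pixels: np.ndarray
    pixel_size: float
    polarity: str = "stain-high"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a rectangular 2-D grid")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def center_px(self) -> tuple[float, float]:
        return ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)

    def radii_angstrom(self, center: tuple[float, float] | None = None) -> np.ndarray:
        """Per-pixel distance (Å) from ``center`` (default: frame center)."""
        cy, cx = center if center is not None else self.center_px
        yy, xx = np.indices(self.shape)
        return np.hypot(yy - cy, xx - cx) * self.pixel_size


def make_endon_image(ring_radius: float = 22.0, size: int = 128, pixel_size: float = 2.0,
                     ring_width: float = 8.0, noise_sd: float = 0.2, seed: int = 0,
                     shape: str = "ring") -> ParticleImage:
    """Generate a synthetic end-on view.

    ``ring``: Gaussian-profile annulus of mean radius ``ring_radius``
    (Å) and 1-sigma width ``ring_width/2``; ``disk``: filled circle of
    that radius; ``flat``: background only.  Gaussian noise of sd
    ``noise_sd`` is added in every case; fixed seeds are deterministic.
    """
    if shape not in ("ring", "disk", "flat"):
        raise ValueError(f"shape must be ring, disk or flat, got {shape!r}")
    if shape != "flat" and ring_radius >= size * pixel_size / 2.0:
        raise ValueError(
            f"ring_radius {ring_radius} Å does not fit in a "
            f"{size}x{size} frame at {pixel_size} Å/px"
        )
    img = ParticleImage(np.zeros((size, size)), pixel_size)
    rho = img.radii_angstrom()
    if shape == "ring":
        sigma = ring_width / 2.0
        signal = np.exp(-0.5 * ((rho - ring_radius) / sigma) ** 2)
    elif shape == "disk":
        signal = (rho <= ring_radius).astype(float)
    else:
        signal = np.zeros_like(rho)
    rng = np.random.default_rng(seed)
    pixels = signal + rng.normal(0.0, noise_sd, signal.shape)
    return ParticleImage(pixels, pixel_size)
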