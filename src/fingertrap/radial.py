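"""Radial density profiling of end-on particle images.

End-on views of a hollow cylindrical particle show an annulus of
intensity around a depressed centre.  The analysis here reproduces
that measurement: locate the particle centre, average the intensity in
concentric annuli, and test for hollowness — the profile must rise
from a significantly depressed centre to an off-centre peak before
falling off to the background level estimated from the outermost
annuli.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .images import ParticleImage

BACKGROUND_FRACTION = 0.1  # outermost fraction of radii used as background
HOLLOW_SIGNIFICANCE = 2.0  # depression threshold in outer-annulus noise sd


@dataclass
class RadialProfile:
    """Annularly averaged intensity versus radius."""

    radii: np.ndarray  # Å, bin centres, strictly increasing
    mean_intensity: np.ndarray
    background: float
    noise_sd: float  # per-pixel noise estimate from the outer annuli
    peak_radius: float | None  # Å; None when no significant peak exists
    hollow: bool
    bin_counts: np.ndarray | None = None  # pixels per annulus

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=float)
        if not np.all(np.diff(self.radii) > 0):
            raise ValueError("radii must be strictly increasing")


def find_center(image: ParticleImage) -> tuple[float, float]:
    """Sub-pixel intensity centroid after median background subtraction.

    Returns (row, col) in pixels.  Raises on (near-)constant images,
    which carry no centring information.
    """
    pix = image.pixels
    if np.ptp(pix) < 1e-12:
        raise ValueError("constant image: centre is undefined")
    med = np.median(pix)
    # robust noise floor: only pixels significantly above background
    # contribute, otherwise clipped noise dilutes the centroid
    mad = np.median(np.abs(pix - med))
    weights = np.clip(pix - (med + 3.0 * 1.4826 * mad), 0.0, None)
    total = weights.sum()
    if total <= 0:
        raise ValueError("no intensity above background to centre on")
    yy, xx = np.indices(pix.shape)
    return float((weights * yy).sum() / total), float((weights * xx).sum() / total)


def _assess(radii: np.ndarray, mean: np.ndarray, counts: np.ndarray,
            pixel_sd: float) -> tuple[float, float | None, bool]:
    """Background, peak radius and hollowness verdict.

    ``pixel_sd`` is the per-pixel noise estimated from the outermost
    annuli; each annular mean carries an uncertainty of
    ``pixel_sd / sqrt(count)``, which protects the sparsely populated
    central bins from spurious hollowness calls.
    """
    n = len(radii)
    n_bg = max(int(np.ceil(n * BACKGROUND_FRACTION)), 2)
    background = float(np.mean(mean[-n_bg:]))
    sigma = pixel_sd / np.sqrt(np.maximum(counts, 1))
    # largest interior local maximum significantly above background
    peak_radius, peak_value, peak_idx = None, None, None
    for i in range(1, n - 1):
        if mean[i] >= mean[i - 1] and mean[i] >= mean[i + 1]:
            if mean[i] > background + 3.0 * max(sigma[i], 1e-12):
                if peak_value is None or mean[i] > peak_value:
                    peak_radius, peak_value, peak_idx = float(radii[i]), float(mean[i]), i
    hollow = False
    if peak_idx is not None:
        depression_sd = HOLLOW_SIGNIFICANCE * np.sqrt(
            sigma[0] ** 2 + sigma[peak_idx] ** 2
        )
        depressed = mean[0] <= peak_value - max(depression_sd, 1e-12)
        off_center = peak_radius > radii[1]
        hollow = bool(depressed and off_center)
    return background, peak_radius, hollow


def radial_profile(image: ParticleImage, center: tuple[float, float] | None = None,
                   bin_width: float = 2.0) -> RadialProfile:
    """Annular mean intensity profile about ``center`` (pixels).

    ``bin_width`` is in Å.  The profile covers radii out to the nearest
    frame edge so that every annulus is complete; the background and
    its noise are estimated from the outermost 10% of annuli.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    cy, cx = center if center is not None else image.center_px
    ny, nx = image.shape
    if not (0 <= cy <= ny - 1 and 0 <= cx <= nx - 1):
        raise ValueError("center lies outside the image")
    rho = image.radii_angstrom((cy, cx))
    r_max = min(cy, ny - 1 - cy, cx, nx - 1 - cx) * image.pixel_size
    n_bins = max(int(r_max / bin_width), 3)
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.digitize(rho.ravel(), edges) - 1
    vals = image.pixels.ravel()
    keep = (idx >= 0) & (idx < n_bins)
    sums = np.bincount(idx[keep], weights=vals[keep], minlength=n_bins)
    counts = np.bincount(idx[keep], minlength=n_bins)
    mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    radii = edges[:-1] + bin_width / 2.0
    ok = counts > 0
    radii, mean, counts = radii[ok], mean[ok], counts[ok]
    outer = rho >= radii[-max(int(np.ceil(len(radii) * BACKGROUND_FRACTION)), 2)]
    pixel_sd = float(np.std(image.pixels[outer & (rho <= radii[-1] + bin_width / 2)]))
    background, peak_radius, hollow = _assess(radii, mean, counts, pixel_sd)
    return RadialProfile(radii, mean, background, pixel_sd, peak_radius, hollow,
                         bin_counts=counts)


def average_profiles(profiles: list[RadialProfile]) -> RadialProfile:
    """Bin-wise mean of profiles sharing a common binning.

    Hollowness is re-decided on the averaged profile, whose outer-bin
    noise shrinks with the number of particles averaged.
    """
    if not profiles:
        raise ValueError("at least one profile is required")
    first = profiles[0]
    for p in profiles[1:]:
        if len(p.radii) != len(first.radii) or not np.allclose(p.radii, first.radii):
            raise ValueError("profiles have mismatched binning")
    mean = np.mean([p.mean_intensity for p in profiles], axis=0)
    pixel_sd = float(np.mean([p.noise_sd for p in profiles])) / np.sqrt(len(profiles))
    counts = first.bin_counts if first.bin_counts is not None else np.ones(len(first.radii))
    background, peak_radius, hollow = _assess(first.radii, mean, counts, pixel_sd)
    return RadialProfile(first.radii.copy(), mean, background, pixel_sd,
                         peak_radius, hollow, bin_counts=counts)


def project_endon(model, pixel_size: float = 2.0, size: int = 96,
                  smooth_sigma_px: float = 1.5) -> ParticleImage:
    """Project a tetramer's Cα density along its supercoil (z) axis.

    Produces a synthetic end-on view: a 2-D histogram of Cα positions
    in the plane perpendicular to the long axis, Gaussian-smoothed.
    The returned image is protein-high; this is the polarity on which
    the annular protein wall of a hollow model appears as a bright
    ring, mirroring the ring produced by stain exclusion in real
    end-on views.
    """
    from scipy.ndimage import gaussian_filter

    from .geometry import principal_axis

    ca = model.ca
    axis = principal_axis(ca)
    com = ca.mean(axis=0)
    rel = ca - com
    # in-plane orthonormal basis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    u = rel @ e1
    v = rel @ e2
    half = size * pixel_size / 2.0
    hist, _, _ = np.histogram2d(u, v, bins=size, range=[[-half, half], [-half, half]])
    smoothed = gaussian_filter(hist, smooth_sigma_px)
    return ParticleImage(smoothed, pixel_size, polarity="protein-high")
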