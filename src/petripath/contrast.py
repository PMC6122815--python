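"""Sobel-based phase-contrast image-quality score, with a synthetic fixture.

The score quantifies how crisp cells appear in a phase-contrast micrograph of
a well: the image is filtered with the 3x3 Sobel gradient magnitude, pixels
inside an elliptical well ROI whose edge response exceeds a threshold are
classed as cell pixels, and the score is the mean edge magnitude over those
pixels.  Curved media menisci blur the optics and lower the score, which is
what makes it a useful readout for well-wall geometry.

``synth_phase_image`` generates a deterministic stand-in for a real
phase-contrast mosaic: dark cell bodies with bright halos on a flat
background, plus noise, optionally blurred to emulate meniscus-induced
defocus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
_SOBEL_Y = _SOBEL_X.T


class ContrastWarning(UserWarning):
    """Empty cell mask or ROI clipped to the image."""


@dataclass
class ImageGrid:
    """A grayscale raster with an optional physical pixel size."""

    pixels: np.ndarray
    pixel_size: float = 1.0  # um/px

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("image must be a 2-D grayscale array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image intensities must be finite")


@dataclass(frozen=True)
class EllipseROI:
    """Elliptical region of interest in pixel coordinates (row/col centre)."""

    cx: float  # column of centre, px
    cy: float  # row of centre, px
    a: float  # semi-axis along columns, px
    b: float  # semi-axis along rows, px

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0):
            raise ValueError("ROI semi-axes must be > 0")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rows, cols = shape
        if (
            self.cx - self.a < -0.5
            or self.cx + self.a > cols - 0.5
            or self.cy - self.b < -0.5
            or self.cy + self.b > rows - 0.5
        ):
            warnings.warn("ROI extends beyond the image; clipping", ContrastWarning, stacklevel=2)
        yy, xx = np.mgrid[0:rows, 0:cols]
        return ((xx - self.cx) / self.a) ** 2 + ((yy - self.cy) / self.b) ** 2 <= 1.0


@dataclass(frozen=True)
class ContrastResult:
    score: float  # mean Sobel magnitude over cell pixels
    mask_fraction: float  # fraction of ROI pixels classed as cell
    threshold: float  # threshold actually applied


def _pixels(img) -> np.ndarray:
    arr = img.pixels if isinstance(img, ImageGrid) else np.asarray(img, dtype=float)
    return np.asarray(arr, dtype=float)


def sobel_magnitude(img) -> np.ndarray:
    """Per-pixel gradient magnitude sqrt(gx^2 + gy^2), 3x3 Sobel kernels.

    Borders are handled by edge replication, so a constant image maps to
    exactly zero everywhere and a unit intensity step responds with
    magnitude 4 in the two columns flanking the edge.
    """
    arr = _pixels(img)
    if arr.ndim != 2 or arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError("image must be at least 3x3")
    gx = ndimage.correlate(arr, _SOBEL_X, mode="nearest")
    gy = ndimage.correlate(arr, _SOBEL_Y, mode="nearest")
    return np.hypot(gx, gy)


def contrast_score(img, roi: EllipseROI, threshold: float | None = None) -> ContrastResult:
    """Mean Sobel magnitude over cell pixels inside an elliptical well ROI.

    Cell pixels are ROI pixels whose Sobel magnitude exceeds ``threshold``
    (Otsu's threshold of the Sobel image within the ROI when not given).  An
    empty mask yields score 0 with a warning rather than an error, so batch
    scoring of blank wells degrades gracefully.
    """
    arr = _pixels(img)
    sob = sobel_magnitude(arr)
    roi_mask = roi.mask(arr.shape)
    if not roi_mask.any():
        raise ValueError("ROI covers no pixels")
    if threshold is None:
        threshold = float(threshold_otsu(sob[roi_mask]))
    elif not threshold > 0:
        raise ValueError("threshold must be > 0")
    cell = roi_mask & (sob > threshold)
    n_cell = int(cell.sum())
    if n_cell == 0:
        warnings.warn("no pixel above threshold; score is 0", ContrastWarning, stacklevel=2)
        return ContrastResult(score=0.0, mask_fraction=0.0, threshold=float(threshold))
    return ContrastResult(
        score=float(sob[cell].mean()),
        mask_fraction=n_cell / int(roi_mask.sum()),
        threshold=float(threshold),
    )


@dataclass(frozen=True)
class SynthImageParams:
    """Parameters of the synthetic phase-contrast fixture.

    Defaults give a 256 px mosaic of ~40 cells whose dark bodies sit 60
    intensity units below a background of 120, ringed by halos 40 units
    above it — roughly the appearance of adherent fibroblasts in phase
    contrast.  ``blur_sigma`` emulates meniscus-induced defocus.
    """

    size: tuple[int, int] = (256, 256)  # rows, cols
    n_cells: int = 40
    cell_radius: float = 6.0  # px
    cell_contrast: float = 60.0  # body darkening, intensity units
    halo_amplitude: float = 40.0  # halo brightening, intensity units
    background: float = 120.0
    blur_sigma: float = 0.0  # px
    noise_sd: float = 4.0
    seed: int = 0
    max_tries: int = 10000

    def __post_init__(self):
        if self.n_cells < 0 or self.cell_radius <= 0:
            raise ValueError("n_cells must be >= 0 and cell_radius > 0")
        if min(self.size) < 3:
            raise ValueError("image must be at least 3x3")
        for name in ("cell_contrast", "halo_amplitude", "blur_sigma", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def synth_phase_image(p: SynthImageParams) -> ImageGrid:
    """Deterministic synthetic phase-contrast image.

    Non-overlapping dark disks with bright halo annuli on a flat background,
    Gaussian noise, then an optional Gaussian blur (applied last, so blur
    degrades both cell edges and noise, as defocus does).  The same seed
    always yields a bit-identical image; if the requested cells cannot be
    placed without overlap within ``max_tries`` draws, a RuntimeError is
    raised.
    """
    rng = np.random.default_rng(p.seed)
    rows, cols = p.size
    img = np.full((rows, cols), float(p.background))
    halo_r = 1.6 * p.cell_radius
    margin = halo_r + 1.0
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < p.n_cells:
        if tries >= p.max_tries:
            raise RuntimeError(
                f"could not place {p.n_cells} non-overlapping cells in {p.max_tries} tries"
            )
        tries += 1
        cy = rng.uniform(margin, rows - margin)
        cx = rng.uniform(margin, cols - margin)
        if all((cy - y) ** 2 + (cx - x) ** 2 >= (2 * halo_r) ** 2 for y, x in centers):
            centers.append((cy, cx))
    yy, xx = np.mgrid[0:rows, 0:cols]
    for cy, cx in centers:
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        img[d2 <= p.cell_radius**2] -= p.cell_contrast
        img[(d2 > p.cell_radius**2) & (d2 <= halo_r**2)] += p.halo_amplitude
    img += rng.normal(0.0, p.noise_sd, size=img.shape)
    if p.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, p.blur_sigma)
    return ImageGrid(pixels=img)
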