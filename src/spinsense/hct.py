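"""Hematocrit quantification from images of a metering channel.

After centrifugation, red cells pack into the radially outward end of a
U-shaped metering channel and appear dark against the lighter plasma;
the fraction of channel pixels below an intensity threshold is the
hematocrit percentage. The pipeline mirrors a straightforward
image-processing chain:

1. :func:`to_grayscale` — luminance conversion, intensities in [0, 1];
2. :func:`correct_background` — despeckle stray marks and divide out a
   low-order polynomial illumination surface fitted to the non-channel
   background;
3. :func:`flatten_profile` — Savitzky–Golay-smoothed longitudinal
   intensity profile, used for QC and edge localization;
4. :func:`compute_threshold` — Otsu's criterion on the masked-pixel
   histogram (256 bins), separating the bimodal cell/plasma population;
5. :func:`quantify_hematocrit` — dark-pixel fraction within the channel;
6. :func:`detect_stabilization` — earliest time a sedimentation series
   settles, declared after ``k`` consecutive small changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, median_filter
from scipy.signal import savgol_filter
from skimage.color import rgb2gray

from .errors import DegenerateHistogramError, InvalidArgument

__all__ = [
    "DiscImage",
    "HematocritResult",
    "StabilizationResult",
    "to_grayscale",
    "correct_background",
    "flatten_profile",
    "compute_threshold",
    "quantify_hematocrit",
    "detect_stabilization",
]


@dataclass(frozen=True)
class DiscImage:
    """A grayscale channel image with its region of interest.

    ``pixels`` are float intensities in [0, 1], row-major with the
    origin at top-left; ``channel_mask`` (same shape, boolean) marks the
    metering-channel pixels. ``bit_depth`` records the source depth.
    """

    pixels: np.ndarray
    channel_mask: np.ndarray | None = None
    bit_depth: int = 8

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise InvalidArgument("DiscImage pixels must be 2-D")
        object.__setattr__(self, "pixels", px)
        if self.channel_mask is not None:
            m = np.asarray(self.channel_mask, dtype=bool)
            if m.shape != px.shape:
                raise InvalidArgument("channel_mask shape must match pixels")
            object.__setattr__(self, "channel_mask", m)

    def masked_values(self) -> np.ndarray:
        if self.channel_mask is None or not self.channel_mask.any():
            raise InvalidArgument("image has no (nonempty) channel mask")
        return self.pixels[self.channel_mask]


@dataclass(frozen=True)
class HematocritResult:
    """Dark-pixel hematocrit: ``hct_percent = 100 * dark / total``."""

    hct_percent: float
    threshold: float
    dark_pixels: int
    total_pixels: int


@dataclass(frozen=True)
class StabilizationResult:
    stable_time: float
    stable_value: float
    reached: bool


def to_grayscale(
    image: np.ndarray, channel_mask: np.ndarray | None = None
) -> DiscImage:
    """Convert a 1- or 3-channel image to a [0, 1] grayscale DiscImage.

    RGB input is reduced with ITU-R BT.709 luminance weights
    (0.2126 R + 0.7152 G + 0.0722 B, as used by scikit-image); integer
    input is scaled by its dtype range. Grayscale float input passes
    through unchanged (idempotent).
    """
    arr = np.asarray(image)
    bit_depth = 8
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        bit_depth = info.bits
        arr = arr.astype(float) / info.max
    else:
        arr = arr.astype(float)
    if arr.ndim == 3:
        if arr.shape[2] != 3:
            raise InvalidArgument(
                f"expected 1 or 3 channels, got shape {arr.shape}"
            )
        arr = rgb2gray(arr)
    elif arr.ndim != 2:
        raise InvalidArgument(f"expected a 2-D or (H, W, 3) image, got {arr.ndim}-D")
    return DiscImage(
        pixels=np.clip(arr, 0.0, 1.0), channel_mask=channel_mask, bit_depth=bit_depth
    )


def _poly2_surface(shape, rows, cols, values) -> np.ndarray:
    """Least-squares 2nd-order polynomial surface through (row, col, value)."""
    h, w = shape
    r = rows / max(h - 1, 1)
    c = cols / max(w - 1, 1)
    A = np.column_stack([np.ones_like(r), r, c, r * c, r**2, c**2])
    coef, *_ = np.linalg.lstsq(A, values, rcond=None)
    rr, cc = np.mgrid[0:h, 0:w]
    rr = rr / max(h - 1, 1)
    cc = cc / max(w - 1, 1)
    return (
        coef[0]
        + coef[1] * rr
        + coef[2] * cc
        + coef[3] * rr * cc
        + coef[4] * rr**2
        + coef[5] * cc**2
    )


def correct_background(image: DiscImage, mark_sigma: float = 3.0) -> DiscImage:
    """Remove stray marks and divide out the illumination surface.

    Background (non-channel) pixels are median-prefiltered (3x3);
    background pixels deviating more than ``mark_sigma`` standard
    deviations from their local median are treated as stray marks and
    replaced by it (pixels bordering the channel are left alone — their
    local median mixes in channel intensities). A 2nd-order polynomial
    surface is then fitted to the cleaned background and divided out of
    the whole image — illumination tilt is multiplicative — rescaled by
    the surface mean so a clean, flat image passes through unchanged,
    and clipped to [0, 1].
    """
    if image.channel_mask is None:
        raise InvalidArgument("correct_background needs a channel mask")
    bg = ~image.channel_mask
    n_bg = int(bg.sum())
    if n_bg < 100:
        raise InvalidArgument(f"only {n_bg} background pixels; need at least 100")

    px = image.pixels.copy()
    # median-filter a background-only view (channel filled with the global
    # background median) so border pixels compare against background
    # neighbours, not channel intensities
    filled = px.copy()
    filled[image.channel_mask] = float(np.median(px[bg]))
    med = median_filter(filled, size=3)
    resid = px - med
    sd = float(resid[bg].std())
    if sd > 0:
        marks = bg & (np.abs(resid) > mark_sigma * sd)
        px[marks] = med[marks]

    rows, cols = np.nonzero(bg)
    surface = _poly2_surface(px.shape, rows, cols, px[bg])
    surface = np.clip(surface, 1e-3, None)
    corrected = px / surface * float(surface[bg].mean())
    return DiscImage(
        pixels=np.clip(corrected, 0.0, 1.0),
        channel_mask=image.channel_mask,
        bit_depth=image.bit_depth,
    )


def flatten_profile(
    image: DiscImage, window: int = 11, order: int = 3, axis: int = 0
) -> np.ndarray:
    """Savitzky–Golay-smoothed longitudinal intensity profile.

    The mean intensity of the channel pixels is taken at each position
    along ``axis`` (default rows, the radial direction), then smoothed
    with a Savitzky–Golay filter of the given odd ``window`` and
    polynomial ``order`` — raising signal-to-noise with minimal
    distortion, since polynomial segments up to ``order`` pass through
    exactly.
    """
    if image.channel_mask is None or not image.channel_mask.any():
        raise InvalidArgument("flatten_profile needs a nonempty channel mask")
    if window % 2 == 0 or window < 3:
        raise InvalidArgument("window must be odd and >= 3")
    if order >= window:
        raise InvalidArgument("order must be smaller than window")
    if axis not in (0, 1):
        raise InvalidArgument("axis must be 0 (rows) or 1 (columns)")

    mask = image.channel_mask
    counts = mask.sum(axis=1 - axis)
    present = np.nonzero(counts > 0)[0]
    lo, hi = present[0], present[-1] + 1
    sums = np.where(mask, image.pixels, 0.0).sum(axis=1 - axis)
    profile = sums[lo:hi] / np.maximum(counts[lo:hi], 1)
    if window >= profile.size:
        raise InvalidArgument(
            f"window {window} must be shorter than the profile ({profile.size})"
        )
    return savgol_filter(profile, window, order, mode="interp")


def compute_threshold(image: DiscImage, nbins: int = 256) -> float:
    """Otsu threshold of the masked-pixel histogram.

    Maximizes the between-class variance over ``nbins`` histogram bins
    of the channel pixels; the result lies strictly between the two
    class means. When the two populations are separated by an empty gap
    every cut inside the gap maximizes the criterion, so ties are
    broken at the midpoint of the maximizing plateau (the center of the
    gap for a symmetric bimodal histogram). Raises
    :class:`DegenerateHistogramError` when the masked region is
    constant.
    """
    values = image.masked_values()
    if np.ptp(values) == 0:
        raise DegenerateHistogramError(
            "masked region is constant; no threshold separates it"
        )
    counts, edges = np.histogram(values, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(counts)[:-1]  # cut after bin i: classes [0..i], [i+1..]
    w1 = counts.sum() - w0
    m = np.cumsum(counts * centers)
    m0 = np.divide(m[:-1], w0, out=np.zeros_like(m[:-1]), where=w0 > 0)
    m1 = np.divide(m[-1] - m[:-1], w1, out=np.zeros_like(m[:-1]), where=w1 > 0)
    between = w0 * w1 * (m0 - m1) ** 2
    best = between.max()
    plateau = np.nonzero(between >= best * (1.0 - 1e-12))[0]
    # cut positions are the bin edges following each plateau index
    return float(edges[plateau + 1].mean())


def quantify_hematocrit(
    image: DiscImage, threshold: float | None = None
) -> HematocritResult:
    """Dark-pixel fraction of the channel: the hematocrit percentage.

    Pixels strictly below the threshold count as packed cells; ties fall
    to plasma. When no threshold is supplied, Otsu's is computed from
    the same image.
    """
    values = image.masked_values()
    thr = compute_threshold(image) if threshold is None else float(threshold)
    dark = int((values < thr).sum())
    total = int(values.size)
    return HematocritResult(
        hct_percent=100.0 * dark / total,
        threshold=thr,
        dark_pixels=dark,
        total_pixels=total,
    )


def detect_stabilization(
    series: list[tuple[float, float]], epsilon: float = 1.0, k: int = 3
) -> StabilizationResult:
    """Earliest settling time of a (time, hct %) series.

    A sample is *settled* when its change from the previous sample is
    below ``epsilon`` percentage points; the series is declared stable
    at the first settled sample of the first run of at least ``k``
    consecutive settled samples, and ``stable_value`` is the mean of
    that run's first ``k`` values. Returns ``reached=False`` when no
    such run exists.
    """
    if k < 1:
        raise InvalidArgument("k must be >= 1")
    if epsilon <= 0:
        raise InvalidArgument("epsilon must be positive")
    times = np.array([t for t, _ in series], dtype=float)
    values = np.array([v for _, v in series], dtype=float)
    if times.size < k + 1:
        raise InvalidArgument(f"need at least k+1={k + 1} points")
    if np.any(np.diff(times) <= 0):
        raise InvalidArgument("times must be strictly increasing")

    settled = np.abs(np.diff(values)) < epsilon  # settled[i] -> sample i+1
    run = 0
    for i, ok in enumerate(settled):
        run = run + 1 if ok else 0
        if run == k:
            first = i + 1 - (k - 1)  # index of the run's first settled sample
            return StabilizationResult(
                stable_time=float(times[first]),
                stable_value=float(values[first : first + k].mean()),
                reached=True,
            )
    return StabilizationResult(stable_time=float("nan"), stable_value=float("nan"), reached=False)
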