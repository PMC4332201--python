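"""Low-level image operators behind nuclear segmentation.

Four operators, all deterministic and boundary-handled by reflection:

* :func:`spot_enhance` — scale-normalised, sign-flipped Laplacian of
  Gaussian, so bright blobs of scale ~sigma become positive peaks.
* :func:`smooth_convolve` — normalised linear convolution with an
  arbitrary odd-sized kernel (the smoothing variant of the macro).
* :func:`triangle_threshold` — automatic histogram threshold at the bin of
  maximal perpendicular distance from the peak-to-tail chord.
* :func:`histogram_mode` — most frequent integer pixel value, used for
  background subtraction of the nuclear/vital/death dyes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from scipy.signal import fftconvolve

from .core import (
    DegenerateHistogramError,
    EmptyInputError,
    InvalidParameterError,
)

__all__ = [
    "IntensityHistogram",
    "spot_enhance",
    "smooth_convolve",
    "triangle_threshold",
    "histogram_mode",
]


@dataclass
class IntensityHistogram:
    """Pixel-intensity histogram with explicit bin edges.

    ``counts[i]`` is the number of pixels with value in
    ``[bin_edges[i], bin_edges[i+1])`` (last bin closed on the right).
    """

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.bin_edges.ndim != 1:
            raise InvalidParameterError("histogram arrays must be 1-D")
        if len(self.counts) != len(self.bin_edges) - 1:
            raise InvalidParameterError("need len(counts) == len(bin_edges) - 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise InvalidParameterError("bin_edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise InvalidParameterError("counts must be nonnegative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @classmethod
    def from_image(cls, image: np.ndarray, bins: int = 256) -> "IntensityHistogram":
        """Histogram an image.

        Integer images get one bin per integer value over their range
        (exact value counts); float images get ``bins`` equal-width bins
        over the observed min–max range.
        """
        image = np.asarray(image)
        if image.size == 0:
            raise EmptyInputError("cannot histogram an empty image")
        flat = image.ravel()
        if np.issubdtype(image.dtype, np.integer):
            lo, hi = int(flat.min()), int(flat.max())
            edges = np.arange(lo - 0.5, hi + 1.5)
            counts = np.bincount(flat.astype(np.int64) - lo, minlength=hi - lo + 1)
        else:
            lo, hi = float(flat.min()), float(flat.max())
            if hi == lo:  # flat image: widen so edges stay increasing
                hi = lo + 1.0
            counts, edges = np.histogram(flat, bins=bins, range=(lo, hi))
        return cls(bin_edges=edges, counts=counts)


def log_kernel(sigma_px: float) -> np.ndarray:
    """Sign-flipped, scale-normalised LoG kernel sampled at pixel centres.

    ``K(x, y) = -sigma² ∇²G_sigma(x, y)`` truncated at 5 sigma; the
    residual truncation sum is removed so a constant image maps exactly
    to zero.
    """
    radius = int(np.ceil(5.0 * sigma_px))
    ax = np.arange(-radius, radius + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    r2 = xx**2 + yy**2
    g = np.exp(-r2 / (2.0 * sigma_px**2)) / (2.0 * np.pi * sigma_px**2)
    kernel = g * (2.0 * sigma_px**2 - r2) / sigma_px**2
    return kernel - kernel.mean()


def spot_enhance(
    image: np.ndarray, sigma_um: float, pixel_size_um: float
) -> np.ndarray:
    """Spot-enhancing filter: sign-flipped Laplacian of Gaussian.

    Convolves with the analytic, scale-normalised kernel of
    :func:`log_kernel` under reflecting boundaries, so a bright blob of
    scale ~sigma yields a positive central peak and a constant image maps
    to zero.  Output has the input's shape, dtype float64.
    """
    if sigma_um <= 0 or pixel_size_um <= 0:
        raise InvalidParameterError("sigma_um and pixel_size_um must be positive")
    sigma_px = sigma_um / pixel_size_um
    if sigma_px < 0.5:
        raise InvalidParameterError(
            f"filter scale {sigma_px:.3f} px is below the 0.5 px sampling limit"
        )
    img = np.asarray(image, dtype=float)
    kernel = log_kernel(sigma_px)
    pad = kernel.shape[0] // 2
    padded = np.pad(img, pad, mode="symmetric")
    out = fftconvolve(padded, kernel, mode="same")
    return out[pad:-pad, pad:-pad] if pad else out


def smooth_convolve(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Normalised linear convolution with reflecting boundaries.

    The kernel must have odd dimensions.  Kernels with nonzero sum are
    normalised to unit sum, so averaging kernels preserve flat images and
    the identity kernel returns the input unchanged.
    """
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 2 or any(d % 2 == 0 for d in kernel.shape):
        raise InvalidParameterError("kernel must be 2-D with odd dimensions")
    s = kernel.sum()
    if s != 0:
        kernel = kernel / s
    return ndi.convolve(np.asarray(image, dtype=float), kernel, mode="reflect")


def _triangle_candidate_distances(
    counts: np.ndarray,
) -> tuple[np.ndarray, int, int]:
    """Perpendicular distances of the bins between peak and tail.

    Geometry is computed in normalised coordinates: the bin-index axis is
    scaled so the peak→tail span is 1, the count axis so the peak count is
    1.  Returns (distance numerators per candidate bin, peak index, tail
    index); candidate bins are those strictly between peak and tail.
    """
    nz = np.flatnonzero(counts)
    peak = int(np.argmax(counts))  # ties: smallest index
    left_span = peak - nz[0]
    right_span = nz[-1] - peak
    # side selection: the longer tail; equal tails -> right
    tail = int(nz[-1]) if right_span >= left_span else int(nz[0])
    lo, hi = sorted((peak, tail))
    idx = np.arange(lo + 1, hi)
    if idx.size == 0:
        return np.array([]), peak, tail
    x = (idx - peak) / (tail - peak)
    y = counts[idx] / counts[peak]
    y_tail = counts[tail] / counts[peak]
    # line through (0, 1) and (1, y_tail); distance ∝ |(y_tail-1)·x - (y-1)|
    num = np.abs((y_tail - 1.0) * x - (y - 1.0))
    return num, peak, tail


def triangle_threshold(hist: IntensityHistogram) -> float:
    """Triangle auto-threshold.

    A chord is drawn from the histogram peak to the farthest nonzero bin on
    the longer-tail side; the threshold is the centre of the bin whose
    (normalised-coordinate) perpendicular distance to that chord is
    maximal.  Ties take the median of the tied bins, rounding toward the
    peak, so two equal spikes separated by an empty plateau threshold at
    the plateau midpoint.
    """
    counts = np.asarray(hist.counts, dtype=float)
    if np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError(
            "triangle threshold needs at least two nonzero bins"
        )
    num, peak, tail = _triangle_candidate_distances(counts)
    centers = hist.centers
    if num.size == 0:  # peak and tail adjacent: threshold between them
        return float(0.5 * (centers[peak] + centers[tail]))
    lo = min(peak, tail)
    tied = np.flatnonzero(num >= num.max() - 1e-12 * max(num.max(), 1.0))
    cand = tied + lo + 1  # back to absolute bin indices
    # median of tied indices, rounding toward the peak when even count
    k = (len(cand) - 1) / 2.0
    j = int(np.floor(k)) if peak < tail else int(np.ceil(k))
    return float(centers[cand[j]])


def histogram_mode(image: np.ndarray) -> int:
    """Most frequent integer pixel value; ties go to the smallest value.

    Float images are rounded to the nearest integer first.  This is the
    background estimate subtracted from the Hoechst, Lysotracker and
    propidium-iodide channels.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise EmptyInputError("cannot take the mode of an empty image")
    if np.issubdtype(image.dtype, np.integer):
        flat = image.ravel().astype(np.int64)
    else:
        flat = np.rint(image.ravel()).astype(np.int64)
    values, counts = np.unique(flat, return_counts=True)
    return int(values[np.argmax(counts)])  # first max = smallest value
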