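"""Box-counting fractal analysis of binary vessel masks.

Global box-counting dimension, sliding-window local fractal dimension (LFD)
maps, LFD histograms with group averaging, and the four histogram summary
features used for group comparison: skewness, excess kurtosis, peak
frequency and maximum LFD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .imaging_io import BinaryMask

__all__ = [
    "LFDMap",
    "LFDHistogram",
    "ComplexityFeatures",
    "box_count",
    "box_count_dimension",
    "dyadic_box_sizes",
    "local_fractal_map",
    "build_lfd_histogram",
    "average_histograms",
    "extract_features",
]


def dyadic_box_sizes(max_size: int, min_size: int = 2) -> list[int]:
    """Powers of two from min_size up to max_size inclusive."""
    sizes = []
    s = min_size
    while s <= max_size:
        sizes.append(s)
        s *= 2
    return sizes


def box_count(mask: np.ndarray, size: int) -> int:
    """Number of size x size boxes (grid anchored at the origin) containing
    at least one foreground pixel."""
    h, w = mask.shape
    ph = (-h) % size
    pw = (-w) % size
    if ph or pw:
        mask = np.pad(mask, ((0, ph), (0, pw)))
    H, W = mask.shape
    blocks = mask.reshape(H // size, size, W // size, size)
    return int(blocks.any(axis=(1, 3)).sum())


def box_count_dimension(
    mask: BinaryMask | np.ndarray,
    box_sizes: list[int] | None = None,
    grid_offset_averaging: bool = False,
) -> float:
    """Box-counting dimension: slope of log N(s) against log(1/s).

    The counting grid is anchored at the image origin; with
    ``grid_offset_averaging`` the count at each size is averaged over a few
    diagonal grid offsets before the fit.
    """
    data = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if not data.any():
        raise ValueError("box-counting dimension undefined for an empty mask")
    if box_sizes is None:
        box_sizes = dyadic_box_sizes(min(data.shape) // 4)
    if len(box_sizes) < 2:
        raise ValueError("need at least two box sizes")
    counts = []
    for s in box_sizes:
        if grid_offset_averaging:
            offs = [(0, 0), (s // 3, s // 3), (2 * s // 3, 2 * s // 3)]
            vals = [box_count(data[oy:, ox:], s) for oy, ox in offs]
            counts.append(float(np.mean(vals)))
        else:
            counts.append(float(box_count(data, s)))
    x = np.log(1.0 / np.asarray(box_sizes, dtype=float))
    y = np.log(np.asarray(counts))
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


@dataclass
class LFDMap:
    """Local fractal dimensions on a sliding-window grid."""

    window_size: int
    stride: int
    origins: np.ndarray  # (n, 2) int, window origins as (x, y)
    values: np.ndarray  # (n,) float LFD per qualifying window

    def __len__(self) -> int:
        return len(self.values)


def local_fractal_map(
    mask: BinaryMask | np.ndarray,
    window_size: int = 128,
    stride: int = 64,
    min_foreground: int = 50,
    box_sizes: list[int] | None = None,
) -> LFDMap:
    """Box-counting dimension inside each qualifying sliding window.

    Windows with fewer than ``min_foreground`` foreground pixels are skipped.
    Default box sizes are dyadic from 2 to window_size/2.
    """
    data = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    h, w = data.shape
    if window_size > min(h, w):
        raise ValueError("window larger than the mask")
    if box_sizes is None:
        box_sizes = dyadic_box_sizes(window_size // 2)
    origins, values = [], []
    for y0 in range(0, h - window_size + 1, stride):
        for x0 in range(0, w - window_size + 1, stride):
            win = data[y0 : y0 + window_size, x0 : x0 + window_size]
            if int(win.sum()) < min_foreground:
                continue
            origins.append((x0, y0))
            values.append(box_count_dimension(win, box_sizes))
    if not values:
        warnings.warn("no window met the min_foreground requirement", stacklevel=2)
        return LFDMap(window_size, stride, np.empty((0, 2), dtype=int), np.empty(0))
    return LFDMap(window_size, stride, np.asarray(origins, dtype=int), np.asarray(values))


@dataclass
class LFDHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    normalized: bool = False

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def build_lfd_histogram(
    lfd_map: LFDMap | np.ndarray,
    bin_width: float = 0.01,
    value_range: tuple[float, float] = (1.0, 2.0),
    normalize: bool = False,
) -> LFDHistogram:
    """Histogram LFD values over fixed bins; out-of-range values clamp to the
    edge bins (with a warning) so counts always sum to the entry count."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    values = lfd_map.values if isinstance(lfd_map, LFDMap) else np.asarray(lfd_map, dtype=float)
    lo, hi = value_range
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + np.arange(n_bins + 1) * bin_width
    if values.size and ((values < lo).any() or (values > hi).any()):
        warnings.warn("LFD values outside the histogram range were clamped", stacklevel=2)
    clipped = np.clip(values, lo, np.nextafter(hi, -np.inf))
    counts, _ = np.histogram(clipped, bins=edges)
    counts = counts.astype(float)
    if normalize and counts.sum() > 0:
        counts = counts / counts.sum()
    return LFDHistogram(edges, counts, normalized=normalize)


def average_histograms(histograms: list[LFDHistogram]) -> LFDHistogram:
    """Per-bin mean across samples (histograms must share their bins)."""
    if not histograms:
        raise ValueError("no histograms to average")
    edges = histograms[0].bin_edges
    for h in histograms[1:]:
        if not np.allclose(h.bin_edges, edges):
            raise ValueError("histograms have mismatched bins")
    counts = np.mean([h.counts for h in histograms], axis=0)
    return LFDHistogram(edges.copy(), counts, normalized=all(h.normalized for h in histograms))


@dataclass
class ComplexityFeatures:
    skewness: float
    kurtosis: float  # excess (Fisher) convention
    peak_frequency: float
    max_lfd: float
    lfd_at_peak: float = float("nan")  # secondary output: bin center of the mode

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def extract_features(hist: LFDHistogram) -> ComplexityFeatures:
    """Four summary features of an LFD histogram.

    Moment features treat the histogram as a weighted sample at bin centers:
    skewness is the adjusted Fisher-Pearson standardized third moment and
    kurtosis is bias-corrected excess kurtosis. With fewer than two occupied
    bins (or insufficient weight) the moments are NaN.
    """
    counts = hist.counts.astype(float)
    nz = np.nonzero(counts)[0]
    if nz.size == 0:
        raise ValueError("empty histogram")
    peak_frequency = float(counts.max())
    centers = hist.bin_centers
    max_lfd = float(hist.bin_edges[nz[-1] + 1])
    lfd_at_peak = float(centers[int(np.argmax(counts))])

    skew = kurt = float("nan")
    n = counts.sum()
    if nz.size >= 2:
        # weighted central moments at bin centers; for normalized histograms
        # n is the frequency total (=1) so the small-sample corrections only
        # apply to count histograms
        w = counts / n
        mu = float(w @ centers)
        d = centers - mu
        m2 = float(w @ d**2)
        if m2 > 0:
            m3 = float(w @ d**3)
            m4 = float(w @ d**4)
            g1 = m3 / m2**1.5
            g2 = m4 / m2**2 - 3.0
            if not hist.normalized and n > 3:
                skew = g1 * np.sqrt(n * (n - 1)) / (n - 2)
                kurt = ((n + 1) * g2 + 6.0) * (n - 1) / ((n - 2) * (n - 3))
            else:
                skew, kurt = g1, g2
    else:
        warnings.warn("moment features undefined for a single-bin histogram", stacklevel=2)
    return ComplexityFeatures(float(skew), float(kurt), peak_frequency, max_lfd, lfd_at_peak)
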