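"""Fruit segmentation by unimodal-histogram (Rosin) thresholding.

Fluorescence scenes of a single fruit on a non-emitting background have a
predominantly unimodal intensity histogram whose main peak is the background
at the low-intensity end.  The Rosin construction draws a straight line from
the histogram peak to the last non-empty bin and takes as threshold the bin
maximizing the perpendicular distance to that line.  The far-red (750 nm)
band gives the best fruit/background contrast and is the segmentation input;
the resulting mask is reused unchanged for the 675 nm image of the same
sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .synth import FluorescenceImage

__all__ = ["FruitMask", "unimodal_threshold", "segment_fruit", "SegmentationError"]


class SegmentationError(ValueError):
    """The histogram lacks the unimodal structure the threshold assumes."""


@dataclass
class FruitMask:
    """Binary fruit mask plus the threshold and histogram that produced it."""

    mask: np.ndarray  # bool raster, single connected component, holes filled
    threshold: float  # intensity in counts
    histogram: tuple[np.ndarray, np.ndarray]  # (raw bin counts, bin edges)


def _smooth_histogram(counts: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return counts.astype(float)
    kernel = np.ones(window) / window
    # edge-pad so the peak location is stable at the ends
    padded = np.pad(counts.astype(float), window // 2, mode="edge")
    return np.convolve(padded, kernel, mode="valid")[: counts.size]


def unimodal_threshold(
    counts: np.ndarray,
    edges: np.ndarray,
    smooth_window: int = 3,
) -> float:
    """Rosin threshold of a unimodal histogram.

    Parameters
    ----------
    counts, edges
        Histogram bin counts and bin edges (``len(edges) == len(counts)+1``).
    smooth_window
        Width of the moving-average smoothing applied before locating the
        peak and measuring distances; the raw histogram is untouched.

    Returns
    -------
    The centre intensity of the bin maximizing the perpendicular distance to
    the line from the histogram peak to the last non-empty bin.  Ties break
    toward the lowest intensity (more inclusive mask); the threshold is
    strictly greater than the mode intensity.
    """
    counts = np.asarray(counts, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if counts.size != edges.size - 1:
        raise ValueError("edges must have one more element than counts")
    nonempty = np.flatnonzero(counts > 0)
    if nonempty.size < 3:
        raise SegmentationError("histogram needs at least 3 non-empty bins")
    sm = _smooth_histogram(counts, smooth_window)
    centers = 0.5 * (edges[:-1] + edges[1:])

    last = nonempty[-1]
    peak = int(np.argmax(sm[: last + 1]))
    if peak >= last:
        raise SegmentationError("histogram mode coincides with its upper tail")
    if np.allclose(sm[peak], sm[last]):
        raise SegmentationError("flat histogram: no unimodal structure")

    # Perpendicular distance of (x_i, h_i) to the peak->tail line, scanned
    # over every bin between peak and tail.  Both axes are normalized to the
    # peak->tail span first, which makes the selected bin invariant to
    # rescaling intensities or counts by any positive constant.
    x0, y0 = centers[peak], sm[peak]
    x1, y1 = centers[last], sm[last]
    idx = np.arange(peak + 1, last + 1)
    xn = (centers[idx] - x0) / (x1 - x0)
    yn = (sm[idx] - y0) / (y1 - y0)
    dist = np.abs(xn - yn) / np.sqrt(2.0)  # distance to the (0,0)->(1,1) line
    best = idx[int(np.argmax(dist))]  # argmax returns the first (lowest-intensity) max
    return float(centers[best])


def segment_fruit(
    image_750: FluorescenceImage | np.ndarray,
    bins: int = 256,
    smooth_window: int = 3,
) -> FruitMask:
    """Segment the fruit from the 750 nm image.

    Builds a 256-bin histogram over [0, max], thresholds it with the Rosin
    construction, keeps the largest 8-connected foreground component and
    fills its interior holes so dark lesions remain part of the fruit region
    rather than being punched out of it.
    """
    pixels = image_750.astype_float() if isinstance(image_750, FluorescenceImage) else np.asarray(
        image_750, dtype=float)
    hi = float(pixels.max())
    if hi <= 0:
        raise SegmentationError("image has no positive intensities")
    raw_counts, edges = np.histogram(pixels, bins=bins, range=(0.0, hi))
    threshold = unimodal_threshold(raw_counts, edges, smooth_window=smooth_window)

    fg = pixels > threshold
    if not fg.any():
        raise SegmentationError(
            f"empty foreground after thresholding at {threshold:.1f} counts"
        )
    labels = measure.label(fg, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = ndi.binary_fill_holes(labels == largest)
    return FruitMask(mask=mask, threshold=threshold, histogram=(raw_counts, edges))
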