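"""Noise removal and bone-contour detection ahead of the ROI search.

Radiographs pick up impulse-like noise during film handling and
digitization; a 3x3 median filter suppresses it without blurring the bone
edges that the later stages rely on.  Bone outlines are then found by
global thresholding (bone is much brighter than soft tissue, so the
histogram is close to bimodal and Otsu's threshold separates the phases)
followed by boundary tracing of the connected foreground components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, segmentation

__all__ = ["ContourMap", "denoise", "detect_bone_contours"]


@dataclass
class ContourMap:
    """Binary edge raster plus the number of closed boundaries found."""

    edges: np.ndarray  # bool, same shape as the source image
    contour_count: int


def denoise(image) -> np.ndarray:
    """3x3 median filter with edge replication; dtype is preserved."""
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    return ndimage.median_filter(arr, size=3, mode="nearest")


def detect_bone_contours(image, threshold: float | None = None) -> ContourMap:
    """Binary bone-boundary map via thresholding + component boundary tracing.

    Parameters
    ----------
    threshold : intensity cut between soft tissue and bone. ``None`` selects
        Otsu's threshold from the image histogram.

    An empty edge map (contour_count 0) is a valid result, e.g. for a blank
    image or a threshold above every pixel.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if threshold is None:
        if np.ptp(arr) == 0:  # constant image: nothing exceeds any sensible cut
            return ContourMap(edges=np.zeros(arr.shape, dtype=bool), contour_count=0)
        threshold = float(filters.threshold_otsu(arr))
    fg = arr > threshold
    labels, count = ndimage.label(fg)
    edges = segmentation.find_boundaries(labels, mode="inner") & fg
    return ContourMap(edges=edges, contour_count=int(count))
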