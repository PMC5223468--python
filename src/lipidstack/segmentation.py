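"""Per-slice lipid droplet detection.

Each slice of the confocal stack is processed independently: the intensity
histogram is reduced to 256 bins and thresholded with the Intermodes
algorithm (iterative 3-point-mean smoothing until the histogram is bimodal;
the threshold is the midpoint of the two surviving peaks), the binary image
is cleaned up (hole filling, minimum-area filter) and split with a
distance-transform watershed, and every resulting particle is registered as a
2D ROI with area, centroid, best-fit ellipse and mean intensity.

Intermodes is used because it suppresses registration of dim out-of-plane
fluorescence bleeding along the optical axis: the threshold sits between the
background mode and the in-focus droplet mode, above the intensity of
out-of-focus halos. The whole module is deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .stacks_io import ImageStack

__all__ = [
    "ROI2D",
    "SegmentationParams",
    "NotBimodalError",
    "intermodes_threshold",
    "binarize_slice",
    "watershed_split",
    "register_particles",
    "segment_stack",
    "segment_stack_detailed",
]

logger = logging.getLogger(__name__)

N_BINS = 256


class NotBimodalError(ValueError):
    """The histogram cannot be reduced to exactly two modes."""


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the per-slice segmentation.

    min_droplet_area
        Connected components smaller than this (um^2) are discarded as noise
        specks. 20 um^2 corresponds to a disk of radius ~2.5 um, below any
        adipocyte lipid droplet.
    smoothing_max_iter
        Cap on Intermodes histogram-smoothing passes before a slice is
        declared not bimodal.
    """

    min_droplet_area: float = 20.0
    smoothing_max_iter: int = 10_000
    watershed_enabled: bool = True
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if self.min_droplet_area < 0:
            raise ValueError("min_droplet_area must be >= 0")
        if self.smoothing_max_iter < 1:
            raise ValueError("smoothing_max_iter must be >= 1")


@dataclass(frozen=True)
class ROI2D:
    """One registered particle in one slice.

    ``centroid`` is the plain pixel centroid in physical um (pixel-center
    convention), ``area = pixel_count * dy * dx`` for automatic ROIs, and the
    semi-axes are those of the second-moment best-fit ellipse, in um.
    ``orientation`` is degrees from the +x axis in (-90, 90].
    """

    slice_index: int
    pixel_count: int
    area: float
    centroid: tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation: float
    mean_intensity: float
    origin: str = "auto"

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError("need semi_major >= semi_minor > 0")
        if self.origin not in ("auto", "manual"):
            raise ValueError(f"origin must be auto|manual, got {self.origin}")

    @property
    def equivalent_radius(self) -> float:
        """Radius (um) of the circle with the same area."""
        return math.sqrt(self.area / math.pi)


# ---------------------------------------------------------------------------
# Intermodes thresholding
# ---------------------------------------------------------------------------

def _interior_maxima(h: np.ndarray) -> list[float]:
    """Centres of local-maximum plateaus strictly inside the bin range.

    A run of equal values higher than both flanking values is one mode (its
    centre is the mean bin index of the run). Noiseless images produce exact
    plateaus under 3-point smoothing, so a strict single-bin test would drop
    real modes from the count.
    """
    centers: list[float] = []
    n = len(h)
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and h[j + 1] == h[i]:
            j += 1
        if j < n - 1 and h[i - 1] < h[i] and h[j + 1] < h[i]:
            centers.append((i + j) / 2.0)
        i = j + 1
    return centers


def intermodes_threshold(histogram: np.ndarray, max_iter: int = 10_000) -> int:
    """Intermodes threshold of a 256-bin histogram.

    The histogram is repeatedly smoothed with a 3-point moving mean (zero
    outside the bin range) until exactly two local maxima remain (an
    equal-valued plateau counts as one maximum at its centre); the
    returned threshold is ``floor((peak1 + peak2) / 2)``. Deterministic.

    Raises
    ------
    NotBimodalError
        Fewer than two nonzero bins, or bimodality not reached in
        ``max_iter`` smoothing passes.
    """
    h = np.asarray(histogram, dtype=np.float64)
    if h.ndim != 1 or len(h) != N_BINS:
        raise ValueError(f"histogram must have {N_BINS} bins, got shape {h.shape}")
    if np.count_nonzero(h) < 2:
        raise NotBimodalError("histogram has fewer than 2 nonzero bins")
    iterations = 0
    while len(_interior_maxima(h)) != 2:
        if iterations >= max_iter:
            raise NotBimodalError(
                f"histogram not reducible to two modes within {max_iter} passes"
            )
        # left + centre + right in that order: the naive summation order keeps
        # repeated smoothing bit-reproducible against a scalar reimplementation
        left = np.concatenate(([0.0], h[:-1]))
        right = np.concatenate((h[1:], [0.0]))
        h = (left + h + right) / 3.0
        iterations += 1
    p1, p2 = _interior_maxima(h)
    return int(math.floor((p1 + p2) / 2.0))


def _slice_histogram(image: np.ndarray, bit_depth: int) -> tuple[np.ndarray, float, float]:
    """256-bin histogram of a slice plus the (vmin, bin width) mapping.

    8-bit images use the full 0..255 range one bin per grey level; 16-bit
    images are rescaled so 256 bins span [min, max] of the slice (the
    classical convention for thresholding high-depth images).
    """
    if bit_depth == 8:
        hist = np.bincount(image.ravel(), minlength=N_BINS)[:N_BINS]
        return hist.astype(np.float64), 0.0, 1.0
    vmin = int(image.min())
    vmax = int(image.max())
    width = (vmax - vmin + 1) / N_BINS
    idx = ((image.astype(np.int64) - vmin) / width).astype(np.int64)
    np.clip(idx, 0, N_BINS - 1, out=idx)
    hist = np.bincount(idx.ravel(), minlength=N_BINS)
    return hist.astype(np.float64), float(vmin), float(width)


def _bin_to_native(bin_index: int, vmin: float, width: float) -> int:
    """Largest native intensity whose histogram bin is <= bin_index."""
    return int(math.ceil(vmin + (bin_index + 1) * width)) - 1


# ---------------------------------------------------------------------------
# Binary cleanup, watershed, particle registration
# ---------------------------------------------------------------------------

def binarize_slice(
    slice_image: np.ndarray,
    threshold: float,
    params: SegmentationParams | None = None,
    pixel_size: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Threshold one slice: foreground = intensity > threshold.

    Holes are filled when ``params.fill_holes``; 8-connected components with
    physical area below ``params.min_droplet_area`` (um^2, via ``pixel_size =
    (dy, dx)``) are removed.
    """
    params = params or SegmentationParams()
    mask = np.asarray(slice_image) > threshold
    if params.fill_holes:
        mask = ndi.binary_fill_holes(mask)
    if params.min_droplet_area > 0 and mask.any():
        dy, dx = pixel_size
        labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
        counts = np.bincount(labels.ravel())
        small = np.nonzero(counts * dy * dx < params.min_droplet_area)[0]
        small = small[small != 0]
        if small.size:
            mask &= ~np.isin(labels, small)
    return mask


def watershed_split(mask: np.ndarray) -> np.ndarray:
    """Split touching convex particles along distance-transform ridges.

    Markers are local maxima of the Gaussian-smoothed (sigma = 1 px) Euclidean
    distance transform with a minimum separation of 3 px; components whose
    smoothed map yields no peak fall back to a single marker at their distance
    maximum, so no foreground is ever lost. Returns a label image; the label
    count is >= the connected-component count.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    components = cc_label(mask, connectivity=2)
    dist = ndi.distance_transform_edt(mask)
    smoothed = ndi.gaussian_filter(dist, sigma=1.0)
    coords = peak_local_max(
        smoothed, min_distance=3, labels=components, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    # Guarantee at least one marker per component.
    seeded = set(np.unique(components[markers > 0]))
    next_id = len(coords) + 1
    for comp in range(1, components.max() + 1):
        if comp not in seeded:
            inside = components == comp
            r, c = np.unravel_index(np.argmax(np.where(inside, dist, -1)), mask.shape)
            markers[r, c] = next_id
            next_id += 1
    labels = watershed(-smoothed, markers=markers, mask=mask, connectivity=2)
    return labels.astype(np.int32)


def _ellipse_semi_axes(prop, dx: float) -> tuple[float, float]:
    """Second-moment best-fit ellipse semi-axes in um (square pixels assumed)."""
    a = prop.axis_major_length / 2.0 * dx
    b = prop.axis_minor_length / 2.0 * dx
    if a <= 0:  # single pixel: treat as the equivalent circle
        r = math.sqrt(prop.num_pixels / math.pi) * dx
        return r, r
    if b <= 0:  # degenerate 1-px-wide line
        b = dx / 2.0
    return a, max(b, 1e-12)


def _orientation_from_x_deg(prop) -> float:
    """Map skimage's row-axis orientation to degrees from +x in (-90, 90]."""
    deg = (90.0 - math.degrees(prop.orientation)) % 180.0
    if deg > 90.0:
        deg -= 180.0
    return deg


def register_particles(
    label_image: np.ndarray,
    slice_image: np.ndarray,
    slice_index: int,
    spacing: tuple[float, float, float],
) -> list[ROI2D]:
    """Register one ROI2D per label: area, centroid, ellipse fit, mean intensity.

    Areas are exact (``pixel_count * dy * dx``); centroids use the
    pixel-center convention. Requires dy == dx for the ellipse fit.
    """
    _, dy, dx = spacing
    rois: list[ROI2D] = []
    for prop in regionprops(np.asarray(label_image), intensity_image=np.asarray(slice_image)):
        row, col = prop.centroid
        a, b = _ellipse_semi_axes(prop, dx)
        rois.append(
            ROI2D(
                slice_index=slice_index,
                pixel_count=int(prop.num_pixels),
                area=float(prop.num_pixels) * dy * dx,
                centroid=((col + 0.5) * dx, (row + 0.5) * dy),
                semi_major=a,
                semi_minor=b,
                orientation=_orientation_from_x_deg(prop),
                mean_intensity=float(prop.intensity_mean),
                origin="auto",
            )
        )
    return rois


def _segment_slice(
    image: np.ndarray,
    slice_index: int,
    stack: ImageStack,
    params: SegmentationParams,
) -> tuple[list[ROI2D], int | None]:
    hist, vmin, width = _slice_histogram(image, stack.bit_depth)
    try:
        bin_thr = intermodes_threshold(hist, params.smoothing_max_iter)
    except NotBimodalError:
        # Blank slices above/below the muscle are expected; skip, don't fail.
        logger.debug("slice %d: histogram not bimodal, no ROIs", slice_index)
        return [], None
    native_thr = _bin_to_native(bin_thr, vmin, width)
    mask = binarize_slice(image, native_thr, params, pixel_size=stack.spacing[1:])
    labels = watershed_split(mask) if params.watershed_enabled else cc_label(
        mask, connectivity=2
    ).astype(np.int32)
    rois = register_particles(labels, image, slice_index, stack.spacing)
    logger.debug("slice %d: threshold %d, %d ROIs", slice_index, native_thr, len(rois))
    return rois, native_thr


def segment_stack_detailed(
    stack: ImageStack, params: SegmentationParams | None = None
) -> tuple[list[list[ROI2D]], list[int | None]]:
    """Segment every slice; also return the per-slice native thresholds.

    Thresholds are ``None`` for slices whose histogram could not be reduced
    to two modes (these yield empty ROI lists).
    """
    params = params or SegmentationParams()
    rois_per_slice: list[list[ROI2D]] = []
    thresholds: list[int | None] = []
    for z in range(stack.n_slices):
        rois, thr = _segment_slice(stack.voxels[z], z, stack, params)
        rois_per_slice.append(rois)
        thresholds.append(thr)
    return rois_per_slice, thresholds


def segment_stack(
    stack: ImageStack, params: SegmentationParams | None = None
) -> list[list[ROI2D]]:
    """Apply threshold -> binarize -> watershed -> register to every slice.

    Deterministic; blank/unimodal slices yield empty lists rather than errors.
    """
    return segment_stack_detailed(stack, params)[0]
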