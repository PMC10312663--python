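"""Automated ROI detection on fluorescence image stacks.

The single-wavelength path follows the difference-image recipe: a reference
image over the unstimulated frames and one over the stimulated frames
(per-pixel mean or standard deviation), their clamped difference, intensity
thresholding (optionally intersected with a Canny-edge / flood-fill outline
mask), morphological cleanup with small-region filtering, and finally
connected-component labeling with optional watershed splitting of touching
cells. The ratiometric path derives cell anatomy from the time-averaged
340 nm stack instead, and traces are then extracted from the ratio stack.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, measure, segmentation

from .stack_io import ImageStack, TraceSet

__all__ = [
    "RoiConfig",
    "reference_image",
    "difference_image",
    "threshold_mask",
    "edge_fill_mask",
    "refine_mask",
    "split_and_label",
    "detect_rois",
    "detect_rois_ratiometric",
    "detect_rois_ratiometric_batch",
    "extract_traces",
]

# 3x3 cross, 4-connectivity: the fixed structuring element for erosion/dilation
_CROSS = ndi.generate_binary_structure(2, 1)


@dataclasses.dataclass(frozen=True)
class RoiConfig:
    """User-determined parameters of the detection pipeline.

    Frame ranges are half-open ``[start, stop)`` frame indices; they must be
    disjoint and inside the stack. ``threshold_value`` is an intensity when
    ``threshold_mode == "absolute"`` and a percentile of the nonzero pixels
    when ``"percentile"``. The Canny/flood-fill outline step only runs when
    ``use_edge_fill`` is set; the default pipeline is threshold-only.
    """

    unstim_range: tuple[int, int]
    stim_range: tuple[int, int]
    statistic: str = "mean"
    threshold_mode: str = "absolute"
    threshold_value: float = 10.0
    use_edge_fill: bool = False
    canny_sigma: float = 2.0
    canny_low: float | None = None
    canny_high: float | None = None
    erode_iter: int = 1
    dilate_iter: int = 1
    min_area: int = 9
    split_touching: bool = False
    min_marker_distance: int = 5

    def __post_init__(self) -> None:
        if self.statistic not in ("mean", "std"):
            raise ValueError(f"statistic must be 'mean' or 'std', got {self.statistic!r}")
        if self.threshold_mode not in ("absolute", "percentile"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        for name in ("unstim_range", "stim_range"):
            a, b = getattr(self, name)
            if not (0 <= a < b):
                raise ValueError(f"{name} must satisfy 0 <= start < stop, got ({a}, {b})")
        u0, u1 = self.unstim_range
        s0, s1 = self.stim_range
        if max(u0, s0) < min(u1, s1):
            raise ValueError("unstim_range and stim_range must be disjoint")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.erode_iter < 0 or self.dilate_iter < 0:
            raise ValueError("morphology iteration counts must be >= 0")


def reference_image(stack: ImageStack, frame_range: tuple[int, int],
                    statistic: str = "mean") -> np.ndarray:
    """Per-pixel mean (or population std) over a half-open frame range."""
    a, b = frame_range
    if not (0 <= a < b <= stack.n_frames):
        raise ValueError(
            f"frame range ({a}, {b}) out of bounds for {stack.n_frames} frames"
        )
    block = stack.frames[a:b]
    if statistic == "mean":
        return block.mean(axis=0)
    if statistic == "std":
        return block.std(axis=0)  # ddof=0: population std
    raise ValueError(f"unknown statistic {statistic!r}")


def difference_image(stim: np.ndarray, unstim: np.ndarray) -> np.ndarray:
    """Stimulated minus unstimulated reference, negatives clamped to zero.

    The subtraction removes static background structure; the clamp discards
    pixels that got dimmer, which carry no activation signal.
    """
    stim = np.asarray(stim, dtype=np.float64)
    unstim = np.asarray(unstim, dtype=np.float64)
    if stim.shape != unstim.shape:
        raise ValueError(f"shape mismatch: {stim.shape} vs {unstim.shape}")
    return np.maximum(stim - unstim, 0.0)


def threshold_mask(image: np.ndarray, mode: str = "absolute",
                   value: float = 10.0) -> np.ndarray:
    """Binary mask of pixels strictly above a cutoff.

    ``absolute`` uses ``value`` directly; ``percentile`` takes the value-th
    percentile of the *nonzero* pixels (difference images are mostly zero,
    so a percentile over all pixels would be meaningless).
    """
    image = np.asarray(image, dtype=np.float64)
    if mode == "absolute":
        cutoff = float(value)
    elif mode == "percentile":
        if not (0 < value < 100):
            raise ValueError("percentile value must be in (0, 100)")
        nonzero = image[image != 0]
        if nonzero.size == 0 or image.max() == image.min():
            warnings.warn("degenerate image in percentile mode: empty mask",
                          stacklevel=2)
            return np.zeros(image.shape, dtype=bool)
        cutoff = float(np.percentile(nonzero, value))
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    return image > cutoff


def edge_fill_mask(image: np.ndarray, canny_sigma: float = 2.0,
                   canny_low: float | None = None,
                   canny_high: float | None = None) -> np.ndarray:
    """Cell outlines by Canny edge detection, interiors by flood fill.

    Closed edge contours are filled; edge fragments that enclose nothing
    (open contours) are dropped. The returned mask covers each closed
    contour's interior plus the immediately adjacent outline pixels — the
    Canny edge straddles the true cell boundary, so taking one ring of it
    keeps the mask area close to the enclosed area.
    """
    image = np.asarray(image, dtype=np.float64)
    edges = feature.canny(image, sigma=canny_sigma,
                          low_threshold=canny_low, high_threshold=canny_high)
    filled = ndi.binary_fill_holes(edges)
    interior = filled & ~edges
    if not interior.any():
        return interior
    return ndi.binary_dilation(interior, structure=_CROSS) & filled


def refine_mask(mask: np.ndarray, erode_iter: int = 1, dilate_iter: int = 1,
                min_area: int = 9) -> np.ndarray:
    """Morphological cleanup: erode, dilate (3×3 cross), then drop
    connected components (8-connectivity) smaller than ``min_area``."""
    mask = np.asarray(mask, dtype=bool)
    if erode_iter > 0:
        mask = ndi.binary_erosion(mask, structure=_CROSS, iterations=erode_iter)
    if dilate_iter > 0:
        mask = ndi.binary_dilation(mask, structure=_CROSS, iterations=dilate_iter)
    if min_area > 1:
        lab = measure.label(mask, connectivity=2)
        counts = np.bincount(lab.ravel())
        keep = counts >= min_area
        keep[0] = False
        mask = keep[lab]
    return mask


def _relabel_by_area(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..K by decreasing area; ties broken by the
    row-major position of each region's first pixel."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return np.zeros_like(labels, dtype=np.int32)
    flat = labels.ravel()
    order = []
    for lab in ids:
        pix = np.nonzero(flat == lab)[0]
        order.append((-pix.size, pix[0], lab))
    order.sort()
    out = np.zeros_like(labels, dtype=np.int32)
    for new, (_, _, lab) in enumerate(order, start=1):
        out[labels == lab] = new
    return out


def split_and_label(mask: np.ndarray, intensity_image: np.ndarray | None = None,
                    split_touching: bool = False,
                    min_marker_distance: int = 5) -> np.ndarray:
    """Label a binary mask; optionally split touching cells by watershed.

    Without splitting this is plain 8-connected component labeling. With
    splitting, markers are placed at local maxima of the distance transform
    (at least ``min_marker_distance`` pixels apart) and the watershed of the
    negated distance transform, constrained to the mask, separates the
    regions along their waist lines. Labels come back renumbered 1..K by
    decreasing area.
    """
    mask = np.asarray(mask, dtype=bool)
    if intensity_image is not None and np.asarray(intensity_image).shape != mask.shape:
        raise ValueError("mask and intensity image shapes differ")
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    if not split_touching:
        labels = measure.label(mask, connectivity=2)
        return _relabel_by_area(labels)
    dist = ndi.distance_transform_edt(mask)
    coords = feature.peak_local_max(
        dist, min_distance=int(min_marker_distance), labels=mask,
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:  # degenerate: fall back to component labeling
        labels = measure.label(mask, connectivity=2)
        return _relabel_by_area(labels)
    labels = segmentation.watershed(-dist, markers=markers, mask=mask)
    return _relabel_by_area(labels)


def detect_rois(stack: ImageStack, cfg: RoiConfig) -> np.ndarray:
    """The full single-wavelength detection pipeline; returns a label image
    (0 background, 1..K cells), deterministically."""
    for name in ("unstim_range", "stim_range"):
        a, b = getattr(cfg, name)
        if b > stack.n_frames:
            raise ValueError(f"{name} ({a}, {b}) exceeds stack length {stack.n_frames}")
    unstim = reference_image(stack, cfg.unstim_range, cfg.statistic)
    stim = reference_image(stack, cfg.stim_range, cfg.statistic)
    diff = difference_image(stim, unstim)
    mask = threshold_mask(diff, cfg.threshold_mode, cfg.threshold_value)
    if cfg.use_edge_fill:
        mask &= edge_fill_mask(diff, cfg.canny_sigma, cfg.canny_low, cfg.canny_high)
    mask = refine_mask(mask, cfg.erode_iter, cfg.dilate_iter, cfg.min_area)
    return split_and_label(mask, diff, cfg.split_touching, cfg.min_marker_distance)


def detect_rois_ratiometric(f340: ImageStack, ratio: ImageStack,
                            cfg: RoiConfig) -> np.ndarray:
    """Ratiometric detection: anatomy from the time-averaged 340 nm stack.

    The 340 nm excitation channel shows cell structure regardless of Ca²⁺
    level, so its time average is thresholded directly (no difference image);
    traces should afterwards be extracted from the *ratio* stack.
    """
    if f340.frames.shape != ratio.frames.shape:
        raise ValueError(
            f"f340 and ratio stacks differ in shape: "
            f"{f340.frames.shape} vs {ratio.frames.shape}"
        )
    anatomy = f340.frames.mean(axis=0)
    mask = threshold_mask(anatomy, cfg.threshold_mode, cfg.threshold_value)
    if cfg.use_edge_fill:
        mask &= edge_fill_mask(anatomy, cfg.canny_sigma, cfg.canny_low, cfg.canny_high)
    mask = refine_mask(mask, cfg.erode_iter, cfg.dilate_iter, cfg.min_area)
    return split_and_label(mask, anatomy, cfg.split_touching, cfg.min_marker_distance)


def detect_rois_ratiometric_batch(pairs, cfg: RoiConfig) -> list[np.ndarray]:
    """Map :func:`detect_rois_ratiometric` over (f340, ratio) pairs,
    preserving order."""
    return [detect_rois_ratiometric(f340, ratio, cfg) for f340, ratio in pairs]


def extract_traces(stack: ImageStack, labels: np.ndarray) -> TraceSet:
    """Per-ROI traces: trace k at frame i is the mean of frame i over the
    pixels labeled k. An empty label image yields an empty TraceSet."""
    labels = np.asarray(labels)
    if labels.shape != stack.spatial_shape:
        raise ValueError(
            f"label image shape {labels.shape} does not match stack "
            f"spatial shape {stack.spatial_shape}"
        )
    K = int(labels.max()) if labels.size else 0
    times = stack.times
    if K == 0:
        return TraceSet(times=times, values=np.empty((stack.n_frames, 0)),
                        roi_ids=np.empty(0, dtype=np.int64))
    flat = labels.ravel()
    counts = np.bincount(flat, minlength=K + 1)[1:]
    if np.any(counts == 0):
        missing = np.nonzero(counts == 0)[0] + 1
        raise ValueError(f"label image not contiguous: empty labels {missing.tolist()}")
    values = np.empty((stack.n_frames, K), dtype=np.float64)
    for i in range(stack.n_frames):
        sums = np.bincount(flat, weights=stack.frames[i].ravel(), minlength=K + 1)[1:]
        values[i] = sums / counts
    return TraceSet(times=times, values=values,
                    roi_ids=np.arange(1, K + 1, dtype=np.int64))
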