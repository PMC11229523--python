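"""Photograph-to-silhouette preprocessing for single-fruit images.

The pipeline turns a color photograph of one prickly, near-ellipsoidal fruit
on a uniform backdrop into a clean, filled binary mask:

1. color adjustment (saturation / contrast gain) to widen the fruit-background
   gap,
2. color segmentation (gray threshold, HSV in-range, or K-means clustering),
3. gray-level thresholding to strip cast shadows,
4. 5x5 median filtering to remove the prickles and salt noise,
5. Canny edge detection,
6. boundary closing + hole filling to recover one filled component.

All images are ``numpy`` arrays: color images are ``(H, W, 3)`` uint8, gray
images ``(H, W)`` uint8, and binary masks ``(H, W)`` uint8 with values in
{0, 1}.  Every operation preserves image dimensions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage import feature, measure, morphology

from .errors import (
    EmptyContourError,
    EmptySegmentationError,
    FruitmorphError,
    InvalidConfigError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "as_color_image",
    "as_gray_image",
    "as_binary_mask",
    "to_gray",
    "adjust_color",
    "median_filter",
    "gray_threshold",
    "canny_edges",
    "trace_and_fill",
    "hsv_segment",
    "kmeans_segment",
    "preprocess_pipeline",
]


@dataclass
class PreprocessConfig:
    """Tunable knobs of the preprocessing pipeline.

    Attributes
    ----------
    saturation_gain, contrast_gain:
        Multiplicative factors (> 0).  Saturation gain is applied on the S
        channel in HSV space; contrast gain is an affine stretch about the
        image's own mean intensity.  Gains of 1 are exact no-ops.
    median_kernel:
        Side of the square median filter used for de-pricking; odd, >= 3.
    gray_threshold, dark_foreground:
        De-shading threshold in [0, 255].  With ``dark_foreground`` the
        foreground predicate is "strictly darker than the threshold"
        (dark fruit on a light backdrop); otherwise strictly brighter.
    canny_low, canny_high, canny_sigma:
        Gradient hysteresis thresholds (low < high, on gradient magnitude of
        the unit-scaled image) and Gaussian pre-smoothing sigma.
    segmentation:
        One of ``"gray"``, ``"hsv"``, ``"kmeans"``.
    kmeans_k, seed:
        Cluster count (>= 2) and RNG seed for the K-means route.
    hsv_hue_range, hsv_sat_range:
        Closed intervals in [0, 1] (skimage HSV convention); a hue interval
        with ``lo > hi`` wraps around the hue circle.
    gap_tolerance:
        Morphological closing radius (px) used to bridge gaps in the edge map
        before hole filling.
    """

    saturation_gain: float = 1.2
    contrast_gain: float = 1.2
    median_kernel: int = 5
    smooth_kernel: int = 9
    gray_threshold: int = 160
    dark_foreground: bool = True
    canny_low: float = 0.10
    canny_high: float = 0.25
    canny_sigma: float = 1.0
    segmentation: str = "kmeans"
    kmeans_k: int = 3
    seed: int = 0
    hsv_hue_range: tuple[float, float] = (0.12, 0.55)
    hsv_sat_range: tuple[float, float] = (0.15, 1.0)
    gap_tolerance: int = 5

    def validate(self) -> "PreprocessConfig":
        if self.saturation_gain <= 0 or self.contrast_gain <= 0:
            raise InvalidConfigError("saturation/contrast gains must be > 0")
        if self.median_kernel < 3 or self.median_kernel % 2 == 0:
            raise InvalidConfigError("median_kernel must be an odd integer >= 3")
        if self.smooth_kernel < 3 or self.smooth_kernel % 2 == 0:
            raise InvalidConfigError("smooth_kernel must be an odd integer >= 3")
        if not 0 <= self.gray_threshold <= 255:
            raise InvalidConfigError("gray_threshold must lie in [0, 255]")
        if not self.canny_low < self.canny_high:
            raise InvalidConfigError("canny_low must be < canny_high")
        if self.segmentation not in ("gray", "hsv", "kmeans"):
            raise InvalidConfigError(f"unknown segmentation {self.segmentation!r}")
        if self.kmeans_k < 2:
            raise InvalidConfigError("kmeans_k must be >= 2")
        if not self.hsv_sat_range[0] <= self.hsv_sat_range[1]:
            raise InvalidConfigError("hsv_sat_range bounds out of order")
        if self.gap_tolerance < 0:
            raise InvalidConfigError("gap_tolerance must be >= 0")
        return self

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PreprocessConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("hsv_hue_range", "hsv_sat_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw).validate()


# ---------------------------------------------------------------------------
# array validation helpers


def as_color_image(img) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidConfigError("color image must be (H, W, 3)")
    if arr.size == 0:
        raise InvalidConfigError("image must have height, width >= 1")
    if arr.min() < 0 or arr.max() > 255:
        raise InvalidConfigError("channel values must lie in [0, 255]")
    return arr.astype(np.uint8, copy=False)


def as_gray_image(img) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 2 or arr.size == 0:
        raise InvalidConfigError("gray image must be a non-empty (H, W) array")
    if arr.min() < 0 or arr.max() > 255:
        raise InvalidConfigError("intensities must lie in [0, 255]")
    return arr.astype(np.uint8, copy=False)


def as_binary_mask(mask) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2 or arr.size == 0:
        raise InvalidConfigError("mask must be a non-empty (H, W) array")
    if arr.dtype == bool:
        return arr.astype(np.uint8)
    if not np.isin(arr, (0, 1)).all():
        raise InvalidConfigError("mask values must be exactly 0 or 1")
    return arr.astype(np.uint8, copy=False)


def to_gray(img) -> np.ndarray:
    """Luminance grayscale of a color image, back on the [0, 255] scale."""
    arr = as_color_image(img)
    return np.clip(np.round(skcolor.rgb2gray(arr) * 255), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# stage operations


def adjust_color(img, cfg: PreprocessConfig) -> np.ndarray:
    """Boost saturation and contrast to separate fruit from background.

    Saturation gain multiplies the HSV S channel (clipped to [0, 1]); contrast
    gain is an affine stretch about the image's global mean, clipped to
    [0, 255].  Unit gains return the input unchanged, bit for bit.
    """
    arr = as_color_image(img)
    if cfg.saturation_gain <= 0 or cfg.contrast_gain <= 0:
        raise InvalidConfigError("gains must be > 0")
    out = arr.astype(np.float64)
    if cfg.saturation_gain != 1.0:
        hsv = skcolor.rgb2hsv(out / 255.0)
        hsv[..., 1] = np.clip(hsv[..., 1] * cfg.saturation_gain, 0.0, 1.0)
        out = skcolor.hsv2rgb(hsv) * 255.0
    if cfg.contrast_gain != 1.0:
        mean = out.mean()
        out = mean + cfg.contrast_gain * (out - mean)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def median_filter(img, kernel: int) -> np.ndarray:
    """Square median filter with replicated borders (de-pricking/denoising)."""
    arr = as_gray_image(img)
    if kernel % 2 == 0 or kernel < 3:
        raise InvalidConfigError("median kernel must be an odd integer >= 3")
    if kernel > min(arr.shape):
        raise InvalidConfigError("median kernel exceeds image extent")
    return ndi.median_filter(arr, size=kernel, mode="nearest")


def gray_threshold(img, t: int, dark_foreground: bool = True) -> np.ndarray:
    """Binarize a gray image; foreground is strictly darker (or brighter) than t."""
    arr = as_gray_image(img)
    if not 0 <= t <= 255:
        raise InvalidConfigError("threshold must lie in [0, 255]")
    fg = arr < t if dark_foreground else arr > t
    return fg.astype(np.uint8)


def canny_edges(img, low: float, high: float, sigma: float = 1.0) -> np.ndarray:
    """Canny edge map; thresholds act on gradient magnitude of the unit-scaled image."""
    arr = as_gray_image(img)
    if not low < high:
        raise InvalidConfigError("canny low threshold must be < high threshold")
    edges = feature.canny(
        arr.astype(np.float64) / 255.0,
        sigma=sigma,
        low_threshold=low,
        high_threshold=high,
    )
    return edges.astype(np.uint8)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return np.zeros_like(mask, dtype=bool)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def trace_and_fill(edges, gap_tolerance: int = 5) -> np.ndarray:
    """Close gaps in an edge map, fill the interior, keep the largest blob.

    Gaps up to ``gap_tolerance`` px are bridged by morphological closing with
    a disk footprint before hole filling.  The result must have a genuine
    interior (a thin open curve that encloses nothing raises
    :class:`EmptyContourError`), and is exactly one connected component.
    """
    e = as_binary_mask(edges).astype(bool)
    if not e.any():
        raise EmptyContourError("edge map is empty")
    # dilate -> fill -> erode: dilation welds boundary gaps (a plain closing
    # cannot bridge gaps in a 1 px curve), filling recovers the interior, and
    # the matching erosion returns the outer boundary to the traced outline
    radius = max(1, -(-gap_tolerance // 2))
    dilated = morphology.dilation(e, morphology.disk(radius))
    filled = morphology.erosion(
        ndi.binary_fill_holes(dilated), morphology.disk(radius)
    )
    largest = _largest_component(filled)
    if not morphology.erosion(largest, morphology.disk(1)).any():
        raise EmptyContourError("no closed boundary recoverable from edge map")
    return largest.astype(np.uint8)


def _postprocess_segmentation(fg: np.ndarray) -> np.ndarray:
    largest = _largest_component(fg)
    if not largest.any():
        raise EmptySegmentationError("segmentation produced no foreground")
    return ndi.binary_fill_holes(largest).astype(np.uint8)


def hsv_segment(img, cfg: PreprocessConfig) -> np.ndarray:
    """In-range HSV segmentation: hue and saturation both inside their intervals."""
    arr = as_color_image(img)
    hue_lo, hue_hi = cfg.hsv_hue_range
    sat_lo, sat_hi = cfg.hsv_sat_range
    if not sat_lo <= sat_hi:
        raise InvalidConfigError("saturation interval bounds out of order")
    hsv = skcolor.rgb2hsv(arr.astype(np.float64) / 255.0)
    h, s = hsv[..., 0], hsv[..., 1]
    if hue_lo <= hue_hi:
        hue_ok = (h >= hue_lo) & (h <= hue_hi)
    else:  # wrap around the hue circle (reds)
        hue_ok = (h >= hue_lo) | (h <= hue_hi)
    fg = hue_ok & (s >= sat_lo) & (s <= sat_hi)
    if not fg.any():
        raise EmptySegmentationError("no pixel falls inside the HSV intervals")
    return _postprocess_segmentation(fg)


def kmeans_segment(img, k: int = 3, seed: int = 0) -> np.ndarray:
    """K-means color clustering; the fruit is the central non-background cluster.

    Pixels are clustered on RGB color.  The background cluster is the majority
    label on the image border; among the remaining clusters the fruit is the
    one whose largest connected component covers the image center (falling
    back to the largest such component).  The winning component is hole-filled.
    """
    from sklearn.cluster import KMeans

    arr = as_color_image(img)
    if k < 2:
        raise InvalidConfigError("k must be >= 2")
    h, w = arr.shape[:2]
    pixels = arr.reshape(-1, 3).astype(np.float64)
    n_colors = np.unique(pixels, axis=0).shape[0]
    if n_colors < 2:
        raise EmptySegmentationError("single-color image cannot be clustered")
    k = min(k, n_colors)  # fewer distinct colors than requested clusters
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(pixels).reshape(h, w)
    border = np.concatenate(
        [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
    )
    background = np.bincount(border, minlength=k).argmax()
    center = (h // 2, w // 2)
    best = None  # (contains_center, area, component)
    for lab in range(k):
        if lab == background:
            continue
        comp = _largest_component(labels == lab)
        area = int(comp.sum())
        if area == 0:
            continue
        key = (bool(comp[center]), area)
        if best is None or key > best[:2]:
            best = (*key, comp)
    if best is None:
        raise EmptySegmentationError("no non-background cluster found")
    return _postprocess_segmentation(best[2])


# ---------------------------------------------------------------------------
# full pipeline

_STAGES = (
    "adjust_color",
    "segment",
    "deshade",
    "deprick",
    "edges",
    "fill",
)


def preprocess_pipeline(img, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Run the full photograph -> filled binary mask pipeline.

    Stage errors are re-raised as their own type with the stage name attached,
    so callers see both where and why the pipeline failed.
    """
    cfg = (cfg or PreprocessConfig()).validate()
    arr = as_color_image(img)

    def run(stage, fn, *args):
        try:
            out = fn(*args)
        except FruitmorphError as exc:
            raise type(exc)(f"[{stage}] {exc}") from exc
        if isinstance(out, np.ndarray) and out.ndim == 2:
            logger.debug("stage %s: %d foreground px", stage, int((out > 0).sum()))
        return out

    adjusted = run("adjust_color", adjust_color, arr, cfg)
    seg = None
    if cfg.segmentation == "hsv":
        seg = run("segment", hsv_segment, adjusted, cfg)
    elif cfg.segmentation == "kmeans":
        seg = run("segment", kmeans_segment, adjusted, cfg.kmeans_k, cfg.seed)

    gray = to_gray(adjusted)
    if seg is not None:
        # push segmented-out pixels to the background side of the threshold
        bg_value = 255 if cfg.dark_foreground else 0
        gray = np.where(seg == 1, gray, bg_value).astype(np.uint8)
    binary = run("deshade", gray_threshold, gray, cfg.gray_threshold, cfg.dark_foreground)
    filtered = run(
        "deprick", median_filter, (binary * 255).astype(np.uint8), cfg.median_kernel
    )
    # the median leaves short prickle-base stubs on the outline; plane them
    # off with an opening at the de-pricking scale, then smooth the boundary
    # with a wider median so no stub survives at the low-curvature flanks
    opened = morphology.opening(filtered > 0, morphology.disk(cfg.median_kernel))
    filtered = run(
        "deprick", median_filter, (opened * 255).astype(np.uint8), cfg.smooth_kernel
    )
    edges = run("edges", canny_edges, filtered, cfg.canny_low, cfg.canny_high, cfg.canny_sigma)
    filled = run("fill", trace_and_fill, edges, cfg.gap_tolerance)
    # the filled region carries a sub-pixel outward bias (edge pixels straddle
    # the true boundary, and median-filtered prickle bases leave a thin rim);
    # a single-pixel erosion recenters the outline on the fruit body
    eroded = morphology.erosion(filled.astype(bool), morphology.disk(1))
    return (_largest_component(eroded) if eroded.any() else filled.astype(bool)).astype(
        np.uint8
    )
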