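"""Annotation-free lung-field segmentation.

Pipeline: CLAHE local histogram equalization, Otsu binarization (dark
foreground by default — lungs are dark in display convention), disc
morphological opening, border clearing, disc dilation, and removal of
connected components smaller than a minimum area ``t``. Components and
border contact use 8-connectivity throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.exposure import equalize_adapthist
from skimage.measure import label as cc_label
from skimage.morphology import dilation, disk, opening
from skimage.segmentation import clear_border as _sk_clear_border

__all__ = [
    "SegmentationParams",
    "EmptyMaskWarning",
    "equalize_local_histogram",
    "otsu_threshold",
    "binarize_otsu",
    "morphological_open",
    "clear_border",
    "dilate",
    "filter_components",
    "segment_lungs",
]

_N_BINS = 256


class EmptyMaskWarning(UserWarning):
    """Emitted when the segmentation pipeline returns an all-background mask."""


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the segmentation pipeline.

    ``clahe_clip_limit`` follows the scikit-image convention (fraction of the
    per-tile histogram, in (0, 1]). ``t`` is the minimum connected-component
    area in pixels; anything smaller is erased.
    """

    clahe_clip_limit: float = 0.02
    clahe_tile_grid: tuple[int, int] = (8, 8)
    otsu_polarity: str = "dark_foreground"
    opening_radius: int = 2
    dilation_radius: int = 8
    t: int = 1310

    def __post_init__(self) -> None:
        if self.clahe_clip_limit <= 0:
            raise ValueError("clahe_clip_limit must be positive")
        if self.otsu_polarity not in ("dark_foreground", "bright_foreground"):
            raise ValueError(f"unknown otsu_polarity {self.otsu_polarity!r}")
        if self.opening_radius < 0 or self.dilation_radius < 0:
            raise ValueError("morphology radii must be non-negative")
        if self.t < 1:
            raise ValueError("t must be >= 1")

    @classmethod
    def for_image_size(cls, height: int, width: int | None = None, **kw) -> "SegmentationParams":
        """Defaults tuned at 256x256, scaled proportionally to the resolution."""
        width = height if width is None else width
        scale = np.sqrt(height * width) / 256.0
        kw.setdefault("opening_radius", max(1, round(2 * scale)))
        kw.setdefault("dilation_radius", max(1, round(8 * scale)))
        kw.setdefault("t", max(1, int(0.02 * height * width)))
        return cls(**kw)


def _check_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError("image contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("image values must lie in [0, 1]")
    return arr


def _check_mask(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError(f"expected a 2-D mask, got shape {m.shape}")
    if m.dtype != bool:
        vals = np.unique(m)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask must be binary")
        m = m.astype(bool)
    return m


def equalize_local_histogram(
    image: np.ndarray, params: SegmentationParams = SegmentationParams()
) -> np.ndarray:
    """Tile-wise contrast-limited adaptive histogram equalization (CLAHE)."""
    arr = _check_image(image)
    ty, tx = params.clahe_tile_grid
    kh, kw = arr.shape[0] // ty, arr.shape[1] // tx
    if kh < 1 or kw < 1:
        raise ValueError(
            f"image {arr.shape} is smaller than one CLAHE tile of a {ty}x{tx} grid"
        )
    out = equalize_adapthist(
        arr, kernel_size=(kh, kw), clip_limit=params.clahe_clip_limit, nbins=_N_BINS
    )
    return np.clip(out, 0.0, 1.0)


def otsu_threshold(image: np.ndarray) -> float:
    """Otsu threshold over a 256-bin histogram of [0, 1] intensities.

    Scans every candidate split exhaustively and maximizes the between-class
    variance; ties break toward the smallest threshold. The returned value is
    the upper edge of the last bin assigned to the lower class, so the pixel
    rule ``value < threshold`` reproduces the bin split exactly.
    """
    arr = _check_image(image)
    idx = np.minimum((arr * _N_BINS).astype(np.int64), _N_BINS - 1)
    counts = np.bincount(idx.ravel(), minlength=_N_BINS).astype(np.float64)
    if np.count_nonzero(counts) < 2:
        raise ValueError("Otsu threshold undefined: image has < 2 distinct levels")
    total = counts.sum()
    centers = (np.arange(_N_BINS) + 0.5) / _N_BINS
    w0 = np.cumsum(counts)[:-1]  # lower class = bins 0..k
    w1 = total - w0
    m0 = np.cumsum(counts * centers)[:-1]
    m_all = (counts * centers).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (m_all - m0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    k = int(np.argmax(sigma_b))  # argmax returns the first (= smallest) maximizer
    return (k + 1) / _N_BINS


def binarize_otsu(image: np.ndarray, polarity: str = "dark_foreground") -> np.ndarray:
    """Otsu binarization; ``dark_foreground`` marks the dark class as 1."""
    if polarity not in ("dark_foreground", "bright_foreground"):
        raise ValueError(f"unknown polarity {polarity!r}")
    thr = otsu_threshold(image)
    arr = np.asarray(image, dtype=np.float64)
    dark = arr < thr
    return dark if polarity == "dark_foreground" else ~dark


def morphological_open(mask: np.ndarray, opening_radius: int) -> np.ndarray:
    """Disc opening (erosion then dilation); radius 0 is the identity."""
    m = _check_mask(mask)
    if opening_radius == 0:
        return m.copy()
    return opening(m, disk(opening_radius))


def clear_border(mask: np.ndarray) -> np.ndarray:
    """Zero every 8-connected component that touches the image border."""
    m = _check_mask(mask)
    labels = cc_label(m, connectivity=2)
    return _sk_clear_border(labels) > 0


def dilate(mask: np.ndarray, dilation_radius: int) -> np.ndarray:
    """Disc dilation; radius 0 is the identity."""
    m = _check_mask(mask)
    if dilation_radius == 0:
        return m.copy()
    return dilation(m, disk(dilation_radius))


def filter_components(mask: np.ndarray, t: int) -> np.ndarray:
    """Erase 8-connected components whose pixel area is below ``t``."""
    if t < 1:
        raise ValueError("t must be >= 1")
    m = _check_mask(mask)
    labels = cc_label(m, connectivity=2)
    if labels.max() == 0:
        return np.zeros_like(m)
    areas = np.bincount(labels.ravel())
    keep = areas >= t
    keep[0] = False
    return keep[labels]


def segment_lungs(
    image: np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray:
    """Full segmentation pipeline; returns a boolean lung mask.

    An empty result is returned as-is with an :class:`EmptyMaskWarning`
    rather than raising, so heterogeneous batches can skip failures.
    """
    arr = _check_image(image)
    if params is None:
        params = SegmentationParams.for_image_size(*arr.shape)
    eq = equalize_local_histogram(arr, params)
    mask = binarize_otsu(eq, params.otsu_polarity)
    mask = morphological_open(mask, params.opening_radius)
    mask = clear_border(mask)
    mask = dilate(mask, params.dilation_radius)
    mask = filter_components(mask, params.t)
    if not mask.any():
        warnings.warn(
            "segmentation produced an empty lung mask", EmptyMaskWarning, stacklevel=2
        )
    return mask
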