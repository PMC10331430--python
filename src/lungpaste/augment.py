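"""Lung-confined cut-paste augmentation.

A rectangular patch is cropped from a normal image and pasted (as a
full-size, zero-padded canvas) at another location. An oval or rectangle
is drawn over the pasted position, its edge softened by a Gaussian blur,
and multiplied with the segmented lung mask to form the blend-weight mask.
The augmented image is the per-pixel convex combination

    out = normal * (1 - mask) + pasted * mask

so every altered pixel lies inside the lung field. Two ablation modes are
supported: ``no_segmentation`` (lung mask replaced by ones) and
``no_blur`` (hard, unblurred shape at full opacity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "AugmentParams",
    "PatchSpec",
    "BlurShape",
    "AugmentedSample",
    "PlacementError",
    "cut_patch",
    "render_pasted_patch",
    "render_blur_shape",
    "make_anatomical_mask",
    "blend",
    "paste_augment",
]

MODES = ("full", "no_segmentation", "no_blur")


class PlacementError(RuntimeError):
    """No admissible patch/shape placement was found within the retry budget."""


@dataclass(frozen=True)
class AugmentParams:
    """Sampling ranges for the augmentation.

    The patch area fraction is uniform on ``area_fraction_range`` and its
    aspect ratio log-uniform on ``aspect_ratio_range``. The shape interior
    opacity ``v`` is uniform on ``value_range`` and the blur radius ``r``
    uniform on ``blur_radius_range`` (pixels); the blur is a Gaussian with
    standard deviation ``r / 3`` truncated at three sigma.
    """

    area_fraction_range: tuple[float, float] = (0.02, 0.15)
    aspect_ratio_range: tuple[float, float] = (1.0 / 3.0, 3.0)
    value_range: tuple[float, float] = (0.59, 1.0)
    blur_radius_range: tuple[float, float] = (0.0, 15.0)
    mode: str = "full"
    max_attempts: int = 100

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        lo, hi = self.area_fraction_range
        if not 0 < lo <= hi < 1:
            raise ValueError("area_fraction_range must satisfy 0 < lo <= hi < 1")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")

    @classmethod
    def for_image_size(cls, size: int, **kw) -> "AugmentParams":
        """Defaults tuned at 256 px, with the blur range scaled to ``size``."""
        scale = size / 256.0
        kw.setdefault("blur_radius_range", (0.0, 15.0 * scale))
        return cls(**kw)


@dataclass(frozen=True)
class PatchSpec:
    """Crop box (row, col, height, width; 0-based, half-open) and paste translation."""

    crop_box: tuple[int, int, int, int]
    paste_offset: tuple[int, int]
    source_seed: int | None = None

    @property
    def paste_box(self) -> tuple[int, int, int, int]:
        r, c, h, w = self.crop_box
        dr, dc = self.paste_offset
        return (r + dr, c + dc, h, w)


@dataclass(frozen=True)
class BlurShape:
    """An oval or rectangle opacity shape before lung masking."""

    kind: str  # "oval" | "rectangle"
    center: tuple[float, float]
    bbox_height: float
    bbox_width: float
    interior_value: float
    blur_radius: float


@dataclass
class AugmentedSample:
    image: np.ndarray
    pretext_label: int
    provenance: dict = field(default_factory=dict)


def _shapes_match(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch: {sorted(shapes)}")


def cut_patch(
    image: np.ndarray,
    rng_seed: int | np.random.Generator,
    params: AugmentParams = AugmentParams(),
) -> PatchSpec:
    """Sample a crop box and a paste translation; deterministic given the seed."""
    img = np.asarray(image)
    h_img, w_img = img.shape
    if h_img < 8 or w_img < 8:
        raise ValueError(f"image {img.shape} too small for patch augmentation")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    frac = rng.uniform(*params.area_fraction_range)
    log_ar = rng.uniform(*np.log(params.aspect_ratio_range))
    aspect = np.exp(log_ar)  # aspect = width / height
    area = frac * h_img * w_img
    ph = int(np.clip(round(np.sqrt(area / aspect)), 1, h_img))
    pw = int(np.clip(round(np.sqrt(area * aspect)), 1, w_img))
    r = int(rng.integers(0, h_img - ph + 1))
    c = int(rng.integers(0, w_img - pw + 1))
    r2 = int(rng.integers(0, h_img - ph + 1))
    c2 = int(rng.integers(0, w_img - pw + 1))
    seed = None if isinstance(rng_seed, np.random.Generator) else int(rng_seed)
    return PatchSpec(crop_box=(r, c, ph, pw), paste_offset=(r2 - r, c2 - c), source_seed=seed)


def render_pasted_patch(image: np.ndarray, spec: PatchSpec) -> np.ndarray:
    """Full-size canvas: zero everywhere except the translated crop content."""
    img = np.asarray(image, dtype=np.float64)
    r, c, ph, pw = spec.crop_box
    pr, pc, _, _ = spec.paste_box
    h_img, w_img = img.shape
    for name, (rr, cc) in (("crop", (r, c)), ("paste", (pr, pc))):
        if rr < 0 or cc < 0 or rr + ph > h_img or cc + pw > w_img:
            raise ValueError(f"{name} box ({rr},{cc},{ph},{pw}) outside image {img.shape}")
    out = np.zeros_like(img)
    out[pr : pr + ph, pc : pc + pw] = img[r : r + ph, c : c + pw]
    return out


def _render_support(shape: BlurShape, grid_shape: tuple[int, int]) -> np.ndarray:
    rr, cc = np.mgrid[0 : grid_shape[0], 0 : grid_shape[1]].astype(np.float64)
    cy, cx = shape.center
    hh, hw = shape.bbox_height / 2.0, shape.bbox_width / 2.0
    if shape.kind == "rectangle":
        return (np.abs(rr - cy) <= hh) & (np.abs(cc - cx) <= hw)
    return ((rr - cy) / hh) ** 2 + ((cc - cx) / hw) ** 2 <= 1.0


def _blur(grid: np.ndarray, radius: float) -> np.ndarray:
    sigma = radius / 3.0
    if sigma <= 1e-12:
        return grid
    return gaussian_filter(grid, sigma=sigma, truncate=3.0, mode="constant")


def _draw_shape(
    constraint_mask: np.ndarray,
    spec: PatchSpec,
    rng: np.random.Generator,
    params: AugmentParams,
    attempts: int,
) -> tuple[BlurShape, np.ndarray, np.ndarray] | None:
    """One or more rejection-sampling draws; returns (shape, support, blurred grid)."""
    pr, pc, ph, pw = spec.paste_box
    crop_area = ph * pw
    for _ in range(attempts):
        kind = "oval" if rng.integers(2) == 0 else "rectangle"
        v = float(rng.uniform(*params.value_range))
        r_blur = float(rng.uniform(*params.blur_radius_range))
        bh = float(rng.uniform(min(2.0, ph), ph))
        bw = float(rng.uniform(min(2.0, pw), pw))
        cy = float(rng.uniform(pr, pr + ph))
        cx = float(rng.uniform(pc, pc + pw))
        if not bh * bw < crop_area:  # constraint (b): shape smaller than the patch
            continue
        shape = BlurShape(kind, (cy, cx), bh, bw, v, r_blur)
        support = _render_support(shape, constraint_mask.shape)
        if not support.any():
            continue
        if not (support & constraint_mask).any():  # constraint (a): lung overlap
            continue
        grid = _blur(support.astype(np.float64) * v, r_blur)
        return shape, support, grid
    return None


def render_blur_shape(
    lung: np.ndarray,
    spec: PatchSpec,
    rng_seed: int | np.random.Generator,
    params: AugmentParams = AugmentParams(),
) -> tuple[BlurShape, np.ndarray]:
    """Sample an admissible shape over the pasted position and blur its edge.

    Constraints: (a) the unblurred shape overlaps the lung mask in at least
    one pixel; (b) the shape bounding-box area is strictly smaller than the
    patch area. Raises :class:`PlacementError` after ``max_attempts`` draws.
    """
    lung_b = np.asarray(lung, dtype=bool)
    if not lung_b.any():
        raise ValueError("lung mask is empty; no shape can satisfy the overlap constraint")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    res = _draw_shape(lung_b, spec, rng, params, params.max_attempts)
    if res is None:
        raise PlacementError(
            f"no admissible shape after {params.max_attempts} attempts "
            "(lung-overlap or size constraint violated)"
        )
    shape, _, grid = res
    return shape, grid


def make_anatomical_mask(
    lung: np.ndarray,
    blur_grid: np.ndarray,
    mode: str = "full",
    hard_support: np.ndarray | None = None,
) -> np.ndarray:
    """Blend-weight mask: lung x blurred shape, with the two ablation modes.

    ``no_segmentation`` drops the lung factor; ``no_blur`` replaces the
    blurred grid with an all-ones hard shape support.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    lung_f = np.asarray(lung, dtype=np.float64)
    grid = np.asarray(blur_grid, dtype=np.float64)
    _shapes_match(lung_f, grid)
    if mode == "no_segmentation":
        return grid.copy()
    if mode == "no_blur":
        if hard_support is None:
            raise ValueError("no_blur mode requires the shape's unblurred support")
        hard = np.asarray(hard_support, dtype=np.float64)
        _shapes_match(lung_f, hard)
        return lung_f * hard
    return lung_f * grid


def blend(normal: np.ndarray, patch: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-pixel convex combination ``normal * (1 - mask) + patch * mask``."""
    x = np.asarray(normal, dtype=np.float64)
    p = np.asarray(patch, dtype=np.float64)
    m = np.asarray(mask, dtype=np.float64)
    _shapes_match(x, p, m)
    if m.min() < 0.0 or m.max() > 1.0:
        raise ValueError("mask values must lie in [0, 1]")
    return x * (1.0 - m) + p * m


def paste_augment(
    image: np.ndarray,
    lung: np.ndarray,
    params: AugmentParams = AugmentParams(),
    rng_seed: int | np.random.Generator = 0,
) -> AugmentedSample:
    """Full augmentation: cut, paste, shape, mask, blend. Label is always 1.

    The whole (patch, shape) pair is re-drawn when no shape placement
    satisfies the constraints for a given paste location.
    """
    img = np.asarray(image, dtype=np.float64)
    lung_b = np.asarray(lung, dtype=bool)
    _shapes_match(img, lung_b)
    if params.mode != "no_segmentation" and not lung_b.any():
        raise ValueError("lung mask is empty; cannot confine augmentation to the lung")
    constraint = np.ones_like(lung_b) if params.mode == "no_segmentation" else lung_b
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )

    patch_draws = max(1, params.max_attempts // 4)
    for _ in range(patch_draws):
        spec = cut_patch(img, rng, params)
        res = _draw_shape(constraint, spec, rng, params, attempts=4)
        if res is not None:
            break
    else:
        raise PlacementError(
            f"no admissible patch/shape placement after {patch_draws} patch draws"
        )
    shape, support, grid = res
    pasted = render_pasted_patch(img, spec)
    mask = make_anatomical_mask(lung_b, grid, params.mode, hard_support=support)
    out = blend(img, pasted, mask)
    seed = None if isinstance(rng_seed, np.random.Generator) else int(rng_seed)
    return AugmentedSample(
        image=out,
        pretext_label=1,
        provenance={
            "seed": seed,
            "mode": params.mode,
            "crop_box": spec.crop_box,
            "paste_offset": spec.paste_offset,
            "shape_kind": shape.kind,
            "shape_center": shape.center,
            "shape_bbox": (shape.bbox_height, shape.bbox_width),
            "interior_value": shape.interior_value,
            "blur_radius": shape.blur_radius,
        },
    )
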