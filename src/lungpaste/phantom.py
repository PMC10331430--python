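"""Synthetic chest-radiograph phantoms with ground-truth lung masks.

A phantom is a square grayscale image in radiographic display convention
(air/lung dark, mediastinum/bone bright) composed, in order, of: a smooth
background gradient, a bright central mediastinal band, two dark lung
ellipses, thin bright rib arcs, a multiplicative vignette, and additive
Gaussian noise. The analytic ellipse-union raster is kept as the
ground-truth lung mask. Abnormal phantoms are produced by adding a
Gaussian-profile bright opacity inside the lung field.

Rendering is a pure function of the spec: the same seed yields
bit-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.morphology import disk, erosion

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "PhantomSample",
    "PhantomGeometryError",
    "default_spec",
    "generate_normal_phantom",
    "inject_opacity",
]


class PhantomGeometryError(ValueError):
    """Raised when a phantom's lung geometry violates the spec invariants."""


@dataclass(frozen=True)
class Ellipse:
    """Rotated ellipse in pixel coordinates (row/col center, semi-axes, degrees)."""

    center_r: float
    center_c: float
    semi_r: float
    semi_c: float
    rotation_deg: float = 0.0

    def raster(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        th = np.deg2rad(self.rotation_deg)
        dr = rr - self.center_r
        dc = cc - self.center_c
        u = np.cos(th) * dr + np.sin(th) * dc
        v = -np.sin(th) * dr + np.cos(th) * dc
        return (u / self.semi_r) ** 2 + (v / self.semi_c) ** 2 <= 1.0

    def bbox_half_extents(self) -> tuple[float, float]:
        """Half-extent of the rotated ellipse's axis-aligned bounding box."""
        th = np.deg2rad(self.rotation_deg)
        er = np.hypot(self.semi_r * np.cos(th), self.semi_c * np.sin(th))
        ec = np.hypot(self.semi_r * np.sin(th), self.semi_c * np.cos(th))
        return float(er), float(ec)


def _default_ellipses(size: int) -> tuple[Ellipse, Ellipse]:
    s = float(size)
    return (
        Ellipse(0.46 * s, 0.31 * s, 0.27 * s, 0.135 * s, 7.0),
        Ellipse(0.46 * s, 0.69 * s, 0.27 * s, 0.135 * s, -7.0),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic radiograph phantom.

    ``geometry_jitter`` scales a per-seed random perturbation of the nominal
    lung ellipses (centers, semi-axes, rotation) so that different seeds
    produce anatomically distinct phantoms; set it to 0 for fixed geometry.
    ``appearance_jitter`` scales per-seed variation of everything outside
    the lung interior (background brightness, mediastinal band, rib
    amplitude, vignette, noise level), so a population of phantoms varies in
    acquisition-like ways while the dark lung fields stay comparable.
    """

    image_size: int = 256
    lung_ellipses: tuple[Ellipse, Ellipse] | None = None
    mediastinum_width_frac: float = 0.20
    rib_count: int = 8
    noise_sigma: float = 0.02
    vignette_strength: float = 0.25
    rng_seed: int = 0
    geometry_jitter: float = 1.0
    appearance_jitter: float = 1.0

    def __post_init__(self) -> None:
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if not 0.0 < self.mediastinum_width_frac < 1.0:
            raise ValueError("mediastinum_width_frac must be in (0, 1)")
        if self.rib_count < 0:
            raise ValueError("rib_count must be non-negative")
        if not 0.0 <= self.noise_sigma <= 0.2:
            raise ValueError("noise_sigma must be in [0, 0.2]")
        if not 0.0 <= self.vignette_strength <= 1.0:
            raise ValueError("vignette_strength must be in [0, 1]")

    def nominal_ellipses(self) -> tuple[Ellipse, Ellipse]:
        if self.lung_ellipses is not None:
            return self.lung_ellipses
        return _default_ellipses(self.image_size)


@dataclass
class PhantomSample:
    """A rendered phantom with ground truth."""

    image: np.ndarray
    lung_truth: np.ndarray  # bool
    label: str  # "normal" | "abnormal"
    anomaly_truth: np.ndarray  # bool, all-False when normal
    spec: PhantomSpec
    ellipses: tuple[Ellipse, Ellipse]
    meta: dict = field(default_factory=dict)


def default_spec(image_size: int = 256, rng_seed: int = 0, **kw) -> PhantomSpec:
    return PhantomSpec(image_size=image_size, rng_seed=rng_seed, **kw)


def _validate_geometry(ellipses: tuple[Ellipse, Ellipse], spec: PhantomSpec) -> None:
    s = spec.image_size
    for i, e in enumerate(ellipses):
        er, ec = e.bbox_half_extents()
        if (
            e.center_r - er < 1
            or e.center_r + er > s - 2
            or e.center_c - ec < 1
            or e.center_c + ec > s - 2
        ):
            raise PhantomGeometryError(
                f"lung ellipse {i} extends outside the image bounds "
                f"(center=({e.center_r:.1f},{e.center_c:.1f}), "
                f"half-extents=({er:.1f},{ec:.1f}), size={s})"
            )
    half_w = 0.5 * spec.mediastinum_width_frac * s
    lo, hi = s / 2 - half_w, s / 2 + half_w
    for i, e in enumerate(ellipses):
        mask = e.raster((s, s))
        area = int(mask.sum())
        if area == 0:
            raise PhantomGeometryError(f"lung ellipse {i} rasterizes to zero area")
        cols = np.arange(s)[None, :]
        in_band = mask & (cols >= lo) & (cols <= hi)
        if in_band.sum() > 0.20 * area:
            raise PhantomGeometryError(
                f"lung ellipse {i} overlaps the mediastinal band by "
                f"{in_band.sum() / area:.0%} (> 20%) of its area"
            )


def _jitter_ellipses(
    ellipses: tuple[Ellipse, Ellipse], spec: PhantomSpec, rng: np.random.Generator
) -> tuple[Ellipse, Ellipse]:
    j = spec.geometry_jitter
    if j == 0:
        return ellipses
    s = spec.image_size
    out = []
    for e in ellipses:
        out.append(
            Ellipse(
                center_r=e.center_r + j * rng.uniform(-0.015, 0.015) * s,
                center_c=e.center_c + j * rng.uniform(-0.012, 0.012) * s,
                semi_r=e.semi_r * (1 + j * rng.uniform(-0.08, 0.08)),
                semi_c=e.semi_c * (1 + j * rng.uniform(-0.08, 0.08)),
                rotation_deg=e.rotation_deg + j * rng.uniform(-4.0, 4.0),
            )
        )
    return (out[0], out[1])


def generate_normal_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render a normal phantom; deterministic given ``spec.rng_seed``.

    Raises :class:`PhantomGeometryError` when the (jittered) lung ellipses
    leave the image bounds or intrude into the mediastinal band.
    """
    s = spec.image_size
    rng = np.random.default_rng(spec.rng_seed)
    ellipses = _jitter_ellipses(spec.nominal_ellipses(), spec, rng)
    _validate_geometry(ellipses, spec)

    # per-seed appearance variation; lung interior intensity is unaffected
    aj = spec.appearance_jitter
    base_off = aj * rng.uniform(-0.04, 0.05)
    grad_slope = 0.05 + aj * rng.uniform(-0.03, 0.04)
    band_amp = 0.17 + aj * rng.uniform(-0.02, 0.02)
    band_width = 1.0 + aj * rng.uniform(-0.10, 0.10)
    rib_amp = 0.08 + aj * rng.uniform(-0.03, 0.03)
    vignette = np.clip(spec.vignette_strength + aj * rng.uniform(-0.03, 0.03), 0.0, 1.0)
    noise_scale = 1.0 + aj * rng.uniform(-0.5, 1.0)

    rr, cc = np.mgrid[0:s, 0:s].astype(np.float64)

    # background: soft-tissue base, slightly brighter toward the abdomen
    img = 0.66 + base_off + grad_slope * (rr / s - 0.5)

    # mediastinal band: flat-topped bright column with soft lateral falloff
    half_w = 0.5 * spec.mediastinum_width_frac * band_width * s
    band = band_amp / (1.0 + ((cc - s / 2) / half_w) ** 6)
    img += band

    # lung fields: dark ellipse union (analytic ground truth)
    lung = ellipses[0].raster((s, s)) | ellipses[1].raster((s, s))
    img[lung] = 0.30

    # rib arcs: thin bright curves across each hemithorax (nuisance structure)
    if spec.rib_count > 0:
        sigma_rib = max(1.0, s / 256.0)
        for e in ellipses:
            spans = np.linspace(
                e.center_r - 0.85 * e.semi_r,
                e.center_r + 0.85 * e.semi_r,
                spec.rib_count,
            )
            half_span = 1.25 * e.semi_c
            in_span = np.abs(cc - e.center_c) <= half_span
            for r0 in spans:
                curve = r0 + 0.12 * e.semi_r * ((cc - e.center_c) / e.semi_c) ** 2
                profile = rib_amp * np.exp(-0.5 * ((rr - curve) / sigma_rib) ** 2)
                img += np.where(in_span, profile, 0.0)

    # vignette: multiplicative radial darkening toward the frame edges
    d2 = ((rr - s / 2) / (s / 2)) ** 2 + ((cc - s / 2) / (s / 2)) ** 2
    img *= 1.0 - vignette * (d2 / 2.0)

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma * noise_scale, size=img.shape)

    img = np.clip(img, 0.0, 1.0)
    return PhantomSample(
        image=img,
        lung_truth=lung,
        label="normal",
        anomaly_truth=np.zeros_like(lung),
        spec=spec,
        ellipses=ellipses,
        meta={"seed": spec.rng_seed},
    )


def inject_opacity(
    sample: PhantomSample,
    rng_seed: int,
    amplitude: float | None = None,
    sigma: float | None = None,
) -> PhantomSample:
    """Add a bright Gaussian-profile opacity inside the lung field.

    Returns a new abnormal sample; ``anomaly_truth`` marks pixels where the
    added amplitude exceeds 10% of the peak. The blob is truncated at
    3 semi-axes, so pixels outside that neighborhood are untouched.
    """
    if sample.label != "normal":
        raise ValueError("inject_opacity expects a normal sample")
    lung = sample.lung_truth
    if not lung.any():
        raise ValueError("cannot inject an opacity: lung_truth is empty")
    if amplitude is not None and amplitude <= 0:
        raise ValueError("opacity amplitude must be strictly positive")

    s = sample.spec.image_size
    rng = np.random.default_rng(rng_seed)
    amp = float(rng.uniform(0.2, 0.5)) if amplitude is None else float(amplitude)
    sig = float(rng.uniform(0.035, 0.06) * s) if sigma is None else float(sigma)
    ratio = rng.uniform(0.7, 1.3)
    theta = rng.uniform(0.0, np.pi)
    sig_u, sig_v = sig, sig * ratio

    # prefer centers whose blob core stays inside the lung
    core = erosion(lung, disk(max(1, int(round(sig)))))
    candidates = core if core.any() else lung
    rows, cols = np.nonzero(candidates)

    rr, cc = np.mgrid[0:s, 0:s].astype(np.float64)
    for _ in range(50):
        k = rng.integers(len(rows))
        cy, cx = float(rows[k]), float(cols[k])
        dr, dc = rr - cy, cc - cx
        u = np.cos(theta) * dr + np.sin(theta) * dc
        v = -np.sin(theta) * dr + np.cos(theta) * dc
        q = (u / sig_u) ** 2 + (v / sig_v) ** 2
        blob = np.where(q <= 9.0, amp * np.exp(-0.5 * q), 0.0)
        truth = blob > 0.1 * amp
        if truth.any() and (truth & lung).sum() >= 0.5 * truth.sum():
            break
    else:  # pragma: no cover - extremely unlikely with eroded candidates
        raise ValueError("failed to place an opacity mostly inside the lung field")

    img = np.clip(sample.image + blob, 0.0, 1.0)
    return PhantomSample(
        image=img,
        lung_truth=lung.copy(),
        label="abnormal",
        anomaly_truth=truth,
        spec=sample.spec,
        ellipses=sample.ellipses,
        meta={**sample.meta, "opacity_seed": rng_seed, "amplitude": amp, "sigma": sig},
    )
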