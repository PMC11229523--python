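"""Synthetic fruit fixtures: rendered images and tabular populations.

Everything the measurement and modeling code consumes can be generated here
with known ground truth, so the whole pipeline is testable offline:

* :func:`render_binary_ellipse` — an analytic rotated-ellipse mask plus its
  exact semi-axes, pose and area.
* :func:`render_fruit_photo` — a color "photograph": ellipse body, radial
  prickle spikes (1-2 px wide, so a 5x5 median filter can remove them), an
  offset desaturated shadow, and salt noise, with a prickle-free,
  shadow-free ground-truth mask.
* :func:`generate_population` — tables of fruit records whose summary
  statistics emulate the 60-fruit *Rosa roxburghii* reference dataset
  (mean mass 18.01 g, mean volume 17.64 ml, axis means 19.72/14.76 mm).
* :func:`make_three_views` — consistent top/side projection specs of one
  triaxial fruit.

All randomness flows from explicit integer seeds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .errors import CanvasError, DomainError
from .estimation import RegressionModel, predict
from .morphometry import (
    FruitRecord,
    compute_cpa,
    ellipsoid_volume,
    paraboloid_volume,
)

__all__ = [
    "FruitImageSpec",
    "PopulationSpec",
    "REFERENCE_SUMMARY",
    "render_binary_ellipse",
    "render_fruit_photo",
    "generate_population",
    "make_three_views",
]

# Mean and standard deviation of each physical characteristic in the
# 60-fruit reference dataset the generator emulates.
REFERENCE_SUMMARY = {
    "a_mm": (19.72, 2.24),
    "b_mm": (14.76, 1.38),
    "pa1_cm2": (9.49, 1.85),
    "pa2_cm2": (9.37, 1.85),
    "pa3_cm2": (12.24, 2.72),
    "cpa_cm2": (10.37, 2.10),
    "mass_g": (18.01, 5.38),
    "volume_ml": (17.64, 5.52),
}

# Effective fruit density (g/ml) against the ellipsoid reference volume,
# calibrated once by large-sample simulation so the default population's mean
# mass lands on the 18.01 g target under the default axis distributions.
_DEFAULT_DENSITY = 0.7025


@dataclass(frozen=True)
class FruitImageSpec:
    """Specification of one rendered fruit image.

    ``semi_axes_px`` is (long, short); ``pose_deg`` rotates the long axis
    counter-clockwise from horizontal.  Prickles are radial spikes rooted on
    the ellipse boundary; the shadow is a desaturated darkened copy of the
    body offset by ``shadow_offset_px`` (rows, cols).  ``salt_rate`` is the
    per-pixel probability of a white salt-noise speck.
    """

    semi_axes_px: tuple[float, float] = (80.0, 50.0)
    pose_deg: float = 0.0
    canvas: tuple[int, int] = (224, 224)
    center: tuple[float, float] | None = None  # (row, col); default canvas center
    fruit_color: tuple[int, int, int] = (95, 150, 70)
    background_color: tuple[int, int, int] = (245, 245, 245)
    prickle_count: int = 50
    prickle_len_px: float = 8.0
    prickle_width_px: int = 2
    shadow_offset_px: tuple[int, int] = (18, 12)
    shadow_intensity: float = 0.8  # multiplies the background gray level
    salt_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        a, b = self.semi_axes_px
        if not a >= b > 0:
            raise DomainError("semi_axes_px must satisfy a >= b > 0")
        if not 0.0 <= self.salt_rate < 1.0:
            raise DomainError("salt_rate must lie in [0, 1)")
        if self.prickle_width_px not in (1, 2):
            raise DomainError("prickles must be 1 or 2 px wide")

    def _center(self) -> tuple[float, float]:
        h, w = self.canvas
        if self.center is not None:
            return self.center
        return ((h - 1) / 2.0, (w - 1) / 2.0)

    def validate_canvas(self, with_prickles: bool = False, with_shadow: bool = False):
        h, w = self.canvas
        cy, cx = self._center()
        margin = self.semi_axes_px[0] + (self.prickle_len_px + 2 if with_prickles else 0)
        boxes = [(cy, cx)]
        if with_shadow:
            boxes.append((cy + self.shadow_offset_px[0], cx + self.shadow_offset_px[1]))
        for by, bx in boxes:
            if by - margin < 0 or by + margin > h - 1 or bx - margin < 0 or bx + margin > w - 1:
                raise CanvasError(
                    f"fruit of extent {margin:.0f} px does not fit canvas {self.canvas}"
                )


def _ellipse_mask(canvas, center, semi_axes, pose_deg) -> np.ndarray:
    h, w = canvas
    cy, cx = center
    a, b = semi_axes
    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - cy
    dx = xx - cx
    th = math.radians(pose_deg)
    u = dx * math.cos(th) + dy * math.sin(th)
    v = -dx * math.sin(th) + dy * math.cos(th)
    return ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(np.uint8)


def render_binary_ellipse(spec: FruitImageSpec) -> tuple[np.ndarray, dict]:
    """Render the analytic rotated-ellipse mask with its ground truth.

    A pixel is foreground iff its center satisfies the rotated-ellipse
    inequality.  The truth dict carries the semi-axes, pose, center and the
    analytic area pi*a*b in px^2.
    """
    spec.validate_canvas()
    a, b = spec.semi_axes_px
    center = spec._center()
    mask = _ellipse_mask(spec.canvas, center, (a, b), spec.pose_deg)
    truth = {
        "a_px": a,
        "b_px": b,
        "pose_deg": spec.pose_deg,
        "center": center,
        "area_px2": math.pi * a * b,
    }
    return mask, truth


def render_fruit_photo(spec: FruitImageSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a color fruit "photograph" and its ground-truth body mask.

    Layer order: background, shadow, fruit body, prickles, salt noise.  The
    ground truth is the body-only mask (no prickles, no shadow, no noise).
    """
    spec.validate_canvas(with_prickles=spec.prickle_count > 0, with_shadow=True)
    rng = np.random.default_rng(spec.seed)
    h, w = spec.canvas
    center = spec._center()
    a, b = spec.semi_axes_px

    img = np.empty((h, w, 3), dtype=np.uint8)
    img[...] = np.array(spec.background_color, dtype=np.uint8)

    if spec.shadow_intensity < 1.0:
        sc = (center[0] + spec.shadow_offset_px[0], center[1] + spec.shadow_offset_px[1])
        shadow = _ellipse_mask(spec.canvas, sc, (a, b), spec.pose_deg).astype(bool)
        gray = int(round(np.mean(spec.background_color) * spec.shadow_intensity))
        img[shadow] = (gray, gray, gray)

    body, _ = render_binary_ellipse(spec)
    img[body.astype(bool)] = spec.fruit_color

    if spec.prickle_count > 0:
        _draw_prickles(img, spec, center, rng)

    if spec.salt_rate > 0:
        salt = rng.random((h, w)) < spec.salt_rate
        img[salt] = (255, 255, 255)

    return img, body


def _draw_prickles(img, spec, center, rng):
    h, w = spec.canvas
    a, b = spec.semi_axes_px
    th = math.radians(spec.pose_deg)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    color = tuple(int(c * 0.85) for c in spec.fruit_color)
    for _ in range(spec.prickle_count):
        phi = rng.uniform(0.0, 2.0 * math.pi)
        base = np.array([a * math.cos(phi), b * math.sin(phi)])  # ellipse frame (x, y)
        normal = np.array([math.cos(phi) / a, math.sin(phi) / b])
        normal /= np.linalg.norm(normal)
        length = rng.uniform(0.6, 1.0) * spec.prickle_len_px
        base_img = rot @ base
        dir_img = rot @ normal
        perp = np.array([-dir_img[1], dir_img[0]])
        # rasterize on the dominant axis so the spike stays 1 px thin, then
        # optionally widen to 2 px by one integer-offset copy near the base
        steps = max(int(math.ceil(length)), 2)
        for t in np.linspace(0.0, length, steps):
            # taper: full width near the base, 1 px towards the tip
            width = spec.prickle_width_px if t < length * 0.5 else 1
            pt = base_img + t * dir_img
            col = int(round(center[1] + pt[0]))
            row = int(round(center[0] + pt[1]))
            offsets = [(0, 0)]
            if width == 2:
                if abs(perp[0]) >= abs(perp[1]):
                    offsets.append((0, 1 if perp[0] > 0 else -1))
                else:
                    offsets.append((1 if perp[1] > 0 else -1, 0))
            for drow, dcol in offsets:
                rr, cc = row + drow, col + dcol
                if 0 <= rr < h and 0 <= cc < w:
                    img[rr, cc] = color


@dataclass(frozen=True)
class PopulationSpec:
    """Statistical recipe for a fruit population table.

    The fruit is modeled as a triaxial ellipsoid with semi-axes
    ``p >= q`` (the two near-equal long axes) and ``r`` (the short vertical
    axis).  ``p`` and ``r`` follow correlated normals matching the reference
    axis summaries; ``q = p * exp(N(0, mid_axis_sigma))``.  Projections:
    PA1 = pi*q*r, PA2 = pi*p*r (side views), PA3 = pi*p*q (top view), each
    with independent multiplicative noise.  The recorded half-axes are
    a = max(p, q), b = r.  Measured volume tracks the paraboloid reference
    volume; mass tracks density times the ellipsoid reference volume (or an
    explicit ``mass_model`` evaluated on the noise-free features).
    """

    n: int = 60
    seed: int = 0
    a_mean_mm: float = REFERENCE_SUMMARY["a_mm"][0]
    a_sd_mm: float = REFERENCE_SUMMARY["a_mm"][1]
    b_mean_mm: float = REFERENCE_SUMMARY["b_mm"][0]
    b_sd_mm: float = REFERENCE_SUMMARY["b_mm"][1]
    ab_corr: float = 0.85
    mid_axis_sigma: float = 0.04
    side_area_cv: float = 0.01
    top_area_cv: float = 0.07
    volume_cv: float = 0.07
    mass_cv: float = 0.08
    density_g_per_ml: float = _DEFAULT_DENSITY
    mass_model: RegressionModel | None = None

    def __post_init__(self):
        if self.n < 1:
            raise DomainError("population size must be >= 1")
        for name in ("a_mean_mm", "a_sd_mm", "b_mean_mm", "b_sd_mm", "density_g_per_ml"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")
        for name in ("mid_axis_sigma", "side_area_cv", "top_area_cv", "volume_cv", "mass_cv"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if not -1.0 < self.ab_corr < 1.0:
            raise DomainError("ab_corr must lie in (-1, 1)")

    def zero_noise(self) -> "PopulationSpec":
        """Copy with every noise scale (and the mid-axis jitter) set to zero."""
        return replace(
            self,
            mid_axis_sigma=0.0,
            side_area_cv=0.0,
            top_area_cv=0.0,
            volume_cv=0.0,
            mass_cv=0.0,
        )


def generate_population(spec: PopulationSpec) -> list[FruitRecord]:
    """Sample a fruit population table per the spec; deterministic in the seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    p = np.clip(spec.a_mean_mm + spec.a_sd_mm * z1, 1.0, None)
    r = (
        spec.b_mean_mm
        + spec.ab_corr * (spec.b_sd_mm / spec.a_sd_mm) * (p - spec.a_mean_mm)
        + spec.b_sd_mm * math.sqrt(1.0 - spec.ab_corr**2) * z2
    )
    if spec.mid_axis_sigma > 0:
        q = p * np.exp(rng.normal(0.0, spec.mid_axis_sigma, n))
    else:
        q = p.copy()
    # keep the fruit oblate: the vertical axis is strictly the shortest
    r = np.clip(r, 1.0, 0.95 * np.minimum(p, q))

    def noisy(cv):
        return 1.0 + cv * rng.standard_normal(n) if cv > 0 else np.ones(n)

    pa1 = math.pi * q * r / 100.0 * noisy(spec.side_area_cv)
    pa2 = math.pi * p * r / 100.0 * noisy(spec.side_area_cv)
    pa3 = math.pi * p * q / 100.0 * noisy(spec.top_area_cv)

    a_rep = np.maximum(p, q)
    b_rep = r
    v_ellip = np.array([ellipsoid_volume(a / 10.0, b / 10.0) for a, b in zip(a_rep, b_rep)])
    v_parab = np.array([paraboloid_volume(a / 10.0, b / 10.0) for a, b in zip(a_rep, b_rep)])
    cpa = (pa1 + pa2 + pa3) / 3.0

    volume = v_parab * noisy(spec.volume_cv)
    if spec.mass_model is not None:
        features = {
            "a": a_rep,
            "b": b_rep,
            "PA1": pa1,
            "PA2": pa2,
            "PA3": pa3,
            "CPA": cpa,
            "Vellip": v_ellip,
            "Vparab": v_parab,
            "V": volume,
        }
        mass = np.asarray(predict(spec.mass_model, features), dtype=float)
        mass = mass * noisy(spec.mass_cv)
    else:
        mass = spec.density_g_per_ml * v_ellip * noisy(spec.mass_cv)

    records = []
    for i in range(n):
        records.append(
            FruitRecord(
                id=f"synth-{i:03d}",
                mass_g=float(mass[i]),
                volume_ml=float(volume[i]),
                a_mm=float(a_rep[i]),
                b_mm=float(b_rep[i]),
                pa1_cm2=float(pa1[i]),
                pa2_cm2=float(pa2[i]),
                pa3_cm2=float(pa3[i]),
                cpa_cm2=float(compute_cpa(pa1[i], pa2[i], pa3[i])),
                v_ellip_ml=float(v_ellip[i]),
                v_parab_ml=float(v_parab[i]),
            )
        )
    return records


def make_three_views(
    semi_axes_mm: tuple[float, float, float],
    mm_per_px: float,
    canvas: tuple[int, int] = (224, 224),
    pose_deg: Mapping[str, float] | None = None,
    seed: int = 0,
    **kwargs,
) -> dict[str, FruitImageSpec]:
    """Projection specs of one triaxial fruit for the x/y/z camera views.

    Semi-axes (p >= q >= r, mm) are sorted internally.  The top (z) view
    projects the two largest semi-axes (p, q); the side views share the
    shortest, vertical axis r: x sees (q, r), y sees (p, r).  Default pose is
    0 deg in every view so the shared axis is vertical in both side views.
    """
    p, q, r = sorted(semi_axes_mm, reverse=True)
    if r <= 0:
        raise DomainError("semi-axes must be > 0")
    if mm_per_px <= 0:
        raise DomainError("mm_per_px must be > 0")
    poses = {"x": 0.0, "y": 0.0, "z": 0.0}
    if pose_deg:
        poses.update(pose_deg)
    axes = {
        "x": (q / mm_per_px, r / mm_per_px),
        "y": (p / mm_per_px, r / mm_per_px),
        "z": (p / mm_per_px, q / mm_per_px),
    }
    return {
        view: FruitImageSpec(
            semi_axes_px=axes[view],
            pose_deg=poses[view],
            canvas=canvas,
            seed=seed + i,
            **kwargs,
        )
        for i, view in enumerate(("x", "y", "z"))
    }


def truth_to_json(truth: dict, path) -> None:
    """Write a ground-truth sidecar next to a rendered fixture image."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
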