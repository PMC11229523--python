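"""Calibrated measurement of fruit silhouettes.

Given a filled binary mask of a near-ellipsoidal fruit, this module measures
the long/short axis chords by rotation scanning, converts pixel counts to
projected areas via a camera calibration, and derives the criterion projected
area (CPA), ellipsoid and paraboloid reference volumes, the slice-and-
integrate reference area, and the mean relative error metric.

Units and conventions
---------------------
* Masks are row-major uint8 {0, 1} grids, origin top-left, 0-based.
* ``a`` (half-long axis) and ``b`` (half-short axis) are reported in mm;
  projected areas in cm^2; volumes in ml (= cm^3).
* The rotation scan searches angles in [0, 180) deg; chord lengths are the
  longest contiguous horizontal run per row.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import DomainError, EmptyMaskError, InvalidConfigError, SchemaError
from .imgproc import as_binary_mask

__all__ = [
    "CameraCalibration",
    "AxisMeasurement",
    "ProjectedAreas",
    "FruitRecord",
    "count_foreground",
    "area_cm2",
    "max_chord",
    "rotate_mask",
    "measure_axes",
    "compute_cpa",
    "slice_integrate_area",
    "mean_relative_error",
    "ellipsoid_volume",
    "paraboloid_volume",
    "measure_fruit",
    "records_to_frame",
    "records_to_csv",
    "read_records_csv",
    "RECORD_COLUMNS",
]


@dataclass(frozen=True)
class CameraCalibration:
    """Pixel-to-physical-unit conversion for length (mm) and area (mm^2).

    The two ratios are redundant in an ideal pinhole setup; they must agree to
    within 5% (``mm2_per_px`` vs ``mm_per_px`` squared), which guards against
    mixed-up units in calibration files.
    """

    mm_per_px: float
    mm2_per_px: float

    def __post_init__(self):
        if self.mm_per_px <= 0 or self.mm2_per_px <= 0:
            raise DomainError("calibration ratios must be > 0")
        expected = self.mm_per_px**2
        if abs(self.mm2_per_px - expected) / expected >= 0.05:
            raise DomainError(
                "length and area calibrations are inconsistent: "
                f"mm2_per_px={self.mm2_per_px:g} vs mm_per_px^2={expected:g}"
            )

    @classmethod
    def from_pixel_ratios(
        cls, px_per_mm: float, px_per_mm2: float | None = None
    ) -> "CameraCalibration":
        """Build from the inverse ('pixels per mm') reading of the ratios."""
        if px_per_mm <= 0:
            raise DomainError("px_per_mm must be > 0")
        mm_per_px = 1.0 / px_per_mm
        mm2 = 1.0 / px_per_mm2 if px_per_mm2 else mm_per_px**2
        return cls(mm_per_px=mm_per_px, mm2_per_px=mm2)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CameraCalibration":
        with open(path) as fh:
            raw = json.load(fh)
        try:
            return cls(mm_per_px=float(raw["mm_per_px"]), mm2_per_px=float(raw["mm2_per_px"]))
        except KeyError as exc:
            raise SchemaError(f"calibration file missing key {exc}") from exc


@dataclass(frozen=True)
class AxisMeasurement:
    """Result of the rotation-scan axis search on one or more masks."""

    L1_px: float  # longest maximal chord over all rotations
    L3_px: float  # shortest maximal chord over all rotations
    a_mm: float  # half-long axis
    b_mm: float  # half-short axis
    theta_at_max_deg: float  # first angle attaining L1

    def __post_init__(self):
        if not self.L1_px >= self.L3_px > 0:
            raise DomainError("axis chords must satisfy L1 >= L3 > 0")


@dataclass(frozen=True)
class ProjectedAreas:
    """Three mutually perpendicular projected areas and their mean (cm^2)."""

    pa1_cm2: float
    pa2_cm2: float
    pa3_cm2: float

    @property
    def cpa_cm2(self) -> float:
        return compute_cpa(self.pa1_cm2, self.pa2_cm2, self.pa3_cm2)


@dataclass
class FruitRecord:
    """One fruit's feature vector; mass/volume may be absent (None)."""

    id: str
    mass_g: float | None = None
    volume_ml: float | None = None
    a_mm: float | None = None
    b_mm: float | None = None
    pa1_cm2: float | None = None
    pa2_cm2: float | None = None
    pa3_cm2: float | None = None
    cpa_cm2: float | None = None
    v_ellip_ml: float | None = None
    v_parab_ml: float | None = None

    def features(self) -> dict:
        """Model-facing names: a/b in mm, PAs and CPA in cm^2, volumes in ml."""
        return {
            "a": self.a_mm,
            "b": self.b_mm,
            "PA1": self.pa1_cm2,
            "PA2": self.pa2_cm2,
            "PA3": self.pa3_cm2,
            "CPA": self.cpa_cm2,
            "Vellip": self.v_ellip_ml,
            "Vparab": self.v_parab_ml,
            "M": self.mass_g,
            "V": self.volume_ml,
        }


RECORD_COLUMNS = [
    "id",
    "mass_g",
    "volume_ml",
    "a_mm",
    "b_mm",
    "pa1_cm2",
    "pa2_cm2",
    "pa3_cm2",
    "cpa_cm2",
    "v_ellip_ml",
    "v_parab_ml",
]

_FEATURE_TO_COLUMN = {
    "M": "mass_g",
    "V": "volume_ml",
    "a": "a_mm",
    "b": "b_mm",
    "PA1": "pa1_cm2",
    "PA2": "pa2_cm2",
    "PA3": "pa3_cm2",
    "CPA": "cpa_cm2",
    "Vellip": "v_ellip_ml",
    "Vparab": "v_parab_ml",
}


# ---------------------------------------------------------------------------
# pixel counting and calibration


def count_foreground(mask) -> int:
    """Exact number of foreground (value 1) pixels."""
    return int(as_binary_mask(mask).sum())


def area_cm2(count: int, cal: CameraCalibration) -> float:
    """Convert a foreground pixel count to a physical area in cm^2."""
    if count < 0:
        raise DomainError("pixel count must be >= 0")
    return count * cal.mm2_per_px / 100.0


# ---------------------------------------------------------------------------
# chord scanning


def max_chord(mask) -> int:
    """Longest contiguous horizontal foreground run over all rows.

    Robust to stray interior holes (a hole splits the run); on hole-free
    filled masks this equals the maximal row sum.  Ties across rows resolve
    to the topmost row, which only matters for diagnostics.
    """
    m = as_binary_mask(mask)
    if m.sum() == 0:
        raise EmptyMaskError("cannot measure chords on an empty mask")
    h, w = m.shape
    # runs per row via padded differences; row boundaries are separated by the pad
    padded = np.zeros((h, w + 2), dtype=np.int8)
    padded[:, 1:-1] = m
    diff = np.diff(padded, axis=1)
    best = 0
    for r in range(h):
        starts = np.flatnonzero(diff[r] == 1)
        if starts.size == 0:
            continue
        ends = np.flatnonzero(diff[r] == -1)
        best = max(best, int((ends - starts).max()))
    return best


def rotate_mask(mask, angle_deg: float) -> np.ndarray:
    """Rotate a mask with nearest-neighbor resampling on an expanded canvas.

    The canvas grows so that no foreground pixel is clipped; for chord
    measurements the (centroid vs canvas-center) pivot distinction is
    irrelevant, so the array center is used as the pivot.
    """
    m = as_binary_mask(mask)
    if angle_deg % 360 == 0:
        return m.copy()
    out = ndi.rotate(m, angle_deg, reshape=True, order=0, mode="constant", cval=0)
    return as_binary_mask(out)


def measure_axes(
    mask, cal: CameraCalibration, step_deg: float = 1.0
) -> AxisMeasurement:
    """Rotation-scan search for the long (L1) and short (L3) axis chords.

    The mask is rotated through ``theta in {0, step, ..., 180 - step}`` and
    the maximal horizontal chord recorded at each pose; L1 is the maximum and
    L3 the minimum of those maxima.  Half-axes are ``a = L1 * mm_per_px / 2``
    and ``b = L3 * mm_per_px / 2``.  On ties the first-attaining angle wins.
    """
    chords = _chord_profile(mask, step_deg)
    angles = np.arange(0.0, 180.0, step_deg)
    i_max = int(np.argmax(chords))
    L1 = float(chords[i_max])
    L3 = float(np.min(chords))
    return AxisMeasurement(
        L1_px=L1,
        L3_px=L3,
        a_mm=L1 * cal.mm_per_px / 2.0,
        b_mm=L3 * cal.mm_per_px / 2.0,
        theta_at_max_deg=float(angles[i_max]),
    )


def _chord_profile(mask, step_deg: float) -> np.ndarray:
    if step_deg <= 0 or abs(round(180.0 / step_deg) - 180.0 / step_deg) > 1e-9:
        raise InvalidConfigError("step_deg must divide 180 evenly")
    m = as_binary_mask(mask)
    if m.sum() == 0:
        raise EmptyMaskError("cannot measure axes on an empty mask")
    angles = np.arange(0.0, 180.0, step_deg)
    return np.array([max_chord(rotate_mask(m, ang)) for ang in angles], dtype=float)


# ---------------------------------------------------------------------------
# derived quantities


def compute_cpa(pa1: float, pa2: float, pa3: float) -> float:
    """Criterion projected area: arithmetic mean of the three projections."""
    if pa1 < 0 or pa2 < 0 or pa3 < 0:
        raise DomainError("projected areas must be >= 0")
    return (pa1 + pa2 + pa3) / 3.0


def slice_integrate_area(profile: Sequence[tuple[float, float]]) -> float:
    """Reference area of a traced outline, summed as circular sectors.

    ``profile`` is an ordered list of ``(delta_theta_deg, radius)`` steps whose
    angles must close the full circle (sum to 360 deg); each step contributes
    ``delta_theta * pi * r^2 / 360``.  The radius unit is the caller's; the
    area comes back in that unit squared.
    """
    steps = list(profile)
    if not steps:
        raise DomainError("profile must contain at least one step")
    angles = np.array([s[0] for s in steps], dtype=float)
    radii = np.array([s[1] for s in steps], dtype=float)
    if (angles <= 0).any():
        raise DomainError("all step angles must be > 0")
    if abs(angles.sum() - 360.0) > 1e-9:
        raise DomainError(
            f"open profile: step angles sum to {angles.sum():g}, expected 360"
        )
    return float(np.sum(angles * math.pi * radii**2 / 360.0))


def mean_relative_error(pv: Iterable[float], mv: Iterable[float]) -> float:
    """Mean of |pv - mv| / mv across paired measurements, in percent."""
    p = np.asarray(list(pv), dtype=float)
    m = np.asarray(list(mv), dtype=float)
    if p.shape != m.shape or p.size == 0:
        raise DomainError("pv and mv must have equal nonzero length")
    if (m <= 0).any():
        raise DomainError("reference measurements must be > 0")
    return float(np.mean(np.abs(p - m) / m) * 100.0)


def ellipsoid_volume(a_cm: float, b_cm: float) -> float:
    """Prolate-ellipsoid reference volume 4*pi*a^2*b/3 (axes in cm, result ml)."""
    if a_cm <= 0 or b_cm <= 0:
        raise DomainError("semi-axes must be > 0")
    return 4.0 * math.pi * a_cm**2 * b_cm / 3.0


def paraboloid_volume(a_cm: float, b_cm: float) -> float:
    """Paraboloid reference volume 4*pi*a*b^2/3 (axes in cm, result ml)."""
    if a_cm <= 0 or b_cm <= 0:
        raise DomainError("semi-axes must be > 0")
    return 4.0 * math.pi * a_cm * b_cm**2 / 3.0


# ---------------------------------------------------------------------------
# whole-fruit measurement


def measure_fruit(
    masks: Mapping[str, np.ndarray],
    cal: CameraCalibration,
    step_deg: float = 1.0,
    fruit_id: str = "fruit",
) -> FruitRecord:
    """Measure a fruit from its three orthogonal view masks.

    ``masks`` maps view labels ``"x"``/``"y"`` (side views) and ``"z"`` (top
    view) to filled binary masks.  Projected areas PA1/PA2/PA3 come from
    calibrated pixel counts of the x/y/z views; the half-axes are searched
    jointly across all three views (global longest and shortest maximal
    chords), treating the fruit as a single approximate ellipsoid.
    """
    for view in ("x", "y", "z"):
        if view not in masks:
            raise SchemaError(f"missing view {view!r}")
        if count_foreground(masks[view]) == 0:
            raise EmptyMaskError(f"view {view!r} has an empty mask")

    pa = {
        view: area_cm2(count_foreground(masks[view]), cal) for view in ("x", "y", "z")
    }
    profiles = {view: _chord_profile(masks[view], step_deg) for view in ("x", "y", "z")}
    L1 = max(float(p.max()) for p in profiles.values())
    L3 = min(float(p.min()) for p in profiles.values())
    a_mm = L1 * cal.mm_per_px / 2.0
    b_mm = L3 * cal.mm_per_px / 2.0
    a_cm, b_cm = a_mm / 10.0, b_mm / 10.0
    return FruitRecord(
        id=fruit_id,
        a_mm=a_mm,
        b_mm=b_mm,
        pa1_cm2=pa["x"],
        pa2_cm2=pa["y"],
        pa3_cm2=pa["z"],
        cpa_cm2=compute_cpa(pa["x"], pa["y"], pa["z"]),
        v_ellip_ml=ellipsoid_volume(a_cm, b_cm),
        v_parab_ml=paraboloid_volume(a_cm, b_cm),
    )


# ---------------------------------------------------------------------------
# tabular IO


def records_to_frame(records: Iterable[FruitRecord]) -> pd.DataFrame:
    """DataFrame with model-facing column names (a, b, PA1..PA3, CPA, M, V...)."""
    rows = []
    for rec in records:
        row = {"id": rec.id}
        row.update(rec.features())
        rows.append(row)
    return pd.DataFrame(rows)


def records_to_csv(records: Iterable[FruitRecord], path) -> None:
    df = pd.DataFrame(
        [{col: getattr(rec, col) for col in RECORD_COLUMNS} for rec in records]
    )
    df.to_csv(path, index=False)


def read_records_csv(path) -> list[FruitRecord]:
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns and c != "id"]
    if "id" not in df.columns:
        raise SchemaError("records CSV must have an 'id' column")
    if missing:
        raise SchemaError(f"records CSV missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        kwargs = {"id": str(row["id"])}
        for col in RECORD_COLUMNS[1:]:
            val = row[col]
            kwargs[col] = None if pd.isna(val) else float(val)
        records.append(FruitRecord(**kwargs))
    return records


def frame_from_csv(path) -> pd.DataFrame:
    """Records CSV -> model-facing DataFrame (convenience for fitting)."""
    return records_to_frame(read_records_csv(path))
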