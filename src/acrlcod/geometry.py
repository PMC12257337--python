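"""Geometry of the large ACR phantom low-contrast insert and 1-D templates.

The low-contrast object detectability (LCOD) insert of the large ACR MRI
phantom consists of four plastic sheets, imaged on slices 8-11 of the
standard 11-slice axial series.  Each sheet carries 30 holes arranged in 10
radial spokes; within a spoke the three holes sit at 12.5, 25 and 38 mm
from the sheet center, and the hole diameter shrinks linearly from 7 mm
(spoke 1) to 1.5 mm (spoke 10) following a clockwise progression.  The hole
depth varies per sheet, producing nominal hole/background contrasts of
1.4, 2.5, 3.6 and 5.1 % on slices 8-11.

Angles throughout the package use a *clock convention*: 0 degrees points at
the image 12 o'clock, and angles grow clockwise (matching the clockwise
spoke numbering of the phantom).  With row 0 at the image top, the unit
direction of a ray at clock angle ``a`` is ``(-cos a, sin a)`` in
(row, col) order.

Detection operates on 1-D radial intensity profiles; this module builds the
matching 1-D design: three binary hole-indicator regressors per spoke plus
an orthonormal polynomial nuisance basis that absorbs smooth intensity
non-uniformity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import GeometryError

__all__ = [
    "PhantomLayout",
    "SpokeSpec",
    "SpokeTemplate",
    "hole_diameter",
    "spoke_spec",
    "build_spoke_template",
    "clock_angle_to_rowcol",
]


def clock_angle_to_rowcol(angle_deg: float) -> tuple[float, float]:
    """Unit direction (row, col) of a ray at a clock-convention angle.

    The angle is reduced to [0, 360) first so equivalent angles map to
    bitwise-identical directions.
    """
    a = math.radians(angle_deg % 360.0)
    return (-math.cos(a), math.sin(a))


def _default_base_angles() -> dict[int, float]:
    # The physical spoke-1 orientations are not standardized in public
    # documentation; a common nominal of 12 o'clock + 90 deg clockwise
    # (3 o'clock) is assumed for every LCOD slice and is user-overridable.
    return {8: 90.0, 9: 90.0, 10: 90.0, 11: 90.0}


def _default_contrasts() -> dict[int, float]:
    return {8: 1.4, 9: 2.5, 10: 3.6, 11: 5.1}


@dataclass(frozen=True)
class PhantomLayout:
    """Geometric ground truth of the LCOD sheets of the large ACR phantom.

    All lengths are millimetres, angles degrees in the clock convention,
    contrasts percent.  ``inner_disk_radius_mm`` is the nominal radius of
    the contrast disk, i.e. the physical span of a 90-sample, ~0.5 mm
    radial profile.
    """

    n_spokes: int = 10
    holes_per_spoke: int = 3
    hole_radial_centers_mm: tuple[float, float, float] = (12.5, 25.0, 38.0)
    diameter_first_spoke_mm: float = 7.0
    diameter_last_spoke_mm: float = 1.5
    spoke_angle_step_deg: float = 36.0
    per_slice_base_angle_deg: Mapping[int, float] = field(
        default_factory=_default_base_angles
    )
    lcod_slice_indices_1based: tuple[int, ...] = (8, 9, 10, 11)
    slice_contrasts_pct: Mapping[int, float] = field(default_factory=_default_contrasts)
    inner_disk_radius_mm: float = 45.0

    def __post_init__(self) -> None:
        centers = self.hole_radial_centers_mm
        if not all(b > a for a, b in zip(centers, centers[1:])):
            raise GeometryError("hole radial centers must be strictly increasing")
        if centers[-1] >= self.inner_disk_radius_mm:
            raise GeometryError("outermost hole center must lie inside the disk")
        if not (self.diameter_first_spoke_mm > self.diameter_last_spoke_mm > 0):
            raise GeometryError("hole diameters must be positive and decreasing")
        if abs(self.n_spokes * self.spoke_angle_step_deg - 360.0) > 1e-9:
            raise GeometryError("spokes must tile the full circle")
        min_gap = min(b - a for a, b in zip(centers, centers[1:]))
        if self.diameter_first_spoke_mm >= min_gap:
            raise GeometryError("hole supports within a spoke must be disjoint")
        missing = [
            s
            for s in self.lcod_slice_indices_1based
            if s not in self.per_slice_base_angle_deg
            or s not in self.slice_contrasts_pct
        ]
        if missing:
            raise GeometryError(f"missing base angle or contrast for slices {missing}")

    # -- serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_spokes": self.n_spokes,
            "holes_per_spoke": self.holes_per_spoke,
            "hole_radial_centers_mm": list(self.hole_radial_centers_mm),
            "diameter_first_spoke_mm": self.diameter_first_spoke_mm,
            "diameter_last_spoke_mm": self.diameter_last_spoke_mm,
            "spoke_angle_step_deg": self.spoke_angle_step_deg,
            "per_slice_base_angle_deg": {
                str(k): v for k, v in self.per_slice_base_angle_deg.items()
            },
            "lcod_slice_indices_1based": list(self.lcod_slice_indices_1based),
            "slice_contrasts_pct": {
                str(k): v for k, v in self.slice_contrasts_pct.items()
            },
            "inner_disk_radius_mm": self.inner_disk_radius_mm,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PhantomLayout":
        d = dict(d)
        for key in ("per_slice_base_angle_deg", "slice_contrasts_pct"):
            if key in d:
                d[key] = {int(k): float(v) for k, v in d[key].items()}
        for key in ("hole_radial_centers_mm", "lcod_slice_indices_1based"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PhantomLayout":
        """Load a layout from a YAML or JSON config file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    @classmethod
    def default(cls) -> "PhantomLayout":
        return cls()


@dataclass(frozen=True)
class SpokeSpec:
    """One spoke of one LCOD slice: diameter, nominal angle, hole centers."""

    spoke_index: int
    diameter_mm: float
    nominal_angle_deg: float
    hole_centers_mm: tuple[float, float, float]


def hole_diameter(spoke_index: int, layout: PhantomLayout | None = None) -> float:
    """Hole diameter (mm) of a spoke, linear in the spoke index.

    The insert's diameters run from 7 mm (spoke 1) to 1.5 mm (spoke 10) in
    uniform clockwise steps, so intermediate spokes are interpolated:
    ``d(k) = 7 - (k - 1) * (7 - 1.5) / 9``.
    """
    layout = layout or PhantomLayout.default()
    k = spoke_index
    if not (isinstance(k, (int, np.integer)) and 1 <= k <= layout.n_spokes):
        raise ValueError(f"spoke_index must be in 1..{layout.n_spokes}, got {k!r}")
    d0 = layout.diameter_first_spoke_mm
    d1 = layout.diameter_last_spoke_mm
    return d0 - (k - 1) * (d0 - d1) / (layout.n_spokes - 1)


def spoke_spec(
    spoke_index: int, slice_index: int, layout: PhantomLayout | None = None
) -> SpokeSpec:
    """Geometry of one spoke on one LCOD slice.

    The nominal angle steps clockwise by 36 degrees per spoke from the
    slice's base (spoke 1) angle, reduced to [0, 360).
    """
    layout = layout or PhantomLayout.default()
    if slice_index not in layout.lcod_slice_indices_1based:
        raise ValueError(
            f"slice {slice_index} is not an LCOD slice "
            f"{layout.lcod_slice_indices_1based}"
        )
    base = layout.per_slice_base_angle_deg[slice_index]
    angle = (base - (spoke_index - 1) * layout.spoke_angle_step_deg) % 360.0
    return SpokeSpec(
        spoke_index=spoke_index,
        diameter_mm=hole_diameter(spoke_index, layout),
        nominal_angle_deg=angle,
        hole_centers_mm=tuple(layout.hole_radial_centers_mm),
    )


@dataclass(frozen=True)
class SpokeTemplate:
    """1-D detection design for one spoke on the resampled profile grid.

    ``hole_indicators`` has one binary column per hole (1 where the sample
    radius falls within the hole support); ``nuisance_basis`` holds an
    orthonormal polynomial basis of degree 0..poly_order that models smooth
    background variation.  The full design is their horizontal stack.
    """

    n_samples: int
    sample_spacing_mm: float
    hole_indicators: np.ndarray  # (n_samples, 3) in {0, 1}
    nuisance_basis: np.ndarray  # (n_samples, poly_order + 1)

    @property
    def design(self) -> np.ndarray:
        return np.hstack([self.hole_indicators, self.nuisance_basis])

    @property
    def n_regressors(self) -> int:
        return self.hole_indicators.shape[1] + self.nuisance_basis.shape[1]


@lru_cache(maxsize=8)
def _orthonormal_poly_basis(n_samples: int, order: int) -> np.ndarray:
    """Discrete orthonormal polynomials of degree 0..order on the grid."""
    x = np.linspace(-1.0, 1.0, n_samples)
    V = np.vander(x, order + 1, increasing=True)
    Q, R = np.linalg.qr(V)
    # fix signs so the constant column is positive (QR sign ambiguity)
    Q = Q * np.sign(np.diag(R))
    Q.setflags(write=False)
    return Q


def build_spoke_template(
    spec: SpokeSpec,
    profile_length_mm: float,
    n_samples: int = 90,
    poly_order: int = 2,
) -> SpokeTemplate:
    """Build the hole-indicator + polynomial design for one spoke.

    Sample ``j`` sits at radius ``r_j = j * profile_length_mm / (n_samples - 1)``;
    hole indicator ``i`` is 1 iff ``|r_j - center_i| <= diameter / 2``
    (inclusive edges; at the ~0.5 mm grid, fractional boundary coverage is
    negligible).
    """
    if n_samples < 30:
        raise GeometryError(f"n_samples must be >= 30, got {n_samples}")
    outer_edge = spec.hole_centers_mm[-1] + spec.diameter_mm / 2.0
    if profile_length_mm < outer_edge:
        raise GeometryError(
            f"profile length {profile_length_mm:.2f} mm does not reach the "
            f"outermost hole edge at {outer_edge:.2f} mm"
        )
    r = np.linspace(0.0, profile_length_mm, n_samples)
    half = spec.diameter_mm / 2.0
    indicators = np.column_stack(
        [(np.abs(r - c) <= half).astype(float) for c in spec.hole_centers_mm]
    )
    if (indicators.sum(axis=0) < 1).any():
        raise GeometryError(
            "a hole support contains no profile sample; increase n_samples"
        )
    basis = _orthonormal_poly_basis(n_samples, poly_order)
    return SpokeTemplate(
        n_samples=n_samples,
        sample_spacing_mm=profile_length_mm / (n_samples - 1),
        hole_indicators=indicators,
        nuisance_basis=basis,
    )
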