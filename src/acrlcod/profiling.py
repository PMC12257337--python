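"""Radial intensity profiles from the disk center of gravity outward.

A ray is cast from the COG at a clock-convention angle, sampling bilinear
interpolated intensities every half pixel pitch (Nyquist-safe for a 256
matrix over a 250 mm FOV).  The ray is truncated at the disk edge — the
segmentation mask, rather than a literal zero-intensity test, defines the
edge because normalized backgrounds are near but not exactly zero.  The
raw trace is then linearly resampled onto a fixed grid of 90 samples
(~0.5 mm per sample), and small integer "jitter" shifts of the resampled
profile compensate residual geometric error when matched to a template.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import RayTooShortError
from .geometry import clock_angle_to_rowcol
from .io import PhantomSlice
from .segmentation import DiskMask

__all__ = [
    "RawProfile",
    "RadialProfile",
    "cast_ray",
    "resample_profile",
    "jitter_variants",
    "shift_samples",
]


@dataclass(frozen=True)
class RawProfile:
    """Variable-length ray trace before resampling."""

    distances_mm: np.ndarray
    values: np.ndarray
    angle_deg: float
    origin_rowcol_px: tuple[float, float]

    @property
    def physical_length_mm(self) -> float:
        return float(self.distances_mm[-1])


@dataclass(frozen=True)
class RadialProfile:
    """Fixed-grid radial profile: ``samples[0]`` at the COG, last at the edge."""

    samples: np.ndarray
    sample_spacing_mm: float
    angle_deg: float
    origin_rowcol_px: tuple[float, float]
    physical_length_mm: float

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def cast_ray(
    slc: PhantomSlice,
    mask: DiskMask,
    angle_deg: float,
    min_length_mm: float = 0.0,
    step_mm: float | None = None,
) -> RawProfile:
    """Sample intensities along a ray from the COG, truncated at the mask edge."""
    cog = mask.cog_rowcol_px
    if not mask.contains(*cog):
        raise RayTooShortError("COG lies outside the disk mask")
    sr, sc = slc.pixel_spacing_mm
    if step_mm is None:
        step_mm = 0.5 * min(sr, sc)
    drow, dcol = clock_angle_to_rowcol(angle_deg)

    h, w = slc.shape
    # rays cannot outrun the segmented disk by much; capping the walk well
    # above its radius keeps the interpolation cheap without truncating
    max_dist = min(
        float(np.hypot(h * sr, w * sc)), 2.0 * mask.equivalent_radius_mm
    )
    n_steps = int(max_dist / step_mm) + 1
    dist = np.arange(n_steps) * step_mm
    rows = cog[0] + dist * drow / sr
    cols = cog[1] + dist * dcol / sc

    # a sample is inside only if its full bilinear support lies in the
    # interior (eroded) mask, so no profile value blends the disk plateau
    # with partial-volume edge pixels or background
    in_image = (rows >= 0) & (rows <= h - 1) & (cols >= 0) & (cols <= w - 1)
    r0 = np.clip(np.floor(rows).astype(int), 0, h - 1)
    r1 = np.clip(np.ceil(rows).astype(int), 0, h - 1)
    c0 = np.clip(np.floor(cols).astype(int), 0, w - 1)
    c1 = np.clip(np.ceil(cols).astype(int), 0, w - 1)
    m = mask.ray_mask
    inside = (
        in_image & m[r0, c0] & m[r0, c1] & m[r1, c0] & m[r1, c1]
    )
    # keep the contiguous inside-run starting at the COG
    first_out = np.argmin(inside) if not inside.all() else n_steps
    if first_out == 0:
        raise RayTooShortError("ray leaves the mask immediately")
    dist = dist[:first_out]
    values = ndimage.map_coordinates(
        slc.intensities, [rows[:first_out], cols[:first_out]], order=1, mode="nearest"
    )
    if dist[-1] < min_length_mm:
        raise RayTooShortError(
            f"ray at {angle_deg:.1f} deg truncated at {dist[-1]:.1f} mm, "
            f"before the outermost hole edge ({min_length_mm:.1f} mm)"
        )
    return RawProfile(
        distances_mm=dist,
        values=np.asarray(values, dtype=float),
        angle_deg=float(angle_deg),
        origin_rowcol_px=cog,
    )


def resample_profile(raw: RawProfile, n_samples: int = 90) -> RadialProfile:
    """Linearly resample a raw ray onto ``n_samples`` evenly spaced points.

    The grid spans [0, physical_length_mm]; with the default 90 samples
    over a ~45 mm disk radius this is approximately 0.5 mm per sample.
    """
    if len(raw.distances_mm) < 2:
        raise RayTooShortError("raw profile needs at least 2 samples")
    length = raw.physical_length_mm
    grid = np.linspace(0.0, length, n_samples)
    samples = np.interp(grid, raw.distances_mm, raw.values)
    return RadialProfile(
        samples=samples,
        sample_spacing_mm=length / (n_samples - 1),
        angle_deg=raw.angle_deg,
        origin_rowcol_px=raw.origin_rowcol_px,
        physical_length_mm=length,
    )


def shift_samples(samples: np.ndarray, shift: int) -> np.ndarray:
    """Shift a 1-D array by ``shift`` indices, replicating the boundary value.

    Positive shifts move content outward (toward larger radius).  Boundary
    replication avoids injecting zeros that would mimic contrast.
    """
    if shift == 0:
        return samples.copy()
    out = np.empty_like(samples)
    if shift > 0:
        out[shift:] = samples[:-shift]
        out[:shift] = samples[0]
    else:
        out[:shift] = samples[-shift:]
        out[shift:] = samples[-1]
    return out


def jitter_variants(profile: RadialProfile, max_shift: int = 5) -> list[RadialProfile]:
    """Profiles shifted by -max_shift..+max_shift samples (edge-replicated).

    Returns ``2 * max_shift + 1`` profiles in ascending shift order; the
    shift-0 variant equals the input.
    """
    if max_shift < 0 or max_shift >= profile.n_samples / 4:
        raise ValueError(
            f"max_shift must be in 0..{profile.n_samples // 4 - 1}, got {max_shift}"
        )
    return [
        replace(profile, samples=shift_samples(profile.samples, s))
        for s in range(-max_shift, max_shift + 1)
    ]
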