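"""Slice normalisation and inner contrast-disk segmentation.

The pipeline's first stage maps each slice to [0, 1], removes background
by automatic histogram (Otsu) thresholding, labels connected components,
and keeps the component that is both near the image center and close in
size to the nominal contrast disk.  Internal holes are filled before the
centroid is taken so the low-contrast holes cannot bias the center of
gravity (COG), which anchors all radial profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure

from .errors import DegenerateInputError, SegmentationError
from .geometry import PhantomLayout
from .io import PhantomSlice

__all__ = ["DiskMask", "normalize_slice", "segment_inner_disk"]


@dataclass(frozen=True)
class DiskMask:
    """Binary mask of the inner contrast disk with its sub-pixel centroid.

    ``interior_mask`` (the mask eroded by one pixel) excludes the
    partial-volume boundary pixels; radial profiles are truncated against
    it so their samples stay on the disk's intensity plateau.
    """

    mask: np.ndarray  # bool, aligned with the slice
    cog_rowcol_px: tuple[float, float]
    equivalent_radius_mm: float
    interior_mask: np.ndarray | None = None

    @property
    def ray_mask(self) -> np.ndarray:
        return self.mask if self.interior_mask is None else self.interior_mask

    def contains(self, row: float, col: float) -> bool:
        r, c = int(round(row)), int(round(col))
        if not (0 <= r < self.mask.shape[0] and 0 <= c < self.mask.shape[1]):
            return False
        return bool(self.mask[r, c])


def normalize_slice(slc: PhantomSlice) -> PhantomSlice:
    """Affinely map slice intensities to [0, 1] (min -> 0, max -> 1)."""
    arr = slc.intensities
    lo, hi = float(arr.min()), float(arr.max())
    if hi <= lo:
        raise DegenerateInputError("constant image cannot be normalized")
    return slc.with_intensities((arr - lo) / (hi - lo))


def segment_inner_disk(
    slc: PhantomSlice,
    layout: PhantomLayout | None = None,
    radius_tolerance: float = 0.20,
) -> DiskMask:
    """Isolate the inner contrast disk of a normalized LCOD slice.

    The normalized image is binarized with Otsu's threshold (256-bin
    histogram), connected foreground components are labeled, and the
    component nearest the image center with equivalent radius
    ``sqrt(area / pi)`` within ``radius_tolerance`` of the layout's
    disk radius is selected (ties by radius match, then larger area).
    Holes are filled and the unweighted centroid of the filled mask is
    returned as the COG.
    """
    layout = layout or PhantomLayout.default()
    img = slc.intensities
    sr, sc = slc.pixel_spacing_mm
    px_area_mm2 = sr * sc
    expected_r = layout.inner_disk_radius_mm

    thresh = filters.threshold_otsu(img, nbins=256)
    binary = img > thresh
    labels = measure.label(binary, connectivity=2)
    center = ((img.shape[0] - 1) / 2.0, (img.shape[1] - 1) / 2.0)

    rows = []
    for prop in measure.regionprops(labels):
        equiv_r_mm = np.sqrt(prop.area * px_area_mm2 / np.pi)
        dist_px = float(np.hypot(prop.centroid[0] - center[0], prop.centroid[1] - center[1]))
        rows.append(
            {
                "label": prop.label,
                "area_px": int(prop.area),
                "equivalent_radius_mm": float(equiv_r_mm),
                "center_distance_px": dist_px,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        raise SegmentationError("no foreground components found", components=table)

    ok = table[
        (table.equivalent_radius_mm - expected_r).abs() <= radius_tolerance * expected_r
    ]
    if ok.empty:
        raise SegmentationError(
            f"no component within +/-{radius_tolerance:.0%} of the expected "
            f"{expected_r:.0f} mm disk radius",
            components=table,
        )
    ok = ok.sort_values(
        by=["center_distance_px", "equivalent_radius_mm", "area_px"],
        key=lambda col: (col - expected_r).abs()
        if col.name == "equivalent_radius_mm"
        else (-col if col.name == "area_px" else col),
    )
    chosen = int(ok.iloc[0]["label"])

    mask = ndimage.binary_fill_holes(labels == chosen)
    coords = np.argwhere(mask)
    cog = coords.mean(axis=0)
    equiv_r_mm = float(np.sqrt(mask.sum() * px_area_mm2 / np.pi))
    if abs(equiv_r_mm - expected_r) > radius_tolerance * expected_r:
        raise SegmentationError(
            f"filled disk radius {equiv_r_mm:.1f} mm outside tolerance",
            components=table,
        )
    return DiskMask(
        mask=mask,
        cog_rowcol_px=(float(cog[0]), float(cog[1])),
        equivalent_radius_mm=equiv_r_mm,
        interior_mask=ndimage.binary_erosion(mask),
    )
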