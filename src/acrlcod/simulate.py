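"""Synthetic large-ACR-phantom LCOD slices with known ground truth.

The simulator renders what the detector assumes: a circular phantom body,
an inner contrast disk separated from the body by a thin dark membrane
ring, and 30 low-contrast holes in 10 spokes (centers at 12.5/25/38 mm,
diameters 7 -> 1.5 mm clockwise).  Hole intensity is
``background * (1 + contrast)`` (hyperintense by default; the polarity is
switchable).  Per-slice hole contrasts default to the phantom's nominal
1.4/2.5/3.6/5.1 % for slices 8-11; slice 7 is rendered as a uniform disk
for SNR measurement.  Rendering is anti-aliased by 4x4 sub-pixel coverage
averaging (a 1.5 mm hole is only ~1.5 px wide at the standard 250 mm /
256 px resolution, so hard binarisation would alias it away).

Optional degradations emulate the acquisition variations that matter to
the detector: additive Gaussian (or Rician magnitude) noise at a
configured SNR, in-plane rotation and translation of the phantom, and a
smooth second-order polynomial intensity bias field.  Noise is drawn from
a per-slice stream derived deterministically from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import PhantomLayout, clock_angle_to_rowcol, spoke_spec
from .io import PhantomSlice, PhantomVolume

__all__ = ["SimulationConfig", "simulate_slice", "simulate_volume"]

_MEMBRANE_WIDTH_MM = 3.0
_MEMBRANE_INTENSITY_FACTOR = 0.1


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of a synthetic LCOD volume.

    ``snr`` sets the additive noise level as sigma = background / snr
    (``None`` disables noise; ``noise_sigma`` overrides directly).  The
    default SNR of 300 sits in the middle of the range typical of clinical
    head-coil acquisitions of this phantom (roughly 100-450).
    """

    matrix_size: int = 256
    fov_mm: float = 250.0
    disk_radius_mm: float = 45.0
    phantom_radius_mm: float = 95.0
    background_intensity: float = 0.6
    slice_contrasts_pct: tuple[float, float, float, float] = (1.4, 2.5, 3.6, 5.1)
    snr: float | None = 300.0
    noise_sigma: float | None = None
    noise_model: str = "gaussian"  # or "rician"
    rotation_deg: float = 0.0
    translation_px: tuple[float, float] = (0.0, 0.0)
    bias_field: tuple[float, ...] | None = None  # (c0, cx, cy, cxx, cxy, cyy)
    base_angles_deg: dict[int, float] | None = None
    hole_polarity: int = +1
    seed: int = 0
    supersample: int = 4

    def __post_init__(self) -> None:
        if self.disk_radius_mm <= 38.0 + 3.5:
            raise ValueError("disk radius must exceed the outermost hole edge")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive")
        if any(c < 0 for c in self.slice_contrasts_pct):
            raise ValueError("contrasts must be non-negative")
        if self.matrix_size <= 0 or self.fov_mm <= 0:
            raise ValueError("matrix size and FOV must be positive")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.hole_polarity not in (+1, -1):
            raise ValueError("hole_polarity must be +1 or -1")

    @property
    def pixel_spacing_mm(self) -> tuple[float, float]:
        p = self.fov_mm / self.matrix_size
        return (p, p)

    def sigma(self) -> float:
        if self.noise_sigma is not None:
            return self.noise_sigma
        if self.snr is None or not np.isfinite(self.snr):
            return 0.0
        return self.background_intensity / self.snr


def _hole_positions(
    config: SimulationConfig, layout: PhantomLayout, slice_index: int
) -> list[dict]:
    """Ground-truth hole centers in pixels, after rotation and translation."""
    if config.base_angles_deg is not None:
        layout = replace(
            layout,
            per_slice_base_angle_deg={
                **dict(layout.per_slice_base_angle_deg),
                **config.base_angles_deg,
            },
        )
    n = config.matrix_size
    sr, sc = config.pixel_spacing_mm
    center = (
        (n - 1) / 2.0 + config.translation_px[0],
        (n - 1) / 2.0 + config.translation_px[1],
    )
    holes = []
    for k in range(1, layout.n_spokes + 1):
        spec = spoke_spec(k, slice_index, layout)
        angle = spec.nominal_angle_deg + config.rotation_deg
        drow, dcol = clock_angle_to_rowcol(angle)
        for i, r_mm in enumerate(spec.hole_centers_mm):
            holes.append(
                {
                    "spoke": k,
                    "hole": i + 1,
                    "row_px": center[0] + r_mm * drow / sr,
                    "col_px": center[1] + r_mm * dcol / sc,
                    "diameter_mm": spec.diameter_mm,
                    "angle_deg": angle % 360.0,
                }
            )
    return holes


def _render(config: SimulationConfig, slice_index: int, layout: PhantomLayout):
    """Anti-aliased noiseless rendering plus ground truth."""
    n, ss = config.matrix_size, config.supersample
    sr, sc = config.pixel_spacing_mm
    fine = n * ss
    # fine-grid pixel centers in coarse pixel units
    coords = (np.arange(fine) + 0.5) / ss - 0.5
    center = (
        (n - 1) / 2.0 + config.translation_px[0],
        (n - 1) / 2.0 + config.translation_px[1],
    )
    row_mm = (coords - center[0])[:, None] * sr
    col_mm = (coords - center[1])[None, :] * sc
    r_mm = np.hypot(row_mm, col_mm)

    bg = config.background_intensity
    img = np.zeros((fine, fine))
    img[r_mm <= config.phantom_radius_mm] = bg

    is_lcod = slice_index in layout.lcod_slice_indices_1based
    holes: list[dict] = []
    contrast = 0.0
    if is_lcod:
        ring = (r_mm > config.disk_radius_mm) & (
            r_mm <= config.disk_radius_mm + _MEMBRANE_WIDTH_MM
        )
        img[ring] = bg * _MEMBRANE_INTENSITY_FACTOR
        contrast = config.slice_contrasts_pct[slice_index - 8] / 100.0
        hole_value = bg * (1.0 + config.hole_polarity * contrast)
        holes = _hole_positions(config, layout, slice_index)
        fine_coord = lambda px: (px + 0.5) * ss - 0.5  # coarse px -> fine index
        for hole in holes:
            rad_px = hole["diameter_mm"] / 2.0 / sr  # isotropic pixels
            fr, fc = fine_coord(hole["row_px"]), fine_coord(hole["col_px"])
            rad_f = rad_px * ss
            lo_r = max(0, int(fr - rad_f) - 2)
            hi_r = min(fine, int(fr + rad_f) + 3)
            lo_c = max(0, int(fc - rad_f) - 2)
            hi_c = min(fine, int(fc + rad_f) + 3)
            sub_r = np.arange(lo_r, hi_r)[:, None] - fr
            sub_c = np.arange(lo_c, hi_c)[None, :] - fc
            within = sub_r**2 + sub_c**2 <= rad_f**2
            block = img[lo_r:hi_r, lo_c:hi_c]
            block[within] = hole_value

    coarse = img.reshape(n, ss, n, ss).mean(axis=(1, 3))

    if config.bias_field is not None:
        x = np.linspace(-1.0, 1.0, n)
        X, Y = np.meshgrid(x, x, indexing="ij")
        c = config.bias_field
        bias = 1.0 + c[0] + c[1] * X + c[2] * Y + c[3] * X**2 + c[4] * X * Y + c[5] * Y**2
        coarse = coarse * bias

    truth = {
        "slice_index": slice_index,
        "contrast_pct": contrast * 100.0,
        "rotation_deg": config.rotation_deg,
        "center_px": list(center),
        "holes": holes,
    }
    return coarse, truth


def simulate_slice(
    config: SimulationConfig,
    slice_index_1based: int,
    layout: PhantomLayout | None = None,
) -> tuple[PhantomSlice, dict]:
    """Render one synthetic slice (7 = uniform, 8-11 = LCOD) plus ground truth.

    Noise is drawn from ``default_rng([seed, slice_index])`` so the same
    configuration always produces bitwise-identical slices and different
    slices get independent noise streams.
    """
    layout = layout or PhantomLayout.default()
    if slice_index_1based not in (7,) + tuple(layout.lcod_slice_indices_1based):
        raise ValueError(
            f"slice {slice_index_1based} not supported (7 or "
            f"{layout.lcod_slice_indices_1based})"
        )
    img, truth = _render(config, slice_index_1based, layout)
    sigma = config.sigma()
    if sigma > 0:
        rng = np.random.default_rng([config.seed, slice_index_1based])
        if config.noise_model == "gaussian":
            img = img + rng.normal(0.0, sigma, img.shape)
        else:  # rician magnitude: two independent Gaussian channels
            img = np.hypot(
                img + rng.normal(0.0, sigma, img.shape),
                rng.normal(0.0, sigma, img.shape),
            )
    slc = PhantomSlice(
        intensities=img,
        pixel_spacing_mm=config.pixel_spacing_mm,
        slice_index_1based=slice_index_1based,
        meta={"synthetic": True, "seed": config.seed},
    )
    return slc, truth


def simulate_volume(
    config: SimulationConfig | None = None,
    layout: PhantomLayout | None = None,
) -> tuple[PhantomVolume, dict]:
    """Render slices 7-11: a uniform SNR slice plus the four LCOD slices."""
    config = config or SimulationConfig()
    layout = layout or PhantomLayout.default()
    slices, truths = [], {}
    for idx in (7,) + tuple(layout.lcod_slice_indices_1based):
        slc, truth = simulate_slice(config, idx, layout)
        slices.append(slc)
        truths[idx] = truth
    volume = PhantomVolume(tuple(slices), meta={"synthetic": True, "seed": config.seed})
    return volume, {"slices": truths, "first_slice_index": 7}
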