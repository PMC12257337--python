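"""Model/Results front end for LCOD scoring.

`LCODModel` wraps a phantom volume plus layout and detection settings;
`fit()` runs the full pipeline (segmentation, radial profiling, GLM
detection, multiple-testing control) and returns an `LCODResults` carrying
the per-spoke estimates, pass flags, per-slice counts, the 0-40 total and
the measured SNR, with `summary()`, a tidy `to_frame()` and QC plotting.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from .detection import DetectionConfig, StudyScore, score_volume
from .geometry import PhantomLayout
from .io import PhantomVolume, read_volume

__all__ = ["LCODModel", "LCODResults"]


class LCODModel:
    """Low-contrast object detectability scorer for one phantom volume.

    Parameters
    ----------
    volume
        A :class:`~acrlcod.io.PhantomVolume` containing slices 8-11
        (slice 7 additionally enables SNR measurement).
    layout
        Phantom geometry; defaults to the large-ACR-phantom layout.
    config
        Detection settings; defaults reproduce the standard procedure
        (two-sided tests, +/-8 degree angle search, 5-sample jitter,
        0.0125 per-slice level with BH within slice).
    """

    def __init__(
        self,
        volume: PhantomVolume,
        layout: PhantomLayout | None = None,
        config: DetectionConfig | None = None,
    ):
        self.volume = volume
        self.layout = layout or PhantomLayout.default()
        self.config = config or DetectionConfig()

    @classmethod
    def from_path(cls, path, layout=None, config=None, **read_kwargs) -> "LCODModel":
        """Build a model directly from a DICOM series directory or NIfTI file."""
        volume = read_volume(path, layout=layout, **read_kwargs)
        return cls(volume, layout=layout, config=config)

    def fit(self) -> "LCODResults":
        """Run the scoring pipeline and return the results object."""
        study = score_volume(self.volume, self.layout, self.config)
        return LCODResults(self, study)


class LCODResults:
    """Fitted LCOD scores: per-spoke GLM results, counts, total and SNR."""

    def __init__(self, model: LCODModel, study: StudyScore):
        self.model = model
        self.study = study

    # -- scalar views ---------------------------------------------------

    @property
    def total(self) -> int:
        return self.study.total

    @property
    def slice_counts(self) -> dict[int, int]:
        return {s.slice_index_1based: s.n_pass for s in self.study.slices}

    @property
    def snr(self) -> float | None:
        return self.study.snr

    # -- tabular views --------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """One row per evaluated spoke (40 rows for a complete study)."""
        rows = []
        for sl in self.study.slices:
            for sp in sl.spokes:
                g = sp.glm
                rows.append(
                    {
                        "slice": sl.slice_index_1based,
                        "spoke": sp.spoke_index,
                        "angle_deg": g.angle_deg,
                        "jitter": g.jitter_samples,
                        "beta_1": g.disk_betas[0],
                        "beta_2": g.disk_betas[1],
                        "beta_3": g.disk_betas[2],
                        "t_1": g.t_stats[0],
                        "t_2": g.t_stats[1],
                        "t_3": g.t_stats[2],
                        "p_1": g.p_values[0],
                        "p_2": g.p_values[1],
                        "p_3": g.p_values[2],
                        "hole_pass_1": sp.hole_pass[0],
                        "hole_pass_2": sp.hole_pass[1],
                        "hole_pass_3": sp.hole_pass[2],
                        "spoke_pass": sp.spoke_pass,
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "snr": self.snr,
            "config_digest": self.study.config_digest,
            "config": self.model.config.to_dict(),
            "slices": [
                {
                    "slice": s.slice_index_1based,
                    "n_pass": s.n_pass,
                    "failed": s.failed,
                    "failure_reason": s.failure_reason,
                    "cog_rowcol_px": s.cog_rowcol_px,
                    "spokes": [
                        {
                            "spoke": sp.spoke_index,
                            "angle_deg": sp.glm.angle_deg,
                            "jitter": sp.glm.jitter_samples,
                            "betas": sp.glm.disk_betas.tolist(),
                            "t": sp.glm.t_stats.tolist(),
                            "p": sp.glm.p_values.tolist(),
                            "hole_pass": list(sp.hole_pass),
                            "spoke_pass": sp.spoke_pass,
                        }
                        for sp in s.spokes
                    ],
                }
                for s in self.study.slices
            ],
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=_json_default)

    def summary(self) -> str:
        """Human-readable study summary (printed totals match to_dict)."""
        lines = ["Low-contrast object detectability (large ACR phantom)"]
        lines.append("=" * len(lines[0]))
        cfg = self.model.config
        lines.append(
            f"per-slice alpha {cfg.per_slice_alpha:g} "
            f"(alpha {cfg.alpha_total:g} / {cfg.n_lcod_slices} slices), "
            f"angle search +/-{cfg.angle_search_deg:g} deg, "
            f"jitter +/-{cfg.max_jitter_samples} samples"
        )
        lines.append(f"config digest {self.study.config_digest}")
        lines.append("")
        lines.append("slice  contrast%  passed spokes")
        contrasts = self.model.layout.slice_contrasts_pct
        for s in self.study.slices:
            status = "  [segmentation FAILED]" if s.failed else ""
            lines.append(
                f"{s.slice_index_1based:>5}  {contrasts[s.slice_index_1based]:>8.1f}"
                f"  {s.n_pass:>2} / 10{status}"
            )
        lines.append("")
        lines.append(f"total score: {self.total} / 40")
        if self.snr is not None:
            lines.append(f"SNR (slice 7): {self.snr:.1f}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<LCODResults total={self.total}/40 snr={self.snr}>"

    # -- plotting -------------------------------------------------------

    def plot_slice(self, slice_index: int, ax=None):
        """QC overlay: normalized slice, COG marker and selected spoke rays."""
        import matplotlib.pyplot as plt

        from .geometry import clock_angle_to_rowcol
        from .segmentation import normalize_slice

        slc = self.model.volume.get_slice(slice_index)
        norm = normalize_slice(slc)
        score = next(
            s for s in self.study.slices if s.slice_index_1based == slice_index
        )
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        ax.imshow(norm.intensities, cmap="gray", interpolation="nearest")
        if score.cog_rowcol_px is not None:
            cog = score.cog_rowcol_px
            ax.plot(cog[1], cog[0], "r+", ms=12)
            sr, sc_mm = slc.pixel_spacing_mm
            length = self.model.layout.inner_disk_radius_mm
            for sp in score.spokes:
                drow, dcol = clock_angle_to_rowcol(sp.glm.angle_deg)
                ax.plot(
                    [cog[1], cog[1] + dcol * length / sc_mm],
                    [cog[0], cog[0] + drow * length / sr],
                    color="lime" if sp.spoke_pass else "red",
                    lw=1.0,
                    alpha=0.8,
                )
        ax.set_title(f"slice {slice_index}: {score.n_pass}/10 spokes")
        ax.set_axis_off()
        return ax


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    return asdict(obj)
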