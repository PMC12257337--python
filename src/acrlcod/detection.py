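"""GLM spoke detection, multiple-testing control, slice and volume scoring.

Each radial profile is regressed on the spoke's three hole indicators plus
a second-order polynomial nuisance basis (ordinary least squares).  A hole
is detected when its regression coefficient differs significantly from
zero (Student-t, two-sided by default, dof = n - 6 at defaults).  To
absorb phantom misplacement, the fit is repeated over a +/-8 degree angle
search around the nominal spoke angle and over integer profile shifts of
up to 5 samples; the candidate maximising the *minimum* per-hole detection
statistic is kept, since a spoke passes only if all three holes do.

Family-wise control follows the original procedure: the overall 0.05 level
is Bonferroni-split across the four LCOD slices (0.0125 per slice), and
within each slice the pooled hole p-values are adjusted by the
Benjamini-Hochberg step-up rule.  A spoke passes when all three of its
holes survive; per-slice pass counts sum to the 0-40 study total.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special
from scipy.linalg import solve_triangular
from statsmodels.stats.multitest import multipletests

from .errors import AcrLcodError, SegmentationError, SnrError
from .geometry import PhantomLayout, SpokeSpec, build_spoke_template, spoke_spec
from .io import PhantomSlice, PhantomVolume, lcod_slices
from .profiling import RadialProfile, cast_ray, resample_profile, shift_samples
from .segmentation import DiskMask, normalize_slice, segment_inner_disk

__all__ = [
    "DetectionConfig",
    "GLMResult",
    "SpokeResult",
    "SliceScore",
    "StudyScore",
    "fit_spoke_glm",
    "evaluate_spoke",
    "benjamini_hochberg",
    "score_slice",
    "score_volume",
    "compute_snr",
]

# Relative scale below which a residual sum of squares is treated as exactly
# zero (noise-free fixtures behave as the limit of vanishing noise).
_RSS_REL_TOL = 1e-24

# Cap on the AR(1) coefficient estimated from fit residuals.
_AR1_RHO_MAX = 0.98


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable parameters of the detection pipeline.

    ``per_slice_alpha`` is derived as ``alpha_total / n_lcod_slices``
    (0.05 / 4 = 0.0125 at defaults) — the Bonferroni split across the four
    LCOD slices — and is also the Benjamini-Hochberg q within a slice.
    """

    alpha_total: float = 0.05
    n_lcod_slices: int = 4
    angle_search_deg: float = 8.0
    angle_step_deg: float = 0.5
    max_jitter_samples: int = 5
    n_profile_samples: int = 90
    poly_order: int = 2
    sidedness: str = "two-sided"  # or "one-sided-with-polarity"
    polarity: int = +1  # sign of expected hole contrast in one-sided mode
    scoring_mode: str = "all-passing"  # or "acr-consecutive"
    bh_pool: str = "holes"  # or "spokes"
    error_model: str = "ar1"  # or "iid"
    rotation_consensus: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.alpha_total < 1):
            raise ValueError("alpha_total must be in (0, 1)")
        if self.n_lcod_slices < 1 or self.n_profile_samples < 30:
            raise ValueError("counts must be positive (n_profile_samples >= 30)")
        if self.angle_search_deg < 0 or self.angle_step_deg <= 0:
            raise ValueError("angle search range/step must be non-negative/positive")
        if self.angle_search_deg > 0 and self.n_angle_candidates < 3:
            raise ValueError("angle step must yield at least 3 candidates")
        if self.max_jitter_samples < 0 or self.max_jitter_samples > 5:
            raise ValueError("max_jitter_samples must be in 0..5")
        if self.sidedness not in ("two-sided", "one-sided-with-polarity"):
            raise ValueError(f"unknown sidedness {self.sidedness!r}")
        if self.scoring_mode not in ("all-passing", "acr-consecutive"):
            raise ValueError(f"unknown scoring_mode {self.scoring_mode!r}")
        if self.bh_pool not in ("holes", "spokes"):
            raise ValueError(f"unknown bh_pool {self.bh_pool!r}")
        if self.error_model not in ("ar1", "iid"):
            raise ValueError(f"unknown error_model {self.error_model!r}")

    @property
    def per_slice_alpha(self) -> float:
        return self.alpha_total / self.n_lcod_slices

    @property
    def n_angle_candidates(self) -> int:
        if self.angle_search_deg == 0:
            return 1
        return 2 * int(round(self.angle_search_deg / self.angle_step_deg)) + 1

    def angle_offsets(self) -> np.ndarray:
        if self.angle_search_deg == 0:
            return np.array([0.0])
        n_half = int(round(self.angle_search_deg / self.angle_step_deg))
        return np.arange(-n_half, n_half + 1) * self.angle_step_deg

    def to_dict(self) -> dict:
        return {
            "alpha_total": self.alpha_total,
            "n_lcod_slices": self.n_lcod_slices,
            "angle_search_deg": self.angle_search_deg,
            "angle_step_deg": self.angle_step_deg,
            "max_jitter_samples": self.max_jitter_samples,
            "n_profile_samples": self.n_profile_samples,
            "poly_order": self.poly_order,
            "sidedness": self.sidedness,
            "polarity": self.polarity,
            "scoring_mode": self.scoring_mode,
            "bh_pool": self.bh_pool,
            "error_model": self.error_model,
            "rotation_consensus": self.rotation_consensus,
        }


@dataclass(frozen=True)
class GLMResult:
    """Per-spoke least-squares fit at the selected angle/jitter candidate."""

    disk_betas: np.ndarray  # (3,) hole effect estimates, normalized units
    nuisance_betas: np.ndarray
    t_stats: np.ndarray  # (3,)
    p_values: np.ndarray  # (3,)
    dof: int
    rss: float
    angle_deg: float
    jitter_samples: int


@dataclass(frozen=True)
class SpokeResult:
    spoke_index: int
    glm: GLMResult
    hole_pass: tuple[bool, bool, bool]
    spoke_pass: bool


@dataclass(frozen=True)
class SliceScore:
    slice_index_1based: int
    spokes: tuple[SpokeResult, ...]
    n_pass: int
    bh_level_used: float
    failed: bool = False
    failure_reason: str | None = None
    cog_rowcol_px: tuple[float, float] | None = None
    equivalent_radius_mm: float | None = None


@dataclass(frozen=True)
class StudyScore:
    slices: tuple[SliceScore, ...]
    total: int
    snr: float | None
    config_digest: str
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# GLM core


class _SpokeDesign:
    """Precomputed solver state for one spoke design matrix.

    Betas are always ordinary least squares.  Standard errors come either
    from the classical iid formula ``sigma^2 * diag((X'X)^-1)`` or from an
    AR(1) sandwich ``sigma^2 * diag(C X'RX C)`` with ``C = (X'X)^-1`` and
    ``R_ij = rho^|i-j|`` estimated from the lag-1 autocorrelation of the
    fit residuals.  The sandwich corrects the optimism of the classical
    formula when profile samples are finer than the acquired pixels and
    hence serially correlated.
    """

    def __init__(self, X: np.ndarray):
        n, k = X.shape
        Q, R = np.linalg.qr(X)
        if np.abs(np.diag(R)).min() < 1e-10 * np.abs(np.diag(R)).max():
            raise AcrLcodError("rank-deficient spoke design")
        self.X = X
        self.n, self.k = n, k
        self.Q = Q
        self.Rinv = solve_triangular(R, np.eye(k))
        self.C = self.Rinv @ self.Rinv.T  # (X'X)^-1
        self.se_unit_iid = np.sqrt(np.diag(self.C))
        # lagged column cross-products A_k[l] = X[:-l].T @ X[l:] via FFT,
        # for the AR(1) sandwich X'RX = X'X + sum_l rho^l (A_l + A_l')
        nfft = 1
        while nfft < 2 * n:
            nfft *= 2
        F = np.fft.rfft(X, n=nfft, axis=0)
        cross = np.fft.irfft(
            np.conj(F)[:, :, None] * F[:, None, :], n=nfft, axis=0
        )
        lagged = cross[1:n]  # (n-1, k, k); lag l at index l-1
        self._lag_sym = lagged + lagged.transpose(0, 2, 1)
        self._lag_weights_pow = np.arange(1, n)

    def se_unit_ar1(self, rho: float) -> np.ndarray:
        """sqrt(diag(C X'RX C)) for an AR(1) residual correlation rho."""
        return self._se_unit_ar1_rows(np.array([rho]))[0]

    def _se_unit_ar1_rows(self, rho: np.ndarray) -> np.ndarray:
        """Sandwich sqrt-diagonals for a vector of per-row rho values."""
        W = np.where(rho[:, None] > 0, rho[:, None], 0.0) ** self._lag_weights_pow
        XtRX = (self.X.T @ self.X)[None] + np.tensordot(W, self._lag_sym, axes=1)
        G = np.einsum("ij,rjk,kl->ril", self.C, XtRX, self.C)
        diag = np.maximum(np.einsum("rii->ri", G), 0.0)
        return np.sqrt(diag)

    def fit_rows(
        self,
        Y: np.ndarray,
        sidedness: str,
        polarity: int,
        error_model: str,
    ):
        """Fit each row of Y; returns (B, rss, t, p) for all regressors."""
        B = (Y @ self.Q) @ self.Rinv.T
        resid = Y - B @ self.X.T
        rss = np.einsum("ij,ij->i", resid, resid)
        dof = self.n - self.k
        y_scale = np.maximum(1.0, np.einsum("ij,ij->i", Y, Y))
        zero_rss = rss <= _RSS_REL_TOL * y_scale
        sigma = np.sqrt(np.where(zero_rss, 1.0, rss) / dof)
        if error_model == "ar1":
            safe_rss = np.where(zero_rss, 1.0, rss)
            rho = np.einsum("ij,ij->i", resid[:, :-1], resid[:, 1:]) / safe_rss
            rho = np.clip(np.where(zero_rss, 0.0, rho), 0.0, _AR1_RHO_MAX)
            se_unit = self._se_unit_ar1_rows(rho)
        else:
            se_unit = np.broadcast_to(self.se_unit_iid, B.shape)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = B / (sigma[:, None] * se_unit)
        if sidedness == "two-sided":
            p = 2.0 * special.stdtr(dof, -np.abs(t))
        else:
            p = special.stdtr(dof, -polarity * t)
        if zero_rss.any():
            beta_tol = 1e-10 * np.sqrt(y_scale)[:, None]
            nonzero = np.abs(B) > beta_tol
            for i in np.nonzero(zero_rss)[0]:
                t[i] = np.where(nonzero[i], np.sign(B[i]) * np.inf, 0.0)
                p[i] = np.where(nonzero[i], 0.0, 1.0)
        return B, rss, t, p


def fit_spoke_glm(
    profile: RadialProfile,
    template,
    sidedness: str = "two-sided",
    polarity: int = +1,
    jitter_samples: int = 0,
    error_model: str = "iid",
) -> GLMResult:
    """Least squares of one profile on one spoke template.

    The design is [3 hole indicators | polynomial nuisance columns] and the
    coefficients are ordinary least squares; per hole, t = beta / SE and p
    from Student-t with dof = n - 6 at defaults.  With the default
    ``error_model="iid"`` the SE is the classical one (unbiased residual
    variance times the inverse Gram diagonal); ``"ar1"`` applies the
    serial-correlation sandwich used by the full pipeline (see
    :class:`DetectionConfig`).  If the residual sum of squares is exactly
    zero, p is 0 for a nonzero hole beta and 1 otherwise.
    """
    X = template.design
    n, k = X.shape
    if profile.n_samples != n:
        raise ValueError(
            f"profile has {profile.n_samples} samples, template expects {n}"
        )
    y = profile.samples
    if jitter_samples:
        y = shift_samples(y, jitter_samples)
    design = _SpokeDesign(X)
    B, rss, t, p = design.fit_rows(y[None, :], sidedness, polarity, error_model)
    return GLMResult(
        disk_betas=B[0, :3].copy(),
        nuisance_betas=B[0, 3:].copy(),
        t_stats=t[0, :3].copy(),
        p_values=p[0, :3].copy(),
        dof=n - k,
        rss=float(rss[0]),
        angle_deg=profile.angle_deg,
        jitter_samples=jitter_samples,
    )


def evaluate_spoke(
    slc: PhantomSlice,
    mask: DiskMask,
    spec: SpokeSpec,
    layout: PhantomLayout | None = None,
    config: DetectionConfig | None = None,
) -> GLMResult:
    """Angle/jitter search around a spoke's nominal geometry.

    For each candidate angle in nominal +/- ``angle_search_deg`` (at
    ``angle_step_deg``) and each integer jitter in
    -``max_jitter_samples``..+``max_jitter_samples``, the profile is
    extracted, shifted and fitted; the candidate maximising the minimum
    per-hole detection statistic (|t| two-sided, signed t one-sided) is
    returned.  Ties keep the earliest candidate (ascending angle, then
    ascending shift), so the search is deterministic.
    """
    layout = layout or PhantomLayout.default()
    config = config or DetectionConfig()
    min_len = (
        layout.hole_radial_centers_mm[-1] + layout.diameter_first_spoke_mm / 2.0
    )
    n = config.n_profile_samples
    shifts = np.arange(-config.max_jitter_samples, config.max_jitter_samples + 1)
    best = None
    best_stat = -np.inf
    errors = []
    for offset in config.angle_offsets():
        angle = spec.nominal_angle_deg + offset
        try:
            raw = cast_ray(slc, mask, angle, min_length_mm=min_len)
        except AcrLcodError as exc:
            errors.append(exc)
            continue
        prof = resample_profile(raw, n)
        template = build_spoke_template(
            spec, prof.physical_length_mm, n, config.poly_order
        )
        design = _SpokeDesign(template.design)
        dof = n - template.design.shape[1]
        Y = np.stack([shift_samples(prof.samples, int(s)) for s in shifts])
        B, rss, t, p = design.fit_rows(
            Y, config.sidedness, config.polarity, config.error_model
        )
        t, p = t[:, :3], p[:, :3]
        stat = (
            np.abs(t).min(axis=1)
            if config.sidedness == "two-sided"
            else (config.polarity * t).min(axis=1)
        )
        i = int(np.argmax(stat))
        if stat[i] > best_stat:
            best_stat = float(stat[i])
            best = GLMResult(
                disk_betas=B[i, :3].copy(),
                nuisance_betas=B[i, 3:].copy(),
                t_stats=t[i].copy(),
                p_values=p[i].copy(),
                dof=dof,
                rss=float(rss[i]),
                angle_deg=float(angle),
                jitter_samples=int(shifts[i]),
            )
    if best is None:
        raise errors[-1] if errors else AcrLcodError("no viable ray for spoke")
    return best


def benjamini_hochberg(p_values, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at false-discovery level q.

    Sort the m p-values ascending, find the largest k with
    p_(k) <= k * q / m and reject hypotheses 1..k (ties at the boundary are
    all rejected).  Returns a boolean array aligned with the input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def _apply_bh(spokes_glm: list[GLMResult], config: DetectionConfig):
    """BH within a slice; returns per-spoke hole-pass flags."""
    q = config.per_slice_alpha
    if config.bh_pool == "holes":
        pooled = np.concatenate([g.p_values for g in spokes_glm])
        reject = benjamini_hochberg(pooled, q).reshape(len(spokes_glm), 3)
        return [tuple(bool(b) for b in row) for row in reject]
    # spoke-level pool: a spoke's evidence is its weakest hole
    spoke_p = np.array([g.p_values.max() for g in spokes_glm])
    reject = benjamini_hochberg(spoke_p, q)
    return [(bool(r),) * 3 for r in reject]


def _count_passes(spoke_pass: list[bool], mode: str) -> int:
    if mode == "acr-consecutive":
        n = 0
        for ok in spoke_pass:
            if not ok:
                break
            n += 1
        return n
    return sum(spoke_pass)


def score_slice(
    slc: PhantomSlice,
    layout: PhantomLayout | None = None,
    config: DetectionConfig | None = None,
) -> SliceScore:
    """Score one LCOD slice: segment, evaluate all 10 spokes, BH-correct.

    A segmentation failure yields a flagged zero score, never a silent one.
    """
    layout = layout or PhantomLayout.default()
    config = config or DetectionConfig()
    idx = slc.slice_index_1based
    if idx not in layout.lcod_slice_indices_1based:
        raise ValueError(f"slice {idx} is not an LCOD slice")
    try:
        norm = normalize_slice(slc)
        mask = segment_inner_disk(norm, layout)
    except (SegmentationError, AcrLcodError) as exc:
        return SliceScore(
            slice_index_1based=idx,
            spokes=(),
            n_pass=0,
            bh_level_used=config.per_slice_alpha,
            failed=True,
            failure_reason=str(exc),
        )
    specs = [spoke_spec(k, idx, layout) for k in range(1, layout.n_spokes + 1)]
    glms = [evaluate_spoke(norm, mask, sp, layout, config) for sp in specs]
    if config.rotation_consensus and config.angle_search_deg > 0:
        # The phantom rotates rigidly, so one in-plane rotation must explain
        # every spoke; testing each spoke at the per-slice consensus offset
        # (median over spokes) removes most of the optimism a free per-spoke
        # angle selection would add to the test statistics.
        offsets = [
            g.angle_deg - sp.nominal_angle_deg for g, sp in zip(glms, specs)
        ]
        consensus = float(np.median(offsets))
        refit_cfg = replace(config, angle_search_deg=0.0)
        glms = [
            evaluate_spoke(
                norm,
                mask,
                replace(sp, nominal_angle_deg=sp.nominal_angle_deg + consensus),
                layout,
                refit_cfg,
            )
            for sp in specs
        ]
    hole_pass = _apply_bh(glms, config)
    spokes = tuple(
        SpokeResult(
            spoke_index=k,
            glm=g,
            hole_pass=hp,
            spoke_pass=all(hp),
        )
        for k, (g, hp) in enumerate(zip(glms, hole_pass), start=1)
    )
    n_pass = _count_passes([s.spoke_pass for s in spokes], config.scoring_mode)
    return SliceScore(
        slice_index_1based=idx,
        spokes=spokes,
        n_pass=n_pass,
        bh_level_used=config.per_slice_alpha,
        cog_rowcol_px=mask.cog_rowcol_px,
        equivalent_radius_mm=mask.equivalent_radius_mm,
    )


def _config_digest(config: DetectionConfig, layout: PhantomLayout) -> str:
    payload = json.dumps(
        {"config": config.to_dict(), "layout": layout.to_dict()}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def score_volume(
    volume: PhantomVolume,
    layout: PhantomLayout | None = None,
    config: DetectionConfig | None = None,
) -> StudyScore:
    """Score slices 8-11 of a phantom volume and sum to the 0-40 total.

    SNR is attached when slice 7 (the uniform slice) is present; failure to
    measure it leaves ``snr`` as None.  The result is deterministic for a
    fixed input and configuration.
    """
    layout = layout or PhantomLayout.default()
    config = config or DetectionConfig()
    scores = [
        score_slice(slc, layout, config) for slc, _ in lcod_slices(volume, layout)
    ]
    snr = None
    if volume.has_slice(7):
        try:
            snr = compute_snr(volume.get_slice(7))
        except (AcrLcodError, ValueError) as exc:
            warnings.warn(f"SNR measurement failed: {exc}", stacklevel=2)
    return StudyScore(
        slices=tuple(scores),
        total=int(sum(s.n_pass for s in scores)),
        snr=snr,
        config_digest=_config_digest(config, layout),
        meta={"failed_slices": [s.slice_index_1based for s in scores if s.failed]},
    )


def compute_snr(slice7: PhantomSlice, layout: PhantomLayout | None = None) -> float:
    """Image SNR from the uniform slice 7.

    Signal is the mean intensity inside a centered disk ROI of half the
    segmented phantom radius; noise is the standard deviation pooled over
    four corner boxes (side = image width / 16) fully outside the phantom,
    shrunk toward the corners if necessary.  Native intensities are used,
    so the ratio is invariant to multiplicative rescaling.
    """
    layout = layout or PhantomLayout.default()
    img = slice7.intensities
    h, w = img.shape
    norm = normalize_slice(slice7)
    from skimage import filters, measure  # local import keeps scope tight

    binary = norm.intensities > filters.threshold_otsu(norm.intensities, nbins=256)
    labels = measure.label(binary, connectivity=2)
    if labels.max() == 0:
        raise SnrError("no phantom found on slice 7")
    areas = np.bincount(labels.ravel())[1:]
    main = int(np.argmax(areas)) + 1
    from scipy import ndimage

    mask = ndimage.binary_fill_holes(labels == main)
    coords = np.argwhere(mask)
    cog = coords.mean(axis=0)
    radius_px = np.sqrt(mask.sum() / np.pi)

    rr, cc = np.ogrid[:h, :w]
    roi = (rr - cog[0]) ** 2 + (cc - cog[1]) ** 2 <= (0.5 * radius_px) ** 2
    signal = float(img[roi].mean())

    grown = ndimage.binary_dilation(mask, iterations=2)
    side = max(h, w) // 16
    noise_pixels = []
    while side >= 4:
        boxes = [
            (slice(0, side), slice(0, side)),
            (slice(0, side), slice(w - side, w)),
            (slice(h - side, h), slice(0, side)),
            (slice(h - side, h), slice(w - side, w)),
        ]
        if not any(grown[b].any() for b in boxes):
            noise_pixels = [img[b].ravel() for b in boxes]
            break
        side //= 2
    if not noise_pixels:
        raise SnrError("corner boxes intersect the phantom; cannot measure noise")
    noise = float(np.concatenate(noise_pixels).std(ddof=1))
    if noise == 0:
        warnings.warn("noise-free image: SNR is infinite", stacklevel=2)
        return float("inf")
    return signal / noise
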