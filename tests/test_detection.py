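"""GLM fitting, multiple-testing control, SNR and slice/volume scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import acrlcod as al
from acrlcod.detection import (
    DetectionConfig,
    _count_passes,
    benjamini_hochberg,
    compute_snr,
    evaluate_spoke,
    fit_spoke_glm,
    score_slice,
    score_volume,
)
from acrlcod.geometry import build_spoke_template, spoke_spec
from acrlcod.io import PhantomSlice
from acrlcod.profiling import RadialProfile, cast_ray, resample_profile
from acrlcod.segmentation import normalize_slice, segment_inner_disk


def _profile_from(samples, length=44.5, angle=0.0):
    samples = np.asarray(samples, dtype=float)
    return RadialProfile(
        samples=samples,
        sample_spacing_mm=length / (len(samples) - 1),
        angle_deg=angle,
        origin_rowcol_px=(128.0, 128.0),
        physical_length_mm=length,
    )


def bh_step_up_oracle(p, q):
    """Brute-force BH: largest k with p_(k) <= k q / m, reject all p <= p_(k)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    ps = np.sort(p)
    ks = [k for k in range(1, m + 1) if ps[k - 1] <= k * q / m]
    if not ks:
        return np.zeros(m, dtype=bool)
    return p <= ps[max(ks) - 1]


class TestFitSpokeGLM:
    def test_exact_model_recovery_zero_rss(self, layout):
        spec = spoke_spec(3, 9, layout)
        tpl = build_spoke_template(spec, 44.5, 90)
        coef = np.array([0.05, 0.05, 0.05, 0.7, 0.02, -0.04])
        prof = _profile_from(tpl.design @ coef)
        res = fit_spoke_glm(prof, tpl)
        assert np.allclose(res.disk_betas, 0.05, atol=1e-10)
        assert np.array_equal(res.p_values, [0.0, 0.0, 0.0])
        assert res.dof == 84

    def test_pure_nuisance_gives_null_holes(self, layout):
        spec = spoke_spec(5, 10, layout)
        tpl = build_spoke_template(spec, 44.5, 90)
        prof = _profile_from(tpl.nuisance_basis @ [0.6, -0.1, 0.05])
        res = fit_spoke_glm(prof, tpl)
        assert np.all(np.abs(res.t_stats) < 1e-6)
        assert np.array_equal(res.p_values, [1.0, 1.0, 1.0])

    def test_betas_match_normal_equations_oracle(self, layout):
        rng = np.random.default_rng(42)
        spec = spoke_spec(4, 8, layout)
        tpl = build_spoke_template(spec, 44.8, 90)
        X = tpl.design
        y = tpl.hole_indicators @ [0.03, 0.03, 0.03] + rng.normal(0, 0.01, 90)
        res = fit_spoke_glm(_profile_from(y), tpl)
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(res.disk_betas, beta_oracle[:3], atol=1e-8)
        assert np.allclose(res.nuisance_betas, beta_oracle[3:], atol=1e-8)

    def test_iid_inference_matches_statsmodels_ols(self, layout):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        spec = spoke_spec(2, 11, layout)
        tpl = build_spoke_template(spec, 45.0, 90)
        y = tpl.design @ [0.02, 0.01, 0.0, 0.5, 0.0, 0.1] + rng.normal(0, 0.005, 90)
        res = fit_spoke_glm(_profile_from(y), tpl, error_model="iid")
        fit = sm.OLS(y, tpl.design).fit()
        assert np.allclose(res.disk_betas, fit.params[:3], atol=1e-10)
        assert np.allclose(res.t_stats, fit.tvalues[:3], atol=1e-8)
        assert np.allclose(res.p_values, fit.pvalues[:3], atol=1e-10)

    def test_ar1_errors_widen_se_under_smoothing(self, layout):
        """Serially correlated residuals must not shrink |t| estimates."""
        rng = np.random.default_rng(3)
        spec = spoke_spec(3, 9, layout)
        tpl = build_spoke_template(spec, 44.5, 90)
        white = rng.normal(0, 0.01, 200)
        smooth = np.convolve(white, np.ones(4) / 4.0, mode="same")[:90]
        y = tpl.hole_indicators @ [0.02, 0.02, 0.02] + smooth
        t_iid = fit_spoke_glm(_profile_from(y), tpl, error_model="iid").t_stats
        t_ar1 = fit_spoke_glm(_profile_from(y), tpl, error_model="ar1").t_stats
        assert np.all(np.abs(t_ar1) < np.abs(t_iid))


class TestBenjaminiHochberg:
    def test_textbook_example_all_rejected(self):
        reject = benjamini_hochberg([0.001, 0.008, 0.039, 0.041], q=0.05)
        assert reject.tolist() == [True, True, True, True]

    def test_all_ones_none_rejected(self):
        assert not benjamini_hochberg([1.0, 1.0, 1.0], q=0.05).any()

    def test_single_hypothesis_boundary(self):
        assert benjamini_hochberg([0.012], q=0.0125).tolist() == [True]
        assert benjamini_hochberg([0.013], q=0.0125).tolist() == [False]

    def test_empty_input(self):
        assert benjamini_hochberg([], q=0.05).size == 0

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=6),
        st.floats(min_value=0.01, max_value=0.2),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_exhaustive_step_up_oracle(self, p, q):
        assert np.array_equal(
            benjamini_hochberg(p, q), bh_step_up_oracle(p, q)
        )


class TestEvaluateSpoke:
    def test_rotation_recovered_by_angle_search(self, layout):
        cfg = al.SimulationConfig(seed=3, snr=300, rotation_deg=4.0)
        slc, _ = al.simulate_slice(cfg, 11)
        norm = normalize_slice(slc)
        mask = segment_inner_disk(norm)
        offsets = []
        for k in range(1, 6):
            spec = spoke_spec(k, 11, layout)
            glm = evaluate_spoke(norm, mask, spec, layout)
            offsets.append(glm.angle_deg - spec.nominal_angle_deg)
        assert abs(np.mean(offsets) - 4.0) <= 1.0
        assert all(abs(o - 4.0) <= 2.0 for o in offsets)

    def test_noisefree_alignment_needs_no_jitter(self, noisefree_slice11, layout):
        slc, _ = noisefree_slice11
        norm = normalize_slice(slc)
        mask = segment_inner_disk(norm)
        for k in (1, 2, 3):
            glm = evaluate_spoke(norm, mask, spoke_spec(k, 11, layout), layout)
            assert glm.jitter_samples in (-1, 0, 1)

    def test_degenerate_search_equals_direct_fit(self, segmented11, layout):
        norm, mask, _ = segmented11
        cfg = DetectionConfig(angle_search_deg=0.0, max_jitter_samples=0)
        spec = spoke_spec(2, 11, layout)
        glm = evaluate_spoke(norm, mask, spec, layout, cfg)
        raw = cast_ray(norm, mask, spec.nominal_angle_deg, min_length_mm=41.5)
        prof = resample_profile(raw, 90)
        tpl = build_spoke_template(spec, prof.physical_length_mm, 90)
        direct = fit_spoke_glm(prof, tpl, error_model="ar1")
        assert np.array_equal(glm.t_stats, direct.t_stats)
        assert np.array_equal(glm.disk_betas, direct.disk_betas)
        assert glm.angle_deg == spec.nominal_angle_deg
        assert glm.jitter_samples == 0


class TestScoring:
    def test_noisefree_high_contrast_slice_scores_ten(self):
        cfg = al.SimulationConfig(seed=0, snr=None, slice_contrasts_pct=(5, 5, 5, 5))
        slc, _ = al.simulate_slice(cfg, 11)
        score = score_slice(slc)
        assert score.n_pass == 10
        assert all(sp.spoke_pass for sp in score.spokes)

    def test_partial_pattern_scores_six_in_both_modes(self, layout):
        """Spokes 1-6 present, 7-10 erased: six passes either way."""
        cfg = al.SimulationConfig(seed=0, snr=None, slice_contrasts_pct=(5, 5, 5, 5))
        slc, truth = al.simulate_slice(cfg, 11)
        img = slc.intensities.copy()
        rr, cc = np.ogrid[: img.shape[0], : img.shape[1]]
        for hole in truth["holes"]:
            if hole["spoke"] >= 7:
                rad_px = hole["diameter_mm"] / 2.0 / slc.pixel_spacing_mm[0] + 1.5
                zone = (rr - hole["row_px"]) ** 2 + (cc - hole["col_px"]) ** 2
                img[zone <= rad_px**2] = 0.6
        erased = slc.with_intensities(img)
        for mode in ("all-passing", "acr-consecutive"):
            score = score_slice(erased, layout, DetectionConfig(scoring_mode=mode))
            assert [sp.spoke_pass for sp in score.spokes] == [True] * 6 + [False] * 4
            assert score.n_pass == 6

    def test_consecutive_counting_stops_at_first_failure(self):
        assert _count_passes([True, True, False, True], "acr-consecutive") == 2
        assert _count_passes([True, True, False, True], "all-passing") == 3
        assert _count_passes([False] * 4, "acr-consecutive") == 0

    def test_segmentation_failure_scores_flagged_zero(self):
        rng = np.random.default_rng(0)
        noise = PhantomSlice(rng.normal(size=(64, 64)), (0.977, 0.977), 8)
        score = score_slice(noise)
        assert score.failed and score.n_pass == 0
        assert score.failure_reason

    def test_zero_contrast_volume_scores_zero(self):
        cfg = al.SimulationConfig(seed=12, snr=300, slice_contrasts_pct=(0, 0, 0, 0))
        vol, _ = al.simulate_volume(cfg)
        assert score_volume(vol).total == 0

    def test_repeat_scoring_bitwise_identical(self, noisy_volume):
        vol, _ = noisy_volume
        a = score_volume(vol)
        b = score_volume(vol)
        assert a.total == b.total
        for sa, sb in zip(a.slices, b.slices):
            for ga, gb in zip(sa.spokes, sb.spokes):
                assert np.array_equal(ga.glm.t_stats, gb.glm.t_stats)
                assert np.array_equal(ga.glm.p_values, gb.glm.p_values)
                assert ga.glm.rss == gb.glm.rss


class TestComputeSnr:
    def test_matches_configured_snr(self):
        cfg = al.SimulationConfig(seed=6, snr=200)
        slc, _ = al.simulate_slice(cfg, 7)
        assert compute_snr(slc) == pytest.approx(200.0, rel=0.10)

    def test_invariant_to_multiplicative_rescaling(self):
        cfg = al.SimulationConfig(seed=6, snr=150)
        slc, _ = al.simulate_slice(cfg, 7)
        a = compute_snr(slc)
        b = compute_snr(slc.with_intensities(slc.intensities * 831.0))
        assert b == pytest.approx(a, rel=1e-6)

    def test_noise_free_returns_infinity_with_warning(self):
        cfg = al.SimulationConfig(seed=6, snr=None)
        slc, _ = al.simulate_slice(cfg, 7)
        with pytest.warns(UserWarning, match="infinite"):
            assert compute_snr(slc) == np.inf


class TestDetectionConfig:
    def test_bonferroni_split(self):
        cfg = DetectionConfig()
        assert cfg.per_slice_alpha == pytest.approx(0.05 / 4)

    def test_angle_candidates(self):
        assert DetectionConfig().n_angle_candidates == 33
        assert DetectionConfig(angle_search_deg=0.0).n_angle_candidates == 1

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha_total": 1.5},
            {"max_jitter_samples": 9},
            {"sidedness": "sideways"},
            {"scoring_mode": "bogus"},
            {"angle_search_deg": 8.0, "angle_step_deg": 20.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DetectionConfig(**kwargs)
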