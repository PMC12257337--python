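"""Agreement statistics: weighted kappa, Krippendorff alpha, ICC, Bland-Altman."""

import itertools

import numpy as np
import pytest

from acrlcod.agreement import (
    RatingTable,
    agreement_report,
    bland_altman,
    icc_oneway,
    krippendorff_alpha,
    weighted_kappa,
)
from conftest import make_ratings


def alpha_pairwise_oracle(scores):
    """Direct D_o / D_e enumeration over all pairable value pairs."""
    units = [row[~np.isnan(row)] for row in np.asarray(scores, dtype=float)]
    units = [u for u in units if len(u) >= 2]
    n = sum(len(u) for u in units)
    d_o = 0.0
    for u in units:
        m = len(u)
        for a, b in itertools.permutations(range(m), 2):
            d_o += (u[a] - u[b]) ** 2 / (m - 1)
    d_o /= n
    pooled = np.concatenate(units)
    d_e = 0.0
    for a, b in itertools.permutations(range(n), 2):
        d_e += (pooled[a] - pooled[b]) ** 2
    d_e /= n * (n - 1)
    return 1.0 - d_o / d_e


class TestWeightedKappa:
    def test_perfect_agreement(self):
        x, _ = make_ratings(seed=1)
        assert weighted_kappa(x, x) == pytest.approx(1.0)

    def test_chance_level_two_by_two(self):
        # observed table [[1,1],[1,1]] equals the marginal product: kappa 0
        assert weighted_kappa([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)

    def test_reversed_ratings_negative(self):
        # hand computation: sum(wO)/n = 8/3, sum(wE) = 12/9, kappa = -1
        assert weighted_kappa([0, 1, 2], [2, 1, 0]) == pytest.approx(-1.0)

    def test_constant_equal_ratings_defined_as_one(self):
        with pytest.warns(UserWarning):
            assert weighted_kappa([3, 3, 3], [3, 3, 3]) == 1.0

    def test_item_permutation_invariance(self):
        x, y = make_ratings(seed=2)
        perm = np.random.default_rng(0).permutation(len(x))
        cats = np.arange(0, 41)
        assert weighted_kappa(x, y, cats) == pytest.approx(
            weighted_kappa(x[perm], y[perm], cats), abs=1e-12
        )


class TestKrippendorffAlpha:
    def test_identical_columns(self):
        x, _ = make_ratings(seed=3)
        table = np.column_stack([x, x])
        assert krippendorff_alpha(table) == pytest.approx(1.0)

    def test_toy_table_matches_enumeration_oracle(self):
        table = np.array([[1, 1], [2, 2], [3, 3], [3, 4]], dtype=float)
        assert krippendorff_alpha(table) == pytest.approx(
            alpha_pairwise_oracle(table), abs=1e-10
        )

    def test_missing_data_matches_oracle(self):
        table = np.array(
            [[1, 1, 2], [2, np.nan, 2], [3, 3, np.nan], [4, 4, 4], [1, 2, 1]]
        )
        assert krippendorff_alpha(table) == pytest.approx(
            alpha_pairwise_oracle(table), abs=1e-10
        )

    def test_constant_versus_random_rater_near_zero(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            table = np.column_stack(
                [np.full(20, 5.0), rng.integers(0, 11, size=20).astype(float)]
            )
            if krippendorff_alpha(table) > 0.05:
                hits += 1
        assert hits <= 5

    def test_rater_order_invariance(self):
        x, y = make_ratings(seed=4)
        a = krippendorff_alpha(np.column_stack([x, y]).astype(float))
        b = krippendorff_alpha(np.column_stack([y, x]).astype(float))
        assert a == pytest.approx(b, abs=1e-12)


class TestIccOneway:
    def test_identical_raters(self):
        x, _ = make_ratings(seed=5)
        with pytest.warns(UserWarning):
            icc, _ = icc_oneway(np.column_stack([x, x, x]).astype(float))
        assert icc == pytest.approx(1.0)

    def test_toy_table_matches_hand_anova(self):
        table = np.array(
            [[9, 2, 5], [6, 1, 3], [8, 4, 6], [7, 1, 2], [10, 5, 6], [6, 2, 4]],
            dtype=float,
        )
        n, k = table.shape
        grand = table.mean()
        msb = k * ((table.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msw = ((table - table.mean(axis=1, keepdims=True)) ** 2).sum() / (n * (k - 1))
        expected = (msb - msw) / (msb + (k - 1) * msw)
        icc, _ = icc_oneway(table)
        assert icc == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin_icc1(self):
        import pandas as pd
        import pingouin as pg

        x, y = make_ratings(seed=6)
        table = np.column_stack([x, y]).astype(float)
        icc, ci = icc_oneway(table)
        long = pd.DataFrame(
            {
                "item": np.repeat(np.arange(len(x)), 2),
                "rater": np.tile(["a", "b"], len(x)),
                "score": table.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="item", raters="rater", ratings="score")
        row = ref[ref.Type == "ICC(1,1)"].iloc[0]
        assert icc == pytest.approx(row.ICC, abs=1e-8)
        assert ci == pytest.approx(tuple(row.CI95), abs=5e-3)

    def test_pure_noise_raters_average_nonpositive(self):
        vals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            vals.append(icc_oneway(rng.normal(size=(12, 3)))[0])
        assert np.mean(vals) <= 0.05

    def test_zero_within_variance(self):
        table = np.array([[1.0, 1.0], [4.0, 4.0], [9.0, 9.0]])
        with pytest.warns(UserWarning):
            icc, ci = icc_oneway(table)
        assert icc == 1.0 and ci == (1.0, 1.0)


class TestBlandAltman:
    def test_constant_offset(self):
        mean, sd, limits = bland_altman([1, 2, 3], [2, 3, 4])
        assert (mean, sd) == (-1.0, 0.0)
        assert limits == (-1.0, -1.0)

    def test_identical_ratings(self):
        mean, sd, limits = bland_altman([3, 7, 9], [3, 7, 9])
        assert mean == 0.0 and sd == 0.0 and limits == (0.0, 0.0)

    def test_two_point_closed_form(self):
        mean, sd, limits = bland_altman([0, 4], [0, 0])
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(2 * np.sqrt(2))
        assert limits[0] == pytest.approx(2 - 1.96 * sd)
        assert limits[1] == pytest.approx(2 + 1.96 * sd)


def test_agreement_report_perfect_scores():
    x, _ = make_ratings(seed=8)
    table = RatingTable(np.column_stack([x, x]).astype(float))
    report = agreement_report(table)
    assert report.kappa_sq_weighted == pytest.approx(1.0)
    assert report.krippendorff_alpha == pytest.approx(1.0)
    assert report.icc_oneway == pytest.approx(1.0)
    assert report.bland_altman_mean == 0.0 and report.bland_altman_sd == 0.0


def test_rating_table_validation():
    with pytest.raises(ValueError):
        RatingTable(np.array([[50.0, 1.0], [2.0, 3.0]]))  # outside 0..40
    with pytest.raises(ValueError):
        RatingTable(np.array([[1.0, 2.0]]))  # single item
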