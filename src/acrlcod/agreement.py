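"""Agreement statistics for validating automated scores against raters.

Implements the statistics used to compare LCOD scorers: squared-weight
Cohen's kappa, Krippendorff's alpha with the interval (squared-difference)
metric, the one-way random-effects intraclass correlation ICC(1) with its
F-based 95% confidence interval, and Bland-Altman limits of agreement.
Scores are integer totals (0-40) or per-slice counts (0-10); the declared
category range matters for kappa's chance-expected table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AcrLcodError

__all__ = [
    "RatingTable",
    "AgreementReport",
    "weighted_kappa",
    "krippendorff_alpha",
    "icc_oneway",
    "bland_altman",
    "agreement_report",
]


@dataclass(frozen=True)
class RatingTable:
    """Items x raters matrix of integer scores (NaN marks missing)."""

    scores: np.ndarray
    rater_labels: tuple[str, ...] | None = None
    item_labels: tuple[str, ...] | None = None
    score_range: tuple[int, int] = (0, 40)

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", arr)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("need at least 2 items and 2 raters")
        lo, hi = self.score_range
        vals = arr[~np.isnan(arr)]
        if ((vals < lo) | (vals > hi)).any():
            raise ValueError(f"scores outside declared range [{lo}, {hi}]")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, score_range=(0, 40)) -> "RatingTable":
        return cls(
            scores=df.to_numpy(dtype=float),
            rater_labels=tuple(map(str, df.columns)),
            item_labels=tuple(map(str, df.index)),
            score_range=score_range,
        )


@dataclass(frozen=True)
class AgreementReport:
    kappa_sq_weighted: float
    krippendorff_alpha: float
    icc_oneway: float
    icc_ci95: tuple[float, float]
    bland_altman_mean: float
    bland_altman_sd: float
    bland_altman_limits: tuple[float, float]


def weighted_kappa(x, y, categories=None) -> float:
    """Cohen's kappa with squared (i - j)^2 disagreement weights.

    kappa = 1 - sum(w * O) / sum(w * E), with O the observed and E the
    chance-expected (marginal-product) category-pair proportions over the
    declared category set.
    """
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("ratings must be equal-length with at least 2 items")
    if categories is None:
        lo = min(x.min(), y.min())
        hi = max(x.max(), y.max())
        categories = np.arange(lo, hi + 1)
    categories = np.asarray(categories)
    if len(categories) < 2:
        warnings.warn(
            "both raters constant and equal: kappa defined as 1", stacklevel=2
        )
        return 1.0
    from sklearn.metrics import cohen_kappa_score

    with np.errstate(invalid="ignore", divide="ignore"):
        k = cohen_kappa_score(x, y, labels=categories, weights="quadratic")
    if np.isnan(k):
        # zero expected disagreement: identical constant ratings
        warnings.warn(
            "zero chance-expected disagreement: kappa defined as 1", stacklevel=2
        )
        return 1.0
    return float(k)


def krippendorff_alpha(table: RatingTable | np.ndarray, metric: str = "interval") -> float:
    """Krippendorff's alpha via the coincidence-matrix formulation.

    alpha = 1 - D_o / D_e with squared-difference (interval) distances;
    missing entries are allowed, units with fewer than two pairable values
    are dropped.
    """
    if metric != "interval":
        raise ValueError("only the interval (squared-difference) metric is supported")
    scores = table.scores if isinstance(table, RatingTable) else np.asarray(table, float)
    values = np.unique(scores[~np.isnan(scores)])
    if values.size == 0:
        raise AcrLcodError("no pairable values")
    v_index = {v: i for i, v in enumerate(values)}
    k = len(values)
    coincidence = np.zeros((k, k))
    for unit in scores:
        unit = unit[~np.isnan(unit)]
        m = len(unit)
        if m < 2:
            continue
        idx = [v_index[v] for v in unit]
        for a in idx:
            for b in idx:
                coincidence[a, b] += 1.0 / (m - 1)
        for a in idx:  # remove self-pairs counted above
            coincidence[a, a] -= 1.0 / (m - 1)
    n = coincidence.sum()
    if n <= 1:
        raise AcrLcodError("fewer than 2 pairable values")
    n_c = coincidence.sum(axis=1)
    delta = (values[:, None] - values[None, :]) ** 2
    d_o = (coincidence * delta).sum() / n
    d_e = (np.outer(n_c, n_c) * delta).sum() / (n * (n - 1))
    if d_e == 0:
        return 1.0
    return float(1.0 - d_o / d_e)


def icc_oneway(table: RatingTable | np.ndarray, confidence: float = 0.95):
    """One-way random-effects ICC(1) with its F-distribution CI.

    ICC(1) = (MSB - MSW) / (MSB + (k - 1) * MSW) from the one-way ANOVA
    across items; the CI follows the standard F bounds.  Cross-checked in
    the test suite against pingouin's ICC1.
    """
    scores = table.scores if isinstance(table, RatingTable) else np.asarray(table, float)
    if np.isnan(scores).any():
        raise ValueError("ICC(1) requires a complete table")
    n, k = scores.shape
    grand = scores.mean()
    item_means = scores.mean(axis=1)
    msb = k * ((item_means - grand) ** 2).sum() / (n - 1)
    msw = ((scores - item_means[:, None]) ** 2).sum() / (n * (k - 1))
    if msw == 0:
        warnings.warn("zero within-item variance: ICC = 1", stacklevel=2)
        return 1.0, (1.0, 1.0)
    icc = (msb - msw) / (msb + (k - 1) * msw)
    from scipy import stats

    f_obs = msb / msw
    a = (1.0 - confidence) / 2.0
    df1, df2 = n - 1, n * (k - 1)
    f_lower = f_obs / stats.f.ppf(1 - a, df1, df2)
    f_upper = f_obs * stats.f.ppf(1 - a, df2, df1)
    ci = (
        float((f_lower - 1) / (f_lower + k - 1)),
        float((f_upper - 1) / (f_upper + k - 1)),
    )
    return float(icc), ci


def bland_altman(x, y):
    """Mean difference, SD of differences and 1.96-SD limits of agreement."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("ratings must be equal-length with at least 2 items")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean, sd, (mean - 1.96 * sd, mean + 1.96 * sd)


def bland_altman_plot(x, y, ax=None):
    """Bland-Altman scatter with mean and limit lines; returns the axes."""
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mean, sd, (lo, hi) = bland_altman(x, y)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((x + y) / 2.0, x - y, s=18)
    ax.axhline(mean, color="tab:blue", ls="--", label=f"mean {mean:.2f}")
    for lim in (lo, hi):
        ax.axhline(lim, color="tab:red", ls="--")
    ax.set_xlabel("mean of scores")
    ax.set_ylabel("difference of scores")
    ax.legend()
    return ax


def agreement_report(table: RatingTable) -> AgreementReport:
    """All agreement statistics for a two-column rating table."""
    if table.scores.shape[1] != 2:
        raise ValueError("agreement_report expects exactly two raters/sessions")
    x, y = table.scores[:, 0], table.scores[:, 1]
    if np.isnan(table.scores).any():
        raise ValueError("agreement_report requires complete ratings")
    icc, ci = icc_oneway(table)
    mean, sd, limits = bland_altman(x, y)
    return AgreementReport(
        kappa_sq_weighted=weighted_kappa(
            x.astype(int), y.astype(int),
            categories=np.arange(table.score_range[0], table.score_range[1] + 1),
        ),
        krippendorff_alpha=krippendorff_alpha(table),
        icc_oneway=icc,
        icc_ci95=ci,
        bland_altman_mean=mean,
        bland_altman_sd=sd,
        bland_altman_limits=limits,
    )
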