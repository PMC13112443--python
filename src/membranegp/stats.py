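"""Treatment-level statistics for cross-dye comparison.

Three layers, matching how ratiometric dye readouts are usually analyzed:

* per-treatment summaries (mean ± SEM, median with quartiles),
* one-way ANOVA followed by Tukey's HSD all-pairs test (Tukey–Kramer form
  for unequal group sizes, studentized-range distribution),
* Deming errors-in-variables regression between two dye readouts measured
  with comparable noise, with jackknife standard errors and a t-test on the
  slope.

Deming regression is used instead of ordinary least squares because both
axes (e.g. the GP of one dye and the excitation ratio of another) carry
measurement error; OLS would attenuate the slope.  The error-variance
ratio ``delta`` = sigma_y^2 / sigma_x^2 defaults to 1 (orthogonal
regression), the standard choice when the ratio is unknown, and is echoed
in every output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TreatmentSummary",
    "TukeyTable",
    "TukeyPair",
    "DemingFit",
    "summarize_treatments",
    "anova_tukey",
    "deming_fit",
    "correlate_dyes",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TreatmentSummary:
    """Per-treatment location and spread of GP-like values."""

    treatment: str
    n: int
    mean: float
    sem: float  # NaN when n == 1 (undefined, not 0)
    median: float
    quartiles: tuple[float, float]


@dataclass(frozen=True)
class TukeyPair:
    group_a: str
    group_b: str
    mean_difference: float
    q_statistic: float
    p_adjusted: float


@dataclass(frozen=True)
class TukeyTable:
    """All unordered pairwise comparisons plus the overall one-way ANOVA."""

    pairs: tuple[TukeyPair, ...]
    f_statistic: float
    df_between: int
    df_within: int
    p_overall: float
    mse: float


@dataclass(frozen=True)
class DemingFit:
    """Closed-form Deming regression estimate with jackknife uncertainty."""

    slope: float
    intercept: float
    delta: float
    slope_se: float
    intercept_se: float
    p_value: float  # H0: slope = 0, t with n-2 df
    n: int


def summarize_treatments(values_by_treatment: dict) -> list[TreatmentSummary]:
    """Mean, SEM (sample SD / sqrt(n)), median and quartiles per treatment.

    Accepts a mapping treatment -> iterable of values.  Treatments with no
    values are excluded with a warning; a single value yields SEM = NaN
    (undefined, deliberately not reported as 0).
    """
    out: list[TreatmentSummary] = []
    for treatment, values in values_by_treatment.items():
        v = np.asarray(list(values), dtype=float)
        if v.size == 0:
            logger.warning("treatment %r has no values; excluded", treatment)
            continue
        sem = float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else float("nan")
        q1, q3 = np.quantile(v, [0.25, 0.75])
        out.append(
            TreatmentSummary(
                treatment=str(treatment),
                n=int(v.size),
                mean=float(v.mean()),
                sem=sem,
                median=float(np.median(v)),
                quartiles=(float(q1), float(q3)),
            )
        )
    return out


def anova_tukey(groups: dict, alpha: float = 0.05) -> TukeyTable:
    """One-way ANOVA followed by Tukey's HSD over all unordered pairs.

    The F statistic comes from the standard between/within sums of squares.
    Pairwise q statistics use the pooled MSE with the Tukey–Kramer
    harmonic-mean form for unequal group sizes,

        q_ij = |m_i - m_j| / sqrt(MSE/2 * (1/n_i + 1/n_j)),

    and adjusted p-values from the studentized-range distribution with
    ``k`` groups and ``N - k`` degrees of freedom.  With zero pooled
    variance but unequal means the p-value is reported as the 0 limit with
    a warning.
    """
    names = list(groups)
    data = [np.asarray(list(groups[g]), dtype=float) for g in names]
    if len(data) < 2:
        raise ValueError("need at least two groups")
    if any(d.size < 2 for d in data):
        raise ValueError("every group needs at least two values")
    k = len(data)
    ns = np.array([d.size for d in data])
    n_total = int(ns.sum())
    means = np.array([d.mean() for d in data])
    grand = float(np.concatenate(data).mean())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((d - d.mean()) ** 2).sum() for d in data))
    df_b, df_w = k - 1, n_total - k
    mse = ss_within / df_w
    if mse > 0:
        f_stat = (ss_between / df_b) / mse
        p_overall = float(sps.f.sf(f_stat, df_b, df_w))
    elif ss_between > 0:
        logger.warning("zero pooled variance with unequal means; p -> 0 limit")
        f_stat, p_overall = float("inf"), 0.0
    else:
        f_stat, p_overall = 0.0, 1.0

    pairs: list[TukeyPair] = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(means[i] - means[j])
            se = math.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            if se > 0:
                q = abs(diff) / se
                p = float(np.clip(sps.studentized_range.sf(q, k, df_w), 0.0, 1.0))
            elif diff != 0:
                q, p = float("inf"), 0.0
            else:
                q, p = 0.0, 1.0
            pairs.append(
                TukeyPair(
                    group_a=str(names[i]),
                    group_b=str(names[j]),
                    mean_difference=diff,
                    q_statistic=q,
                    p_adjusted=p,
                )
            )
    return TukeyTable(
        pairs=tuple(pairs),
        f_statistic=f_stat,
        df_between=df_b,
        df_within=df_w,
        p_overall=p_overall,
        mse=mse,
    )


def _deming_slope(x: np.ndarray, y: np.ndarray, delta: float) -> float:
    """Closed-form Deming slope, numerically stable for large delta."""
    s_xx = float(np.var(x, ddof=1))
    s_yy = float(np.var(y, ddof=1))
    s_xy = float(np.cov(x, y, ddof=1)[0, 1])
    if s_xy == 0:
        raise ValueError("zero covariance between x and y: Deming slope undefined")
    u = s_yy - delta * s_xx
    disc = math.sqrt(u * u + 4.0 * delta * s_xy * s_xy)
    if u >= 0:
        numerator = u + disc
    else:
        # avoid cancellation when delta*s_xx dominates s_yy
        numerator = 4.0 * delta * s_xy * s_xy / (disc - u)
    return numerator / (2.0 * s_xy)


def deming_fit(x, y, delta: float = 1.0) -> DemingFit:
    """Deming errors-in-variables regression of y on x.

    Uses the closed-form maximum-likelihood estimator for a given error
    variance ratio ``delta`` = sigma_y^2/sigma_x^2; ``delta = 1`` is
    orthogonal (total least squares) regression and ``delta -> inf``
    approaches ordinary least squares of y on x.  Standard errors come
    from the leave-one-out jackknife and the slope p-value from
    ``t = slope / slope_se`` with ``n - 2`` degrees of freedom — a
    distribution-free choice that needs no assumption on the error
    variances themselves.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("Deming regression needs at least 3 points")
    if delta <= 0:
        raise ValueError("delta must be positive")
    if np.ptp(x) == 0:
        raise ValueError("x values are all equal")

    slope = _deming_slope(x, y, delta)
    intercept = float(y.mean() - slope * x.mean())

    loo_slopes = np.empty(n)
    loo_intercepts = np.empty(n)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        xi, yi = x[keep], y[keep]
        loo_slopes[i] = _deming_slope(xi, yi, delta)
        loo_intercepts[i] = yi.mean() - loo_slopes[i] * xi.mean()
        keep[i] = True
    slope_se = math.sqrt((n - 1) / n * float(((loo_slopes - loo_slopes.mean()) ** 2).sum()))
    intercept_se = math.sqrt(
        (n - 1) / n * float(((loo_intercepts - loo_intercepts.mean()) ** 2).sum())
    )
    if slope_se > 0:
        t = slope / slope_se
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    else:
        p = 0.0 if slope != 0 else 1.0
    return DemingFit(
        slope=float(slope),
        intercept=intercept,
        delta=float(delta),
        slope_se=float(slope_se),
        intercept_se=float(intercept_se),
        p_value=p,
        n=int(n),
    )


def correlate_dyes(
    table,
    x: str,
    ys: list[str] | tuple[str, ...],
    delta: float = 1.0,
    alpha: float = 0.05,
) -> dict[str, dict]:
    """Deming fits of each readout in ``ys`` against the readout ``x``.

    ``table`` is a pandas DataFrame of matched treatment-level means (one
    row per treatment).  Rows with a missing value in ``x`` or the current
    ``y`` are dropped pairwise; fewer than 3 matched rows is an error.
    Returns, per ``y``, the :class:`DemingFit` and a significance flag at
    ``alpha`` (no multiple-testing correction across pairs: the raw
    p-values are reported, as is conventional for these two-way dye
    comparisons, and this is stated in the output metadata).
    """
    results: dict[str, dict] = {}
    for y in ys:
        sub = table[[x, y]].dropna()
        if len(sub) < 3:
            raise ValueError(
                f"need at least 3 matched treatment rows for {x!r} vs {y!r}, "
                f"got {len(sub)}"
            )
        fit = deming_fit(sub[x].to_numpy(), sub[y].to_numpy(), delta=delta)
        results[y] = {
            "fit": fit,
            "significant": bool(fit.p_value < alpha),
            "alpha": alpha,
            "multiple_testing_correction": "none (raw p-values reported)",
        }
    return results
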