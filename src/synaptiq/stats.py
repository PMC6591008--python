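"""Statistical layer: rank/distribution tests, ROUT outliers, activation indices.

Wraps the two-sided Mann-Whitney U and two-sample Kolmogorov-Smirnov tests
used to compare per-cell and per-track measurements, implements a univariate
specialization of ROUT (Robust regression and OUTlier removal) at a given
false-discovery rate Q, and computes the flow-cytometry-style activation
index: the antigen-induced increase in a marker's geometric mean, optionally
expressed as a percent of the control response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "RoutResult",
    "mann_whitney_u",
    "ks_two_sample",
    "rout_outliers",
    "geometric_mean",
    "ag_induced_increase",
    "percent_of_control",
    "paired_t",
]


@dataclass(frozen=True)
class RoutResult:
    """Outcome of ROUT outlier flagging on one sample."""

    outlier_flags: np.ndarray  # bool, aligned with the input
    q_percent: float
    robust_center: float
    rsdr: float
    n_flagged: int


def _check_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    return arr


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of sample a, p).

    The p-value is exact (enumeration) for small samples without ties
    (``n_a * n_b <= 400``), otherwise the normal approximation with tie and
    continuity corrections is used.
    """
    a = _check_sample(a, "a")
    b = _check_sample(b, "b")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test; returns (D, p) with the
    asymptotic p-value."""
    a = _check_sample(a, "a")
    b = _check_sample(b, "b")
    res = sps.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def rout_outliers(values, q_percent: float = 1.0) -> RoutResult:
    """Univariate ROUT: FDR-controlled outlier flagging around the median.

    The method fits the simplest robust model (the sample median), estimates
    the robust SD of the residuals as the 68.27th percentile of their
    absolute values times ``n/(n-1)``, and tests the most extreme values
    outermost-first: the i-th most extreme value, with t-ratio
    ``|residual| / RSDR`` and two-sided p from a t distribution with
    ``n - 1`` df, is declared an outlier together with everything more
    extreme if ``p <= (Q/100) * i / n`` (Benjamini-Hochberg-style schedule).

    Raises
    ------
    ValueError
        If fewer than 3 values are supplied.
    """
    v = _check_sample(values, "values")
    n = v.size
    if n < 3:
        raise ValueError("ROUT requires at least 3 values")
    center = float(np.median(v))
    resid = v - center
    abs_resid = np.abs(resid)
    if np.all(abs_resid == 0):
        return RoutResult(np.zeros(n, dtype=bool), q_percent, center, 0.0, 0)
    rsdr = float(np.percentile(abs_resid, 68.27)) * n / (n - 1)
    if rsdr == 0:
        rsdr = float(np.mean(abs_resid)) * n / (n - 1)

    order = np.argsort(abs_resid)[::-1]  # outermost first
    t_ratios = abs_resid[order] / rsdr
    pvals = 2.0 * sps.t.sf(t_ratios, df=n - 1)
    alpha = q_percent / 100.0
    thresholds = alpha * np.arange(1, n + 1) / n
    passing = np.nonzero(pvals <= thresholds)[0]
    flags = np.zeros(n, dtype=bool)
    if passing.size:
        k = int(passing.max()) + 1  # flag the k most extreme values
        flags[order[:k]] = True
    return RoutResult(flags, q_percent, center, rsdr, int(flags.sum()))


def geometric_mean(values) -> float:
    """exp(mean(log x)); all values must be strictly positive."""
    v = _check_sample(values, "values")
    if np.any(v <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(v))))


def ag_induced_increase(stim, control) -> float:
    """Antigen-induced increase of a fluorescence marker: geometric mean of
    the stimulated sample minus geometric mean of the control sample."""
    return geometric_mean(stim) - geometric_mean(control)


def percent_of_control(treated_increase: float, control_increase: float) -> float:
    """Treated response as a percent of the control response (= 100%)."""
    if control_increase == 0:
        raise ValueError("control increase is zero; percent undefined")
    return 100.0 * treated_increase / control_increase


def paired_t(a, b) -> tuple[float, float]:
    """Two-tailed paired t-test on matched samples; returns (t, p)."""
    a = _check_sample(a, "a")
    b = _check_sample(b, "b")
    if a.size != b.size:
        raise ValueError("paired t-test requires equal-length samples")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
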