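"""Statistical comparisons: OLS regressions and Welch's t-test.

These back the cross-level consistency regressions (Order vs Family and
BIN Distance), the generation-time association, and the contrast of
Family Distance between families with and without indels.  The t-test
is Welch's (unequal variances) with Satterthwaite degrees of freedom;
regression p-values are two-sided with no multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    df: float
    p_value: float
    group_means: tuple[float, float]
    group_sizes: tuple[int, int]


def ols(x, y) -> RegressionResult:
    """Simple least squares of y on x; pairs with missing values dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    fit = sps.linregress(x, y)
    return RegressionResult(slope=float(fit.slope),
                            intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue ** 2),
                            p_value=float(fit.pvalue), n=n)


def welch_t(a, b) -> TTestResult:
    """Welch's two-sample t-test with Satterthwaite df (two-sided)."""
    a = np.asarray([v for v in np.asarray(a, dtype=float) if not np.isnan(v)])
    b = np.asarray([v for v in np.asarray(b, dtype=float) if not np.isnan(v)])
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 observations")
    m1, m2 = float(a.mean()), float(b.mean())
    v1, v2 = float(a.var(ddof=1)), float(b.var(ddof=1))
    se2 = v1 / n1 + v2 / n2
    if se2 == 0.0:
        # both groups constant: identical means give t = 0, p = 1
        t = 0.0 if m1 == m2 else float("inf") * np.sign(m1 - m2)
        df = float(n1 + n2 - 2)
        p = 1.0 if m1 == m2 else 0.0
        return TTestResult(t, df, p, (m1, m2), (n1, n2))
    t = (m1 - m2) / np.sqrt(se2)
    denom = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    # denom can underflow to 0 for near-constant groups
    df = se2 ** 2 / denom if denom > 0 else float(n1 + n2 - 2)
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TTestResult(float(t), float(df), p, (m1, m2), (n1, n2))


def indel_family_contrast(family_distances: pd.Series,
                          indel_families: set[str]) -> TTestResult:
    """Welch contrast of per-family Family Distance, split by indel presence.

    ``family_distances`` is indexed by family name (or (order, family));
    a family is in the indel group when its family-level label is in
    ``indel_families``.
    """
    labels = family_distances.index
    if isinstance(labels, pd.MultiIndex):
        fam_names = labels.get_level_values(-1)
    else:
        fam_names = labels
    in_group = pd.Index(fam_names).isin(indel_families)
    with_indels = family_distances[in_group].dropna()
    without = family_distances[~in_group].dropna()
    if len(with_indels) == 0 or len(without) == 0:
        raise ValueError("one of the contrast groups is empty")
    return welch_t(with_indels.to_numpy(), without.to_numpy())
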