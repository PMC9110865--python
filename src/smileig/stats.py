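"""Supporting statistics: Spearman rank correlation, Kolmogorov-Smirnov
normality screening, and median (P25, P75) summaries.

Spearman rho is the Pearson correlation of mid-ranks (average ranks on
ties); its two-sided p-value uses the t approximation
``t = rho * sqrt((n - 2) / (1 - rho^2))`` with n - 2 degrees of freedom,
standard at cohort sizes in the hundreds to thousands.  For n <= 8 an exact
permutation p-value is available.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["CorrelationResult", "spearman", "ks_normality", "median_iqr",
           "correlation_table"]


@dataclasses.dataclass(frozen=True)
class CorrelationResult:
    feature: str
    rho: float
    p_value: float
    n: int

    @property
    def direction(self) -> str:
        if math.isnan(self.rho) or self.rho == 0:
            return "None"
        return "Positive" if self.rho > 0 else "Negative"


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    return float((rx * ry).sum() / denom)


def spearman(x, y, feature: str = "", exact: bool | None = None) -> CorrelationResult:
    """Spearman rank correlation on complete pairs.

    ``exact=True`` (only for n <= 8) enumerates all permutations of one
    argument's ranks for the two-sided p-value; by default the t
    approximation is used.  A constant argument yields rho = NaN with a
    warning.
    """
    x = pd.Series(np.asarray(x, dtype=float))
    y = pd.Series(np.asarray(y, dtype=float))
    mask = x.notna() & y.notna()
    x, y = x[mask].to_numpy(), y[mask].to_numpy()
    n = x.size
    if n < 3:
        raise ValueError("spearman needs at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("spearman: constant input, rho undefined", stacklevel=2)
        return CorrelationResult(feature, float("nan"), float("nan"), n)

    rx = sps.rankdata(x)  # mid-ranks on ties
    ry = sps.rankdata(y)
    rho = _rho_from_ranks(rx, ry)

    if exact:
        if n > 8:
            raise ValueError("exact permutation p only for n <= 8")
        hits = total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_rho_from_ranks(rx, np.asarray(perm))) >= abs(rho) - 1e-12:
                hits += 1
        p = hits / total
    elif abs(rho) >= 1.0 - 1e-15:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho ** 2))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(feature, rho, p, n)


def ks_normality(x) -> tuple[float, float]:
    """One-sample KS statistic and asymptotic p against a normal with the
    sample mean and SD; used to decide median-vs-mean reporting."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 5:
        raise ValueError("ks_normality needs n >= 5")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("ks_normality: constant sample, degenerate", stacklevel=2)
        return float("nan"), float("nan")
    stat, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return float(stat), float(p)


def median_iqr(x) -> tuple[float, float, float]:
    """(median, P25, P75) with linear-interpolation quantiles."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("median_iqr: empty input")
    med, p25, p75 = np.quantile(x, [0.5, 0.25, 0.75])
    return float(med), float(p25), float(p75)


def correlation_table(df: pd.DataFrame, features, outcome: str) -> list[CorrelationResult]:
    """Spearman correlation of each feature against the outcome column."""
    return [spearman(df[f], df[outcome], feature=f) for f in features]
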