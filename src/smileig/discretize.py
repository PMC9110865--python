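"""Discretization of the refractive outcome and of continuous features.

The 3-month spherical equivalent is mapped to three accuracy classes around
emmetropia::

    class 0 : -0.25 D <= SE <= 0.25 D         (on target)
    class 1 : -0.50 D <= SE < -0.25 D  or  0.25 D < SE <= 0.50 D
    class 2 : SE < -0.50 D  or  SE > 0.50 D   (off target)

Continuous candidate features are binned (equal-frequency by default) before
conditional-entropy computation; categorical features pass through unchanged.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["DiscretizationScheme", "bin_outcome", "bin_feature"]

#: Default outcome class boundaries (inner, outer), diopters.
DEFAULT_OUTCOME_BOUNDS: tuple[float, float] = (0.25, 0.50)


@dataclasses.dataclass(frozen=True)
class DiscretizationScheme:
    """How outcome and features are mapped to discrete labels.

    Parameters
    ----------
    outcome_bounds : (inner, outer) absolute boundaries in diopters for the
        three outcome classes; class 0 is ``|v| <= inner``, class 1 extends to
        ``outer`` with the inner boundary open, class 2 is beyond ``outer``.
    feature_strategy : 'equal_frequency' | 'equal_width' | 'custom'.
    n_feature_bins : number of feature bins (>= 2), default 4.
    custom_boundaries : for 'custom', per-feature ascending interior
        boundaries.
    categorical_passthrough : leave categorical features as their own levels.
    """

    outcome_bounds: tuple[float, float] = DEFAULT_OUTCOME_BOUNDS
    feature_strategy: str = "equal_frequency"
    n_feature_bins: int = 4
    custom_boundaries: Mapping[str, Sequence[float]] | None = None
    categorical_passthrough: bool = True

    def __post_init__(self) -> None:
        if self.n_feature_bins < 2:
            raise ValueError("n_feature_bins must be >= 2")
        inner, outer = self.outcome_bounds
        if not (0 < inner < outer):
            raise ValueError("outcome bounds must satisfy 0 < inner < outer")
        if self.feature_strategy not in ("equal_frequency", "equal_width", "custom"):
            raise ValueError(f"unknown feature_strategy {self.feature_strategy!r}")


def bin_outcome(post_se, bounds: tuple[float, float] = DEFAULT_OUTCOME_BOUNDS):
    """Map 3-month spherical equivalent (D) to outcome class {0, 1, 2}.

    Boundaries of class 0 are closed, the adjacent class-1 intervals are
    half-open on the inner side and closed on the outer side.  NaN raises.
    Scalar in, scalar out; array in, int array out.
    """
    inner, outer = bounds
    v = np.asarray(post_se, dtype=float)
    if np.any(np.isnan(v)):
        raise ValueError("bin_outcome: NaN outcome value")
    a = np.abs(v)
    cls = np.where(a <= inner, 0, np.where(a <= outer, 1, 2))
    return int(cls) if cls.ndim == 0 else cls.astype(np.int64)


def _searchsorted_lower(bounds: np.ndarray, values: np.ndarray) -> np.ndarray:
    # side='left': a value equal to a boundary falls in the lower bin.
    return np.searchsorted(bounds, values, side="left").astype(np.int64)


def bin_feature(
    values,
    scheme: DiscretizationScheme = DiscretizationScheme(),
    feature: str | None = None,
) -> np.ndarray:
    """Discretize one feature vector to integer labels 0..k-1.

    Equal-frequency bins put boundaries at the k-quantiles (linear
    interpolation) with ties assigned to the lower bin; equal-width bins
    partition [min, max] uniformly.  Categorical input passes through as
    level codes when ``scheme.categorical_passthrough`` is set.  An
    all-constant vector collapses to a single bin with a warning.
    """
    s = pd.Series(values)
    if scheme.categorical_passthrough and (
        s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool
    ):
        codes, _ = pd.factorize(s, sort=True)
        return codes.astype(np.int64)

    v = s.to_numpy(dtype=float)
    distinct = np.unique(v)
    if distinct.size == 1:
        warnings.warn("bin_feature: constant vector collapses to a single bin "
                      "(information gain will be 0)", stacklevel=2)
        return np.zeros(v.shape, dtype=np.int64)

    k = scheme.n_feature_bins
    if distinct.size <= k and scheme.feature_strategy != "custom":
        # few-valued numeric feature: each distinct value is its own bin
        return np.searchsorted(distinct, v).astype(np.int64)
    if scheme.feature_strategy == "custom":
        if not scheme.custom_boundaries or feature not in scheme.custom_boundaries:
            raise ValueError(f"custom boundaries missing for feature {feature!r}")
        bounds = np.asarray(scheme.custom_boundaries[feature], dtype=float)
        if np.any(np.diff(bounds) <= 0):
            raise ValueError("custom boundaries must be strictly ascending")
    elif scheme.feature_strategy == "equal_width":
        bounds = np.linspace(v.min(), v.max(), k + 1)[1:-1]
    else:  # equal_frequency
        probs = np.linspace(0.0, 1.0, k + 1)[1:-1]
        bounds = np.quantile(v, probs)
        uniq = np.unique(bounds)
        if uniq.size < bounds.size:
            warnings.warn(
                f"bin_feature: duplicate quantile boundaries collapse "
                f"{bounds.size + 1 - uniq.size} bin(s)", stacklevel=2)
            bounds = uniq
    return _searchsorted_lower(bounds, v)
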