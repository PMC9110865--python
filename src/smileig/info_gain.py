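"""Entropy-based feature weighting and the two-stage multicenter selection.

The importance of a candidate feature ``a`` for the discretized refractive
outcome ``S`` is the information gain

    IG(S, a) = H(S) - H(S | a)

with Shannon entropy in bits.  Within one ranking the raw gains are
normalized to weights that sum to one, so a feature's weight is its share of
the total information the candidate set carries about the outcome.  The
multicenter procedure keeps the features whose weight exceeds a primary
threshold (default 0.05) in *every* center, re-ranks that common subset per
center (weights renormalize over the subset), and finally keeps the features
above a secondary threshold (default 0.10) in every center.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .data_model import OUTCOME, Cohort
from .discretize import DiscretizationScheme, bin_feature, bin_outcome

__all__ = [
    "FeatureWeight",
    "SelectionResult",
    "entropy",
    "conditional_entropy",
    "information_gain",
    "information_gain_from_counts",
    "rank_features",
    "select_common",
    "secondary_selection",
    "InformationGainRanker",
]

PRIMARY_THRESHOLD = 0.05
SECONDARY_THRESHOLD = 0.10


@dataclasses.dataclass(frozen=True)
class FeatureWeight:
    """A feature's raw information gain and normalized share of a ranking."""

    feature: str
    raw_ig: float   # bits, >= 0
    weight: float   # share in [0, 1]; weights of one ranking sum to 1
    n_used: int     # complete cases the gain was computed on


@dataclasses.dataclass
class SelectionResult:
    """Outcome of one selection stage across centers."""

    per_center_rankings: dict[str, list[FeatureWeight]]
    per_center_selected: dict[str, set[str]]
    common_features: set[str]
    stage: str          # 'primary' | 'secondary'
    threshold: float


def _as_codes(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.size == 0:
        raise ValueError("empty label vector")
    _, codes = np.unique(arr, return_inverse=True)
    return codes


def entropy(labels) -> float:
    """Shannon entropy (bits) of a discrete label vector, 0*log 0 := 0."""
    codes = _as_codes(labels)
    counts = np.bincount(codes).astype(float)
    p = counts / counts.sum()
    return float(-np.sum(xlogy(p, p)) / np.log(2.0))


def conditional_entropy(outcome, feature_bins) -> float:
    """H(S|a): group-size-weighted entropy of the outcome within feature groups."""
    s = _as_codes(outcome)
    a = _as_codes(feature_bins)
    if s.shape != a.shape:
        raise ValueError("outcome and feature vectors differ in length")
    n = s.size
    table = np.zeros((s.max() + 1, a.max() + 1))
    np.add.at(table, (s, a), 1.0)
    col = table.sum(axis=0)
    h = 0.0
    for v in range(table.shape[1]):
        if col[v] == 0:
            continue
        p = table[:, v] / col[v]
        h += (col[v] / n) * float(-np.sum(xlogy(p, p)) / np.log(2.0))
    return h


def information_gain_from_counts(table) -> float | np.ndarray:
    """Information gain from an outcome-by-feature contingency table.

    ``table`` has shape ``(..., K, V)`` (outcome classes by feature values);
    leading axes are broadcast, so a stack of tables is evaluated in one call.
    Computed as H(S) minus the weighted within-group entropies, clipped at 0
    to absorb rounding at machine precision.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim < 2:
        raise ValueError("contingency table must be at least 2-D")
    n = t.sum(axis=(-2, -1))
    if np.any(n < 2):
        raise ValueError("information gain needs at least 2 complete cases")
    row = t.sum(axis=-1)                      # (..., K) outcome class totals
    col = t.sum(axis=-2)                      # (..., V) feature group totals
    log2 = np.log(2.0)
    p_row = row / n[..., None]
    h_s = -np.sum(xlogy(p_row, p_row), axis=-1) / log2
    with np.errstate(divide="ignore", invalid="ignore"):
        p_cond = np.where(col[..., None, :] > 0, t / np.where(
            col[..., None, :] > 0, col[..., None, :], 1.0), 0.0)
    h_groups = -np.sum(xlogy(p_cond, p_cond), axis=-2) / log2   # (..., V)
    h_s_given_a = np.sum(col / n[..., None] * h_groups, axis=-1)
    ig = np.maximum(h_s - h_s_given_a, 0.0)
    return float(ig) if ig.ndim == 0 else ig


def information_gain(outcome, feature_bins) -> float:
    """IG(S, a) = H(S) - H(S|a) in bits for paired discrete vectors."""
    s = _as_codes(outcome)
    a = _as_codes(feature_bins)
    if s.shape != a.shape:
        raise ValueError("outcome and feature vectors differ in length")
    if s.size < 2:
        raise ValueError("information gain needs at least 2 complete cases")
    table = np.zeros((s.max() + 1, a.max() + 1))
    np.add.at(table, (s, a), 1.0)
    return float(information_gain_from_counts(table))


def _normalize(raw: dict[str, tuple[float, int]]) -> list[FeatureWeight]:
    total = sum(v for v, _ in raw.values())
    if total == 0.0:
        warnings.warn("all information gains are zero; weights undefined, "
                      "returning all-zero weights", stacklevel=3)
        weights = {f: 0.0 for f in raw}
    else:
        weights = {f: v / total for f, (v, _) in raw.items()}
    ranked = sorted(raw, key=lambda f: (-weights[f], f))
    return [FeatureWeight(f, raw[f][0], weights[f], raw[f][1]) for f in ranked]


def rank_features(
    cohort: Cohort,
    scheme: DiscretizationScheme = DiscretizationScheme(),
    features: Sequence[str] | None = None,
) -> list[FeatureWeight]:
    """Rank candidate features by normalized information gain.

    Each feature's gain is computed on that feature's complete cases
    (pairwise deletion with the outcome).  Weights are the raw gains divided
    by their sum, in descending order with name tie-breaks.
    """
    features = tuple(features) if features is not None else cohort.feature_names
    df = cohort.df
    missing = [f for f in features if f not in df.columns]
    if missing:
        raise KeyError(f"features not in cohort: {missing}")
    if OUTCOME not in df.columns:
        raise KeyError(f"cohort lacks outcome column {OUTCOME!r}")
    outcome = df[OUTCOME]
    raw: dict[str, tuple[float, int]] = {}
    for f in features:
        mask = outcome.notna() & df[f].notna()
        n_used = int(mask.sum())
        if n_used < 2:
            raise ValueError(f"feature {f!r}: fewer than 2 complete cases")
        s = bin_outcome(outcome[mask].to_numpy(dtype=float), scheme.outcome_bounds)
        a = bin_feature(df.loc[mask, f], scheme, feature=f)
        raw[f] = (information_gain(s, a), n_used)
    return _normalize(raw)


def select_common(
    rankings: Mapping[str, Sequence[FeatureWeight]],
    threshold: float = PRIMARY_THRESHOLD,
    stage: str = "primary",
) -> SelectionResult:
    """Intersect the per-center sets of features with weight strictly above
    ``threshold`` (Venn-style overlap across centers)."""
    if not rankings:
        raise ValueError("select_common needs at least one center")
    selected = {
        center: {fw.feature for fw in ranking if fw.weight > threshold}
        for center, ranking in rankings.items()
    }
    common: set[str] = set.intersection(*selected.values())
    return SelectionResult(
        per_center_rankings={c: list(r) for c, r in rankings.items()},
        per_center_selected=selected,
        common_features=common,
        stage=stage,
        threshold=threshold,
    )


def secondary_selection(
    cohorts: Mapping[str, Cohort],
    scheme: DiscretizationScheme = DiscretizationScheme(),
    subset: Sequence[str] | None = None,
    threshold: float = SECONDARY_THRESHOLD,
) -> SelectionResult:
    """Re-rank a feature subset per center and apply the secondary cut.

    Restricting the ranking to the subset renormalizes the weights over a
    smaller denominator, so each surviving feature's weight grows; the final
    cut keeps features above ``threshold`` in every center.
    """
    if not subset:
        raise ValueError("secondary_selection needs a non-empty feature subset")
    rankings = {
        center: rank_features(cohort, scheme, features=subset)
        for center, cohort in cohorts.items()
    }
    return select_common(rankings, threshold=threshold, stage="secondary")


class InformationGainRanker(BaseEstimator, TransformerMixin):
    """Scikit-learn style information-gain feature ranker / selector.

    ``fit(X, y)`` discretizes the continuous outcome ``y`` into the three
    refractive accuracy classes (unless ``discretize_outcome=False``, in which
    case ``y`` is taken as already discrete), bins each column of ``X``, and
    computes per-feature information gain plus sum-to-one weights.
    ``transform`` keeps the columns whose weight exceeds ``threshold``.

    Parameters
    ----------
    n_bins : feature bins for continuous columns (default 4, equal-frequency).
    strategy : 'equal_frequency' or 'equal_width'.
    outcome_bounds : class boundaries (inner, outer) in diopters.
    discretize_outcome : whether ``y`` is a continuous SE to be discretized.
    threshold : normalized-weight cutoff used by ``transform`` (strictly >).

    Attributes
    ----------
    feature_names_in_ : column names seen at fit.
    raw_ig_ : per-feature information gain, bits.
    weights_ : normalized weights (sum to 1).
    ranking_ : list of :class:`FeatureWeight`, descending weight.
    """

    def __init__(
        self,
        n_bins: int = 4,
        strategy: str = "equal_frequency",
        outcome_bounds: tuple[float, float] = (0.25, 0.50),
        discretize_outcome: bool = True,
        threshold: float = PRIMARY_THRESHOLD,
    ) -> None:
        self.n_bins = n_bins
        self.strategy = strategy
        self.outcome_bounds = outcome_bounds
        self.discretize_outcome = discretize_outcome
        self.threshold = threshold

    def _scheme(self) -> DiscretizationScheme:
        return DiscretizationScheme(
            outcome_bounds=tuple(self.outcome_bounds),
            feature_strategy=self.strategy,
            n_feature_bins=self.n_bins,
        )

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        scheme = self._scheme()
        s = bin_outcome(y.astype(float), scheme.outcome_bounds) \
            if self.discretize_outcome else _as_codes(y)
        raw: dict[str, tuple[float, int]] = {}
        y_ok = pd.Series(s, index=X.index).notna()
        for f in X.columns:
            mask = X[f].notna() & y_ok
            a = bin_feature(X.loc[mask, f], scheme, feature=f)
            raw[str(f)] = (information_gain(np.asarray(s)[mask.to_numpy()], a),
                           int(mask.sum()))
        self.feature_names_in_ = np.asarray([str(c) for c in X.columns], dtype=object)
        self.n_features_in_ = len(raw)
        self.ranking_ = _normalize(raw)
        self.raw_ig_ = np.array([raw[f][0] for f in self.feature_names_in_])
        total = self.raw_ig_.sum()
        self.weights_ = self.raw_ig_ / total if total > 0 else np.zeros_like(self.raw_ig_)
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "weights_")
        return self.weights_ > self.threshold

    def transform(self, X):
        check_is_fitted(self, "weights_")
        X = pd.DataFrame(X)
        keep = [f for f, s in zip(self.feature_names_in_, self.get_support()) if s]
        return X[keep]
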