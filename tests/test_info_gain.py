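import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from smileig.data_model import Cohort
from smileig.discretize import DiscretizationScheme
from smileig.info_gain import (
    FeatureWeight, InformationGainRanker, conditional_entropy, entropy,
    information_gain, information_gain_from_counts, rank_features,
    secondary_selection, select_common,
)

labels_st = st.lists(st.integers(0, 3), min_size=2, max_size=60)


# ---------------------------------------------------------------- entropy

def test_entropy_closed_forms():
    assert entropy([0, 1, 2]) == pytest.approx(math.log2(3), abs=1e-12)
    assert entropy([7, 7, 7, 7]) == 0.0
    assert entropy([0, 0, 1, 2]) == pytest.approx(1.5, abs=1e-12)


def test_entropy_rejects_empty():
    with pytest.raises(ValueError):
        entropy([])


def test_conditional_entropy_examples():
    outcome = [0, 0, 1, 0, 1, 1]
    feature = ["a", "a", "a", "b", "b", "b"]
    # direct double-sum over the 2x2 count table
    assert conditional_entropy(outcome, feature) == pytest.approx(0.9182958, abs=1e-6)
    assert conditional_entropy(outcome, outcome) == 0.0
    assert conditional_entropy(outcome, ["z"] * 6) == pytest.approx(
        entropy(outcome), abs=1e-12)


def test_information_gain_examples():
    outcome = [0, 0, 1, 0, 1, 1]
    feature = ["a", "a", "a", "b", "b", "b"]
    assert information_gain(outcome, feature) == pytest.approx(
        1.0 - 0.9182958, abs=1e-6)
    assert information_gain(outcome, [1] * 6) == 0.0
    assert information_gain(outcome, outcome) == pytest.approx(
        entropy(outcome), abs=1e-12)


def test_information_gain_needs_two_cases():
    with pytest.raises(ValueError):
        information_gain([0], [1])
    with pytest.raises(ValueError):
        information_gain([0, 1], [0, 1, 2])


@settings(max_examples=120, derandomize=True)
@given(s=labels_st, a=labels_st)
def test_ig_bounds_and_symmetric_invariances(s, a):
    n = min(len(s), len(a))
    s, a = np.asarray(s[:n]), np.asarray(a[:n])
    ig = information_gain(s, a)
    assert 0.0 <= ig <= min(entropy(s), entropy(a)) + 1e-12
    # permutation of samples
    perm = np.argsort(np.sin(np.arange(n) * 12.9898))
    assert information_gain(s[perm], a[perm]) == pytest.approx(ig, abs=1e-12)
    # relabeling of classes and bins
    assert information_gain(5 - s, 7 - a) == pytest.approx(ig, abs=1e-12)
    # duplicating the whole dataset
    assert information_gain(np.tile(s, 2), np.tile(a, 2)) == pytest.approx(
        ig, abs=1e-12)
    assert entropy(np.tile(s, 3)) == pytest.approx(entropy(s), abs=1e-12)


def test_ig_from_counts_batched_matches_scalar():
    rng = np.random.default_rng(3)
    tables = rng.integers(0, 4, size=(50, 3, 4)).astype(float)
    tables[0] = 1.0  # guard: ensure at least n>=2 everywhere
    keep = tables.sum(axis=(1, 2)) >= 2
    tables = tables[keep]
    batch = information_gain_from_counts(tables)
    for i, t in enumerate(tables):
        assert batch[i] == pytest.approx(
            information_gain_from_counts(t), abs=1e-14)


# ---------------------------------------------------------------- ranking

def _toy_cohort(n=400, seed=0) -> Cohort:
    rng = np.random.default_rng(seed)
    strong = rng.normal(size=n)
    weak = rng.normal(size=n)
    post = np.where(strong > 0, 0.1, 0.7) + rng.normal(0, 0.05, n)
    df = pd.DataFrame({
        "strong": strong, "weak": weak,
        "noise": rng.normal(size=n),
        "post_se_3m": post,
    })
    return Cohort(df=df, feature_names=("strong", "weak", "noise"))


def test_rank_features_weights_sum_to_one_and_order():
    ranking = rank_features(_toy_cohort())
    assert sum(fw.weight for fw in ranking) == pytest.approx(1.0, abs=1e-12)
    weights = [fw.weight for fw in ranking]
    raws = [fw.raw_ig for fw in ranking]
    assert weights == sorted(weights, reverse=True)
    assert raws == sorted(raws, reverse=True)
    assert ranking[0].feature == "strong"


def test_rank_features_normalization_example():
    # raw gains [0.2, 0.2, 0.1] -> weights [0.4, 0.4, 0.2]
    raw = {"a": (0.2, 10), "b": (0.2, 10), "c": (0.1, 10)}
    from smileig.info_gain import _normalize
    out = _normalize(raw)
    assert [round(fw.weight, 12) for fw in out] == [0.4, 0.4, 0.2]
    assert [fw.feature for fw in out] == ["a", "b", "c"]  # name tie-break


def test_rank_features_step_function_of_pre_se_tops():
    rng = np.random.default_rng(1)
    n = 500
    pre_se = rng.uniform(-8, -1, n)
    df = pd.DataFrame({
        "pre_se": pre_se,
        "other": rng.normal(size=n),
        "post_se_3m": np.where(pre_se < -5, 0.6, 0.0),
    })
    cohort = Cohort(df=df, feature_names=("pre_se", "other"))
    assert rank_features(cohort)[0].feature == "pre_se"


def test_all_zero_gains_flagged_not_divided():
    df = pd.DataFrame({
        "x": [1.0, 2.0, 3.0, 4.0] * 5,
        "post_se_3m": [0.0] * 20,     # constant outcome: H(S) = 0
    })
    cohort = Cohort(df=df, feature_names=("x",))
    with pytest.warns(UserWarning, match="zero"):
        ranking = rank_features(cohort)
    assert all(fw.weight == 0.0 for fw in ranking)


def test_pairwise_deletion_counts():
    df = pd.DataFrame({
        "x": [1.0, 2.0, 3.0, 4.0, np.nan, 6.0] * 4,
        "y": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0] * 4,
        "post_se_3m": [0.0, 0.3, 0.6, 0.0, 0.3, 0.6] * 4,
    })
    cohort = Cohort(df=df, feature_names=("x", "y"))
    by_name = {fw.feature: fw for fw in rank_features(cohort)}
    assert by_name["x"].n_used == 20
    assert by_name["y"].n_used == 24


# ---------------------------------------------------------------- selection

def _fw(feature, weight):
    return FeatureWeight(feature, weight, weight, 100)


def test_select_common_nine_feature_overlap():
    nine = ["pre_k1", "pre_km", "rst", "max_lenticule", "pre_cct",
            "pre_sd", "pre_se", "pre_udva", "nomogram"]
    rankings = {}
    for center, extra in (("A", "age"), ("B", "pre_iop"), ("C", "optical_zone")):
        ranking = [_fw(f, 0.08) for f in nine] + [_fw(extra, 0.06),
                                                  _fw("sex", 0.01)]
        rankings[center] = ranking
    result = select_common(rankings, threshold=0.05)
    assert result.common_features == set(nine)
    assert result.per_center_selected["A"] == set(nine) | {"age"}


def test_select_common_single_center_and_disjoint():
    one = select_common({"A": [_fw("x", 0.2), _fw("y", 0.01)]}, 0.05)
    assert one.common_features == {"x"}
    disjoint = select_common(
        {"A": [_fw("x", 0.2)], "B": [_fw("y", 0.2)]}, 0.05)
    assert disjoint.common_features == set()


def test_select_common_threshold_is_strict():
    result = select_common({"A": [_fw("x", 0.05), _fw("y", 0.0500001)]}, 0.05)
    assert result.common_features == {"y"}


def test_secondary_singleton_weight_is_one(small_cohort):
    result = secondary_selection({"A": small_cohort}, subset=["pre_se"],
                                 threshold=0.10)
    ranking = result.per_center_rankings["A"]
    assert len(ranking) == 1 and ranking[0].weight == pytest.approx(1.0)


def test_secondary_weights_grow_when_subset_shrinks(small_cohort):
    full = {fw.feature: fw for fw in rank_features(small_cohort)}
    subset = ["pre_se", "pre_km", "pre_cct", "rst"]
    result = secondary_selection({"A": small_cohort}, subset=subset)
    for fw in result.per_center_rankings["A"]:
        assert fw.weight >= full[fw.feature].weight - 1e-12
        assert fw.raw_ig == pytest.approx(full[fw.feature].raw_ig, abs=1e-12)


# ---------------------------------------------------------------- estimator

def test_ranker_estimator_fit_transform(small_cohort):
    X = small_cohort.df[list(small_cohort.feature_names)]
    y = small_cohort.df["post_se_3m"]
    ranker = InformationGainRanker(threshold=0.05).fit(X, y)
    assert ranker.weights_.sum() == pytest.approx(1.0, abs=1e-12)
    assert len(ranker.ranking_) == len(small_cohort.feature_names)
    kept = ranker.transform(X)
    assert set(kept.columns) == {
        f for f, w in zip(ranker.feature_names_in_, ranker.weights_)
        if w > 0.05}


def test_ranker_is_sklearn_compatible(small_cohort):
    from sklearn.base import clone
    ranker = InformationGainRanker(n_bins=5, threshold=0.02)
    cloned = clone(ranker)
    assert cloned.get_params()["n_bins"] == 5
    X = small_cohort.df[["pre_se", "pre_km", "age"]]
    y = small_cohort.df["post_se_3m"].to_numpy()
    weights = cloned.fit(X, y).weights_
    assert weights.shape == (3,)


def test_ranker_agrees_with_rank_features(small_cohort):
    scheme = DiscretizationScheme()
    by_fn = {fw.feature: fw.raw_ig for fw in rank_features(small_cohort, scheme)}
    X = small_cohort.df[list(small_cohort.feature_names)]
    y = small_cohort.df["post_se_3m"]
    ranker = InformationGainRanker().fit(X, y)
    for f, ig in zip(ranker.feature_names_in_, ranker.raw_ig_):
        assert ig == pytest.approx(by_fn[f], abs=1e-12)
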