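"""Triad classification, survival estimation and group statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from immunotriad import ImmuneCorrelates
from immunotriad.outcome import (
    group_compare,
    immune_group_clustering,
    km_estimate,
    logrank,
    triad_status,
)


@pytest.mark.parametrize(
    "itype, ab, spread, expected",
    [
        ("polyF_triple", True, True, True),
        ("polyF_triple", True, False, False),
        ("polyF_double", True, True, False),
        ("none", False, False, False),
    ],
)
def test_triad_conjunction(itype, ab, spread, expected):
    assert triad_status(itype, ab, spread) is expected


def test_triad_missing_component_is_undetermined():
    with pytest.raises(ValueError):
        triad_status("polyF_triple", None, True)


def test_km_hand_computed_product_limit():
    """times (2,4,6,8), all events: S steps 0.75/0.50/0.25/0, median 4."""
    curve = km_estimate([2, 4, 6, 8], [1, 1, 1, 1])
    steps = dict(zip(curve.timeline, curve.survival))
    assert steps[2.0] == pytest.approx(0.75)
    assert steps[4.0] == pytest.approx(0.50)
    assert steps[6.0] == pytest.approx(0.25)
    assert steps[8.0] == pytest.approx(0.0)
    assert curve.median_months == pytest.approx(4.0)


def test_km_all_censored_median_undefined():
    curve = km_estimate([3, 5, 9], [0, 0, 0])
    assert np.allclose(curve.survival, 1.0)
    assert math.isinf(curve.median_months)


def test_km_without_censoring_equals_empirical_survival():
    rng = np.random.default_rng(3)
    t = rng.exponential(10, size=200)
    curve = km_estimate(t, np.ones_like(t))
    for time, s in zip(curve.timeline, curve.survival):
        if time == 0:
            continue
        assert s == pytest.approx((t > time).mean(), abs=1e-12)


def test_logrank_identical_groups_null():
    t = [2, 4, 6, 8, 12]
    e = [1, 1, 0, 1, 1]
    stat, p = logrank(t, e, t, e)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_no_events_statistic_zero():
    assert logrank([1, 2], [0, 0], [3, 4], [0, 0]) == (0.0, 1.0)


def test_logrank_symmetric_and_nonnegative():
    rng = np.random.default_rng(5)
    ta, tb = rng.exponential(10, 50), rng.exponential(5, 50)
    ea = eb = np.ones(50)
    s1, p1 = logrank(ta, ea, tb, eb)
    s2, p2 = logrank(tb, eb, ta, ea)
    assert s1 == pytest.approx(s2)
    assert p1 == pytest.approx(p2)
    assert s1 >= 0


def test_logrank_power_on_separated_hazards():
    rng = np.random.default_rng(6)
    ta = rng.exponential(4, 200)  # hazard ratio 4
    tb = rng.exponential(1, 200)
    _, p = logrank(ta, np.ones(200), tb, np.ones(200))
    assert p < 1e-10


def test_group_compare_identical_continuous():
    x = list(range(10))
    u, p = group_compare(x, x)
    assert p > 0.9


def test_group_compare_separated_matches_exact_permutation_floor():
    """Fully separated n=10 vs n=10: two-sided Mann-Whitney p equals 2/C(20,10)."""
    a = np.arange(10)
    b = np.arange(100, 110)
    _, p = group_compare(a, b)
    expected = 2.0 / math.comb(20, 10)
    assert p == pytest.approx(expected, rel=1e-9)


def test_group_compare_categorical_printed_counts():
    """Concurrent Th1 among Ab+ (30/31) vs Ab- (4/19): Fisher p far below 0.001."""
    stat, p = group_compare((30, 31), (4, 19), kind="categorical")
    assert 30 / 31 == pytest.approx(0.968, abs=5e-4)
    assert 4 / 19 == pytest.approx(0.211, abs=5e-4)
    assert p < 0.001


def test_group_compare_chi2_for_large_tables():
    stat, p = group_compare((50, 100), (30, 100), kind="categorical")
    from scipy import stats as ss

    expected, pexp, _, _ = ss.chi2_contingency([[50, 50], [30, 70]], correction=False)
    assert stat == pytest.approx(expected)
    assert p == pytest.approx(pexp)


def test_clustering_recovers_separated_blocks():
    block_a = pd.DataFrame({"x": [0.0] * 8, "y": [1.0] * 8, "z": np.arange(8) * 0.01})
    block_b = pd.DataFrame({"x": [10.0] * 8, "y": [9.0] * 8, "z": np.arange(8) * 0.01})
    features = pd.concat([block_a, block_b], ignore_index=True)
    _, labels = immune_group_clustering(features, k=2, seed=0)
    assert labels.iloc[:8].nunique() == 1
    assert labels.iloc[8:].nunique() == 1
    assert labels.iloc[0] != labels.iloc[8]


def test_clustering_rejects_single_patient_and_drops_constants():
    with pytest.raises(ValueError):
        immune_group_clustering(pd.DataFrame({"x": [1.0]}), k=2)
    features = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "const": [5.0] * 4})
    with pytest.warns(UserWarning, match="constant"):
        immune_group_clustering(features, k=2, seed=0)


def test_clustering_deterministic_given_seed():
    rng = np.random.default_rng(8)
    features = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
    _, l1 = immune_group_clustering(features, k=3, seed=42)
    _, l2 = immune_group_clustering(features, k=3, seed=42)
    assert (l1 == l2).all()


def test_triad_cocluster_in_synthetic_cohort(cohort):
    """Triad patients land in the same k-means cluster for most seeds."""
    results = ImmuneCorrelates.from_tables(cohort).fit()
    tab = results.patient_table.dropna(subset=["triad"]).set_index("patient_id")
    # default feature encoding: continuous where available, binary otherwise
    features = pd.DataFrame(
        {
            "spots": tab["max_specific_spots"].fillna(0.0),
            "triple": (tab["immunotype"] == "polyF_triple").astype(float),
            "ab": tab["ab_positive"].fillna(False).astype(float),
            "spreading": tab["spreading_positive"].fillna(False).astype(float),
        }
    )
    triad_ids = tab.index[tab["triad"].astype(bool)]
    assert len(triad_ids) >= 2
    together = 0
    n_runs = 20
    for seed in range(n_runs):
        _, labels = immune_group_clustering(features, k=4, seed=seed)
        together += labels.loc[triad_ids].nunique() == 1
    assert together / n_runs >= 0.95


def test_model_triad_matches_brute_force_conjunction(cohort):
    results = ImmuneCorrelates.from_tables(cohort).fit()
    tab = results.patient_table
    brute = (
        (tab["immunotype"] == "polyF_triple")
        & tab["ab_positive"].fillna(False).astype(bool)
        & tab["spreading_positive"].fillna(False).astype(bool)
    ).sum()
    assert results.triad_count() == int(brute)


def test_model_summary_mentions_key_quantities(cohort):
    results = ImmuneCorrelates.from_tables(cohort).fit()
    text = results.summary()
    assert "immune triad" in text
    assert "log-rank" in text
    assert "exploratory" in text
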