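"""Random-subgroup permutation test for treatment associations."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sfpanel import (
    SubgroupPermutationTest,
    load_patient_table,
    scan_treatment_labels,
    subgroup_permutation_test,
)
from sfpanel.metadata import records_to_frame


def brute_force_subgroup_p(scores, k, observed):
    """Independent oracle: enumerate every size-k subgroup."""
    scores = np.asarray(scores, float)
    n = scores.size
    hits = total = 0
    for idx in itertools.combinations(range(n), k):
        sub = scores[list(idx)].mean()
        rest = np.delete(scores, list(idx)).mean()
        total += 1
        if abs(sub - rest) >= observed - 1e-12:
            hits += 1
    return hits / total


def test_identical_scores_give_p_one():
    model = SubgroupPermutationTest([2.0] * 6, [True, True, False, False, False, False])
    res = model.fit(seed=0)
    assert res.observed_statistic == 0.0
    assert res.p_value == 1.0


def test_cohort_of_three_matches_hand_enumeration():
    scores = [1.0, 2.0, 6.0]
    model = SubgroupPermutationTest(scores, [False, False, True])
    res = model.fit(seed=0)
    assert res.method == "exhaustive"
    # subgroups {1}, {2}, {6}: |diffs| = 3, 1.5, 4.5; only 4.5 >= 4.5
    assert res.observed_statistic == pytest.approx(4.5)
    assert res.p_value == pytest.approx(1 / 3)
    assert res.p_value == pytest.approx(
        brute_force_subgroup_p(scores, 1, res.observed_statistic)
    )


def test_montecarlo_converges_to_enumeration():
    rng = np.random.default_rng(7)
    scores = rng.normal(0, 1, 12)
    mask = np.zeros(12, bool)
    mask[:4] = True
    exact = SubgroupPermutationTest(scores, mask).fit().p_value
    mc = SubgroupPermutationTest(scores, mask).fit(
        n_permutations=30_000, seed=1, exhaustive_limit=1
    )
    assert mc.method == "monte-carlo"
    assert mc.p_value == pytest.approx(exact, abs=0.01)


def test_deterministic_under_seed_and_order_invariant():
    rng = np.random.default_rng(8)
    scores = rng.normal(0, 1, 40)
    mask = np.zeros(40, bool)
    mask[:5] = True
    a = SubgroupPermutationTest(scores, mask).fit(seed=3)
    b = SubgroupPermutationTest(scores, mask).fit(seed=3)
    assert a == b
    order = rng.permutation(40)
    c = SubgroupPermutationTest(scores[order], mask[order]).fit(seed=3)
    assert c.observed_statistic == pytest.approx(a.observed_statistic)


def test_p_never_zero_and_bounded():
    scores = np.concatenate([np.zeros(30), np.full(5, 100.0)])
    mask = np.zeros(35, bool)
    mask[30:] = True
    res = SubgroupPermutationTest(scores, mask).fit(
        n_permutations=500, seed=0, exhaustive_limit=1
    )
    assert 1 / 501 <= res.p_value <= 1.0


def test_empty_or_full_subgroup_rejected():
    with pytest.raises(ValueError):
        SubgroupPermutationTest([1.0, 2.0], [False, False])
    with pytest.raises(ValueError):
        SubgroupPermutationTest([1.0, 2.0], [True, True])
    with pytest.raises(ValueError):
        SubgroupPermutationTest([1.0, 2.0, 3.0], [True, False, False]).fit(
            n_permutations=0
        )


def _patient_profiles(records, rng):
    frame = records_to_frame(records)
    return pd.DataFrame(
        {
            "sample_id": frame["patient_id"],
            "subject_id": frame["patient_id"],
            "group": "patient",
            "composite_score": rng.normal(1.0, 0.2, len(frame)),
        }
    )


def test_treatment_label_join_on_bundled_table():
    records = load_patient_table()
    profiles = _patient_profiles(records, np.random.default_rng(0))
    model = SubgroupPermutationTest.from_treatment_label(profiles, records, "Avastin")
    res = model.fit(n_permutations=1000, seed=5)
    assert res.n_subgroup == 3
    assert res.n_total == 31
    # C(31, 3) = 4495 subgroups, so the auto-switch enumerates exactly
    assert res.method == "exhaustive"
    assert res.n_draws == 4495


def test_scan_labels_reports_holm(default_profiles):
    records = load_patient_table()
    profiles = _patient_profiles(records, np.random.default_rng(1))
    table = scan_treatment_labels(profiles, records, n_permutations=500, seed=2)
    assert "avastin" in set(table["label"])
    assert (table["p_holm"] >= table["p_raw"] - 1e-15).all()
    assert (table["n_subgroup"] < table["n_total"]).all()


def test_null_calibration_of_subgroup_test():
    """Random treatment assignment: p approximately uniform, level ~ alpha."""
    rng = np.random.default_rng(10)
    ps = []
    for _ in range(300):
        scores = rng.normal(0, 1, 31)
        mask = np.zeros(31, bool)
        mask[rng.choice(31, 3, replace=False)] = True
        res = SubgroupPermutationTest(scores, mask).fit(
            n_permutations=199, seed=int(rng.integers(2**31)), exhaustive_limit=1
        )
        ps.append(res.p_value)
    rate = np.mean(np.array(ps) <= 0.05)
    assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / 300)
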