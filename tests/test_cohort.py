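"""Two-group permutation comparison, age stratification, per-target table."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from sfpanel import (
    GroupComparison,
    PANEL_TARGETS,
    SimulationConfig,
    compare_groups,
    per_target_summary,
    quantify_profiles,
    simulate_ct_dataset,
    stratify_by_age,
)


def _profiles(healthy_scores, patient_scores):
    scores = list(healthy_scores) + list(patient_scores)
    groups = ["healthy"] * len(healthy_scores) + ["patient"] * len(patient_scores)
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(scores))],
            "group": groups,
            "composite_score": scores,
        }
    )


def brute_force_two_sided_p(x, y):
    """Independent oracle: enumerate every label assignment."""
    pooled = np.array(list(x) + list(y), dtype=float)
    observed = abs(np.mean(y) - np.mean(x))
    hits = total = 0
    for idx in itertools.combinations(range(pooled.size), len(x)):
        mask = np.zeros(pooled.size, bool)
        mask[list(idx)] = True
        diff = abs(pooled[~mask].mean() - pooled[mask].mean())
        total += 1
        if diff >= observed - 1e-12:
            hits += 1
    return hits / total


def test_identical_groups_give_p_one():
    res = compare_groups(_profiles([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
    assert res.p_value == 1.0
    assert res.direction == "none"


def test_exhaustive_matches_brute_force_oracle():
    x, y = [0.0, 0.0, 0.0], [10.0, 10.0, 10.0]
    res = compare_groups(_profiles(x, y))
    assert res.method == "exhaustive"
    assert res.p_value == pytest.approx(brute_force_two_sided_p(x, y))
    # C(6,3) = 20 assignments; only the two extreme splits reach |10|
    assert res.p_value == pytest.approx(2 / 20)


def test_exhaustive_matches_brute_force_on_irregular_values():
    x, y = [1.2, 3.4, 2.2, 0.1], [4.5, 6.1, 5.0]
    res = compare_groups(_profiles(x, y))
    assert res.method == "exhaustive"
    assert res.p_value == pytest.approx(brute_force_two_sided_p(x, y))


def test_montecarlo_close_to_exhaustive():
    rng = np.random.default_rng(0)
    x, y = rng.normal(0, 1, 6), rng.normal(1.0, 1, 5)
    exact = compare_groups(_profiles(x, y)).p_value
    mc = compare_groups(
        _profiles(x, y), n_permutations=20_000, seed=1, exhaustive_limit=1
    )
    assert mc.method == "permutation"
    assert mc.p_value == pytest.approx(exact, abs=0.02)


def test_order_invariance_and_group_swap_flips_direction():
    rng = np.random.default_rng(3)
    x, y = rng.normal(0, 1, 8), rng.normal(0.8, 1, 7)
    base = compare_groups(_profiles(x, y))
    shuffled = _profiles(x, y).sample(frac=1.0, random_state=1)
    assert compare_groups(shuffled).p_value == pytest.approx(base.p_value)
    swapped = compare_groups(_profiles(y, x))
    assert swapped.p_value == pytest.approx(base.p_value)
    assert {base.direction, swapped.direction} == {
        "higher_in_patients", "lower_in_patients",
    }


def test_p_bounds_for_montecarlo():
    rng = np.random.default_rng(4)
    x, y = rng.normal(0, 1, 30), rng.normal(3, 1, 30)
    res = compare_groups(_profiles(x, y), n_permutations=99, seed=0)
    assert 1 / 100 <= res.p_value <= 1.0


def test_welch_option_agrees_with_scipy():
    from scipy import stats

    rng = np.random.default_rng(5)
    x, y = rng.normal(0, 1, 12), rng.normal(1, 2, 9)
    res = compare_groups(_profiles(x, y), method="welch")
    expected = stats.ttest_ind(y, x, equal_var=False)
    assert res.p_value == pytest.approx(expected.pvalue)


def test_degenerate_group_errors():
    with pytest.raises(ValueError):
        compare_groups(_profiles([1.0, 2.0], [3.0]))


def test_stratify_partition_and_median_balance():
    profiles = pd.DataFrame(
        {"age": [30, 40, 60, 70], "group": ["healthy"] * 4, "composite_score": 1.0}
    )
    strata = stratify_by_age(profiles, cut=50)
    assert strata.young["age"].tolist() == [30, 40]
    assert strata.old["age"].tolist() == [60, 70]

    # tie-free ages: a pooled-median cut makes the strata sizes differ by <= 1
    rng = np.random.default_rng(6)
    big = pd.DataFrame({"age": rng.uniform(20, 80, 41), "composite_score": 1.0})
    auto = stratify_by_age(big)
    assert abs(len(auto.young) - len(auto.old)) <= 1


def test_stratify_all_below_cut_degenerates_cleanly():
    profiles = _profiles([1.0, 2.0], [3.0, 4.0])
    profiles["age"] = [30, 31, 32, 33]
    strata = stratify_by_age(profiles, cut=90)
    assert strata.old.empty
    with pytest.raises(ValueError):
        compare_groups(strata.old)


def test_per_target_summary_signs_and_holm(default_profiles):
    table = per_target_summary(default_profiles, n_permutations=499, seed=0)
    assert set(table["endpoint"]) == set(PANEL_TARGETS) | {"composite"}
    signs = table.set_index("endpoint")["direction"]
    assert signs["HNRNPA2B1"] == "lower_in_patients"
    for t in PANEL_TARGETS:
        if t != "HNRNPA2B1":
            assert signs[t] == "higher_in_patients"
    assert (table["p_holm"] >= table["p_raw"] - 1e-15).all()


def test_power_monotone_in_effect_size():
    """Larger disease effects never make the composite test less powerful."""
    rejections = []
    for scale in (0.0, 0.5, 1.0):
        hits = 0
        for rep in range(30):
            beta = {t: scale * b for t, b in
                    zip(PANEL_TARGETS, [-0.7, 0.4, -0.7, -0.7, -0.7, -0.7, -0.7])}
            cfg = SimulationConfig(
                n_healthy=15, n_patients=15, beta=beta, seed=9000 + rep
            )
            profiles = quantify_profiles(simulate_ct_dataset(cfg))
            p = compare_groups(profiles, n_permutations=199, seed=rep).p_value
            hits += p <= 0.05
        rejections.append(hits / 30)
    assert rejections[0] <= rejections[1] + 0.15
    assert rejections[1] <= rejections[2] + 0.15
    assert rejections[2] > rejections[0]


def test_composite_rejects_at_alpha_01_in_majority_of_seeds():
    hits = 0
    for seed in range(15):
        profiles = quantify_profiles(
            simulate_ct_dataset(SimulationConfig(seed=3000 + seed))
        )
        p = compare_groups(profiles, n_permutations=999, seed=seed).p_value
        hits += p <= 0.01
    assert hits > 15 / 2
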