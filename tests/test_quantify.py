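"""Comparative-Ct arithmetic, replicate aggregation and the composite score."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sfpanel import (
    PANEL_TARGETS,
    SimulationConfig,
    aggregate_replicates,
    composite_score,
    delta_ct,
    quantify_profiles,
    relative_expression,
    simulate_ct_dataset,
)
from sfpanel.quantify import UndetectedNormalizerError
from sfpanel.simulate import DEFAULT_MU


@pytest.mark.parametrize(
    "cts, expected_mean, expected_n",
    [
        ([25.1, 25.0, 24.9], 25.0, 3),
        ([30.0], 30.0, 1),
        ([24.8, 25.3, math.nan], 25.05, 2),  # undetected well skipped
    ],
)
def test_replicate_aggregation(cts, expected_mean, expected_n):
    mean, n = aggregate_replicates(cts)
    assert mean == pytest.approx(expected_mean)
    assert n == expected_n


def test_all_replicates_undetected_flags_target():
    mean, n = aggregate_replicates([math.nan, math.nan, math.nan])
    assert math.isnan(mean) and n == 0


def test_nonpositive_ct_rejected():
    with pytest.raises(ValueError):
        aggregate_replicates([25.0, -1.0])


@pytest.mark.parametrize(
    "ct_t, ct_n, expected", [(25, 25, 0.0), (27, 25, 2.0), (23.5, 25.0, -1.5)]
)
def test_delta_ct_arithmetic(ct_t, ct_n, expected):
    assert delta_ct(ct_t, ct_n) == pytest.approx(expected)


def test_delta_ct_undetected_normalizer_is_sample_failure():
    with pytest.raises(UndetectedNormalizerError):
        delta_ct(25.0, math.nan)


@pytest.mark.parametrize("dct, expected", [(0, 1.0), (2, 0.25), (-1, 2.0)])
def test_relative_expression_values(dct, expected):
    assert relative_expression(dct) == pytest.approx(expected)


@given(
    st.floats(-20, 20),
    st.floats(min_value=1e-6, max_value=10),
)
def test_relative_expression_strictly_decreasing(dct, step):
    assert relative_expression(dct) > relative_expression(dct + step)


@given(st.floats(-20, 20))
def test_delta_ct_roundtrip_through_log2(dct):
    assert -np.log2(relative_expression(dct)) == pytest.approx(dct, abs=1e-12)


def test_composite_score_examples():
    assert composite_score([1.0] * 7) == pytest.approx(7.0)
    assert composite_score([1, 0.25, 2, 1, 1, 0.5, 0.25]) == pytest.approx(6.0)


def test_composite_score_all_undetected_errors():
    with pytest.raises(ValueError):
        composite_score([math.nan] * 7)


def test_composite_score_strict_vs_rescale():
    values = dict(zip(PANEL_TARGETS, [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, math.nan]))
    assert math.isnan(composite_score(values, missing_policy="strict"))
    assert composite_score(values, missing_policy="rescale") == pytest.approx(7.0)


@given(st.permutations(list(range(7))))
def test_composite_score_order_invariant(perm):
    base = [1.0, 0.25, 2.0, 0.5, 4.0, 0.125, 1.5]
    shuffled = [base[i] for i in perm]
    assert composite_score(shuffled) == pytest.approx(composite_score(base))


def test_noise_free_pipeline_recovers_mu_exactly():
    """With all noise off, every healthy subject's rel_expr is 2**(-mu_g)."""
    cfg = SimulationConfig(
        n_healthy=4,
        n_patients=3,
        sigma_between=0.0,
        sigma_within=0.0,
        sigma_replicate=0.0,
        seed=0,
    )
    profiles = quantify_profiles(simulate_ct_dataset(cfg))
    healthy = profiles[profiles["group"] == "healthy"]
    patient = profiles[profiles["group"] == "patient"]
    for t in PANEL_TARGETS:
        np.testing.assert_allclose(
            healthy[f"delta_ct_{t}"], DEFAULT_MU[t], rtol=0, atol=1e-12
        )
        np.testing.assert_allclose(
            healthy[f"rel_expr_{t}"], 2.0 ** -DEFAULT_MU[t], rtol=0, atol=1e-12
        )
        beta = cfg.beta[t]
        np.testing.assert_allclose(
            patient[f"delta_ct_{t}"], DEFAULT_MU[t] + beta, rtol=0, atol=1e-12
        )


def test_samples_with_undetected_normalizer_are_dropped():
    ct = pd.DataFrame(
        {
            "sample_id": ["s1"] * 2 + ["s2"] * 2,
            "target": ["HNRNPA1", "PPIA"] * 2,
            "replicate": [1, 1, 1, 1],
            "ct": [27.0, 25.0, 27.0, math.nan],
        }
    )
    profiles = quantify_profiles(ct, missing_policy="rescale")
    assert profiles["sample_id"].tolist() == ["s1"]
    with pytest.raises(UndetectedNormalizerError):
        quantify_profiles(ct, on_missing_normalizer="raise")


def test_delta_ct_sum_score_option():
    cfg = SimulationConfig(
        n_healthy=2, n_patients=2,
        sigma_between=0.0, sigma_within=0.0, sigma_replicate=0.0, seed=0,
    )
    profiles = quantify_profiles(simulate_ct_dataset(cfg), score_scale="delta_ct")
    expected = sum(DEFAULT_MU.values())
    healthy = profiles[profiles["group"] == "healthy"]
    np.testing.assert_allclose(healthy["composite_score"], expected, atol=1e-12)
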