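"""Biotype exclusion, low-count filtering, presence calls, histogram."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sfpanel import (
    FilterConfig,
    abundance_histogram,
    apply_filters,
    call_present,
    exclude_biotypes,
    filter_low_counts,
)


def _table(biotypes, counts):
    counts = np.atleast_2d(np.asarray(counts).T).T
    df = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(len(biotypes))],
            "symbol": [f"G{i}" for i in range(len(biotypes))],
            "biotype": biotypes,
        }
    )
    for j in range(counts.shape[1]):
        df[f"s{j + 1}"] = counts[:, j]
    return df


def test_exclude_biotypes_direct_rule():
    table = _table(["snoRNA", "protein_coding"], [[5], [5]])
    out = exclude_biotypes(table)
    assert out["biotype"].tolist() == ["protein_coding"]


def test_exclude_biotypes_empty_set_is_identity():
    table = _table(["snoRNA", "protein_coding"], [[5], [5]])
    pd.testing.assert_frame_equal(exclude_biotypes(table, frozenset()), table)


def test_exclude_biotypes_missing_annotation_retained():
    table = _table(["snoRNA", None, ""], [[5], [5], [5]])
    out = exclude_biotypes(table)
    assert len(out) == 2  # only the annotated snoRNA gene is dropped


def test_constructed_excluded_fraction_matches():
    biotypes = ["rRNA"] * 20 + ["protein_coding"] * 80
    table = _table(biotypes, [[1]] * 100)
    out = exclude_biotypes(table)
    assert len(out) == 80


@pytest.mark.parametrize(
    "counts, min_total, kept",
    [([1, 1], 3, False), ([3, 0], 3, True), ([2, 1], 3, True), ([0, 0], 3, False)],
)
def test_low_count_boundary(counts, min_total, kept):
    table = _table(["protein_coding"], [[counts[0]], [counts[1]]][:1])
    table["s1"], table["s2"] = counts[0], counts[1]
    out = filter_low_counts(table, min_total)
    assert (len(out) == 1) is kept


def test_low_count_fixture_63_of_100_survive():
    rng = np.random.default_rng(0)
    low = rng.integers(0, 3, 37)  # row sums <= 2
    high = rng.integers(3, 100, 63)
    counts = np.concatenate([low, high])
    table = _table(["protein_coding"] * 100, counts.reshape(-1, 1))
    assert len(filter_low_counts(table, 3)) == 63


def test_presence_boundary_49_inclusive():
    table = _table(["protein_coding"] * 2, np.array([[49], [48]]))
    present = call_present(table, 49)
    assert list(present) == ["g0"]


def test_presence_threshold_zero_keeps_all():
    table = _table(["protein_coding"] * 3, np.array([[0], [5], [100]]))
    assert len(call_present(table, 0)) == 3


def test_constructed_fixture_present_set_size():
    n_present = 1254
    counts = np.concatenate([np.full(n_present, 60), np.full(500, 10)])
    table = _table(["protein_coding"] * counts.size, counts.reshape(-1, 1))
    assert len(call_present(table, 49)) == n_present


def test_present_set_monotone_in_threshold():
    rng = np.random.default_rng(1)
    table = _table(
        ["protein_coding"] * 200, rng.integers(0, 200, 200).reshape(-1, 1)
    )
    sizes = [len(call_present(table, t)) for t in (0, 10, 49, 100)]
    assert sizes == sorted(sizes, reverse=True)


@given(st.lists(st.integers(0, 10_000), min_size=1, max_size=60))
def test_histogram_mass_conserved(counts):
    table = _table(["protein_coding"] * len(counts), np.array(counts).reshape(-1, 1))
    hist = abundance_histogram(table, [0, 3, 49, 1000])
    assert hist.sum() == len(counts)


def test_histogram_known_occupancies():
    counts = np.array([0, 1, 2, 3, 48, 49, 50, 1000])
    table = _table(["protein_coding"] * 8, counts.reshape(-1, 1))
    hist = abundance_histogram(table, [0, 3, 49, 100])
    assert hist.tolist() == [3, 2, 3]  # [0,3): {0,1,2}; [3,49): {3,48}; rest folded


def test_histogram_unsorted_edges_error():
    table = _table(["protein_coding"], np.array([[5]]))
    with pytest.raises(ValueError):
        abundance_histogram(table, [0, 10, 5])


def test_filters_idempotent_and_ordered():
    rng = np.random.default_rng(2)
    biotypes = rng.choice(["snoRNA", "protein_coding", "lincRNA"], 300)
    counts = rng.integers(0, 120, 300).reshape(-1, 1)
    table = _table(biotypes, counts)
    config = FilterConfig()
    once, present_once, _ = apply_filters(table, config)
    twice, present_twice, _ = apply_filters(once, config)
    pd.testing.assert_frame_equal(once, twice)
    assert list(present_once) == list(present_twice)


def test_negative_or_fractional_counts_rejected():
    table = _table(["protein_coding"], np.array([[5]]))
    table["s1"] = [-1]
    with pytest.raises(ValueError):
        filter_low_counts(table)
    table["s1"] = [1.5]
    with pytest.raises(ValueError):
        filter_low_counts(table)
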