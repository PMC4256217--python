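"""Enrichment statistics: chi-square, exact binomial, circular
permutation, Fisher / gene-set scans, distribution comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from namgwas import (binomial_class_test, circular_permutation_test,
                     compare_distributions, gene_set_scan, gene_set_test,
                     overall_chisq)
from statsmodels.stats.multitest import multipletests


# ---- chi-square -----------------------------------------------------

def test_proportional_counts_give_zero_statistic():
    inp = {"a": 100, "b": 300, "c": 600}
    hits = {"a": 10, "b": 30, "c": 60}
    res = overall_chisq(inp, hits)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.pvalue == pytest.approx(1.0)


def test_low_expected_classes_are_dropped():
    inp = {"a": 490, "b": 9510, "rare": 100}
    hits = {"a": 30, "b": 450, "rare": 4}   # expected rare = 484*100/10100 = 4.79
    res = overall_chisq(inp, hits)
    assert res.dropped_classes == ["rare"]
    assert set(res.tested_classes) == {"a", "b"}


def test_statistic_matches_hand_computation():
    inp = {"a": 200, "b": 300, "c": 500}
    hits = {"a": 30, "b": 30, "c": 40}
    res = overall_chisq(inp, hits)
    exp = {c: 100 * inp[c] / 1000 for c in inp}
    by_hand = sum((hits[c] - exp[c]) ** 2 / exp[c] for c in inp)
    assert res.statistic == pytest.approx(by_hand, rel=1e-12)
    assert res.df == 2


def test_chisq_needs_two_surviving_classes():
    with pytest.raises(ValueError):
        overall_chisq({"a": 100, "b": 100}, {"a": 2, "b": 1})


# ---- exact binomial -------------------------------------------------

def _minlike_oracle(k, n, p0):
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    return pmf[pmf <= pmf[k] * (1 + 1e-12)].sum()


@given(n=st.integers(1, 20), frac=st.floats(0, 1), p0=st.floats(0.05, 0.95))
@settings(derandomize=True, deadline=None, max_examples=100)
def test_binomial_matches_enumeration_oracle(n, frac, p0):
    k = int(round(frac * n))
    assert binomial_class_test(k, n, p0) == pytest.approx(
        _minlike_oracle(k, n, p0), abs=1e-12)


def test_binomial_known_values():
    # symmetric tail: k=0, n=10, p0=0.5 -> both extreme outcomes
    assert binomial_class_test(0, 10, 0.5) == pytest.approx(2 / 1024, rel=1e-9)
    # the mode's point probability bounds every other: p = 1
    mode = int(np.floor(1001 * 0.242))
    assert binomial_class_test(mode, 1000, 0.242) == pytest.approx(1.0)


def test_binomial_swap_symmetry():
    k, n, p0 = 298, 970, 0.2
    assert binomial_class_test(k, n, p0) == pytest.approx(
        binomial_class_test(n - k, n, 1 - p0), rel=1e-9)


def test_binomial_validation():
    with pytest.raises(ValueError):
        binomial_class_test(5, 3, 0.5)
    with pytest.raises(ValueError):
        binomial_class_test(1, 3, 0.0)


# ---- circular permutation ------------------------------------------

def _hits(positions):
    return pd.DataFrame({"chrom": "1", "pos": np.asarray(positions)})


def test_everywhere_true_predicate_is_degenerate():
    res = circular_permutation_test(_hits([5, 50, 500]),
                                    lambda c, p: np.ones(len(p), bool),
                                    {"1": 1000}, n_perm=200, seed=1)
    assert res.degenerate
    assert res.observed == 3
    assert res.null_sd == 0.0


def test_rotation_preserves_count_and_spacing():
    pos = np.array([10, 40, 41, 900])
    L = 1000
    for off in (1, 13, 999):
        rot = np.sort((pos + off) % L)
        assert len(rot) == len(pos)
        gaps = np.sort(np.diff(np.concatenate([rot, [rot[0] + L]])))
        gaps0 = np.sort(np.diff(np.concatenate([np.sort(pos),
                                                [np.sort(pos)[0] + L]])))
        np.testing.assert_array_equal(gaps, gaps0)


def test_exhaustive_half_coverage_null_mean():
    """One hit, predicate true on exactly half the positions: the
    enumeration over all rotations averages one half."""
    L = 500
    pred = lambda c, p: np.asarray(p) < L // 2
    res = circular_permutation_test(_hits([123]), pred, {"1": L},
                                    exhaustive=True)
    assert res.null_mean == pytest.approx(0.5)
    assert len(res.null_counts) == L


def test_zero_length_chromosome_errors():
    with pytest.raises(ValueError, match="zero-length"):
        circular_permutation_test(_hits([1]), lambda c, p: p < 5, {"1": 0},
                                  n_perm=200)


# ---- gene-set tests -------------------------------------------------

def test_fisher_symmetric_table_is_one():
    _, p = gene_set_test(1, 2, 2, 4)
    assert p == pytest.approx(1.0)


def test_saturated_sets_give_p_one():
    p_b, p_f = gene_set_test(10, 10, 50, 50)
    assert p_b == pytest.approx(1.0)
    assert p_f == pytest.approx(1.0)


def test_fisher_matches_hypergeometric_enumeration():
    rng = np.random.default_rng(112)
    for _ in range(25):
        N = int(rng.integers(10, 101))
        n = int(rng.integers(1, N))
        K = int(rng.integers(1, N))
        k = int(rng.integers(max(0, K + n - N), min(n, K) + 1))
        _, p_f = gene_set_test(k, n, K, N)
        # enumeration: sum of hypergeometric masses no more likely than k's
        supp = np.arange(max(0, K + n - N), min(n, K) + 1)
        pmf = stats.hypergeom.pmf(supp, N, K, n)
        oracle = pmf[pmf <= pmf[supp == k][0] * (1 + 1e-9)].sum()
        assert p_f == pytest.approx(oracle, rel=1e-10, abs=1e-14)


def test_gene_set_scan_by_adjustment_properties():
    rng = np.random.default_rng(113)
    background = {f"g{i}" for i in range(400)}
    hit = set(rng.choice(sorted(background), 60, replace=False))
    sets = {f"s{j}": set(rng.choice(sorted(background),
                                    rng.integers(10, 80), replace=False))
            for j in range(12)}
    out = gene_set_scan(sets, hit, background)
    raw = out["p_fisher"].to_numpy()
    bh = multipletests(raw, method="fdr_bh")[1]
    assert (out["p_adjusted"].to_numpy() >= bh - 1e-12).all()
    assert (out["p_adjusted"].to_numpy() >= raw - 1e-12).all()
    # a single set needs no correction (BY factor c(1) = 1)
    one = gene_set_scan({"only": sets["s0"]}, hit, background)
    assert one["p_adjusted"].iloc[0] == pytest.approx(one["p_fisher"].iloc[0])
    # all-null p-values stay 1
    full = gene_set_scan({"a": background, "b": background}, hit, background)
    assert np.allclose(full["p_adjusted"], 1.0)


def test_gene_set_scan_validation():
    with pytest.raises(ValueError, match="background"):
        gene_set_scan({"s": {"g"}}, set(), set())
    with pytest.raises(ValueError, match="subset"):
        gene_set_scan({"s": {"g"}}, {"x"}, {"g"})


# ---- distribution comparison ---------------------------------------

def test_identical_samples_have_zero_ks_distance():
    a = np.arange(50.0)
    res = compare_distributions(a, a)
    assert res["ks_distance"] == 0.0
    assert res["p_ks"] == pytest.approx(1.0)


def test_shift_is_detected():
    rng = np.random.default_rng(114)
    a = rng.normal(size=1000)
    res = compare_distributions(a, a + 1.0)
    assert res["p_mannwhitney"] < 1e-10
    assert res["median_shift"] == pytest.approx(1.0, abs=0.2)


def test_comparison_is_symmetric():
    rng = np.random.default_rng(115)
    a, b = rng.normal(size=300), rng.normal(0.3, 1.2, size=400)
    r1 = compare_distributions(a, b)
    r2 = compare_distributions(b, a)
    assert r1["p_mannwhitney"] == pytest.approx(r2["p_mannwhitney"], rel=1e-9)
    assert r1["p_ks"] == pytest.approx(r2["p_ks"], rel=1e-9)
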