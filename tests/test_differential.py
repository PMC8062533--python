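import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from atacmotif.differential import (
    DifferentialAccessibility,
    bh_adjust,
    classify_acs,
    equalize_counts,
    estimate_common_dispersion,
    log2_fold_change,
    nb_exact_test,
    tmm_factors,
)
from atacmotif.simulate import SyntheticTruth, simulate_counts


def _null_counts(n_acs, dispersion, seed, mean=100.0):
    truth = SyntheticTruth(seed=0, acs_ids=[f"a{i}" for i in range(n_acs)],
                           acs_log2fc_true=[0.0] * n_acs)
    return simulate_counts(truth, 3, seed=seed, dispersion=dispersion,
                           mean_count=mean)


def naive_tmm(yk, yr):
    """Oracle: spreadsheet-style trimmed weighted mean of M-values."""
    nk, nr = yk.sum(), yr.sum()
    keep = (yk > 0) & (yr > 0)
    yk, yr = yk[keep], yr[keep]
    m = np.log2((yk / nk) / (yr / nr))
    a = 0.5 * np.log2((yk / nk) * (yr / nr))
    w = 1.0 / ((nk - yk) / (nk * yk) + (nr - yr) / (nr * yr))
    m_lo, m_hi = np.quantile(m, [0.3, 0.7])
    a_lo, a_hi = np.quantile(a, [0.05, 0.95])
    sel = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
    return 2 ** (np.sum(w[sel] * m[sel]) / np.sum(w[sel]))


class TestTmm:
    def test_identical_columns(self):
        y = pd.DataFrame({"a": [10, 20, 30, 5], "b": [10, 20, 30, 5]})
        np.testing.assert_allclose(tmm_factors(y), [1.0, 1.0], atol=1e-12)

    def test_pure_library_size_difference(self):
        y = pd.DataFrame({"a": [10, 20, 30, 5], "b": [20, 40, 60, 10]})
        np.testing.assert_allclose(tmm_factors(y), [1.0, 1.0], atol=1e-9)

    def test_matches_naive_computation(self):
        rng = np.random.default_rng(5)
        yk = rng.integers(5, 500, 40).astype(float)
        yr = rng.integers(5, 500, 40).astype(float)
        f = tmm_factors(pd.DataFrame({"r": yr, "k": yk}), ref_sample="r")
        expected = naive_tmm(yk, yr)
        # factors are rescaled to geometric mean 1: ratio k/r is preserved
        assert f[1] / f[0] == pytest.approx(expected, rel=1e-9)

    def test_all_zero_sample_rejected(self):
        y = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(y)


class TestDispersion:
    def test_poisson_counts_near_zero(self):
        counts = _null_counts(2000, 0.0, seed=21)
        phi = estimate_common_dispersion(counts, counts.attrs["groups"])
        assert phi <= 0.02

    def test_recovers_moderate_dispersion(self):
        counts = _null_counts(2000, 0.4, seed=22)
        phi = estimate_common_dispersion(counts, counts.attrs["groups"])
        assert 0.3 <= phi <= 0.5

    def test_exact_replicates_hit_lower_bound(self):
        y = pd.DataFrame({"a": [50] * 20, "b": [50] * 20,
                          "c": [50] * 20, "d": [50] * 20})
        groups = {"a": "P10", "b": "P10", "c": "adult", "d": "adult"}
        phi = estimate_common_dispersion(y, groups)
        assert phi <= 2e-6


class TestExactTest:
    def test_all_zero_gives_one(self):
        p = nb_exact_test(np.zeros((3, 3)), np.zeros((3, 3)), 0.1)
        np.testing.assert_array_equal(p, 1.0)

    def test_balanced_mode_gives_one(self):
        p = nb_exact_test(np.array([[10, 10, 10]]), np.array([[10, 10, 10]]), 0.1)
        assert p[0] == pytest.approx(1.0)

    def test_extreme_split_closed_form(self):
        # 1v1, phi=0: conditional Binomial(30, 1/2), both tails of (30, 0)
        p = nb_exact_test(np.array([[30]]), np.array([[0]]), 0.0)
        assert p[0] == pytest.approx(2 * 0.5**30, rel=1e-9)

    def test_phi_zero_equals_conditional_binomial(self, rng):
        # n_a = 2, n_b = 1: split ~ Binomial(t, 2/3) at phi = 0
        for _ in range(20):
            a = rng.integers(0, 40, size=(1, 2))
            b = rng.integers(0, 40, size=(1, 1))
            t = int(a.sum() + b.sum())
            if t == 0:
                continue
            x = np.arange(t + 1)
            f = sps.binom.pmf(x, t, 2 / 3)
            expected = f[f <= f[int(a.sum())] * (1 + 1e-10)].sum()
            got = nb_exact_test(a, b, 0.0)[0]
            assert got == pytest.approx(expected, rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test(np.array([[-1]]), np.array([[1]]), 0.1)


class TestLog2FoldChange:
    def test_identical_group_means_zero(self):
        y = pd.DataFrame(np.full((5, 6), 40.0))
        groups = ["P10"] * 3 + ["adult"] * 3
        fc = log2_fold_change(y, np.ones(6), groups, "adult", "P10")
        np.testing.assert_allclose(fc, 0.0, atol=1e-12)

    def test_prior_augmented_ratio(self):
        # single sample per group, equal libraries: means 20 vs 5, prior 0.5
        y = pd.DataFrame({"p": [5, 95], "a": [20, 80]})
        fc = log2_fold_change(y, np.ones(2), ["P10", "adult"], "adult", "P10",
                              prior_count=0.5)
        assert fc[0] == pytest.approx(np.log2(20.5 / 5.5), rel=1e-9)

    def test_swapping_groups_negates(self, rng):
        y = pd.DataFrame(rng.integers(1, 200, (30, 6)).astype(float))
        groups = ["P10"] * 3 + ["adult"] * 3
        f = np.ones(6)
        fwd = log2_fold_change(y, f, groups, "adult", "P10")
        rev = log2_fold_change(y, f, groups, "P10", "adult")
        np.testing.assert_allclose(fwd, -rev, atol=1e-12)


class TestBhAdjust:
    def test_textbook_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_and_saturated(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=200))
    def test_matches_step_up_definition(self, pvals):
        p = np.asarray(pvals)
        n = len(p)
        order = np.argsort(p, kind="stable")
        brute = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            running = min(running, p[order[rank - 1]] * n / rank)
            brute[order[rank - 1]] = running
        np.testing.assert_allclose(bh_adjust(p), brute, atol=1e-12)


class TestClassify:
    @pytest.mark.parametrize("log2fc,p,fdr,expected", [
        (1.2, 0.01, 0.10, "Up"),
        (-0.8, 0.03, 0.15, "Down"),
        (2.0, 0.20, 0.50, "Stable"),   # fails the p threshold
        (0.5, 0.01, 0.30, "Stable"),   # fails the FDR threshold
    ])
    def test_threshold_rules(self, log2fc, p, fdr, expected):
        table = pd.DataFrame({"log2fc": [log2fc], "p_value": [p], "fdr": [fdr]})
        assert classify_acs(table).iloc[0] == expected


class TestModelCalibrationAndPower:
    def test_null_type_one_error_and_uniformity(self):
        counts = _null_counts(2000, 0.1, seed=11)
        res = DifferentialAccessibility(counts, counts.attrs["groups"]).fit()
        rate = (res.table["p_value"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07
        assert sps.kstest(res.table["p_value"], "uniform").pvalue > 0.01

    def test_power_monotone_in_effect_size(self):
        # mostly-null study with sign-balanced effects (TMM's regime)
        rng = np.random.default_rng(31)
        effects = [0.5, 1.0, 2.0]
        n_null, n_per_effect = 2400, 200
        log2fc = np.zeros(n_null + len(effects) * n_per_effect)
        for i, e in enumerate(effects):
            lo = n_null + i * n_per_effect
            log2fc[lo:lo + n_per_effect] = e * rng.choice(
                [-1, 1], n_per_effect)
        truth = SyntheticTruth(seed=0,
                               acs_ids=[f"a{i}" for i in range(len(log2fc))],
                               acs_log2fc_true=list(log2fc))
        counts = simulate_counts(truth, 3, seed=31, dispersion=0.15)
        res = DifferentialAccessibility(counts, counts.attrs["groups"]).fit()
        p = res.table["p_value"].to_numpy()
        rates = [(p[np.abs(log2fc) == e] < 0.05).mean() for e in [0.0, *effects]]
        assert all(b >= a - 0.02 for a, b in zip(rates, rates[1:]))
        assert rates[-1] > 0.9

    def test_summary_reports_fractions(self):
        counts = _null_counts(200, 0.1, seed=41)
        res = DifferentialAccessibility(counts, counts.attrs["groups"]).fit()
        text = res.summary()
        assert "common dispersion" in text and "Stable" in text
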