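import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from mircross.de import (
    bh_adjust,
    consensus_test,
    effect_and_power,
    exclusive_rule,
    t_test_power,
    welch_t,
    welch_t_from_stats,
)
from mircross.io_formats import CountMatrix


class TestWelch:
    def test_reproduces_summary_statistics(self):
        # group summaries with known t (means 845/368, SDs 528/379, n 26/15)
        t, df, p = welch_t_from_stats(845, 528, 26, 368, 379, 15)
        assert t == pytest.approx(3.35, abs=0.005)
        t, _, _ = welch_t_from_stats(3687, 1407, 26, 2141, 1190, 15)
        assert t == pytest.approx(3.74, abs=0.005)

    def test_identical_groups_give_zero_t(self):
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])  # both variances zero
        t, _, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_antisymmetric_in_group_order(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 8), rng.normal(1, 2, 6)
        t1, df1, p1 = welch_t(x, y)
        t2, df2, p2 = welch_t(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)
        assert df1 == pytest.approx(df2)

    def test_agrees_with_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 10), rng.normal(0.5, 2, 7)
        t, _, p = welch_t(x, y)
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


def _bh_brute_force(pvalues):
    """Step-up definition, written directly: find the largest k with
    p_(k) <= k*alpha/m for every alpha; equivalently q_(i) is the
    smallest alpha at which p_(i) is rejected."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for pos, i in enumerate(order, start=1):
        q[i] = min(min(p[order[j - 1]] * m / j for j in range(pos, m + 1)), 1.0)
    return q


class TestBH:
    def test_closed_form_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_equals_brute_force_up_to_length_8(self, pvals):
        assert bh_adjust(pvals) == pytest.approx(_bh_brute_force(pvals))

    def test_equals_statsmodels_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = rng.uniform(0, 1, size=rng.integers(2, 60))
            ref = multipletests(p, method="fdr_bh")[1]
            assert bh_adjust(p) == pytest.approx(ref)


class TestEffectAndPower:
    @pytest.mark.parametrize(
        "summary, fc, d, power",
        [
            ((845, 528, 368, 379), 2.3, 1.05, 0.89),
            ((3687, 1407, 2141, 1190), 1.72, 1.19, 0.95),
            ((4137, 1532, 2255, 896), 1.83, 1.55, 0.99),
        ],
    )
    def test_group_summaries_reproduce_effect_columns(self, summary, fc, d, power):
        m1, s1, m2, s2 = summary
        ep = effect_and_power(m1, s1, m2, s2, 26, 15)
        assert ep.fold_change == pytest.approx(fc, abs=0.011)
        assert ep.d == pytest.approx(d, abs=0.005)
        assert ep.power == pytest.approx(power, abs=0.01)

    def test_equal_means_give_null_power(self):
        ep = effect_and_power(10, 2, 10, 2, 10, 10, alpha=0.05)
        assert ep.d == 0.0
        assert ep.power == pytest.approx(0.05, abs=1e-6)

    def test_power_monotone_in_effect_and_sample_size(self):
        grid_d = [0.2, 0.5, 0.8, 1.2]
        powers = [t_test_power(d, 12, 12) for d in grid_d]
        assert powers == sorted(powers)
        grid_n = [4, 8, 16, 32]
        powers_n = [t_test_power(0.8, n, n) for n in grid_n]
        assert powers_n == sorted(powers_n)

    def test_zero_case_mean_is_error(self):
        with pytest.raises(ValueError):
            effect_and_power(10, 2, 0, 2, 5, 5)


def _null_matrix(rng, n_transcripts=30, n_per_group=10):
    mu = rng.lognormal(4, 1, size=(n_transcripts, 1))
    counts = rng.negative_binomial(10, 10 / (10 + mu * np.ones((n_transcripts, 2 * n_per_group))))
    samples = [f"s{i}" for i in range(2 * n_per_group)]
    return CountMatrix(
        counts=pd.DataFrame(counts, index=[f"g{i}" for i in range(n_transcripts)], columns=samples),
        lengths=pd.Series(22, index=[f"g{i}" for i in range(n_transcripts)]),
        groups=pd.Series(["control"] * n_per_group + ["case"] * n_per_group, index=samples),
    )


class TestConsensus:
    def test_rpkm_only_significance_is_not_consensus(self, nb_matrix):
        res = consensus_test(nb_matrix)
        only_rpkm = (res["rpkm_q"] < 0.05) & ~((res["quantile_q"] < 0.05) & (res["tmm_q"] < 0.05))
        assert not res.loc[only_rpkm, "consensus"].any()

    def test_ranks_are_one_based_permutations(self, nb_matrix):
        res = consensus_test(nb_matrix)
        for method in ("rpkm", "quantile", "tmm"):
            assert sorted(res[f"{method}_rank"]) == list(range(1, len(res) + 1))
            assert res[f"{method}_q"].between(0, 1).all()
            assert (res[f"{method}_q"] >= res[f"{method}_p"] - 1e-12).all()

    def test_consensus_no_looser_than_each_method(self):
        rng = np.random.default_rng(31)
        fp_consensus, fp_single = 0, 0
        for _ in range(40):
            res = consensus_test(_null_matrix(rng))
            fp_consensus += int(res["consensus"].sum())
            fp_single += int((res["rpkm_q"] < 0.05).sum())
        assert fp_consensus <= fp_single


class TestExclusiveRule:
    def _matrix(self, control_counts, case_counts):
        counts = pd.DataFrame(
            [control_counts + case_counts], index=["g0"],
            columns=[f"c{i}" for i in range(len(control_counts))] + [f"x{i}" for i in range(len(case_counts))],
        )
        groups = pd.Series(
            ["control"] * len(control_counts) + ["case"] * len(case_counts), index=counts.columns
        )
        return CountMatrix(counts=counts, groups=groups)

    def test_exclusive_with_enough_reads_reported(self):
        report = exclusive_rule(self._matrix([0, 0, 0], [4, 4, 3]), min_total=10)
        assert list(report.index) == ["g0"]
        assert report.at["g0", "present_in"] == "case"

    def test_exclusive_below_threshold_dropped(self):
        assert exclusive_rule(self._matrix([0, 0, 0], [3, 3, 3]), min_total=10).empty

    def test_present_in_both_groups_not_exclusive(self):
        assert exclusive_rule(self._matrix([1, 0, 0], [5, 5, 5]), min_total=10).empty
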