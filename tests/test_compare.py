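"""Sample/intron matching, rank tests, corrections and effect sizes."""

import itertools

import numpy as np
import pandas as pd
import pytest

from missplice.compare import (
    ComparisonError,
    SampleMeta,
    adjust_pvalues,
    age_stratified_comparison,
    binding_contingency,
    binding_density_chisq,
    expression_corrected_msr,
    match_introns_by_expression,
    match_samples,
    pooled_msr,
    rank_factor_contributions,
    tpm,
    wilcoxon_superiority,
)


class TestMatchSamples:
    def test_rule_evaluation(self):
        pairs = match_samples({"a1": 7.0, "a2": 8.0}, {"b1": 7.01, "b2": 9.0}, 0.05)
        assert pairs == [("a1", "b1")]

    def test_identical_groups_fully_paired(self):
        keys = {f"s{i}": 6 + i * 0.5 for i in range(6)}
        other = {f"t{i}": 6 + i * 0.5 for i in range(6)}
        pairs = match_samples(keys, other, 0.05)
        assert len(pairs) == 6
        assert all(keys[a] == other[b] for a, b in pairs)

    def test_zero_pairs_is_error(self):
        with pytest.raises(ComparisonError):
            match_samples({"a": 6.0}, {"b": 9.0}, 0.05)

    def test_greedy_against_bruteforce_optimum(self, rng):
        """Greedy pairing yields a maximal matching: never larger than the
        brute-force optimum and (by the standard maximal-matching bound)
        at least half its size. Greedy can genuinely fall short of the
        optimum — e.g. keys {1.0, 1.06} vs {1.05, 1.11} at tolerance 0.06 —
        which is the documented cost of its determinism."""
        for _ in range(30):
            na, nb = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            a = {f"a{i}": float(np.round(rng.uniform(6, 7), 2)) for i in range(na)}
            b = {f"b{i}": float(np.round(rng.uniform(6, 7), 2)) for i in range(nb)}
            tol = 0.1
            try:
                greedy = match_samples(a, b, tol)
            except ComparisonError:
                greedy = []
            # brute force maximum bipartite matching via permutations
            best = 0
            a_ids, b_ids = list(a), list(b)
            for k in range(min(na, nb), 0, -1):
                for a_sub in itertools.permutations(a_ids, k):
                    for b_sub in itertools.combinations(b_ids, k):
                        if all(abs(a[x] - b[y]) <= tol for x, y in zip(a_sub, b_sub)):
                            best = k
                            break
                    if best:
                        break
                if best:
                    break
            assert best / 2 <= len(greedy) <= best


class TestMatchIntrons:
    def test_equal_means_retained(self):
        a = pd.Series({"i1": 100.0, "i2": 100.0})
        b = pd.Series({"i1": 100.0, "i3": 50.0})
        kept = match_introns_by_expression(a, b)
        assert list(kept) == ["i1"]

    def test_small_log_difference_dropped(self):
        a = pd.Series({"i1": 100.0})
        b = pd.Series({"i1": 102.0})  # |log10 diff| ~ 0.0086 > 0.005
        assert len(match_introns_by_expression(a, b)) == 0

    def test_symmetry_and_bruteforce(self, rng):
        ids = [f"i{k}" for k in range(200)]
        a = pd.Series(rng.lognormal(3, 1, 200), index=ids)
        b = pd.Series(a.to_numpy() * rng.lognormal(0, 0.01, 200), index=ids)
        kept_ab = match_introns_by_expression(a, b)
        kept_ba = match_introns_by_expression(b, a)
        assert set(kept_ab) == set(kept_ba)
        expected = {
            i for i in ids
            if abs(np.log10(a[i]) - np.log10(b[i])) <= 0.005
        }
        assert set(kept_ab) == expected


class TestWilcoxonSuperiority:
    def test_identical_paired_distributions(self):
        a = [0.1, 0.2, 0.3, 0.4]
        res = wilcoxon_superiority(a, a, paired=True, sided="one_greater")
        assert res.effect_size == 0.5
        assert res.p == pytest.approx(1.0)

    def test_unpaired_complete_separation(self):
        res = wilcoxon_superiority([4, 5, 6], [1, 2, 3], paired=False, sided="two")
        assert res.effect_size == 1.0

    def test_unpaired_effect_matches_pair_counting(self, rng):
        for _ in range(100):
            a = rng.normal(0, 1, int(rng.integers(3, 30)))
            b = rng.normal(0.3, 1, int(rng.integers(3, 30)))
            res = wilcoxon_superiority(a, b, paired=False, sided="two")
            wins = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
            assert abs(res.effect_size - wins / (len(a) * len(b))) < 1e-12

    def test_paired_effect_matches_rank_biserial_oracle(self, rng):
        from scipy.stats import rankdata

        for _ in range(50):
            n = int(rng.integers(5, 40))
            a = rng.normal(0.1, 1, n)
            b = rng.normal(0, 1, n)
            res = wilcoxon_superiority(a, b, paired=True, sided="two")
            d = a - b
            d = d[d != 0]
            ranks = rankdata(np.abs(d))
            r = (ranks[d > 0].sum() - ranks[d < 0].sum()) / ranks.sum()
            assert res.effect_size == pytest.approx((r + 1) / 2, abs=1e-12)

    def test_insufficient_data_raises(self):
        with pytest.raises(ComparisonError):
            wilcoxon_superiority([1, 2], [3, 4], paired=True)

    def test_unpaired_effect_invariant_under_monotone_transform(self, rng):
        """The pair-counting effect depends only on orderings, so any strictly
        monotone transform leaves it unchanged. (The matched-pairs effect is
        deliberately not tested here: rank-biserial weights difference
        magnitudes, which monotone transforms reorder.)"""
        a = rng.lognormal(0, 1, 50)
        b = rng.lognormal(0.2, 1, 50)
        e1 = wilcoxon_superiority(a, b, paired=False).effect_size
        e2 = wilcoxon_superiority(np.log(a), np.log(b), paired=False).effect_size
        assert e1 == pytest.approx(e2)
        e3 = wilcoxon_superiority(a ** 3, b ** 3, paired=False).effect_size
        assert e1 == pytest.approx(e3)


class TestAdjustPvalues:
    def test_bh_step_up_hand_computed(self):
        q = adjust_pvalues([0.01, 0.02, 0.03], "BH")
        np.testing.assert_allclose(q, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.04], "BH")[0] == pytest.approx(0.04)
        assert adjust_pvalues([0.04], "bonferroni")[0] == pytest.approx(0.04)

    def test_bonferroni_capped(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.4, 0.01, 0.5], "bonferroni"), [1.0, 0.03, 1.0]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5], "BH")


class TestExpressionCorrection:
    def test_unit_foldchange_identity(self):
        msr = pd.Series([0.01, 0.02])
        corrected, f = expression_corrected_msr(msr, [10.0, 10.0], [10.0, 10.0])
        assert f == pytest.approx(1.0)
        np.testing.assert_allclose(corrected, msr)

    def test_downregulated_factor_shrinks_case_msr(self):
        # factor halved in case; the default mode divides by the inverse
        # fold-change, restoring a proportionally inflated MSR
        msr = pd.Series([0.02])
        corrected, f = expression_corrected_msr(msr, [5.0], [10.0])
        assert f == pytest.approx(0.5)
        assert corrected[0] == pytest.approx(0.01)

    def test_reciprocal_reading_behind_flag(self):
        msr = pd.Series([0.02])
        corrected, _ = expression_corrected_msr(
            msr, [5.0], [10.0], mode="divide_by_foldchange"
        )
        assert corrected[0] == pytest.approx(0.04)

    def test_zero_control_expression_rejected(self):
        with pytest.raises(ComparisonError):
            expression_corrected_msr(pd.Series([0.01]), [5.0], [0.0])

    def test_corrected_values_stay_below_one(self):
        corrected, _ = expression_corrected_msr(
            pd.Series([0.9]), [50.0], [10.0]
        )
        assert 0 <= corrected[0] < 1


class TestRankFactors:
    def test_neutral_factor_contributes_zero_and_ranks_last(self, rng):
        n = 500
        ctrl = pd.Series(rng.uniform(0.001, 0.01, n))
        case = ctrl * 2 * rng.lognormal(0, 0.05, n)
        factors = {
            "causal": ([5.0] * 10, [10.0] * 10),
            "neutral": ([10.0] * 10, [10.0] * 10),
        }
        table = rank_factor_contributions(case, ctrl, factors)
        assert list(table["factor"]) == ["causal", "neutral"]
        assert table.set_index("factor").loc["neutral", "contribution"] == pytest.approx(0.0)

    def test_single_factor_ranks_first(self):
        ctrl = pd.Series(np.linspace(0.001, 0.01, 10))
        case = ctrl * 1.5
        table = rank_factor_contributions(case, ctrl, {"f": ([8.0], [10.0])})
        assert table.index[0] == 1 and table.iloc[0]["factor"] == "f"

    def test_no_factors_rejected(self):
        with pytest.raises(ComparisonError):
            rank_factor_contributions(pd.Series([0.1] * 5), pd.Series([0.1] * 5), {})


class TestBindingChisq:
    def test_direct_formula_evaluation(self):
        res = binding_density_chisq([[10, 20], [20, 10]])
        assert res.statistic == pytest.approx(20 / 3)
        assert res.extra["odds_ratio"] == pytest.approx(0.25)

    def test_independent_table_is_zero(self):
        res = binding_density_chisq([[15, 15], [15, 15]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_matches_expected_count_formula_on_random_tables(self, rng):
        for _ in range(50):
            t = rng.integers(1, 100, size=(2, 2)).astype(float)
            res = binding_density_chisq(t)
            row = t.sum(axis=1, keepdims=True)
            col = t.sum(axis=0, keepdims=True)
            expected = row @ col / t.sum()
            chi2 = ((t - expected) ** 2 / expected).sum()
            assert res.statistic == pytest.approx(chi2)

    def test_small_expected_cell_flagged(self):
        res = binding_density_chisq([[0, 1], [1, 60]])
        assert res.flagged

    def test_contingency_builder(self):
        case = pd.Series({"i1": 0.2, "i2": 0.1, "i3": 0.3})
        ctrl = pd.Series({"i1": 0.1, "i2": 0.2, "i3": 0.1})
        binding = {"i1": True, "i2": False, "i3": False}
        table = binding_contingency(case, ctrl, binding)
        # higher in case: i1 (bound), i3 (unbound); lower: i2 (unbound)
        np.testing.assert_array_equal(table, [[1, 1], [0, 1]])


class TestTpm:
    def test_equal_rates(self):
        np.testing.assert_allclose(tpm([10, 90], [1000, 9000]), [5e5, 5e5])

    def test_single_gene(self):
        np.testing.assert_allclose(tpm([7], [1234]), [1e6])

    def test_sums_to_a_million(self, rng):
        values = tpm(rng.integers(1, 1000, 200), rng.integers(200, 10_000, 200))
        assert values.sum() == pytest.approx(1e6, abs=1e-6)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            tpm([1], [0])


def _age_fixture(rng, n_introns=40, per_bin=25, old_shift=0.0):
    samples = []
    ages = {"20-39": (20, 39), "40-59": (40, 59), "60-79": (60, 79)}
    for label, (lo, hi) in ages.items():
        for k in range(per_bin):
            samples.append(
                SampleMeta(
                    sample_id=f"{label}_{k}",
                    group=label,
                    age=float(rng.integers(lo, hi + 1)),
                    rin=float(np.round(rng.uniform(6, 10), 2)),
                )
            )
    cols = [s.sample_id for s in samples]
    idx = [f"i{k}" for k in range(n_introns)]
    ann = pd.DataFrame(
        rng.integers(500, 1500, (n_introns, len(cols))), index=idx, columns=cols
    )
    base = rng.uniform(0.002, 0.01, n_introns)
    novel = np.zeros_like(ann, dtype=np.int64)
    for j, s in enumerate(samples):
        p = base * (1 + (old_shift if s.group == "60-79" else 0.0))
        novel[:, j] = rng.binomial(ann.iloc[:, j].to_numpy(), p)
    novel = pd.DataFrame(novel, index=idx, columns=cols)
    return samples, novel, ann


class TestAgeStratified:
    def test_bin_membership_matches_age_filter(self, rng):
        samples, novel, ann = _age_fixture(rng)
        for s in samples:
            expected = None
            for label, (lo, hi) in {"20-39": (20, 39), "40-59": (40, 59),
                                    "60-79": (60, 79)}.items():
                if lo <= s.age <= hi:
                    expected = label
            assert s.age_bin == expected

    def test_identical_bins_give_half_effect(self, rng):
        samples, novel, ann = _age_fixture(rng, old_shift=0.0)
        results = age_stratified_comparison({"donor": novel}, ann, samples)
        assert results["donor"].effect_size == pytest.approx(0.5, abs=0.2)

    def test_old_excess_detected(self, rng):
        samples, novel, ann = _age_fixture(rng, n_introns=150, old_shift=0.6)
        results = age_stratified_comparison({"donor": novel}, ann, samples)
        assert results["donor"].effect_size > 0.5
        assert results["donor"].p < 0.05

    def test_underfilled_bin_rejected(self, rng):
        samples, novel, ann = _age_fixture(rng, per_bin=10)
        with pytest.raises(ComparisonError):
            age_stratified_comparison({"donor": novel}, ann, samples)
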