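"""Proportion/contingency statistics, factor partitioning, letter displays."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nichetropism import group_stats as gs
from ._oracles import fisher_two_sided_p, pearson_r_and_p, pooled_z


def _binomial_records(rng, n_per_cell, p_by_cell):
    rows = []
    for (host, strain), p in p_by_cell.items():
        hits = rng.random(n_per_cell) < p
        rows.extend(
            {
                "host_background": host,
                "wolbachia_strain": strain,
                "tropism": bool(h),
                "ratio": 0.0,
            }
            for h in hits
        )
    return pd.DataFrame(rows)


class TestTwoProportion:
    def test_identical_samples(self):
        res = gs.two_proportion_test(10, 20, 10, 20)
        assert (res.statistic, res.p_value) == (0.0, 1.0)

    def test_strong_difference_significant(self):
        res = gs.two_proportion_test(18, 20, 2, 20)
        assert res.p_value < 0.001
        # exact unconditional enumeration at the pooled proportion agrees on
        # the significance call
        z_obs = abs(pooled_z(18, 20, 2, 20))
        pool = 0.5
        p_exact = sum(
            sps.binom.pmf(x1, 20, pool) * sps.binom.pmf(x2, 20, pool)
            for x1 in range(21)
            for x2 in range(21)
            if abs(pooled_z(x1, 20, x2, 20)) >= z_obs - 1e-12
        )
        assert p_exact < 0.001

    def test_matches_closed_form_z(self):
        for k1, n1, k2, n2 in [(5, 12, 9, 15), (1, 30, 4, 8), (0, 10, 3, 10)]:
            res = gs.two_proportion_test(k1, n1, k2, n2)
            z = pooled_z(k1, n1, k2, n2)
            assert res.statistic == pytest.approx(z)
            assert res.p_value == pytest.approx(2 * sps.norm.sf(abs(z)))

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportions_ztest

        stat, p = proportions_ztest([7, 3], [20, 25])
        res = gs.two_proportion_test(7, 20, 3, 25)
        assert res.statistic == pytest.approx(stat)
        assert res.p_value == pytest.approx(p)

    def test_continuity_correction_reduces_z(self):
        plain = gs.two_proportion_test(15, 20, 8, 20)
        corr = gs.two_proportion_test(15, 20, 8, 20, continuity=True)
        assert abs(corr.statistic) < abs(plain.statistic)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gs.two_proportion_test(1, 0, 1, 2)
        with pytest.raises(ValueError):
            gs.two_proportion_test(5, 4, 1, 2)

    def test_bonferroni_formula(self):
        assert gs.bonferroni(0.02, 3) == pytest.approx(0.06)
        assert gs.bonferroni(0.5, 3) == 1.0

    def test_type_one_error_calibrated(self):
        # 5000 null simulations at p=0.3, n=50 per arm
        rng = np.random.default_rng(1234)
        k1 = rng.binomial(50, 0.3, size=5000)
        k2 = rng.binomial(50, 0.3, size=5000)
        rejections = sum(
            gs.two_proportion_test(int(a), 50, int(b), 50).p_value < 0.05
            for a, b in zip(k1, k2)
        )
        assert 0.04 <= rejections / 5000 <= 0.07


class TestFisherExact:
    def test_balanced_table(self):
        assert gs.fisher_exact([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_perfect_association(self):
        res = gs.fisher_exact([[10, 0], [0, 10]])
        assert res.p_value == pytest.approx(2 / math.comb(20, 10))

    def test_empty_margin(self):
        assert gs.fisher_exact([[0, 5], [0, 7]]).p_value == pytest.approx(1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            gs.fisher_exact([[1, -1], [2, 3]])

    def test_matches_enumeration_small_margins(self):
        # sub-sample of the full margins<=15 sweep run in the acceptance suite
        for a, b, c, d in itertools.product(range(0, 7, 2), repeat=4):
            if a + b == 0 or c + d == 0:
                continue
            p_impl = gs.fisher_exact([[a, b], [c, d]]).p_value
            p_oracle = fisher_two_sided_p(a, b, c, d)
            assert p_impl == pytest.approx(p_oracle, rel=1e-9, abs=1e-12)


class TestFactorPartition:
    def test_balanced_no_effect_data(self):
        # perfectly balanced cells: identical proportions everywhere
        rows = []
        for host in ("hostA", "hostB"):
            for strain in ("s1", "s2"):
                rows += [
                    {"host_background": host, "wolbachia_strain": strain,
                     "tropism": i < 30, "ratio": 1.0}
                    for i in range(100)
                ]
        res = gs.partition_frequency(pd.DataFrame(rows))
        assert res.model == "logistic"
        assert abs(res.params["host_background"]) < 0.1
        assert abs(res.params["wolbachia_strain"]) < 0.1
        assert res.p_values["host_background"] > 0.5
        assert res.p_values["wolbachia_strain"] > 0.5

    def test_strain_odds_ratio_recovered(self):
        # strain odds ratio 9, no host effect, n=400: strain significant,
        # host not, in >=90% of 20 seeds
        base = 0.2
        p_hi = base * 9 / (1 - base + base * 9)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            df = _binomial_records(
                rng,
                100,
                {
                    ("hostA", "s1"): base,
                    ("hostA", "s2"): p_hi,
                    ("hostB", "s1"): base,
                    ("hostB", "s2"): p_hi,
                },
            )
            res = gs.partition_frequency(df)
            if res.model == "logistic" and (
                res.p_values["wolbachia_strain"] < 0.01
                and res.p_values["host_background"] > 0.05
            ):
                hits += 1
        assert hits >= 18

    def test_logistic_log_odds_within_three_se(self):
        base, oratio = 0.25, 4.0
        p_hi = base * oratio / (1 - base + base * oratio)
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            df = _binomial_records(
                rng,
                150,
                {
                    ("hostA", "s1"): base,
                    ("hostA", "s2"): p_hi,
                    ("hostB", "s1"): base,
                    ("hostB", "s2"): p_hi,
                },
            )
            res = gs.partition_frequency(df)
            if res.model != "logistic":
                continue
            est = res.params["wolbachia_strain"]
            se = res.bse["wolbachia_strain"]
            if abs(est - math.log(oratio)) < 3 * se:
                ok += 1
        assert ok >= 18

    def test_zero_frequency_triggers_fisher_fallback(self):
        rng = np.random.default_rng(0)
        df = _binomial_records(
            rng,
            50,
            {
                ("hostA", "s1"): 0.0,
                ("hostA", "s2"): 0.5,
                ("hostB", "s1"): 0.0,
                ("hostB", "s2"): 0.5,
            },
        )
        res = gs.partition_frequency(df)
        assert res.separation is True
        assert res.model == "fisher_fallback"
        assert res.p_values["wolbachia_strain"] < 0.001

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame(
            {
                "host_background": ["h1"] * 4,
                "wolbachia_strain": ["s1", "s1", "s2", "s2"],
                "tropism": [True, False, True, False],
            }
        )
        with pytest.raises(ValueError, match="levels"):
            gs.partition_frequency(df)

    def test_confounded_design_rejected(self):
        df = pd.DataFrame(
            {
                "host_background": ["h1"] * 10 + ["h2"] * 10,
                "wolbachia_strain": ["s1"] * 10 + ["s2"] * 10,
                "tropism": [True, False] * 10,
            }
        )
        with pytest.raises(ValueError, match="confounded"):
            gs.partition_frequency(df)

    def test_linear_identical_ratios(self):
        rows = [
            {"host_background": h, "wolbachia_strain": s, "ratio": 2.0}
            for h in ("h1", "h2")
            for s in ("s1", "s2")
            for _ in range(10)
        ]
        res = gs.partition_density(pd.DataFrame(rows))
        assert res.params["host_background"] == pytest.approx(0.0, abs=1e-10)
        assert res.params["wolbachia_strain"] == pytest.approx(0.0, abs=1e-10)

    def test_linear_strain_shift_recovered(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            rows = []
            for host in ("h1", "h2"):
                for strain in ("s1", "s2"):
                    shift = 1.0 if strain == "s2" else 0.0
                    for _ in range(50):
                        rows.append(
                            {
                                "host_background": host,
                                "wolbachia_strain": strain,
                                "ratio": 1.0 + shift + rng.normal(0, 0.5),
                            }
                        )
            res = gs.partition_density(pd.DataFrame(rows))
            if 0.7 < res.params["wolbachia_strain"] < 1.3:
                hits += 1
        assert hits >= 18


class TestLettering:
    def test_identical_groups_share_one_letter(self):
        res = gs.assign_letters({"a": (5, 20), "b": (5, 20), "c": (5, 20)})
        assert set(res.letters.values()) == {"a"}

    def test_extreme_groups_get_distinct_letters(self):
        res = gs.assign_letters({"g1": (0, 20), "g2": (10, 20), "g3": (20, 20)})
        letters = list(res.letters.values())
        assert len(set(letters)) == 3
        assert all(len(l) == 1 for l in letters)
        assert (res.pairwise["p_adj"] < 0.05).all()

    def test_two_groups_match_single_test(self):
        k = gs.two_proportion_test(18, 20, 3, 20)
        res = gs.assign_letters({"x": (18, 20), "y": (3, 20)}, alpha=0.05)
        share = res.letters["x"] == res.letters["y"]
        assert share == (k.p_value >= 0.05)

    def test_lettering_invariant_to_group_order(self):
        groups = {"g1": (0, 20), "g2": (9, 20), "g3": (11, 20), "g4": (20, 20)}
        res1 = gs.assign_letters(dict(sorted(groups.items())))
        res2 = gs.assign_letters(dict(sorted(groups.items(), reverse=True)))
        # partition structure identical regardless of insertion order
        def partition(res):
            return {
                frozenset(g for g in groups if l in res.letters[g])
                for l in set("".join(res.letters.values()))
            }
        assert partition(res1) == partition(res2)

    def test_share_letter_iff_not_significant(self):
        groups = {"a": (1, 25), "b": (6, 25), "c": (12, 25), "d": (24, 25)}
        res = gs.assign_letters(groups)
        sig = {
            frozenset((r.group1, r.group2))
            for r in res.pairwise.itertuples()
            if r.significant
        }
        for g1, g2 in itertools.combinations(groups, 2):
            shares = bool(set(res.letters[g1]) & set(res.letters[g2]))
            assert shares == (frozenset((g1, g2)) not in sig)

    def test_t_lettering(self):
        rng = np.random.default_rng(0)
        res = gs.assign_letters(
            {
                "lo": list(rng.normal(1.0, 0.2, 30)),
                "mid": list(rng.normal(1.02, 0.2, 30)),
                "hi": list(rng.normal(3.0, 0.2, 30)),
            },
            test="t",
        )
        assert res.letters["lo"] == res.letters["mid"]
        assert res.letters["hi"] != res.letters["lo"]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            gs.assign_letters({"a": (0, 0), "b": (1, 2)})


class TestChiSquare:
    def test_identical_rows(self):
        res = gs.chi_square_groups([[5, 15], [5, 15], [5, 15]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 2

    def test_two_by_two_equals_squared_z(self):
        z = gs.two_proportion_test(12, 20, 5, 20).statistic
        chi = gs.chi_square_groups([[12, 8], [5, 15]])
        assert chi.statistic == pytest.approx(z**2)

    def test_zero_expected_count_guides_to_fisher(self):
        with pytest.raises(ValueError, match="fisher"):
            gs.chi_square_groups([[0, 5], [0, 7]])

    def test_matches_permutation_null(self):
        # Pearson's test is asymptotic; its exact counterpart is the
        # permutation null of the same statistic.  At n=300 the two agree to
        # ~0.02 (mid-p handles the discrete atom at the observed statistic).
        table = np.array([[45, 55], [55, 45], [50, 50]])
        res = gs.chi_square_groups(table)
        rng = np.random.default_rng(3)
        labels = np.repeat(np.arange(3), table.sum(axis=1))
        outcomes = np.concatenate([np.r_[np.ones(r[0]), np.zeros(r[1])] for r in table])
        ge = gt = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(outcomes)
            t = np.array(
                [
                    [perm[labels == g].sum(), (1 - perm[labels == g]).sum()]
                    for g in range(3)
                ]
            )
            row = t.sum(axis=1, keepdims=True)
            col = t.sum(axis=0, keepdims=True)
            exp = row @ col / t.sum()
            stat = ((t - exp) ** 2 / exp).sum()
            if stat >= res.statistic - 1e-9:
                ge += 1
            if stat > res.statistic + 1e-9:
                gt += 1
        p_mid = (ge + gt) / (2 * n_perm)
        se = math.sqrt(p_mid * (1 - p_mid) / n_perm)
        assert abs(res.p_value - p_mid) < 0.02 + 3 * se


class TestPresenceCorrelation:
    def test_identical_vectors(self):
        res = gs.presence_correlation({"a": (1, 1), "b": (2, 2), "c": (5, 5)})
        assert res.statistic == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            gs.presence_correlation({"a": (1, 2), "b": (1, 5), "c": (1, 9)})

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            gs.presence_correlation({"a": (1, 2), "b": (3, 4)})

    def test_matches_closed_form(self):
        pairs = {"a": (0.0, 10.0), "b": (17.0, 30.0), "c": (71.0, 45.0),
                 "d": (95.0, 99.0), "e": (2.3, 1.0)}
        res = gs.presence_correlation(pairs)
        r, p = pearson_r_and_p([v[0] for v in pairs.values()],
                               [v[1] for v in pairs.values()])
        assert res.statistic == pytest.approx(r)
        assert res.p_value == pytest.approx(p)

    def test_spearman_option(self):
        pairs = {"a": (1, 2), "b": (2, 3), "c": (3, 10), "d": (4, 30)}
        res = gs.presence_correlation(pairs, method="spearman")
        assert res.statistic == pytest.approx(1.0)
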