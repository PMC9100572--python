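"""Permutation-calibrated disparity test: statistics, calibration, letters."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from latscan.disparity import (
    GeneDisparity,
    lsd_letters,
    observed_statistic,
    permutation_calibrate,
)


class TestObservedStatistic:
    def test_identical_groups_give_zero_t(self):
        kind, value = observed_statistic([10, 10, 10, 10, 10, 10], list("AAABBB"))
        assert kind == "t"
        assert value == pytest.approx(0.0)

    def test_hand_computed_t(self):
        # means 2 vs 5, pooled SD 1, SE = sqrt(2/3) -> |t| = 3/sqrt(2/3)
        kind, value = observed_statistic([1, 2, 3, 4, 5, 6], list("AAABBB"))
        assert kind == "t"
        assert value == pytest.approx(3.6742, abs=1e-4)

    def test_matches_scipy_pooled_t(self, rng):
        x, y = rng.normal(40, 2, 30), rng.normal(41, 2, 12)
        _, value = observed_statistic(
            np.concatenate([x, y]), ["a"] * 30 + ["b"] * 12
        )
        t_ref = stats.ttest_ind(x, y, equal_var=True).statistic
        assert value == pytest.approx(abs(t_ref), rel=1e-10)

    def test_matches_scipy_anova_f(self, rng):
        groups = [rng.normal(m, 1.5, n) for m, n in [(40, 20), (41, 15), (40.5, 30)]]
        y = np.concatenate(groups)
        labels = ["a"] * 20 + ["b"] * 15 + ["c"] * 30
        kind, value = observed_statistic(y, labels)
        assert kind == "F"
        assert value == pytest.approx(stats.f_oneway(*groups).statistic, rel=1e-10)

    def test_shift_invariance(self, rng):
        y = rng.normal(size=24)
        labels = rng.choice(["a", "b", "c"], 24)
        while len(set(labels)) < 3 or min(np.bincount(pd.factorize(labels)[0])) < 2:
            labels = rng.choice(["a", "b", "c"], 24)
        _, v1 = observed_statistic(y, labels)
        _, v2 = observed_statistic(y + 123.4, labels)
        assert v1 == pytest.approx(v2, rel=1e-8)

    def test_label_swap_invariance(self):
        y = [1, 2, 3, 7, 8, 9.5]
        _, v1 = observed_statistic(y, list("AAABBB"))
        _, v2 = observed_statistic(y, list("BBBAAA"))
        assert v1 == pytest.approx(v2)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than two"):
            observed_statistic([1, 2, 3], ["a", "a", "b"])


def _exact_permutation_p(y, labels):
    """Oracle: enumerate all distinct group assignments of the given sizes."""
    y = np.asarray(y, float)
    n = len(y)
    n_a = sum(1 for l in labels if l == labels[0])
    _, obs = observed_statistic(y, labels)
    stats_all = []
    for idx_a in itertools.combinations(range(n), n_a):
        lab = np.array(["b"] * n)
        lab[list(idx_a)] = "a"
        stats_all.append(observed_statistic(y, lab)[1])
    stats_all = np.array(stats_all)
    return float((stats_all >= obs - 1e-12).mean())


class TestPermutationCalibrate:
    def test_p_never_zero_and_bounded(self, rng):
        y = np.concatenate([rng.normal(0, 1, 8), rng.normal(50, 1, 8)])  # extreme
        labels = ["a"] * 8 + ["b"] * 8
        _, p = permutation_calibrate(y, labels, n_perm=1000, seed=1)
        assert 1.0 / 1001 <= p <= 1.0
        assert p == pytest.approx(1.0 / 1001)

    def test_matches_exhaustive_enumeration_small_instance(self, rng):
        """Two groups of four: empirical p within Monte-Carlo error of the
        exact p over all C(8,4) = 70 assignments."""
        y = rng.normal(40, 1.5, 8)
        y[:4] += 1.2
        labels = ["a"] * 4 + ["b"] * 4
        p_exact = _exact_permutation_p(y, labels)
        _, p_emp = permutation_calibrate(y, labels, n_perm=4000, seed=7)
        mc_err = 3 * np.sqrt(p_exact * (1 - p_exact) / 4000) + 1 / 4000
        assert abs(p_emp - p_exact) < mc_err + 1e-9

    def test_deterministic_under_seed(self, rng):
        y = rng.normal(40, 2, 30)
        labels = ["a"] * 18 + ["b"] * 12
        r1 = permutation_calibrate(y, labels, seed=42)
        r2 = permutation_calibrate(y, labels, seed=42)
        assert r1 == r2

    def test_small_n_perm_warns(self, rng):
        y = rng.normal(size=12)
        with pytest.warns(UserWarning, match="unstable"):
            permutation_calibrate(y, ["a"] * 6 + ["b"] * 6, n_perm=50, seed=0)

    def test_critical_value_is_95th_percentile(self, rng):
        y = rng.normal(40, 2, 40)
        labels = ["a"] * 25 + ["b"] * 15
        crit, _ = permutation_calibrate(y, labels, n_perm=500, alpha=0.05, seed=9)
        # recompute the permutation distribution with the same stream
        from latscan.disparity import _batch_statistic, _group_design

        G, _, ns = _group_design(labels)
        rng2 = np.random.default_rng(9)
        V = rng2.permuted(np.broadcast_to(np.asarray(y, float), (500, 40)), axis=1)
        assert crit == pytest.approx(np.percentile(_batch_statistic(V, G, ns), 95))


class TestLsdLetters:
    def test_equal_means_share_one_letter(self):
        letters = lsd_letters([40.0, 40.0, 40.0], [20, 20, 20], mse=1.0, df=57)
        assert letters == ["a", "a", "a"]

    def test_separated_means_get_distinct_letters(self):
        # LSD at df=297, mse=0.25, n=100: t_.975 ~ 1.968, lsd ~ 0.139
        letters = lsd_letters([45.0, 45.0, 40.0], [100, 100, 100], mse=0.25, df=297)
        assert letters[0] == letters[1]
        assert letters[2] != letters[0]

    def test_splice_variant_pattern(self):
        """Three-allele layout where the splice-carrying allele sits higher
        and the other alternate matches Ref: the high group is lettered apart
        from Ref, Ref and the similar allele share a letter."""
        means = [40.0, 40.88, 40.05]       # Ref, splice allele, missense allele
        ns = [150, 25, 12]
        letters = lsd_letters(means, ns, mse=1.0, df=184)
        assert letters[1] != letters[0]
        assert set(letters[0]) & set(letters[2])

    def test_overlap_chain_shares_letters(self):
        # middle group indistinguishable from both ends; ends differ
        # with n=8 and mse=1 the LSD is ~1.04: 1° apart is not significant, 2° is
        letters = lsd_letters([42.0, 41.0, 40.0], [8, 8, 8], mse=1.0, df=21)
        assert set(letters[0]) & set(letters[1])
        assert set(letters[1]) & set(letters[2])
        assert not set(letters[0]) & set(letters[2])

    def test_nonpositive_df_rejected(self):
        with pytest.raises(ValueError):
            lsd_letters([1.0, 2.0, 3.0], [3, 3, 3], mse=1.0, df=0)


class TestGeneDisparityModel:
    def test_fit_reports_groups_deltas_and_antisymmetry(self, rng):
        y = np.concatenate([rng.normal(40, 1, 30), rng.normal(42, 1, 20)])
        labels = ["Ref"] * 30 + ["Alt1"] * 20
        res = GeneDisparity(y, labels, gene_id="G").fit(n_perm=300, seed=3)
        assert res.kind == "t"
        assert set(res.group_table["allele"]) == {"Ref", "Alt1"}
        assert res.delta("Alt1", "Ref") == pytest.approx(-res.delta("Ref", "Alt1"))
        assert res.delta("Alt1", "Ref") == pytest.approx(2.0, abs=0.8)
        assert res.northern_allele == "Alt1"
        assert res.significant == (res.statistic >= res.critical_value)
        assert "Latitudinal disparity" in res.summary()

    def test_three_allele_fit_assigns_letters(self, rng):
        y = np.concatenate(
            [rng.normal(40, 0.5, 40), rng.normal(42, 0.5, 30), rng.normal(40.1, 0.5, 20)]
        )
        labels = ["Ref"] * 40 + ["Alt1"] * 30 + ["Alt2"] * 20
        res = GeneDisparity(y, labels).fit(n_perm=300, seed=5)
        assert res.kind == "F"
        assert res.letters is not None
        assert res.letters["Alt1"] != res.letters["Ref"]
        assert set(res.letters["Ref"]) & set(res.letters["Alt2"])

    def test_identical_seed_reproduces_fit(self, rng):
        y = rng.normal(40, 2, 50)
        labels = ["Ref"] * 35 + ["Alt1"] * 15
        r1 = GeneDisparity(y, labels).fit(seed=11)
        r2 = GeneDisparity(y, labels).fit(seed=11)
        assert r1.pvalue == r2.pvalue
        assert r1.critical_value == r2.critical_value
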