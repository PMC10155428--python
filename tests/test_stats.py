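"""Nonparametric battery: exact p-values vs enumeration, calibration,
Bonferroni and equivalence testing."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

import synergykit as sk
from synergykit.stats import run_group_analysis


def wilcoxon_oracle(x, y):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    dist = np.array([np.sum(ranks[list(signs)])
                     for signs in itertools.product([False, True], repeat=n)
                     ], dtype=float)
    lo = np.mean(dist <= w_plus + 1e-12)
    hi = np.mean(dist >= w_plus - 1e-12)
    return min(1.0, 2 * min(lo, hi))


def mannwhitney_oracle(a, b):
    """Exact two-sided U-test p by enumerating all group assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n = len(a)
    u_obs = sum(1 for x in a for y in b if x > y) + \
        0.5 * sum(1 for x in a for y in b if x == y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n):
        ga = pooled[list(idx)]
        gb = np.delete(pooled, list(idx))
        us.append(sum(1 for x in ga for y in gb if x > y)
                  + 0.5 * sum(1 for x in ga for y in gb if x == y))
    us = np.asarray(us)
    lo = np.mean(us <= u_obs + 1e-12)
    hi = np.mean(us >= u_obs - 1e-12)
    return min(1.0, 2 * min(lo, hi))


class TestWilcoxon:
    def test_five_positive_pairs_give_exact_p(self):
        x = np.array([11.0, 12, 13, 14, 15])
        y = np.array([10.0, 10, 10, 10, 10])
        stat, p = sk.wilcoxon_signed_rank(x, y)
        assert p == pytest.approx(0.0625)           # 2 / 2^5
        assert p == pytest.approx(wilcoxon_oracle(x, y))

    def test_identical_pairs_are_degenerate(self):
        x = np.arange(6.0)
        with pytest.raises(sk.DegenerateSeriesError):
            sk.wilcoxon_signed_rank(x, x)

    def test_too_few_nonzero_differences(self):
        with pytest.raises(sk.ParameterError):
            sk.wilcoxon_signed_rank([1.0, 2, 3, 4], [0.0, 0, 0, 0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_for_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        _, p = sk.wilcoxon_signed_rank(x, y)
        assert p == pytest.approx(wilcoxon_oracle(x, y), abs=1e-12)

    def test_type_one_error_is_calibrated(self):
        rej = 0
        for i in range(200):
            rng = np.random.default_rng(1000 + i)
            _, p = sk.wilcoxon_signed_rank(rng.standard_normal(20),
                                           rng.standard_normal(20))
            rej += p < 0.05
        assert 0.03 <= rej / 200 <= 0.08


class TestMannWhitney:
    def test_separated_triples_give_exact_p(self):
        a, b = [1.0, 2, 3], [10.0, 11, 12]
        u, p = sk.mann_whitney_u(a, b)
        assert u == 0.0
        assert p == pytest.approx(0.1)              # 2 / C(6, 3)
        assert p == pytest.approx(mannwhitney_oracle(a, b))

    def test_identical_multisets_give_half_nm(self):
        a = [1.0, 2, 3, 4]
        u, _ = sk.mann_whitney_u(a, a)
        assert u == len(a) ** 2 / 2

    def test_empty_group_rejected(self):
        with pytest.raises(sk.ParameterError):
            sk.mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_for_small_samples(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = rng.standard_normal(int(rng.integers(3, 6)))
        b = rng.standard_normal(int(rng.integers(3, 6)))
        _, p = sk.mann_whitney_u(a, b)
        assert p == pytest.approx(mannwhitney_oracle(a, b), abs=1e-12)

    def test_type_one_error_is_calibrated(self):
        rej = 0
        for i in range(200):
            rng = np.random.default_rng(5000 + i)
            _, p = sk.mann_whitney_u(rng.standard_normal(15),
                                     rng.standard_normal(15))
            rej += p < 0.05
        assert 0.03 <= rej / 200 <= 0.08


class TestKsNormality:
    def test_tiny_sample_rejected(self):
        with pytest.raises(sk.ParameterError):
            sk.ks_normality([0.0, 1.0])

    def test_detects_uniform_data(self):
        hits = 0
        for i in range(20):
            rng = np.random.default_rng(300 + i)
            hits += sk.ks_normality(rng.uniform(0, 1, 1000)) < 0.05
        assert hits >= 19

    def test_accepts_normal_data_at_nominal_rate(self):
        rej = 0
        for i in range(100):
            rng = np.random.default_rng(400 + i)
            rej += sk.ks_normality(rng.standard_normal(1000)) < 0.05
        assert rej / 100 <= 0.10


class TestBonferroni:
    def test_paper_family_of_67_displays_0007(self):
        th = sk.bonferroni_alpha(0.05, 67)
        assert th.exact == pytest.approx(0.05 / 67)
        assert th.display == 0.0007

    @pytest.mark.parametrize("alpha, m, expected", [(0.05, 1, 0.05),
                                                    (0.05, 5, 0.01)])
    def test_simple_families(self, alpha, m, expected):
        assert sk.bonferroni_alpha(alpha, m).exact == pytest.approx(expected)

    def test_threshold_strictly_decreases_with_family_size(self):
        exacts = [sk.bonferroni_alpha(0.05, m).exact for m in range(1, 30)]
        assert all(b < a for a, b in zip(exacts, exacts[1:]))

    def test_zero_tests_rejected(self):
        with pytest.raises(sk.ParameterError):
            sk.bonferroni_alpha(0.05, 0)


class TestEquivalence:
    def test_identical_samples_are_equivalent(self):
        rng = np.random.default_rng(500)
        x = rng.standard_normal(40)
        res = sk.tost_equivalence(x, x + 0.001, margin=1.0)
        assert res.equivalent

    def test_widely_separated_means_are_not_equivalent(self):
        rng = np.random.default_rng(501)
        a = rng.standard_normal(30)
        res = sk.tost_equivalence(a, a + 10.0, margin=1.0)
        assert not res.equivalent

    def test_nonpositive_margin_rejected(self):
        with pytest.raises(sk.ParameterError):
            sk.tost_equivalence([1.0, 2, 3], [1.0, 2, 3], margin=0.0)

    def test_power_grows_with_sample_size(self):
        hits = {n: 0 for n in (10, 80)}
        for n in hits:
            for i in range(50):
                rng = np.random.default_rng(600 + i)
                a = rng.standard_normal(n)
                b = rng.standard_normal(n)
                hits[n] += sk.tost_equivalence(a, b, margin=1.0).equivalent
        assert hits[80] >= hits[10]
        assert hits[80] >= 45                 # strong power at n=80, margin 1 SD


class TestRunGroupAnalysis:
    @staticmethod
    def _cohort_table(n_participants=8, effect=0.0, seed=0,
                      conditions=("stim", "no_stim", "control")):
        rng = np.random.default_rng(seed)
        rows = []
        for p in range(n_participants):
            for muscle in sk.CHANNEL_NAMES:
                for movement in sk.MOVEMENTS:
                    for cond in conditions:
                        shift = -effect if cond == "stim" else 0.0
                        rows.append({
                            "participant": f"P{p}", "session": 1,
                            "muscle": muscle, "movement": movement,
                            "condition": cond,
                            "hfd": 1.5 + shift + 0.1 * rng.standard_normal()})
        return pd.DataFrame(rows)

    def test_report_covers_both_contrasts_per_cell(self):
        table = self._cohort_table()
        report = run_group_analysis(table)
        assert len(report.comparisons) == 2 * 10 * 6
        assert set(report.comparisons.comparison) == {"stim_vs_no_stim",
                                                      "control_vs_stim"}
        assert report.threshold.m == 120

    def test_planted_strong_effect_is_significant_everywhere(self):
        table = self._cohort_table(n_participants=14, effect=1.0, seed=1)
        report = run_group_analysis(table)
        paired = report.comparisons.query("comparison == 'stim_vs_no_stim'")
        assert paired.significant.all()

    def test_missing_cells_are_skipped_with_reason(self):
        table = self._cohort_table(n_participants=3)
        report = run_group_analysis(table)
        assert report.skipped                        # too few pairs for Wilcoxon
        assert all("stim_vs_no_stim" in s for s in report.skipped)

    def test_equivalence_attached_when_both_groups_present(self):
        rng = np.random.default_rng(2)
        table = self._cohort_table(n_participants=6)
        report = run_group_analysis(
            table, r2_values={"SCI": 0.9 + 0.01 * rng.standard_normal(8),
                              "control": 0.9 + 0.01 * rng.standard_normal(8)},
            equivalence_margin=0.05)
        assert report.equivalence is not None
        assert report.equivalence.equivalent
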