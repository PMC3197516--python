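"""Quantile summaries and the exact Mann–Whitney U test against brute force."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from noflow import compare_phases, mann_whitney_exact, scenario_metrics, summarize
from noflow.stats import _exact_p_no_ties, _normal_approx_p, wilcoxon_signed_rank


def enumerate_p(x, y) -> float:
    """Reference two-sided p: U over every labeling of the pooled sample."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    u_obs = ranks[:n1].sum() - offset
    us = [
        sum(ranks[i] for i in c) - offset
        for c in itertools.combinations(range(len(pooled)), n1)
    ]
    lo = np.mean([u <= u_obs + 1e-9 for u in us])
    hi = np.mean([u >= u_obs - 1e-9 for u in us])
    return min(1.0, 2.0 * min(lo, hi))


class TestSummarize:
    def test_singleton(self):
        s = summarize([5.0], "x")
        assert (s.median, s.q25, s.q75, s.n) == (5.0, 5.0, 5.0, 1)

    def test_spss_weighted_average_convention(self):
        # (n+1)p positions: 1.25, 2.5, 3.75 for n=4
        s = summarize([1.0, 2.0, 3.0, 4.0], "x")
        assert (s.q25, s.median, s.q75) == (1.25, 2.5, 3.75)

    def test_conventions_differ_where_expected(self):
        linear = summarize([1.0, 2.0, 3.0, 4.0], "x", quantile_method="linear")
        assert (linear.q25, linear.q75) == (1.75, 3.25)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_quartile_ordering(self, values):
        s = summarize(values, "x")
        assert s.q25 <= s.median <= s.q75

    def test_empty_and_bad_method(self):
        with pytest.raises(ValueError):
            summarize([], "x")
        with pytest.raises(ValueError, match="quantile method"):
            summarize([1.0], "x", quantile_method="nope")


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        res = mann_whitney_exact([1, 2, 3], [1, 2, 3])
        assert res.p_two_sided == 1.0

    def test_complete_separation_at_thirteen(self):
        x = list(range(13))
        y = list(range(100, 113))
        res = mann_whitney_exact(x, y)
        assert res.method == "exact"
        assert res.u_statistic == 0.0
        assert res.p_two_sided == pytest.approx(2 / math.comb(26, 13), rel=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_exact_dp_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(1, 6), rng.integers(1, 6)
        x = rng.normal(size=n1)  # continuous draws: no ties
        y = rng.normal(size=n2)
        res = mann_whitney_exact(x, y)
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(enumerate_p(x, y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_tied_samples_match_permutation_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.integers(0, 3, size=4).astype(float)  # heavy ties
        y = rng.integers(0, 3, size=4).astype(float)
        res = mann_whitney_exact(x, y)
        assert res.method == "exact_ties"
        assert res.p_two_sided == pytest.approx(enumerate_p(x, y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_scipy_exact(self, seed):
        rng = np.random.default_rng(200 + seed)
        x = rng.normal(size=8)
        y = rng.normal(loc=0.5, size=9)
        res = mann_whitney_exact(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.u_statistic == pytest.approx(ref.statistic)
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)

    @given(
        st.lists(st.floats(-100, 100), min_size=1, max_size=8),
        st.lists(st.floats(-100, 100), min_size=1, max_size=8),
    )
    @settings(max_examples=60, deadline=None)
    def test_u_complement_and_symmetry(self, x, y):
        res_xy = mann_whitney_exact(x, y)
        res_yx = mann_whitney_exact(y, x)
        n1, n2 = len(x), len(y)
        assert res_xy.u_statistic + res_yx.u_statistic == pytest.approx(n1 * n2)
        assert res_xy.p_two_sided == pytest.approx(res_yx.p_two_sided, abs=1e-12)

    def test_exact_and_normal_converge_for_large_samples(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=50)
        y = rng.normal(loc=0.5, size=50)
        from noflow.stats import _u_statistics

        u1, _ = _u_statistics(np.asarray(x), np.asarray(y))
        p_exact = _exact_p_no_ties(u1, 50, 50)
        p_norm = _normal_approx_p(u1, 50, 50, np.concatenate([x, y]))
        assert abs(p_exact - p_norm) < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1.0])


class TestComparePhases:
    @staticmethod
    def _cohort(n=6, delta=0.0, seed=0):
        from noflow import Fixed, GeneratorConfig, generate_scenario

        rng = np.random.default_rng(seed)
        cohort = []
        for i in range(n):
            fr = 0.35 + 0.1 * rng.random()
            cfg = GeneratorConfig(
                seed=seed, responder_nfr_target=Fixed(fr), team_nfr_target=Fixed(fr - delta)
            )
            log, _ = generate_scenario(cfg, i)
            cohort.append(scenario_metrics(log))
        return cohort

    def test_bookkeeping_counts(self):
        cohort = self._cohort(n=5, delta=0.1)
        s_fr, s_team, cmp = compare_phases(cohort, "nfr")
        assert s_fr.n == s_team.n == cmp.n1 == cmp.n2 == 5

    def test_separated_phases_are_significant(self):
        cohort = self._cohort(n=8, delta=0.2, seed=3)
        _, _, cmp = compare_phases(cohort, "nfr")
        assert cmp.p_two_sided < 0.05

    def test_missing_phase_reported_by_scenario_id(self):
        from conftest import make_log, metronome

        cohort = self._cohort(n=3, delta=0.1)
        bare = scenario_metrics(make_log(compressions=metronome(0, 300), t_end=300.0))
        with pytest.raises(ValueError, match="test"):
            compare_phases(cohort + [bare], "nfr")

    def test_paired_variant_runs(self):
        cohort = self._cohort(n=8, delta=0.2, seed=5)
        _, _, cmp = compare_phases(cohort, "nfr", paired=True)
        assert cmp.method == "wilcoxon_paired"
        assert 0 < cmp.p_two_sided <= 1

    def test_wilcoxon_requires_equal_lengths(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0])
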