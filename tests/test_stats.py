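import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from fetalprsa import DegenerateInputError, RRSeries, reference
from fetalprsa.stats import (
    quartile_summary,
    sdnn,
    significant_T_ranges,
    spearman,
    wilcoxon_signed_rank_paired,
)


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        rho_rev, _ = spearman([1, 2, 3, 4], [40, 30, 20, 10])
        assert rho_rev == pytest.approx(-1.0)

    def test_tied_data_matches_exhaustive_enumeration(self):
        """rho and the exact p agree with a from-scratch enumeration oracle."""
        x = [1.0, 2.0, 2.0, 5.0]
        y = [3.0, 3.0, 7.0, 9.0]

        def mid_ranks(v):
            order = sorted(range(len(v)), key=lambda i: v[i])
            ranks = [0.0] * len(v)
            i = 0
            while i < len(v):
                j = i
                while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                    j += 1
                avg = (i + j) / 2.0 + 1.0
                for k in range(i, j + 1):
                    ranks[order[k]] = avg
                i = j + 1
            return ranks

        def pearson(u, v):
            mu, mv = sum(u) / len(u), sum(v) / len(v)
            num = sum((a - mu) * (b - mv) for a, b in zip(u, v))
            den = math.sqrt(
                sum((a - mu) ** 2 for a in u) * sum((b - mv) ** 2 for b in v)
            )
            return num / den

        rx, ry = mid_ranks(x), mid_ranks(y)
        rho_oracle = pearson(rx, ry)
        count = sum(
            abs(pearson(rx, list(perm))) >= abs(rho_oracle) - 1e-12
            for perm in itertools.permutations(ry)
        )
        p_oracle = count / math.factorial(4)

        rho, p = spearman(x, y)
        assert rho == pytest.approx(rho_oracle, abs=1e-12)
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(12)
        y = rng.standard_normal(12)
        rho, p = spearman(x, y)
        rho2, p2 = spearman(np.exp(x), y**3)
        assert rho2 == pytest.approx(rho, abs=1e-12)
        assert p2 == pytest.approx(p, abs=1e-12)

    def test_zero_rank_variance_is_error(self):
        with pytest.raises(DegenerateInputError):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(17)
        x = rng.standard_normal(30)
        y = x + 0.5 * rng.standard_normal(30)
        rho, p = spearman(x, y)
        rho_sp, p_sp = sps.spearmanr(x, y)
        assert rho == pytest.approx(rho_sp, abs=1e-12)
        assert p == pytest.approx(p_sp, rel=1e-6)


class TestWilcoxon:
    def test_seven_concordant_pairs(self):
        a = [10.0, 12, 11, 14, 13, 12, 15]
        b = [v - 1.0 for v in a]
        assert wilcoxon_signed_rank_paired(a, b) == pytest.approx(2.0 / 128.0)

    def test_balanced_alternating_differences_give_p_one(self):
        a = np.zeros(6)
        b = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        assert wilcoxon_signed_rank_paired(a, b) == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(5, 10), st.integers(0, 10**6))
    def test_exact_p_matches_sign_enumeration(self, n, seed):
        """DP distribution equals brute-force enumeration of all 2^n signs."""
        rng = np.random.default_rng(seed)
        d = rng.integers(-5, 6, size=n).astype(float)
        d[d == 0] = 1.0
        a = d
        b = np.zeros(n)
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        stats_all = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=n)
        ]
        p_le = sum(w <= w_obs + 1e-9 for w in stats_all) / 2**n
        p_ge = sum(w >= w_obs - 1e-9 for w in stats_all) / 2**n
        p_oracle = min(1.0, 2.0 * min(p_le, p_ge))
        assert wilcoxon_signed_rank_paired(a, b) == pytest.approx(p_oracle, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(23)
        a = rng.standard_normal(12)
        b = rng.standard_normal(12)
        p = wilcoxon_signed_rank_paired(a, b)
        p_sp = sps.wilcoxon(a, b, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(p_sp, abs=1e-12)

    def test_all_zero_differences_is_error(self):
        with pytest.raises(DegenerateInputError):
            wilcoxon_signed_rank_paired([1.0] * 6, [1.0] * 6)

    def test_too_few_informative_pairs_is_error(self):
        with pytest.raises(DegenerateInputError):
            wilcoxon_signed_rank_paired([1, 2, 3, 4.0], [0, 1, 2, 3.0])


class TestSignificantRanges:
    def test_all_significant_is_single_full_range(self):
        p = {t: 0.001 for t in range(1, 51)}
        assert significant_T_ranges(p) == [(1, 50)]

    def test_contiguous_block(self):
        p = {t: (0.001 if t in (2, 3, 4, 5) else 0.5) for t in range(1, 51)}
        assert significant_T_ranges(p) == [(2, 5)]

    def test_alternating_matches_scan_oracle(self):
        rng = np.random.default_rng(2)
        p = {t: float(rng.choice([0.001, 0.9])) for t in range(1, 51)}
        got = significant_T_ranges(p)
        flat = []
        for t in range(1, 51):
            if p[t] * 3 < 0.05:
                flat.append(t)
        oracle = []
        for t in flat:
            if oracle and oracle[-1][1] == t - 1:
                oracle[-1] = (oracle[-1][0], t)
            else:
                oracle.append((t, t))
        assert got == oracle

    def test_bonferroni_is_applied(self):
        # raw p = 0.02 -> corrected 0.06, not significant at 0.05
        assert significant_T_ranges({1: 0.02}) == []


class TestQuartiles:
    def test_cohort_tau_summaries(self):
        q = quartile_summary(reference.COHORT_TAU_STIM_S)
        assert q.median == pytest.approx(14.22)
        assert (q.q1, q.q3) == (pytest.approx(12.11), pytest.approx(34.605))
        assert q.mean == pytest.approx(23.35, abs=0.005)
        q2 = quartile_summary(reference.COHORT_TAU_REC_S)
        assert q2.median == pytest.approx(5.22)
        assert (q2.q1, q2.q3) == (pytest.approx(4.33), pytest.approx(6.035))
        assert q2.mean == pytest.approx(5.32, abs=0.005)

    def test_single_value(self):
        q = quartile_summary([7.0])
        assert q == (7.0, 7.0, 7.0, 7.0)

    def test_even_n_against_sort_interpolate_oracle(self):
        rng = np.random.default_rng(5)
        v = rng.standard_normal(10)
        q = quartile_summary(v)
        sv = np.sort(v)

        def interp(p):
            pos = p * (len(sv) - 1)
            lo = int(np.floor(pos))
            frac = pos - lo
            return sv[lo] * (1 - frac) + sv[min(lo + 1, len(sv) - 1)] * frac

        assert q.q1 == pytest.approx(interp(0.25), abs=1e-12)
        assert q.median == pytest.approx(interp(0.5), abs=1e-12)
        assert q.q3 == pytest.approx(interp(0.75), abs=1e-12)


class TestSDNN:
    def test_constant_series_is_zero(self):
        s = RRSeries.from_rr(np.full(10, 500.0))
        assert sdnn(s) == 0.0

    def test_two_beat_closed_form(self):
        s = RRSeries.from_rr(np.array([390.0, 410.0]))
        assert sdnn(s) == pytest.approx(math.sqrt(200.0))

    def test_reconstructed_beats_excluded(self):
        s = RRSeries.from_rr(np.array([400.0, 400.0, 4000.0, 400.0]))
        s.reconstructed[2] = True
        s.anchor_eligible[2] = False
        assert sdnn(s) == 0.0

    def test_matches_two_pass_oracle_in_window(self):
        rng = np.random.default_rng(44)
        s = RRSeries.from_rr(400 + 25 * rng.standard_normal(300))
        w = (20.0, 80.0)
        inside = (s.onset_time >= w[0]) & (s.onset_time <= w[1])
        vals = s.rr[inside]
        mean = vals.sum() / vals.size
        oracle = math.sqrt(((vals - mean) ** 2).sum() / (vals.size - 1))
        assert sdnn(s, w) == pytest.approx(oracle, abs=1e-12)

    def test_fewer_than_two_beats_is_error(self):
        s = RRSeries.from_rr(np.array([400.0]))
        with pytest.raises(DegenerateInputError):
            sdnn(s)
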