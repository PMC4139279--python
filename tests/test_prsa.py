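import numpy as np
import pytest

from fetalprsa import DegenerateInputError, RRSeries
from fetalprsa.prsa import (
    PRSAParams,
    capacity_spectrum,
    compute_capacity,
    compute_prsa_curve,
    select_anchor_points,
    t_to_cutoff_frequency,
)

from conftest import alternating_series, random_series


# ---------------------------------------------------------------------------
# Independent oracle: materialize every window, no shared code with the
# implementation under test.
# ---------------------------------------------------------------------------


def oracle_anchors(rr, T, L, mode, eligible=None):
    n = len(rr)
    m = max(T, L)
    out = []
    for i in range(m, n - m + 1):
        fwd = sum(rr[i : i + T]) / T
        bwd = sum(rr[i - T : i]) / T
        hit = fwd > bwd if mode == "deceleration" else fwd < bwd
        if hit and (eligible is None or eligible[i]):
            out.append(i)
    return out


def oracle_capacity(rr, anchors, L, s):
    windows = np.array([rr[a - L : a + L] for a in anchors])
    X = windows.mean(axis=0)
    return (X[L : L + s].sum() - X[L - s : L].sum()) / (2.0 * s)


class TestOracleEquivalence:
    def test_streaming_equals_materialized_windows(self):
        """AC/DC from the cumulative-sum path match a brute-force oracle."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            s = random_series(rng, n=500)
            T = int(rng.integers(1, 11))
            L = int(rng.integers(T, 15))
            for mode in ("deceleration", "acceleration"):
                params = PRSAParams(T=T, L=L, s=T, mode=mode, min_anchors=1)
                anchors = select_anchor_points(s, params)
                expected = oracle_anchors(s.rr, T, L, mode, s.anchor_eligible)
                assert list(anchors) == expected
                if not expected:
                    continue
                got = compute_capacity(compute_prsa_curve(s, anchors, params))
                want = oracle_capacity(s.rr, expected, L, T)
                assert got == pytest.approx(want, abs=1e-12)

    def test_spectrum_consistent_with_single_T_calls(self):
        rng = np.random.default_rng(7)
        s = random_series(rng, n=800)
        results = capacity_spectrum(s, range(1, 11), L=20, min_anchors=150)
        for r in results:
            p_dec = PRSAParams(T=r.T, L=20, s=r.T, mode="deceleration", min_anchors=150)
            anchors = select_anchor_points(s, p_dec)
            assert r.n_anchors_dec == anchors.size
            dc = compute_capacity(compute_prsa_curve(s, anchors, p_dec))
            assert r.dc_abs == pytest.approx(abs(dc), abs=1e-12)


class TestClosedForms:
    def test_alternating_series_capacity_equals_half_amplitude_swing(self):
        """For rr = a -+ b and T = s = 1, DC = |AC| = b."""
        s = alternating_series(a=400.0, b=10.0)
        for mode, sign in (("deceleration", 1.0), ("acceleration", -1.0)):
            params = PRSAParams(T=1, L=2, s=1, mode=mode, min_anchors=1)
            anchors = select_anchor_points(s, params)
            # deceleration anchors are exactly the interior high beats
            expected_parity = 1 if mode == "deceleration" else 0
            assert all(a % 2 == expected_parity for a in anchors)
            cap = compute_capacity(compute_prsa_curve(s, anchors, params))
            assert cap == pytest.approx(sign * 10.0, abs=1e-12)

    def test_alternating_curve_values(self):
        s = alternating_series(a=400.0, b=10.0)
        params = PRSAParams(T=1, L=2, s=1, mode="deceleration", min_anchors=1)
        curve = compute_prsa_curve(s, select_anchor_points(s, params), params)
        assert curve.x(0) == pytest.approx(410.0)
        assert curve.x(-1) == pytest.approx(390.0)
        assert curve.x(1) == pytest.approx(390.0)

    def test_scale_two_reduces_to_quarter_sum_formula(self):
        rng = np.random.default_rng(11)
        s = random_series(rng, n=600)
        params = PRSAParams(T=2, L=10, s=2, mode="deceleration", min_anchors=1)
        curve = compute_prsa_curve(s, select_anchor_points(s, params), params)
        manual = (curve.x(0) + curve.x(1) - curve.x(-1) - curve.x(-2)) / 4.0
        assert compute_capacity(curve) == pytest.approx(manual, abs=1e-12)

    def test_single_anchor_curve_is_the_window_verbatim(self):
        rng = np.random.default_rng(5)
        s = random_series(rng, n=100)
        params = PRSAParams(T=1, L=5, s=1, min_anchors=1)
        curve = compute_prsa_curve(s, [50], params)
        np.testing.assert_allclose(curve.values, s.rr[45:55])


class TestAnchorRules:
    def test_constant_series_has_no_anchors(self, constant_series):
        for mode in ("deceleration", "acceleration"):
            params = PRSAParams(T=3, L=10, s=3, mode=mode, min_anchors=1)
            assert select_anchor_points(constant_series, params).size == 0

    def test_all_ineligible_yields_no_anchors(self):
        rng = np.random.default_rng(1)
        s = random_series(rng, n=300)
        s.anchor_eligible[:] = False
        params = PRSAParams(T=2, L=10, s=2, min_anchors=1)
        assert select_anchor_points(s, params).size == 0

    def test_ineligible_values_still_enter_averages(self):
        rng = np.random.default_rng(9)
        s = random_series(rng, n=300)
        params = PRSAParams(T=3, L=10, s=3, min_anchors=1, apply_eligibility=True)
        base = select_anchor_points(s, params)
        # flag one non-anchor beat adjacent to an anchor: anchor list of
        # *other* beats must be unchanged (values still in the averages)
        victim = int(base[5]) - 1
        s.anchor_eligible[victim] = False
        after = select_anchor_points(s, params)
        assert set(after) == set(base) - {victim}

    def test_too_short_series_raises(self):
        s = RRSeries.from_rr(np.full(20, 400.0))
        with pytest.raises(DegenerateInputError):
            select_anchor_points(s, PRSAParams(T=1, L=20, s=1, min_anchors=1))

    def test_windows_do_not_cross_segment_boundaries_by_default(self):
        rng = np.random.default_rng(13)
        s = random_series(rng, n=200)
        s.segment_boundaries = np.array([100], dtype=np.int64)
        params = PRSAParams(T=2, L=10, s=2, min_anchors=1)
        anchors = select_anchor_points(s, params)
        assert all(10 <= a <= 90 or 110 <= a <= 190 for a in anchors)
        crossing = PRSAParams(T=2, L=10, s=2, min_anchors=1, allow_cross_boundary=True)
        wide = select_anchor_points(s, crossing)
        assert set(anchors) <= set(wide)
        assert any(90 < a < 110 for a in wide)


class TestInvariances:
    def test_offset_invariance_and_scale_equivariance(self):
        rng = np.random.default_rng(21)
        s = random_series(rng, n=400)
        params = PRSAParams(T=3, L=12, s=3, min_anchors=1, apply_eligibility=False)

        def cap(series):
            anchors = select_anchor_points(series, params)
            return compute_capacity(compute_prsa_curve(series, anchors, params))

        base = cap(s)
        shifted = RRSeries.from_rr(s.rr + 123.0)
        assert cap(shifted) == pytest.approx(base, abs=1e-12)
        scaled = RRSeries.from_rr(s.rr * 2.5)
        assert cap(scaled) == pytest.approx(2.5 * base, rel=1e-12)

    def test_time_reversal_duality(self):
        """|AC(x)| equals |DC(reverse(x))| with exclusion rules disabled."""
        rng = np.random.default_rng(31)
        s = random_series(rng, n=400)
        rev = RRSeries.from_rr(s.rr[::-1].copy())
        for T in (1, 2, 5):
            ac_p = PRSAParams(T=T, L=8, s=T, mode="acceleration",
                              min_anchors=1, apply_eligibility=False)
            dc_p = PRSAParams(T=T, L=8, s=T, mode="deceleration",
                              min_anchors=1, apply_eligibility=False)
            ac = compute_capacity(
                compute_prsa_curve(s, select_anchor_points(s, ac_p), ac_p)
            )
            dc_rev = compute_capacity(
                compute_prsa_curve(rev, select_anchor_points(rev, dc_p), dc_p)
            )
            assert abs(ac) == pytest.approx(abs(dc_rev), abs=1e-12)


class TestSpectrum:
    def test_full_T_range_cardinality(self):
        rng = np.random.default_rng(4)
        s = random_series(rng, n=3000)
        results = capacity_spectrum(s, range(1, 51), L=50, min_anchors=150)
        assert len(results) == 50
        assert sum(r.reliable_dec for r in results) == 50

    def test_low_anchor_count_flagged_not_dropped(self):
        rng = np.random.default_rng(4)
        s = random_series(rng, n=220)
        results = capacity_spectrum(s, [5], L=50, min_anchors=150)
        (r,) = results
        assert r.n_anchors_dec <= 150 and not r.reliable_dec
        assert np.isfinite(r.dc_abs)


class TestCutoffFrequency:
    @pytest.mark.parametrize("T, expected", [(1, 1.25), (4, 0.3125)])
    def test_adopted_formula(self, T, expected):
        assert t_to_cutoff_frequency(T, 0.4) == pytest.approx(expected)

    def test_doubling_T_halves_cutoff(self):
        assert t_to_cutoff_frequency(10, 0.5) == pytest.approx(
            t_to_cutoff_frequency(5, 0.5) / 2.0
        )
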