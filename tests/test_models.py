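"""The three association tests against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from poolassoc.data import PoolDesign
from poolassoc.models import (DispersionFit, eb1_test, eb2_test,
                              fisher_exact_2x2, fisher_test, odds_ratio,
                              pearson_chi2_2x2)

from conftest import make_counts


def _swap_design(design):
    swap = {"case": "control", "control": "case"}
    return PoolDesign(design.pool_ids,
                      tuple(swap[g] for g in design.group), design.s)


# ---------------------------------------------------------------------------
# Fisher
# ---------------------------------------------------------------------------

class TestFisherExact:
    def test_brute_force_hypergeometric_all_small_tables(self):
        """p equals the direct hypergeometric summation for every 2x2
        table with margins <= 30."""
        from math import comb
        rng = np.random.default_rng(0)
        checked = 0
        for _ in range(400):
            a, b, c, d = rng.integers(0, 16, size=4)
            M, n1, K = a + b + c + d, a + b, a + c
            if M == 0 or M > 60:
                continue
            # enumerate the conditional distribution exactly
            lo, hi = max(0, n1 + K - M), min(n1, K)
            pmf = np.array([comb(K, x) * comb(M - K, n1 - x) / comb(M, n1)
                            for x in range(lo, hi + 1)])
            p_obs = pmf[a - lo]
            p_exact = pmf[pmf <= p_obs * (1 + 1e-7)].sum()
            table = np.array([[a, b], [c, d]], dtype=float)
            assert fisher_exact_2x2(table) == pytest.approx(p_exact, abs=1e-10)
            checked += 1
        assert checked > 200

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            t = rng.integers(0, 200, size=(2, 2)).astype(float)
            assert fisher_exact_2x2(t) == pytest.approx(
                stats.fisher_exact(t)[1], rel=1e-9, abs=1e-12)

    def test_single_pool_example(self):
        # 1 valid pool per group, s = 96: table [[90, 96], [6, 0]]
        t = np.array([[90.0, 96.0], [6.0, 0.0]])
        assert fisher_exact_2x2(t) == pytest.approx(
            stats.fisher_exact(t)[1], rel=1e-9)


class TestFisherTest:
    def test_identical_groups_p_one(self, design4):
        c = make_counts([[90, 90, 90, 90]], [[100, 100, 100, 100]],
                        design4.pool_ids)
        r = fisher_test(c, design4)[0]
        assert r.p_value == pytest.approx(1.0)
        assert r.statistic == pytest.approx(1.0)  # odds ratio

    def test_label_swap_invariance(self, design4, counts4):
        p1 = [r.p_value for r in fisher_test(counts4, design4)]
        p2 = [r.p_value for r in fisher_test(counts4, _swap_design(design4))]
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_chromosome_counts_rounded_from_unweighted_mean(self, design4):
        # control pools: freqs 0.9 and 0.8 -> mean 0.85 -> 17 of 20
        c = make_counts([[45, 72, 36, 63]], [[50, 90, 40, 70]],
                        design4.pool_ids)
        r = fisher_test(c, design4)[0]
        assert r.table[0, 0] == 17  # major chromosomes, control
        assert r.table[:, 0].sum() == 2 * design4.s

    def test_no_valid_pool_excluded(self, design4):
        c = make_counts([[0, 0, 90, 90]], [[0, 0, 100, 100]],
                        design4.pool_ids)
        r = fisher_test(c, design4)[0]
        assert r.status == "excluded"

    def test_coverage_mask_restricts_pools(self, design4):
        c = make_counts([[45, 0, 36, 63]], [[50, 100, 40, 70]],
                        design4.pool_ids)
        mask = np.array([[True, False, True, True]])
        r = fisher_test(c, design4, coverage_mask=mask)[0]
        assert r.p_hat_control == pytest.approx(0.9)  # pool c2 ignored


# ---------------------------------------------------------------------------
# EB1 (Williams)
# ---------------------------------------------------------------------------

class TestEB1:
    def _design(self, n_per_group, s=100):
        n = 2 * n_per_group
        return PoolDesign(
            tuple(f"p{i}" for i in range(n)),
            tuple(["control"] * n_per_group + ["case"] * n_per_group),
            s=s,
        )

    def test_pure_binomial_phi_near_zero_and_calibrated(self):
        """On binomial data phi should be ~0 on average and the test
        should hold its nominal level within Monte-Carlo error."""
        rng = np.random.default_rng(11)
        design = self._design(10)
        n_snps, depth = 400, 500
        R = np.full((n_snps, 20), float(depth))
        y = rng.binomial(depth, 0.9, size=(n_snps, 20)).astype(float)
        c = make_counts(y, R, design.pool_ids,
                        snp_ids=[f"s{i}" for i in range(n_snps)])
        results, fits = eb1_test(c, design)
        phis = np.array([f.phi for f in fits if f is not None])
        # phi is floored at zero; under the null most fits sit on the
        # floor and the mean stays far below any real heterogeneity
        assert np.median(phis) == 0.0
        assert phis.mean() < 1e-3
        ps = np.array([r.p_value for r in results if r.status == "tested"])
        rate = (ps < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(ps))
        assert rate < 0.05 + 3 * se + 0.01

    def test_phi_zero_reduces_to_plain_score_test(self, design4):
        """With phi = 0 the statistic equals the Pearson-X2 difference
        of the two plain logistic fits computed independently."""
        y = np.array([[45.0, 80.0, 30.0, 60.0]])
        R = np.array([[50.0, 90.0, 40.0, 70.0]])
        c = make_counts(y, R, design4.pool_ids)
        results, fits = eb1_test(c, design4)
        f = fits[0]
        if f.phi == 0.0:
            # independent plain-GLM computation
            def x2(groups):
                tot = 0.0
                for idx in groups:
                    pi = y[0, idx].sum() / R[0, idx].sum()
                    tot += (((y[0, idx] - R[0, idx] * pi) ** 2)
                            / (R[0, idx] * pi * (1 - pi))).sum()
                return tot
            full = x2([[0, 1], [2, 3]])
            null = x2([[0, 1, 2, 3]])
            assert results[0].statistic == pytest.approx(null - full, abs=1e-9)

    def test_zero_minor_reads_in_group_excluded(self, design4):
        c = make_counts([[50, 90, 30, 60]], [[50, 90, 40, 70]],
                        design4.pool_ids)
        r, _ = eb1_test(c, design4)
        assert r[0].status == "excluded"
        assert "control" in r[0].reason

    def test_delta_x2_nonnegative_and_label_invariant(self, rng):
        design = self._design(5, s=50)
        for _ in range(20):
            R = rng.integers(20, 400, size=(1, 10)).astype(float)
            q = rng.uniform(0.02, 0.3)
            y = R - rng.binomial(R.astype(int), q)
            c = make_counts(y.astype(float), R, design.pool_ids)
            res, fits = eb1_test(c, design)
            if res[0].status != "tested":
                continue
            assert res[0].statistic >= -1e-8
            # the group means solve the quasi-score, not a least-squares
            # problem, so X2_null may dip below X2_full by a hair
            assert fits[0].X2_null >= fits[0].X2_full - 0.02
            res_sw, _ = eb1_test(c, _swap_design(design))
            assert res_sw[0].p_value == pytest.approx(res[0].p_value, abs=1e-9)

    def test_overdispersed_data_gets_positive_phi(self):
        rng = np.random.default_rng(4)
        design = self._design(10)
        R = np.full((1, 20), 2000.0)
        q = rng.beta(8, 32, size=20)  # pool-to-pool frequency heterogeneity
        y = R - rng.binomial(2000, q)
        c = make_counts(y.astype(float), R, design.pool_ids)
        _, fits = eb1_test(c, design)
        assert fits[0].phi > 0


# ---------------------------------------------------------------------------
# EB2
# ---------------------------------------------------------------------------

class TestEB2:
    def test_identity_adjustment_reduces_to_pearson(self, design4):
        """(a, b) making R* = R turns EB2 into the plain chi-square on
        the raw pooled table (verified against a hand-computed value)."""
        R0 = 100.0
        y = np.array([[90.0, 85.0, 80.0, 75.0]])
        R = np.full((1, 4), R0)
        c = make_counts(y, R, design4.pool_ids)
        # a = 0, b = s/R0  =>  R* = s R /(b R) = R0
        fit = DispersionFit.from_params(a=0.0, b=design4.s / R0, s=design4.s)
        r = eb2_test(c, design4, fit)[0]
        raw = np.array([[175.0, 155.0], [25.0, 45.0]])
        # hand-computed Pearson chi-square of the raw table
        expected = 400 * (175 * 45 - 155 * 25) ** 2 / (330 * 70 * 200 * 200)
        assert r.statistic == pytest.approx(expected, abs=1e-10)
        assert r.statistic == pytest.approx(
            stats.chi2_contingency(raw, correction=False)[0], abs=1e-10)

    def test_identical_pools_statistic_zero(self, design4):
        c = make_counts([[90, 90, 90, 90]], [[100, 100, 100, 100]],
                        design4.pool_ids)
        fit = DispersionFit.from_params(a=1.0, b=1.0, s=design4.s)
        r = eb2_test(c, design4, fit)[0]
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_four_pool_toy_spreadsheet_oracle(self, design4):
        """Statistic equals a step-by-step scalar computation to 1e-10."""
        y = [45.0, 80.0, 30.0, 60.0]
        R = [50.0, 90.0, 40.0, 70.0]
        a, b, s = 0.7, 2.0, 10
        # independent spreadsheet-style arithmetic
        tbl = np.zeros((2, 2))
        for j, (yy, rr) in enumerate(zip(y, R)):
            rstar = s * rr / (a * s + b * rr)
            ph = yy / rr
            col = 0 if j < 2 else 1
            tbl[0, col] += ph * rstar
            tbl[1, col] += (1 - ph) * rstar
        N = tbl.sum()
        det = tbl[0, 0] * tbl[1, 1] - tbl[0, 1] * tbl[1, 0]
        expected = (N * det * det
                    / (tbl.sum(1)[0] * tbl.sum(1)[1] * tbl.sum(0)[0] * tbl.sum(0)[1]))
        c = make_counts([y], [R], design4.pool_ids)
        fit = DispersionFit.from_params(a=a, b=b, s=s)
        r = eb2_test(c, design4, fit)[0]
        assert r.statistic == pytest.approx(expected, abs=1e-10)

    def test_statistic_nonincreasing_in_b(self, design4, counts4):
        """Growing b shrinks adjusted depths and the statistic."""
        stats_by_b = []
        for b in [0.5, 1.0, 2.0, 5.0, 20.0]:
            fit = DispersionFit.from_params(a=1.0, b=b, s=design4.s)
            stats_by_b.append(eb2_test(counts4, design4, fit)[0].statistic)
        assert all(s1 >= s2 - 1e-12
                   for s1, s2 in zip(stats_by_b, stats_by_b[1:]))

    def test_label_and_orientation_invariance(self, design4, counts4):
        fit = DispersionFit.from_params(a=0.9, b=1.5, s=design4.s)
        base = eb2_test(counts4, design4, fit)
        swapped = eb2_test(counts4, _swap_design(design4), fit)
        for r1, r2 in zip(base, swapped):
            assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)
        flipped = counts4.copy()
        flipped.major_reads = flipped.depth - flipped.major_reads
        for r1, r2 in zip(base, eb2_test(flipped, design4, fit)):
            assert r1.statistic == pytest.approx(r2.statistic, abs=1e-9)

    def test_negative_adjusted_depth_drops_pool(self, design4):
        # b < 0 makes R* negative at high depth
        fit = DispersionFit.from_params(a=1.0, b=-2.0, s=design4.s)
        c = make_counts([[45, 80, 30, 60]], [[50, 90, 40, 70]],
                        design4.pool_ids)
        r = eb2_test(c, design4, fit)[0]
        assert r.status == "excluded"

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(a=st.floats(0.1, 3.0), b=st.floats(0.1, 20.0))
    def test_continuity_in_ab(self, a, b):
        design = PoolDesign(("c1", "c2", "t1", "t2"),
                            ("control", "control", "case", "case"), s=10)
        c = make_counts([[45, 80, 30, 60]], [[50, 90, 40, 70]],
                        design.pool_ids)
        s0 = eb2_test(c, design, DispersionFit.from_params(a, b, 10))[0].statistic
        s1 = eb2_test(c, design,
                      DispersionFit.from_params(a * (1 + 1e-9), b, 10))[0].statistic
        assert s1 == pytest.approx(s0, rel=1e-6)


class TestOddsRatio:
    @pytest.mark.parametrize("ctrl,case,expected", [
        (0.53, 0.41, 0.62),
        (0.043, 0.011, 0.25),
        (0.13, 0.082, 0.60),
        (0.093, 0.15, 1.72),
        (0.0025, 0.020, 8.14),
        (0.23, 0.32, 1.58),
        (0.11, 0.084, 0.74),
    ])
    def test_reported_values(self, ctrl, case, expected):
        assert round(odds_ratio(ctrl, case), 2) == pytest.approx(expected)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(x=st.floats(0.001, 0.999))
    def test_identity(self, x):
        assert odds_ratio(x, x) == pytest.approx(1.0, rel=1e-9)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.3])
    def test_boundary_rejected(self, bad):
        with pytest.raises(ValueError):
            odds_ratio(bad, 0.5)
        with pytest.raises(ValueError):
            odds_ratio(0.5, bad)


def test_pearson_chi2_empty_margin_zero():
    assert pearson_chi2_2x2(np.array([[0.0, 0.0], [3.0, 4.0]])) == 0.0
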