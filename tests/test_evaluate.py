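"""Evaluation machinery: TDR curves, baselines, recovery metrics."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from methsingle.dmr import DmrRegion
from methsingle.errors import ValidationError
from methsingle.evaluate import (
    TdrCurve,
    fisher_baseline,
    meandiff_baseline,
    recovery_metrics,
    region_tdr,
    site_tdr,
    true_dml_mask,
)
from methsingle.io import CountPair, SiteCounts
from methsingle.simulate import SimTruth
from methsingle.smoothing import smooth_moving_average


def fisher_two_sided_oracle(x1, n1, x2, n2):
    """Independent oracle: hypergeometric enumeration of the two-sided p.

    Sums P(K = k) over all tables with the observed margins whose
    probability does not exceed the observed one (with the customary
    1 + 1e-7 relative slack for floating-point ties).
    """
    M, n, N = n1 + n2, x1 + x2, n1
    kmin, kmax = max(0, n - n2), min(n, n1)
    ks = np.arange(kmin, kmax + 1)
    pmf = hypergeom.pmf(ks, M, n, N)
    p_obs = hypergeom.pmf(x1, M, n, N)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def simple_truth(positions, mu1, mu2, intervals):
    return SimTruth(
        chrom="chr1",
        positions=np.asarray(positions),
        mu_true_1=np.asarray(mu1, dtype=float),
        mu_true_2=np.asarray(mu2, dtype=float),
        dmr_intervals=intervals,
        span=500,
        seed=0,
    )


class TestSiteTdr:
    def test_hand_example(self):
        """10 sites, 3 true ones ranked 1st, 2nd and 5th -> TDR(5) = 0.6."""
        truth = np.zeros(10, dtype=bool)
        ranking = np.array([3, 7, 0, 1, 9, 2, 4, 5, 6, 8])
        truth[[3, 7, 9]] = True
        curve = site_tdr(ranking, truth, k_grid=[5, 10])
        assert curve.tdr[0] == pytest.approx(0.6)
        assert curve.tdr[1] == pytest.approx(0.3)

    def test_perfect_ranking(self):
        truth = np.array([True] * 5 + [False] * 5)
        curve = site_tdr(np.arange(10), truth, k_grid=[5])
        assert curve.tdr[0] == 1.0

    def test_random_ranking_matches_base_rate(self, rng):
        truth = rng.random(20_000) < 0.1
        tdrs = []
        for _ in range(10):
            order = rng.permutation(len(truth))
            tdrs.append(site_tdr(order, truth, k_grid=[2000]).tdr[0])
        se = np.sqrt(0.1 * 0.9 / 2000)
        assert abs(np.mean(tdrs) - truth.mean()) < 3 * se

    def test_unknown_site_rejected(self):
        with pytest.raises(ValidationError):
            site_tdr(np.array([0, 99]), np.zeros(10, dtype=bool))


def mk_region(start, end, area=10.0, chrom="chr1"):
    return DmrRegion(
        chrom=chrom, start=start, end=end, n_cpg=5, n_sig=4,
        mean_mu1=0.8, mean_mu2=0.2, mean_diff=0.6, area_stat=area,
    )


class TestRegionTdr:
    def test_exact_match_gives_unity(self):
        truth = simple_truth([100], [0.5], [0.9], [(1000, 1999, (0, 0))])
        curve = region_tdr([mk_region(1000, 1999)], truth)
        assert curve.tdr[0] == 1.0
        assert curve.axis[0] == 1000

    def test_half_overlap(self):
        truth = simple_truth([100], [0.5], [0.9], [(1000, 1999, (0, 0))])
        curve = region_tdr([mk_region(1500, 2499)], truth)
        assert curve.tdr[0] == pytest.approx(0.5)

    def test_cumulative_walk(self):
        truth = simple_truth([100], [0.5], [0.9], [(1000, 1999, (0, 0))])
        regions = [mk_region(1000, 1999, area=20.0), mk_region(5000, 5999, area=5.0)]
        curve = region_tdr(regions, truth)
        assert curve.tdr[-1] == pytest.approx(0.5)

    def test_overlapping_regions_rejected(self):
        truth = simple_truth([100], [0.5], [0.9], [])
        with pytest.raises(ValidationError):
            region_tdr([mk_region(1000, 1999), mk_region(1500, 2499)], truth)

    def test_empty_ranking(self):
        truth = simple_truth([100], [0.5], [0.9], [])
        curve = region_tdr([], truth)
        assert len(curve.axis) == 0

    def test_at_clamps_to_curve_ends(self):
        curve = TdrCurve(np.array([100.0, 200.0]), np.array([1.0, 0.5]))
        assert curve.at(50) == 1.0  # below the first prefix
        assert curve.at(150) == 1.0
        assert curve.at(10_000) == 0.5


class TestFisherBaseline:
    @staticmethod
    def pair_from_tables(tables):
        pos = np.arange(1, len(tables) + 1) * 100
        g1 = SiteCounts.from_arrays(
            "chr1", pos, [t[1] for t in tables], [t[0] for t in tables]
        )
        g2 = SiteCounts.from_arrays(
            "chr1", pos, [t[3] for t in tables], [t[2] for t in tables]
        )
        return CountPair(g1, g2)

    def test_identical_margins_give_unity(self):
        p = fisher_baseline(self.pair_from_tables([(5, 10, 5, 10)]))
        assert p[0] == pytest.approx(1.0)

    def test_extreme_table(self):
        # [[10,0],[0,10]]: p = 2 / C(20,10)
        p = fisher_baseline(self.pair_from_tables([(10, 10, 0, 10)]))
        assert p[0] == pytest.approx(2.0 / 184_756, rel=1e-9)

    def test_row_swap_invariance(self):
        a = fisher_baseline(self.pair_from_tables([(7, 12, 2, 9)]))
        b = fisher_baseline(self.pair_from_tables([(2, 9, 7, 12)]))
        assert a[0] == pytest.approx(b[0], rel=1e-12)

    def test_zero_coverage_undefined(self):
        p = fisher_baseline(self.pair_from_tables([(0, 0, 3, 10)]))
        assert np.isnan(p[0])

    def test_matches_hypergeometric_enumeration(self, rng):
        """All random tables with N <= 30 agree with the oracle to 1e-12."""
        tables = []
        for _ in range(300):
            n1 = int(rng.integers(1, 31))
            n2 = int(rng.integers(1, 31))
            x1 = int(rng.integers(0, n1 + 1))
            x2 = int(rng.integers(0, n2 + 1))
            tables.append((x1, n1, x2, n2))
        got = fisher_baseline(self.pair_from_tables(tables))
        want = np.array([fisher_two_sided_oracle(*t) for t in tables])
        np.testing.assert_allclose(got, want, atol=1e-12)


class TestMeandiffBaseline:
    @staticmethod
    def smoothed(pos, n, x):
        return smooth_moving_average(
            SiteCounts.from_arrays("chr1", pos, n, x), half_width=50
        )

    def test_identical_curves_score_zero(self):
        m = self.smoothed([100, 200], [10, 10], [5, 5])
        assert np.allclose(meandiff_baseline(m, m), 0.0)

    def test_differing_site_ranks_first(self):
        pos = [100, 1000, 2000]
        m1 = self.smoothed(pos, [10, 10, 10], [5, 5, 5])
        m2 = self.smoothed(pos, [10, 10, 10], [5, 8, 5])
        scores = meandiff_baseline(m1, m2)
        assert np.argmax(scores) == 1

    def test_swap_invariant(self):
        pos = [100, 1000]
        m1 = self.smoothed(pos, [10, 10], [2, 9])
        m2 = self.smoothed(pos, [10, 10], [7, 3])
        np.testing.assert_allclose(
            meandiff_baseline(m1, m2), meandiff_baseline(m2, m1)
        )


class TestRecoveryMetrics:
    def test_perfect_estimate(self):
        r, mse = recovery_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r, mse) == (pytest.approx(1.0), 0.0)

    def test_anticorrelated(self):
        r, _ = recovery_metrics([3.0, 2.0, 1.0], [1.0, 2.0, 3.0])
        assert r == pytest.approx(-1.0)

    def test_hand_mse(self):
        _, mse = recovery_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert mse == pytest.approx(1.0 / 3.0)

    def test_nan_entries_excluded(self):
        r, mse = recovery_metrics([1.0, np.nan, 3.0], [1.0, 2.0, 3.0])
        assert (r, mse) == (pytest.approx(1.0), 0.0)

    def test_underdetermined_is_nan(self):
        r, mse = recovery_metrics([1.0], [2.0])
        assert np.isnan(r) and np.isnan(mse)


class TestTrueDmlMask:
    def test_requires_interval_membership_and_effect(self):
        truth = simple_truth(
            [100, 200, 300],
            [0.5, 0.5, 0.5],
            [0.9, 0.505, 0.9],
            [(100, 200, (0, 1))],
        )
        mask = true_dml_mask(truth)
        # site 0: in interval, big effect; site 1: in interval, tapered to
        # nothing; site 2: big effect but outside any interval
        assert mask.tolist() == [True, False, False]
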