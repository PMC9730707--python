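import numpy as np
import pytest

from lysiphen.drydown import (
    aggregate_replicates,
    bootstrap_uncertainty,
    conditional_ls,
    dynamic_period_points,
    fit_piecewise,
    hinge_predict,
)
from lysiphen.errors import AggregationError, DegeneratePartitionError, FitError

from conftest import hinge


def _noisy(seed, sd=0.05, a=1.0, k=3.0, theta=0.15, n=26):
    rng = np.random.default_rng(seed)
    v = np.linspace(0.30, 0.05, n)
    y = np.clip(hinge(v, a, k, theta) + rng.normal(0, sd * a, n), 0, None)
    return np.column_stack([v, y])


def _grid_argmin(pts, n_grid):
    """Independent exhaustive-search oracle for the profile-RSS breakpoint."""
    v = pts[:, 0]
    vs = np.sort(v)
    grid = np.linspace(vs[1], vs[-2], n_grid)
    best_theta, best_rss = None, np.inf
    for th in grid:
        try:
            rss = conditional_ls(pts, th)[2]
        except DegeneratePartitionError:
            continue
        if rss < best_rss:
            best_theta, best_rss = th, rss
    return best_theta, grid[1] - grid[0]


class TestConditionalLs:
    def test_exact_model_at_true_breakpoint(self, exact_hinge_points):
        a, k, rss = conditional_ls(exact_hinge_points, 0.15)
        assert a == pytest.approx(1.0, abs=1e-12)
        assert k == pytest.approx(3.0, abs=1e-9)
        assert rss == pytest.approx(0.0, abs=1e-18)

    def test_misplaced_breakpoint_has_positive_rss(self, exact_hinge_points):
        _, _, rss = conditional_ls(exact_hinge_points, 0.10)
        assert rss > 1e-6

    def test_flat_data(self):
        v = np.linspace(0.05, 0.30, 12)
        pts = np.column_stack([v, np.full(12, 0.8)])
        a, k, rss = conditional_ls(pts, 0.15)
        assert (a, k) == (pytest.approx(0.8), pytest.approx(0.0, abs=1e-12))
        assert rss == pytest.approx(0.0, abs=1e-18)

    def test_degenerate_partition_rejected(self, exact_hinge_points):
        with pytest.raises(DegeneratePartitionError):
            conditional_ls(exact_hinge_points, 0.06)  # single point below


class TestFitPiecewise:
    def test_exact_recovery_of_generating_parameters(self, exact_hinge_points):
        f = fit_piecewise(exact_hinge_points)
        assert f.theta_cri == pytest.approx(0.15, rel=1e-4)
        assert f.a == pytest.approx(1.0, rel=1e-4)
        assert f.k == pytest.approx(3.0, rel=1e-4)
        assert f.r2 == pytest.approx(1.0, abs=1e-9)
        assert f.converged

    @pytest.mark.parametrize("a,k,theta", [(0.5, 2.0, 0.12), (2.0, 8.0, 0.20), (0.08, 4.6, 0.141)])
    def test_exact_recovery_across_parameterisations(self, a, k, theta):
        v = np.linspace(0.29, 0.04, 30)
        f = fit_piecewise(np.column_stack([v, hinge(v, a, k, theta)]))
        assert f.theta_cri == pytest.approx(theta, rel=1e-4)
        assert f.k == pytest.approx(k, rel=1e-4)

    def test_noisy_breakpoint_near_truth_and_matches_dense_grid(self):
        pts = _noisy(seed=42)
        f = fit_piecewise(pts)
        assert abs(f.theta_cri - 0.15) < 0.02
        oracle_theta, cell = _grid_argmin(pts, 10_000)
        assert abs(f.theta_cri - oracle_theta) <= cell

    def test_breakpoint_stays_interior(self):
        pts = _noisy(seed=7, sd=0.15)
        f = fit_piecewise(pts)
        v = pts[:, 0]
        assert v.min() < f.theta_cri < v.max()

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_piecewise(_noisy(seed=1)[:5])

    def test_r2_improves_as_noise_shrinks(self):
        """Mean R² at low noise exceeds mean R² at high noise (200 reps each)."""
        r2 = {}
        for sd in (0.02, 0.08):
            vals = [fit_piecewise(_noisy(seed=s, sd=sd), grid_resolution=60, refine=False).r2
                    for s in range(200)]
            r2[sd] = np.mean(vals)
        assert r2[0.02] > r2[0.08]


class TestBootstrap:
    def test_noiseless_data_has_null_spread(self, exact_hinge_points):
        se_a, se_k, se_theta = bootstrap_uncertainty(exact_hinge_points, n_boot=30, seed=1)
        assert se_a == pytest.approx(0.0, abs=1e-6)
        assert se_theta == pytest.approx(0.0, abs=1e-4)

    def test_seeded_determinism(self):
        pts = _noisy(seed=3)
        r1 = bootstrap_uncertainty(pts, n_boot=50, seed=9)
        r2 = bootstrap_uncertainty(pts, n_boot=50, seed=9)
        assert r1 == r2

    def test_se_theta_tracks_monte_carlo_spread(self):
        """Bootstrap SE within a factor 2 of the true sampling sd of θ̂."""
        mc = [fit_piecewise(_noisy(seed=1000 + s), grid_resolution=80).theta_cri
              for s in range(120)]
        mc_sd = np.std(mc, ddof=1)
        _, _, se_theta = bootstrap_uncertainty(_noisy(seed=5), n_boot=120, seed=2, grid_resolution=80)
        assert 0.5 * mc_sd <= se_theta <= 2.0 * mc_sd


class TestAggregateReplicates:
    def _fit(self, theta, k=3.0):
        return fit_piecewise(
            np.column_stack([np.linspace(0.30, 0.05, 26),
                             hinge(np.linspace(0.30, 0.05, 26), 1.0, k, theta)])
        )

    def test_hand_arithmetic(self):
        fits = [self._fit(t) for t in (0.14, 0.15, 0.16)]
        agg = aggregate_replicates(fits, group="demo")
        row = agg[agg["parameter"] == "theta_cri"].iloc[0]
        assert row["mean"] == pytest.approx(0.15, abs=1e-4)
        assert row["sd"] == pytest.approx(0.01, abs=1e-4)
        assert row["n"] == 3

    def test_identical_replicates_zero_sd(self):
        fits = [self._fit(0.15) for _ in range(3)]
        agg = aggregate_replicates(fits)
        assert np.allclose(agg[agg["parameter"] == "theta_cri"]["sd"], 0.0, atol=1e-9)

    def test_single_fit_rejected(self):
        with pytest.raises(AggregationError):
            aggregate_replicates([self._fit(0.15)])


class TestDynamicPeriodPoints:
    def test_static_tail_excluded(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "pot_id": "p",
                "date": pd.date_range("2022-04-01", periods=8).date,
                "phase": "progressive_drought",
                "vwc_m": [0.30, 0.28, 0.26, 0.24, 0.235, 0.2345, 0.2344, 0.2343],
                "tr_m_vpd": 1.0,
            }
        )
        pts = dynamic_period_points(df, min_daily_drop=0.0015)
        assert len(pts) == 5  # first day kept, tail of <0.0015 drops excluded

    def test_prediction_matches_hinge(self, exact_hinge_points):
        f = fit_piecewise(exact_hinge_points)
        v = exact_hinge_points[:, 0]
        assert np.allclose(f.predict(v), hinge_predict(v, f.a, f.k, f.theta_cri))
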