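"""Rejection acceptance rule, likelihood surfaces, bounds, profile CIs."""

import numpy as np
import pandas as pd
import pytest

from imabc.coalsim import (
    ISOLATION,
    ONGOING_MIGRATION,
    SECONDARY_CONTACT,
    LocusSpec,
    ModelParams,
)
from imabc.demolik import (
    GridSpec,
    LikelihoodSurface,
    RejectionConfig,
    accept,
    approx_lnL,
    grid_search,
    profile_ci,
    zero_acceptance_bound,
)
from imabc.sumstats import WHStats


@pytest.fixture
def small_specs():
    return [LocusSpec(f"l{i}", length=150, n_west=6, n_east=6) for i in range(4)]


@pytest.fixture
def small_obs(small_specs, mu):
    """Observed statistics simulated once at a known parameter point."""
    from imabc.coalsim import simulate_wh_dataset

    p = ModelParams(ONGOING_MIGRATION, theta=0.004, T_gen=4e6, m=1.0)
    arr = simulate_wh_dataset(p, small_specs, mu, 123)
    return WHStats(*(int(v) for v in arr))


class TestAcceptRule:
    def test_within_componentwise_bounds(self):
        cfg = RejectionConfig(epsilon_pct=25.0, n_sims=10)
        obs = WHStats(10, 8, 5, 2)
        assert accept(WHStats(12, 7, 4, 2), obs, cfg)

    def test_one_component_outside_rejects(self):
        cfg = RejectionConfig(epsilon_pct=25.0, n_sims=10)
        obs = WHStats(10, 8, 5, 2)
        assert not accept(WHStats(13, 8, 5, 2), obs, cfg)  # 13 > 12.5

    def test_exact_match_accepted_any_epsilon(self):
        obs = WHStats(10, 8, 5, 2)
        for eps in (0.001, 1.0, 25.0):
            assert accept(obs, obs, RejectionConfig(epsilon_pct=eps, n_sims=10))

    def test_total_sum_mode(self):
        cfg = RejectionConfig(epsilon_pct=25.0, n_sims=10, acceptance_mode="total_sum")
        obs = WHStats(10, 8, 5, 2)  # total 25, band [18.75, 31.25]
        assert accept(WHStats(0, 0, 0, 19), obs, cfg)
        assert not accept(WHStats(0, 0, 0, 32), obs, cfg)

    def test_zero_observed_component_requires_zero(self):
        cfg = RejectionConfig(epsilon_pct=25.0, n_sims=10)
        obs = WHStats(10, 8, 5, 0)
        assert accept(WHStats(10, 8, 5, 0), obs, cfg)
        assert not accept(WHStats(10, 8, 5, 1), obs, cfg)


class TestZeroAcceptanceBound:
    def test_study_bound(self):
        bound = zero_acceptance_bound(1_000_000)
        assert bound == pytest.approx(-13.8155, abs=5e-4)

    def test_hand_values(self):
        assert zero_acceptance_bound(40_000) == pytest.approx(-10.5966, abs=5e-4)
        assert zero_acceptance_bound(1) == 0.0

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            zero_acceptance_bound(0)


class TestApproxLnL:
    def test_lnl_consistent_with_acceptance_count(self, small_obs, small_specs, mu):
        p = ModelParams(ONGOING_MIGRATION, theta=0.004, T_gen=4e6, m=1.0)
        cfg = RejectionConfig(n_sims=500, rng_seed=9)
        n_acc, lnl, is_bound = approx_lnL(small_obs, p, small_specs, mu, cfg)
        if n_acc:
            assert lnl == pytest.approx(np.log(n_acc / cfg.n_sims))
            assert not is_bound
        else:
            assert lnl == zero_acceptance_bound(cfg.n_sims)
            assert is_bound

    def test_bit_reproducible(self, small_obs, small_specs, mu):
        p = ModelParams(ONGOING_MIGRATION, theta=0.004, T_gen=4e6, m=1.0)
        cfg = RejectionConfig(n_sims=400, rng_seed=5)
        first = approx_lnL(small_obs, p, small_specs, mu, cfg)
        second = approx_lnL(small_obs, p, small_specs, mu, cfg)
        assert first == second

    def test_monotone_in_epsilon(self, small_obs, small_specs, mu):
        """Same seeds: widening the tolerance can only add acceptances."""
        p = ModelParams(ONGOING_MIGRATION, theta=0.004, T_gen=4e6, m=1.0)
        counts = [
            approx_lnL(
                small_obs,
                p,
                small_specs,
                mu,
                RejectionConfig(epsilon_pct=eps, n_sims=400, rng_seed=3),
            )[0]
            for eps in (10.0, 25.0, 50.0)
        ]
        assert counts[0] <= counts[1] <= counts[2]

    def test_acceptance_rate_unbiased(self, small_obs, small_specs, mu):
        """Replicate acceptance rates bracket a long-run reference."""
        p = ModelParams(ONGOING_MIGRATION, theta=0.004, T_gen=4e6, m=1.0)
        ref_cfg = RejectionConfig(n_sims=20_000, rng_seed=1000)
        ref_acc, _, _ = approx_lnL(small_obs, p, small_specs, mu, ref_cfg)
        p_ref = ref_acc / ref_cfg.n_sims
        reps = [
            approx_lnL(
                small_obs, p, small_specs, mu, RejectionConfig(n_sims=500, rng_seed=r)
            )[0]
            / 500
            for r in range(30)
        ]
        n_total = 30 * 500
        se = np.sqrt(p_ref * (1 - p_ref) / n_total + p_ref * (1 - p_ref) / ref_cfg.n_sims)
        assert abs(np.mean(reps) - p_ref) < 3 * se


class TestGrid:
    def test_default_grid_matches_study(self):
        grid = GridSpec()
        assert len(grid.T_gen) == 21
        assert len(grid.theta) == 19  # 0.001..0.01 by 0.001 and 0.01..0.1 by 0.01
        assert len(grid.m) == 20  # 0..1 by 0.1 and 1..10 by 1, 1.0 shared
        assert len(grid.tau) == 10
        assert len(grid.points(ISOLATION)) == 21 * 19

    def test_model_specific_axes(self):
        grid = GridSpec(T_gen=(1e6,), theta=(0.002,), m=(0.0, 0.5), tau=(0.5, 1.0))
        assert len(grid.points(ISOLATION)) == 1
        assert len(grid.points(ONGOING_MIGRATION)) == 2
        assert len(grid.points(SECONDARY_CONTACT)) == 4

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(T_gen=()).points(ISOLATION)

    def test_surface_lnl_nonpositive_and_mle_on_grid(self, small_obs, small_specs, mu):
        grid = GridSpec(T_gen=(4e6,), theta=(0.002, 0.004, 0.008), m=(1.0,))
        cfg = RejectionConfig(n_sims=300, rng_seed=2)
        surface = grid_search(small_obs, ONGOING_MIGRATION, grid, small_specs, mu, cfg)
        assert (surface.table["lnL"] <= 0).all()
        assert surface.mle().theta in grid.theta

    def test_nested_models_with_shared_streams(self, small_obs, small_specs, mu):
        """Point-wise shared simulation streams make the nested maxima
        ordered exactly: each smaller grid is a subset of the larger."""
        cfg = RejectionConfig(n_sims=300, rng_seed=4)
        t_axis = (2e6, 4e6)
        th_axis = (0.002, 0.004)
        iso = grid_search(
            small_obs,
            ISOLATION,
            GridSpec(T_gen=t_axis, theta=th_axis, m=(0.0,), tau=(1.0,)),
            small_specs,
            mu,
            cfg,
        )
        mig = grid_search(
            small_obs,
            ONGOING_MIGRATION,
            GridSpec(T_gen=t_axis, theta=th_axis, m=(0.0, 1.0), tau=(1.0,)),
            small_specs,
            mu,
            cfg,
        )
        sec = grid_search(
            small_obs,
            SECONDARY_CONTACT,
            GridSpec(T_gen=t_axis, theta=th_axis, m=(0.0, 1.0), tau=(0.5, 1.0)),
            small_specs,
            mu,
            cfg,
        )
        assert sec.max_lnL >= mig.max_lnL >= iso.max_lnL


class TestProfileCI:
    def _surface(self, thetas, lnls):
        return LikelihoodSurface(
            pd.DataFrame(
                {
                    "model": "isolation",
                    "theta": thetas,
                    "T_gen": 0.0,
                    "m": 0.0,
                    "tau": 1.0,
                    "n_accepted": 1,
                    "n_sims": 10,
                    "lnL": lnls,
                    "is_bound": False,
                }
            )
        )

    def test_interval_within_1p92_units(self):
        surface = self._surface(
            [0.001, 0.002, 0.003, 0.004, 0.005], [-12.0, -9.0, -8.0, -9.5, -12.0]
        )
        lo, hi, cl, ch = profile_ci(surface, "theta")
        assert (lo, hi) == (0.002, 0.004)
        assert not cl and not ch

    def test_flat_profile_censored_both_ends(self):
        surface = self._surface([0.001, 0.002, 0.003], [-5.0, -5.0, -5.0])
        lo, hi, cl, ch = profile_ci(surface, "theta")
        assert (lo, hi) == (0.001, 0.003)
        assert cl and ch

    def test_monotone_profile_censored_at_upper_boundary(self):
        surface = self._surface([0.001, 0.002, 0.003], [-12.0, -9.0, -6.0])
        lo, hi, cl, ch = profile_ci(surface, "theta")
        assert hi == 0.003 and ch
        assert not cl

    def test_unknown_axis_rejected(self):
        with pytest.raises(ValueError):
            profile_ci(self._surface([0.001], [-1.0]), "bogus")
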