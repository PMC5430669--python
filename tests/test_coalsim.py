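"""Structured-coalescent simulator: scaling, closed forms, model collapses,
and distributional agreement with an independent coalescent simulator."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

import msprime

from imabc.coalsim import (
    ISOLATION,
    ONGOING_MIGRATION,
    SECONDARY_CONTACT,
    LocusSpec,
    ModelParams,
    coalescent_scaling,
    simulate_genealogy,
    simulate_locus,
    simulate_wh_dataset,
    to_ms_text,
)
from imabc.seqio import MutationRate
from imabc.sumstats import wh_from_sim


def _t_gen_for(theta: float, mu: MutationRate, t_coal: float) -> float:
    """Split time in generations mapping to a target coalescent depth."""
    return t_coal * 4.0 * theta / (4.0 * mu.mu)


class TestScaling:
    def test_effective_size_and_split_depth(self, mu):
        p = ModelParams(ONGOING_MIGRATION, theta=0.002, T_gen=8.5e6, m=0.7)
        n_e, t_coal, m_coal = coalescent_scaling(p, mu)
        assert n_e == pytest.approx(185873.6, abs=0.1)
        assert t_coal == pytest.approx(11.432, abs=1e-3)
        assert m_coal == pytest.approx(2.8)

    def test_zero_migration_scales_to_zero(self, mu):
        p = ModelParams(ISOLATION, theta=0.002, T_gen=1e6, m=0.0)
        assert coalescent_scaling(p, mu)[2] == 0.0

    def test_scaled_convention_switch(self, mu):
        p = ModelParams(ONGOING_MIGRATION, theta=0.002, T_gen=1e6, m=0.7)
        assert coalescent_scaling(p, mu, "scaled")[2] == pytest.approx(0.7)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(ISOLATION, theta=0.002, T_gen=1e6, m=1.0)
        with pytest.raises(ValueError):
            ModelParams(ONGOING_MIGRATION, theta=0.002, T_gen=1e6, m=1.0, tau=0.5)
        with pytest.raises(ValueError):
            ModelParams(SECONDARY_CONTACT, theta=0.002, T_gen=1e6, m=1.0, tau=0.0)


class TestGenealogies:
    def test_pair_tmrca_expectation_panmictic(self, mu):
        """With T = 0 the model collapses to the standard coalescent;
        a sample of two has expected TMRCA 1 coalescent unit."""
        p = ModelParams(ISOLATION, theta=0.002, T_gen=0.0)
        spec = LocusSpec("x", length=100, n_west=1, n_east=1)
        t = np.array(
            [simulate_genealogy(p, spec, mu, s).tmrca for s in range(10_000)]
        )
        se = t.std() / np.sqrt(t.size)
        assert abs(t.mean() - 1.0) < 3 * se

    def test_ultrametric_and_spans_split(self, mu):
        p = ModelParams(ISOLATION, theta=0.002, T_gen=2e6)
        _, t_coal, _ = coalescent_scaling(p, mu)
        spec = LocusSpec("x", length=100, n_west=4, n_east=4)
        for seed in range(50):
            g = simulate_genealogy(p, spec, mu, seed)
            # all leaves at time 0 and times increase towards the root
            assert np.all(g.node_time[: g.n_leaves] == 0.0)
            parents = g.parent[g.parent >= 0]
            children = np.flatnonzero(g.parent >= 0)
            assert np.all(g.node_time[parents] >= g.node_time[children])
            # both demes sampled without migration: root predates the split
            assert g.tmrca >= t_coal

    def test_isolation_equals_migration_with_m_zero(self, mu):
        p_iso = ModelParams(ISOLATION, theta=0.002, T_gen=2e6)
        p_mig = ModelParams(ONGOING_MIGRATION, theta=0.002, T_gen=2e6, m=0.0)
        spec = LocusSpec("x", length=100, n_west=3, n_east=3)
        t_iso = [simulate_genealogy(p_iso, spec, mu, s).tmrca for s in range(5000)]
        t_mig = [
            simulate_genealogy(p_mig, spec, mu, 10_000 + s).tmrca for s in range(5000)
        ]
        assert ks_2samp(t_iso, t_mig).pvalue > 0.01

    def test_secondary_contact_tau_one_equals_ongoing(self, mu):
        p_sec = ModelParams(SECONDARY_CONTACT, theta=0.002, T_gen=2e6, m=1.0, tau=1.0)
        p_mig = ModelParams(ONGOING_MIGRATION, theta=0.002, T_gen=2e6, m=1.0)
        spec = LocusSpec("x", length=100, n_west=3, n_east=3)
        t_sec = [simulate_genealogy(p_sec, spec, mu, s).tmrca for s in range(5000)]
        t_mig = [
            simulate_genealogy(p_mig, spec, mu, 20_000 + s).tmrca for s in range(5000)
        ]
        assert ks_2samp(t_sec, t_mig).pvalue > 0.01


class TestMutations:
    def test_watterson_expected_segregating_sites(self, mu):
        """Panmictic n = 10 with theta_locus = 5: E[S] = 5 * sum(1/i, i<10)."""
        p = ModelParams(ISOLATION, theta=0.002, T_gen=0.0)
        spec = LocusSpec("w", length=2500, n_west=5, n_east=5)  # theta_locus = 5
        s_counts = np.array(
            [simulate_locus(p, spec, mu, seed)[1].num_sites for seed in range(5000)]
        )
        expected = 5.0 * sum(1.0 / i for i in range(1, 10))
        se = s_counts.std() / np.sqrt(s_counts.size)
        assert abs(s_counts.mean() - expected) < 3 * se

    def test_pair_segregating_sites_theta_one(self, mu):
        """n = 2, theta_locus = 1: E[S] = 1."""
        p = ModelParams(ISOLATION, theta=0.002, T_gen=0.0)
        spec = LocusSpec("w", length=500, n_west=1, n_east=1)
        s_counts = np.array(
            [simulate_locus(p, spec, mu, seed)[1].num_sites for seed in range(5000)]
        )
        se = s_counts.std() / np.sqrt(s_counts.size)
        assert abs(s_counts.mean() - 1.0) < 3 * se

    def test_pairwise_diversity_matches_theta(self, mu):
        """Within-population per-site heterozygosity approximates theta."""
        theta = 0.004
        p = ModelParams(ISOLATION, theta=theta, T_gen=0.0)
        spec = LocusSpec("w", length=1000, n_west=2, n_east=2)
        diffs = []
        for seed in range(4000):
            _, sl = simulate_locus(p, spec, mu, seed)
            w, _ = sl.derived_counts()
            diffs.append(int(((w == 1)).sum()))  # sites differing within west pair
        diffs = np.asarray(diffs, dtype=float) / spec.length
        se = diffs.std() / np.sqrt(diffs.size)
        assert abs(diffs.mean() - theta) < 3 * se

    def test_zero_theta_gives_no_sites(self, mu):
        p = ModelParams(ISOLATION, theta=0.0, T_gen=0.0)
        spec = LocusSpec("w", length=500, n_west=2, n_east=2)
        _, sl = simulate_locus(p, spec, mu, 1)
        assert sl.num_sites == 0

    def test_mutation_positions_unique_and_carriers_proper(self, mu):
        p = ModelParams(ONGOING_MIGRATION, theta=0.01, T_gen=2e6, m=1.0)
        spec = LocusSpec("w", length=400, n_west=4, n_east=4)
        for seed in range(30):
            _, sl = simulate_locus(p, spec, mu, seed)
            assert len(np.unique(sl.positions)) == sl.num_sites
            if sl.num_sites:
                counts = sl.carriers.sum(axis=1)
                assert counts.min() >= 1
                assert counts.max() <= sl.carriers.shape[1] - 1


class TestFusedPath:
    def test_fused_dataset_matches_object_path(self, mu):
        """The multi-locus kernel replays the per-locus object path."""
        p = ModelParams(ONGOING_MIGRATION, theta=0.002, T_gen=8.5e6, m=0.7)
        spec = LocusSpec("l", length=200, n_west=6, n_east=8)
        for seed in range(50):
            fused = simulate_wh_dataset(p, [spec], mu, seed)
            _, sl = simulate_locus(p, spec, mu, seed)
            assert tuple(fused) == tuple(wh_from_sim(sl).as_array())

    def test_migration_monotone_trend(self, mu):
        """More migration: fewer fixed differences, more shared sites."""
        spec = LocusSpec("l", length=300, n_west=6, n_east=6)
        means = {}
        for m in (0.0, 1.0, 10.0):
            model = ISOLATION if m == 0 else ONGOING_MIGRATION
            p = ModelParams(model, theta=0.002, T_gen=4e6, m=m)
            stats = np.array(
                [simulate_wh_dataset(p, [spec], mu, s) for s in range(2000)]
            )
            means[m] = stats.mean(axis=0)
        assert means[0.0][3] >= means[1.0][3] >= means[10.0][3]
        assert means[0.0][2] <= means[1.0][2] <= means[10.0][2]


class TestAgainstIndependentSimulator:
    """Distributional identity with msprime configured at the same scaled
    rates (two demes of pairwise coalescence rate 1, migration M/2 per
    lineage, merge at T_coal, mutation rate theta_locus/2)."""

    N_REPS = 4000
    ALPHA = 0.01 / 5  # five statistics compared

    def _msprime_stats(self, n, t_coal, m_coal, theta_half, tau, seed):
        dem = msprime.Demography()
        dem.add_population(name="W", initial_size=1.0)
        dem.add_population(name="E", initial_size=1.0)
        dem.add_population(name="A", initial_size=1.0)
        if m_coal > 0:
            dem.set_symmetric_migration_rate(["W", "E"], rate=m_coal / 2.0)
            if tau < 1.0:
                dem.add_symmetric_migration_rate_change(
                    time=tau * t_coal, populations=["W", "E"], rate=0.0
                )
        dem.add_population_split(time=t_coal, derived=["W", "E"], ancestral="A")
        dem.sort_events()
        reps = msprime.sim_ancestry(
            samples={"W": n, "E": n},
            demography=dem,
            ploidy=1,
            sequence_length=1,
            num_replicates=self.N_REPS,
            random_seed=seed,
        )
        rng = np.random.default_rng(seed)
        out = []
        for ts in reps:
            mts = msprime.sim_mutations(
                ts,
                rate=theta_half,
                discrete_genome=False,
                random_seed=int(rng.integers(1, 2**31)),
            )
            gm = mts.genotype_matrix()
            if gm.size == 0:
                out.append((0, 0, 0, 0, 0))
                continue
            der = gm > 0
            w = der[:, :n].sum(axis=1)
            e = der[:, n:].sum(axis=1)
            poly_w = (w > 0) & (w < n)
            poly_e = (e > 0) & (e < n)
            present = (w + e) > 0
            fixed = present & ~poly_w & ~poly_e & ~((w == n) & (e == n))
            out.append(
                (
                    gm.shape[0],
                    int((poly_w & ~poly_e).sum()),
                    int((poly_e & ~poly_w).sum()),
                    int((poly_w & poly_e).sum()),
                    int(fixed.sum()),
                )
            )
        return np.array(out)

    @pytest.mark.parametrize(
        "model,m,tau",
        [
            (ONGOING_MIGRATION, 0.5, 1.0),
            (ISOLATION, 0.0, 1.0),
            (SECONDARY_CONTACT, 1.0, 0.4),
        ],
    )
    def test_segregating_sites_and_wh_components(self, mu, model, m, tau):
        theta = 0.002
        t_coal = 1.0
        n = 4
        theta_locus = 2.0
        p = ModelParams(
            model,
            theta=theta,
            T_gen=_t_gen_for(theta, mu, t_coal),
            m=m,
            tau=tau if model == SECONDARY_CONTACT else 1.0,
        )
        spec = LocusSpec("x", length=int(round(theta_locus / theta)), n_west=n, n_east=n)
        mine = []
        for seed in range(self.N_REPS):
            _, sl = simulate_locus(p, spec, mu, seed + 1)
            wh = wh_from_sim(sl)
            mine.append(
                (sl.num_sites, wh.private_west, wh.private_east, wh.shared, wh.fixed)
            )
        mine = np.array(mine)
        _, t_coal_actual, m_coal = coalescent_scaling(p, mu)
        theirs = self._msprime_stats(
            n, t_coal_actual, m_coal, theta_locus / 2.0, tau, seed=42
        )
        for j in range(5):
            assert ks_2samp(mine[:, j], theirs[:, j]).pvalue > self.ALPHA


def test_ms_text_output(mu):
    p = ModelParams(ONGOING_MIGRATION, theta=0.01, T_gen=2e6, m=1.0)
    spec = LocusSpec("x", length=300, n_west=3, n_east=3)
    loci = [simulate_locus(p, spec, mu, s)[1] for s in (1, 2)]
    text = to_ms_text(loci)
    assert text.count("//") == 2
    assert f"segsites: {loci[0].num_sites}" in text
    rows = [l for l in text.splitlines() if set(l) <= {"0", "1"} and l]
    assert len(rows) == sum(6 for l in loci if l.num_sites)


def test_invalid_seed_rejected(mu):
    p = ModelParams(ISOLATION, theta=0.002, T_gen=0.0)
    spec = LocusSpec("x", length=100, n_west=2, n_east=2)
    with pytest.raises(ValueError):
        simulate_genealogy(p, spec, mu, -1)
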