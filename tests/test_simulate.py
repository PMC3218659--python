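import numpy as np
import pytest
from scipy import stats as sps

from ldsplit import (
    SimConfig,
    crossover_probability,
    enforce_trajectory,
    evolve,
    meiosis,
    mutate,
    sample_breakpoint,
    sample_panels,
    transmission_distortion,
)
from ldsplit.simulate import Population, _draw_sexes, _target_freq, initial_population


def small_config(**kw):
    defaults = dict(
        pop_size=100,
        generations=50,
        mutation_rate=0.02,
        init_sites=60,
        start_hot_freq=1.0,
        end_hot_freq=0.5,
        seed=0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimConfig(start_hot_freq=1.5)
        with pytest.raises(ValueError):
            SimConfig(het_multiplier=0.5)

    def test_default_rates(self):
        cfg = SimConfig()
        assert cfg.background_crossover_prob == 0.001
        assert cfg.bgc_prob == 0.5
        assert cfg.tract_mean == 500.0


class TestCrossoverProbability:
    @pytest.mark.parametrize("geno,expected", [(0, 0.001), (1, 0.01), (2, 0.02)])
    def test_genotype_rates(self, geno, expected):
        assert crossover_probability(geno, SimConfig()) == pytest.approx(expected)

    def test_bad_genotype(self):
        with pytest.raises(ValueError):
            crossover_probability(3, SimConfig())


class TestBreakpoints:
    def test_background_uniform(self):
        cfg = SimConfig()
        g = np.random.default_rng(0)
        draws = np.array([sample_breakpoint(False, cfg, g) for _ in range(3000)])
        assert (draws >= 0).all() and (draws < cfg.region_length).all()
        se = cfg.region_length / np.sqrt(12 * len(draws))
        assert abs(draws.mean() - cfg.region_length / 2) < 3 * se
        assert sps.kstest(draws / cfg.region_length, "uniform").pvalue > 0.01

    def test_hotspot_centered(self):
        cfg = SimConfig()
        g = np.random.default_rng(1)
        draws = np.array([sample_breakpoint(True, cfg, g) for _ in range(2000)])
        assert abs(draws.mean() - cfg.hotspot_center) < 3 * cfg.breakpoint_sigma / np.sqrt(
            len(draws)
        )
        assert (draws >= 0).all() and (draws < cfg.region_length).all()


class TestMutate:
    def test_zero_rate_is_identity(self):
        cfg = small_config(mutation_rate=0.0)
        g = np.random.default_rng(0)
        pop = initial_population(cfg, g)
        before = pop.haplotypes.copy()
        after = mutate(pop, cfg, g)
        assert np.array_equal(after.haplotypes, before)

    def test_poisson_influx_moment(self):
        cfg = small_config(mutation_rate=0.05, init_sites=0)
        g = np.random.default_rng(2)
        pop = initial_population(cfg, g)
        n2 = 2 * cfg.pop_size
        total_new = 0
        reps = 60
        for _ in range(reps):
            before = pop.haplotypes.shape[1]
            new_pop = mutate(pop, cfg, g)
            # count insertions before fixation-removal noise: all new sites
            # are singletons and survive drop_fixed_sites
            total_new += new_pop.haplotypes.shape[1] - before
        mean_per_hap = total_new / (reps * n2)
        se = np.sqrt(cfg.mutation_rate / (reps * n2))
        assert abs(mean_per_hap - cfg.mutation_rate) < 4 * se

    def test_fixed_site_removed(self):
        cfg = small_config(mutation_rate=0.0)
        g = np.random.default_rng(3)
        pop = initial_population(cfg, g)
        H = pop.haplotypes.copy()
        H[:, 0] = 1  # fix a site by hand
        pop = Population(H, pop.positions, pop.causal, pop.sex)
        after = mutate(pop, cfg, g).drop_fixed_sites()
        assert pop.positions[0] not in after.positions


class TestMeiosis:
    def test_no_bgc_mendelian(self):
        cfg = SimConfig(bgc_prob=0.0, tract_mean=300_000, tract_sigma=1.0)
        frac, n = transmission_distortion(cfg, 4000, rng=0)
        assert n >= 4000
        se = 0.5 / np.sqrt(n)
        assert abs(frac - 0.5) < 4 * se

    def test_full_bgc_analytic_limit(self):
        cfg = SimConfig(bgc_prob=1.0, tract_mean=300_000, tract_sigma=1.0)
        frac, n = transmission_distortion(cfg, 4000, rng=1)
        assert frac == pytest.approx(1.0, abs=0.01)

    def test_single_meiosis_record(self):
        cfg = small_config()
        g = np.random.default_rng(4)
        pop = initial_population(cfg, g)
        gamete, allele, record = meiosis(pop, 0, cfg, g)
        assert gamete.shape == (pop.haplotypes.shape[1],)
        assert allele in (0, 1)
        assert set(record) >= {"recombinant", "causal_allele", "bgc"}


class TestTrajectory:
    def test_linear_interpolant(self):
        cfg = small_config(start_hot_freq=1.0, end_hot_freq=0.0, generations=100)
        assert _target_freq(50, cfg) == pytest.approx(0.5)

    def test_cooling_reaches_target(self):
        cfg = small_config(seed=5)
        pop, log = evolve(cfg)
        assert abs(pop.hot_freq - cfg.end_hot_freq) <= cfg.trajectory_tol + 1 / (
            2 * cfg.pop_size
        )

    def test_heating_rises_within_band(self):
        cfg = small_config(start_hot_freq=0.0, end_hot_freq=0.5, seed=6)
        pop, log = evolve(cfg)
        freqs = np.array([ev.hot_freq for ev in log])
        targets = np.array(
            [_target_freq(ev.generation, cfg) for ev in log]
        )
        # each generation within the enforcement band (or between old and new)
        assert np.all(np.abs(freqs - targets) <= cfg.trajectory_tol + 0.06)
        assert pop.hot_freq > 0.4

    def test_budget_exhaustion_reports_context(self):
        cfg = small_config(trajectory_tol=1e-9, rejection_budget=2)
        g = np.random.default_rng(0)
        pop = initial_population(cfg, g)
        with pytest.raises(RuntimeError, match="generation"):
            enforce_trajectory(pop, 25, cfg, g)


class TestEvolve:
    def test_seed_determinism(self):
        cfg = small_config(seed=9)
        a, _ = evolve(cfg)
        b, _ = evolve(cfg)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.causal, b.causal)
        assert np.array_equal(a.positions, b.positions)

    def test_constant_population_size(self):
        cfg = small_config(seed=10)
        pop, _ = evolve(cfg)
        assert pop.n_individuals == cfg.pop_size
        assert pop.haplotypes.shape[0] == 2 * cfg.pop_size

    def test_no_fixed_sites_retained(self):
        cfg = small_config(seed=11)
        pop, _ = evolve(cfg)
        f = pop.haplotypes.mean(axis=0)
        assert ((f > 0) & (f < 1)).all()

    def test_crossover_counts_track_mean_probability(self):
        cfg = small_config(seed=12, generations=80)
        pop, log = evolve(cfg)
        total = sum(ev.crossovers for ev in log)
        meioses = sum(ev.meioses for ev in log)
        # mean crossover prob between 0.001 (all cold) and 0.02 (all hot)
        assert 0.001 * meioses * 0.5 < total < 0.02 * meioses


class TestSamplePanels:
    def test_shapes_and_flags(self):
        cfg = small_config(seed=13)
        pop, _ = evolve(cfg)
        samples = sample_panels(pop, cfg, rng=0, n_subsets=3, subset_size=20)
        assert len(samples) == 3
        for s in samples:
            assert s.panel.n_chromosomes == 40
            # causal column is where it claims to be
            col = s.panel.haplotypes[:, s.causal_snp]
            f = col.mean()
            assert min(f, 1 - f) == pytest.approx(s.causal_maf)
            assert s.flagged == (s.causal_maf < 0.3)
            assert s.panel.snps[s.causal_snp].snp_id == "causal"

    def test_whole_population_subset(self):
        cfg = small_config(seed=14)
        pop, _ = evolve(cfg)
        s = sample_panels(pop, cfg, rng=1, n_subsets=1, subset_size=cfg.pop_size,
                          site_maf_min=0.0)[0]
        assert s.panel.n_chromosomes == 2 * cfg.pop_size
        assert s.panel.n_snps == pop.haplotypes.shape[1] + 1

    def test_sexes_always_mixed(self):
        for seed in range(5):
            sex = _draw_sexes(6, np.random.default_rng(seed))
            assert 0 < sex.sum() < 6
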