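import numpy as np
import pytest

from tortflow import founders as fnd
from tortflow import landscape as lsc
from tortflow import simulate as sim


def test_growth_rate_from_annual_estimate():
    assert sim.growth_rate_from_annual(0.01, 48) == pytest.approx(0.48)


def test_config_validation():
    with pytest.raises(ValueError):
        sim.SimulationConfig(dispersal_probability=1.5)
    with pytest.raises(ValueError):
        sim.SimulationConfig(mutation_model="stepwise?")
    with pytest.raises(ValueError):
        sim.SimulationConfig(dispersal_kernel="teleport")


class TestInitialization:
    @pytest.mark.parametrize(
        "density,expected", [("low", 1875), ("moderate", 8750), ("high", 12500)]
    )
    def test_published_initial_sizes(self, density, expected, freqs20):
        surface = lsc.build_scenario_surface("no_barrier", density=density)
        panel = fnd.sample_founders(freqs20, n=expected, seed=1)
        state = sim.initialize_population(surface, density, panel, seed=2)
        assert state.n == expected

    def test_variable_density_seeds_at_k(self, freqs20):
        habitat = lsc.HabitatGrid(np.full((10, 10), 0.45))
        surface = lsc.build_heterogeneous_surface(habitat, [])
        panel = fnd.sample_founders(freqs20, n=100, seed=1)
        state = sim.initialize_population(surface, "variable", panel, seed=2)
        assert state.n == surface.total_capacity

    def test_unknown_density_rejected(self, freqs20, open_surface):
        panel = fnd.sample_founders(freqs20, n=10, seed=1)
        with pytest.raises(ValueError):
            sim.initialize_population(open_surface, "extreme", panel, seed=2)


class TestDispersal:
    @pytest.mark.parametrize("kernel", ["walk", "ring"])
    def test_zero_probability_nobody_moves(self, kernel, freqs20, open_surface):
        panel = fnd.sample_founders(freqs20, n=500, seed=1)
        state = sim.initialize_population(open_surface, "low", panel, seed=2)
        cfg = sim.SimulationConfig(dispersal_probability=0.0,
                                   dispersal_kernel=kernel)
        before = (state.row.copy(), state.col.copy())
        state = sim.disperse(state, open_surface, cfg, np.random.default_rng(3))
        assert np.array_equal(state.row, before[0])
        assert np.array_equal(state.col, before[1])

    def test_ring_kernel_reaches_exact_max_distance(self, freqs20, open_surface,
                                                    state_factory):
        geno = fnd.sample_founders(freqs20, n=1, seed=1).genotypes
        cfg = sim.SimulationConfig(dispersal_probability=1.0,
                                   dispersal_kernel="ring")
        rng = np.random.default_rng(4)
        for _ in range(50):
            state = state_factory([12], [12], [0], geno, freqs20)
            state = sim.disperse(state, open_surface, cfg, rng)
            d = max(abs(int(state.row[0]) - 12), abs(int(state.col[0]) - 12))
            assert d == 10

    def test_walk_kernel_stays_within_max_distance(self, freqs20, open_surface,
                                                   state_factory):
        geno = np.repeat(fnd.sample_founders(freqs20, n=1, seed=1).genotypes,
                         200, axis=0)
        state = state_factory([12] * 200, [12] * 200, [0] * 200, geno, freqs20)
        cfg = sim.SimulationConfig(dispersal_probability=1.0)
        state = sim.disperse(state, open_surface, cfg, np.random.default_rng(5))
        d = np.maximum(np.abs(state.row - 12), np.abs(state.col - 12))
        assert np.all(d <= 10)
        assert np.mean(d > 0) > 0.9  # walks almost never return to origin

    @pytest.mark.parametrize("kernel", ["walk", "ring"])
    def test_barrier_impermeable(self, kernel, freqs20):
        """No lineage changes sides across an absolute barrier."""
        surface = lsc.build_scenario_surface("barrier", density="low")
        loci = fnd.generate_frequencies(1, 0.45, 2, seed=1)
        panel = fnd.sample_founders(loci, n=1800, seed=2)
        state = sim.initialize_population(surface, "low", panel, seed=3)
        # tag sides with private alleles
        west = state.col < 12
        state.genotypes[west] = 1
        state.genotypes[~west] = 2
        cfg = sim.SimulationConfig(mutation_rate=0.0, dispersal_kernel=kernel,
                                   n_generations=15)
        rng = np.random.default_rng(6)
        for _ in range(15):
            state = sim.step(state, surface, cfg, rng)
            if state.n == 0:
                break
            west = state.col < 12
            assert np.all(state.genotypes[west] == 1)
            assert np.all(state.genotypes[~west] == 2)


class TestReproduction:
    def _pair_state(self, freqs20, state_factory, n_f=1, n_m=1):
        n = n_f + n_m
        geno = fnd.sample_founders(freqs20, n=n, seed=1).genotypes
        return state_factory([2] * n, [2] * n, [0] * n_f + [1] * n_m,
                             geno, freqs20)

    def test_single_individual_strict_no_offspring(self, freqs20,
                                                   flat_k24_surface,
                                                   state_factory):
        geno = fnd.sample_founders(freqs20, n=1, seed=1).genotypes
        state = state_factory([2], [2], [0], geno, freqs20)
        cfg = sim.SimulationConfig(mating_system="strict")
        row, *_ = sim.reproduce(state, flat_k24_surface, cfg,
                                np.random.default_rng(1))
        assert len(row) == 0

    def test_single_sex_group_no_offspring(self, freqs20, flat_k24_surface,
                                           state_factory):
        state = self._pair_state(freqs20, state_factory, n_f=3, n_m=0)
        cfg = sim.SimulationConfig()
        row, *_ = sim.reproduce(state, flat_k24_surface, cfg,
                                np.random.default_rng(1))
        assert len(row) == 0

    def test_pair_logistic_expectation(self, freqs20, flat_k24_surface,
                                       state_factory):
        """A mixed pair at K=24 recruits 2 + 0.48*2*(22/24) = 2.88 on average."""
        cfg = sim.SimulationConfig()
        rng = np.random.default_rng(2)
        counts = []
        for _ in range(2000):
            state = self._pair_state(freqs20, state_factory)
            row, *_ = sim.reproduce(state, flat_k24_surface, cfg, rng)
            counts.append(len(row))
        assert np.mean(counts) == pytest.approx(2.88, abs=0.05)

    def test_cell_at_capacity_replaces_itself(self, freqs20, flat_k24_surface,
                                              state_factory):
        n = 24
        geno = fnd.sample_founders(freqs20, n=n, seed=3).genotypes
        state = state_factory([1] * n, [1] * n, [0] * 12 + [1] * 12,
                              geno, freqs20)
        cfg = sim.SimulationConfig()
        row, *_ = sim.reproduce(state, flat_k24_surface, cfg,
                                np.random.default_rng(3))
        assert len(row) == 24  # logistic increment is exactly 0 at N = K

    def test_occupied_zero_k_cell_is_an_error(self, freqs20, state_factory):
        surface = lsc.ResistanceSurface(
            resistance=np.array([[0.0, 1.0]]), carrying=np.array([[3, 0]])
        )
        geno = fnd.sample_founders(freqs20, n=2, seed=1).genotypes
        state = state_factory([0, 0], [1, 1], [0, 1], geno, freqs20)
        with pytest.raises(RuntimeError):
            sim.reproduce(state, surface, sim.SimulationConfig(),
                          np.random.default_rng(1))

    def test_offspring_alleles_come_from_parents(self, freqs20,
                                                 flat_k24_surface,
                                                 state_factory):
        state = self._pair_state(freqs20, state_factory, n_f=2, n_m=2)
        cfg = sim.SimulationConfig(mutation_rate=0.0)
        row, col, sex, geno = sim.reproduce(state, flat_k24_surface, cfg,
                                            np.random.default_rng(4))
        for j in range(geno.shape[1]):
            parent_alleles = set(state.genotypes[:, j, :].ravel().tolist())
            child_alleles = set(geno[:, j, :].ravel().tolist())
            assert child_alleles <= parent_alleles


class TestMutation:
    def test_zero_rate_unchanged(self, freqs20):
        geno = fnd.sample_founders(freqs20, n=100, seed=1).genotypes.copy()
        before = geno.copy()
        cfg = sim.SimulationConfig(mutation_rate=0.0)
        n = sim.mutate(geno, freqs20, cfg, np.random.default_rng(1))
        assert n == 0
        assert np.array_equal(geno, before)

    def test_expected_mutation_count(self, freqs20):
        geno = fnd.sample_founders(freqs20, n=5000, seed=1).genotypes.copy()
        cfg = sim.SimulationConfig(mutation_rate=0.0005)
        n = sim.mutate(geno, freqs20, cfg, np.random.default_rng(2))
        expected = 5000 * 20 * 2 * 0.0005  # = 100
        assert abs(n - expected) < 4 * np.sqrt(expected)

    def test_two_allele_locus_flips(self):
        locus = fnd.LocusFrequencyTable(
            locus_id="L01", allele_states=[1, 2], frequencies=[0.5, 0.5]
        )
        geno = np.full((50, 1, 2), 1, dtype=np.int16)
        cfg = sim.SimulationConfig(mutation_rate=1.0)
        sim.mutate(geno, [locus], cfg, np.random.default_rng(3))
        assert np.all(geno == 2)

    def test_single_state_locus_cannot_mutate(self):
        loci = fnd.generate_frequencies(1, 0.0, 1, seed=1)
        geno = np.ones((50, 1, 2), dtype=np.int16)
        cfg = sim.SimulationConfig(mutation_rate=1.0)
        n = sim.mutate(geno, loci, cfg, np.random.default_rng(3))
        assert n == 0
        assert np.all(geno == 1)


class TestStepAndReplicates:
    def test_all_male_population_goes_extinct_under_strict_mating(
            self, freqs20, open_surface, state_factory):
        geno = fnd.sample_founders(freqs20, n=20, seed=1).genotypes
        state = state_factory([5] * 20, [5] * 20, [1] * 20, geno, freqs20)
        cfg = sim.SimulationConfig(mating_system="strict")
        out = sim.step(state, open_surface, cfg, np.random.default_rng(1))
        assert out.n == 0
        assert out.extinct

    def test_step_conserves_alleles_without_mutation(self, freqs20,
                                                     open_surface):
        panel = fnd.sample_founders(freqs20, n=1875, seed=1)
        state = sim.initialize_population(open_surface, "low", panel, seed=2)
        cfg = sim.SimulationConfig(mutation_rate=0.0)
        new = sim.step(state, open_surface, cfg, np.random.default_rng(3))
        for j in range(new.genotypes.shape[1]):
            assert set(np.unique(new.genotypes[:, j, :])) <= set(
                np.unique(state.genotypes[:, j, :])
            )

    def test_culvert_quota_respected(self, freqs20):
        surface = lsc.build_scenario_surface("culverts", density="moderate")
        panel = fnd.sample_founders(freqs20, n=9000, seed=1)
        state = sim.initialize_population(surface, "moderate", panel, seed=2)
        cfg = sim.SimulationConfig()
        rng = np.random.default_rng(3)
        for _ in range(8):
            state = sim.step(state, surface, cfg, rng)
            crossings = state.last_info["culvert_crossings"]
            assert all(v <= 3 for v in crossings.values())

    def test_replicates_deterministic_and_counted(self, freqs20, open_surface):
        panel = fnd.sample_founders(freqs20, n=1875, seed=1)
        cfg = sim.SimulationConfig(n_generations=10, sample_interval=5,
                                   n_replicates=2)
        a = sim.run_replicates(open_surface, "low", panel, cfg, seed=77)
        b = sim.run_replicates(open_surface, "low", panel, cfg, seed=77)
        assert len(a) == 2
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.census, rb.census)
            assert sorted(ra.snapshots) == [0, 5, 10]
            for g in ra.snapshots:
                assert np.array_equal(
                    ra.snapshots[g].genotypes, rb.snapshots[g].genotypes
                )

    def test_allele_frequency_martingale(self):
        """With mu=0 the grid-wide frequency of an allele drifts without bias."""
        loci = fnd.generate_frequencies(1, 0.45, 2, seed=1)
        panel = fnd.sample_founders(loci, n=1875, seed=2)
        surface = lsc.build_scenario_surface("no_barrier", density="low")
        cfg = sim.SimulationConfig(mutation_rate=0.0, n_generations=15,
                                   n_replicates=12)
        target = loci[0].allele_states[0]
        p0 = np.mean(panel.genotypes == target)
        finals = []
        for rep in sim.run_replicates(surface, "low", panel, cfg, seed=5,
                                      snapshot_generations=[15]):
            if 15 in rep.snapshots:
                finals.append(np.mean(rep.snapshots[15].genotypes == target))
        assert len(finals) >= 8
        assert np.mean(finals) == pytest.approx(p0, abs=0.06)
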