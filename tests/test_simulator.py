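"""Forward-simulator behaviour: initialisation, soft selection, transmission,
offspring capping, rescaling, and agreement with the deterministic oracle."""

import dataclasses

import numpy as np
import pytest

from seglift.ne import standardized_variance, variance_ne
from seglift.simulator import (
    Arm,
    DemographySchedule,
    GenomeLayout,
    Simulation,
    SimulationConfig,
    rescale_config,
    run_scenario,
    sample_parents,
    season_of,
)
from seglift.sl_fitness import SeasonalLocusParams, sample_locus_params
from seglift.synthetic import single_locus_recursion


def _config(**kw):
    base = dict(n_seasonal_loci=0, epistasis_y=1.0, generations_per_season=5,
                total_generations=20,
                demography=DemographySchedule(summer_size=200))
    base.update(kw)
    return SimulationConfig(**base)


class TestInitialisation:
    def test_exact_half_frequency_at_start(self, rng):
        loci = sample_locus_params(30, rng)
        sim = Simulation(_config(n_seasonal_loci=30), loci, rng)
        np.testing.assert_array_equal(sim.seasonal_frequencies(), 0.5)

    def test_linked_mode_keeps_3R_selection_free(self, rng):
        loci = sample_locus_params(60, rng)
        cfg = _config(n_seasonal_loci=60,
                      genome=GenomeLayout.dmel_default())
        sim = Simulation(cfg, loci, rng)
        arms = {p.position[0] for p in sim.loci}
        assert "3R" not in arms
        assert arms <= {"2L", "2R", "3L"}
        np.testing.assert_array_equal(sim.seasonal_frequencies(), 0.5)

    def test_non_default_initial_frequency_exact(self, rng):
        loci = sample_locus_params(10, rng)
        cfg = _config(n_seasonal_loci=10, initial_frequency=0.3)
        sim = Simulation(cfg, loci, rng)
        expected = round(2 * 200 * 0.3) / (2 * 200)
        np.testing.assert_array_equal(sim.seasonal_frequencies(), expected)

    def test_unlinked_loci_count(self, rng):
        loci = sample_locus_params(100, rng)
        sim = Simulation(_config(n_seasonal_loci=100), loci, rng)
        assert len(sim.loci) == 100
        assert all(p.position == "unlinked" for p in sim.loci)

    def test_loci_count_mismatch_rejected(self, rng, small_loci):
        with pytest.raises(ValueError):
            Simulation(_config(n_seasonal_loci=3), small_loci, rng)


class TestSoftSelection:
    def test_census_follows_schedule_under_any_fitness(self, rng):
        loci = sample_locus_params(10, rng)
        demo = DemographySchedule(mode="boom_bust", summer_size=300,
                                  winter_size=60)
        cfg = _config(n_seasonal_loci=10, epistasis_y=20.0, demography=demo,
                      total_generations=20)
        sim = Simulation(cfg, loci, rng)
        for _ in range(20):
            sim.step()
            expected = demo.size_at(sim.generation, 5)
            assert sim.n == expected
            assert sim.seasonal_dosages().shape[0] == expected

    def test_identical_individuals_uniform_parents(self, rng):
        # no fitness variance: allele frequencies are pure drift in
        # expectation and every parent is equally likely
        w = np.ones(500)
        parents = sample_parents(w, 500, rng)
        counts = np.bincount(parents.ravel(), minlength=500)
        assert counts.sum() == 1000
        # uniform multinomial: variance of counts ~ mean = 2
        assert counts.var() < 6


class TestSeasonCycling:
    def test_season_flips_every_gs(self):
        assert [season_of(g, 3) for g in range(8)] == [
            "summer"] * 3 + ["winter"] * 3 + ["summer"] * 2

    def test_simulation_starts_in_summer(self, rng):
        sim = Simulation(_config(), [], rng)
        assert sim.season == "summer"
        sim.run(5)
        assert sim.season == "winter"


class TestNeutralDrift:
    def test_pure_neutral_recovers_census_ne(self):
        # L = 0: trajectories are binomial drift; the temporal estimator
        # should recover the census size on average
        N, g, reps = 200, 10, 60
        estimates = []
        for seed in range(reps):
            sim = Simulation(_config(demography=DemographySchedule(
                summer_size=N)), [], np.random.default_rng(seed))
            sim.insert_neutral_markers(count=150)
            sim.run(g)
            F = standardized_variance(0.5, sim.neutral_frequencies()).mean()
            estimates.append(variance_ne(F, g))
        assert np.mean(estimates) == pytest.approx(N, rel=0.10)

    def test_fixed_loci_stay_fixed(self, rng):
        # no mutation: once lost or fixed a locus never segregates again
        loci = sample_locus_params(40, rng)
        cfg = _config(n_seasonal_loci=40, epistasis_y=8.0,
                      demography=DemographySchedule(summer_size=30),
                      total_generations=200)
        sim = Simulation(cfg, loci, rng)
        ever_fixed = np.zeros(40, bool)
        fixed_value = np.zeros(40)
        for _ in range(200):
            sim.step()
            f = sim.seasonal_frequencies()
            assert ((f >= 0) & (f <= 1)).all()
            was = ever_fixed.copy()
            np.testing.assert_array_equal(f[was], fixed_value[was])
            ever_fixed |= (f == 0) | (f == 1)
            fixed_value[ever_fixed & ~was] = f[ever_fixed & ~was]
        assert ever_fixed.any()  # strong selection at N=30 fixes some loci


class TestDeterministicOracle:
    def test_large_N_tracks_single_locus_recursion(self):
        # one symmetric locus at N = 1e5: the stochastic trajectory follows
        # the infinite-N recursion within binomial noise for 4 cycles
        locus = SeasonalLocusParams(0, 0.7, 0.7, 0.5, 0.5)
        N, g_s, n_cycles = 100_000, 5, 4
        total = n_cycles * 2 * g_s
        cfg = SimulationConfig(
            n_seasonal_loci=1, epistasis_y=2.0, generations_per_season=g_s,
            total_generations=total,
            demography=DemographySchedule(summer_size=N))
        traj, _ = run_scenario(cfg, [locus], np.random.default_rng(5))
        expected = single_locus_recursion(locus, 2.0, g_s, 0.5, total)
        sim_p = traj.frequencies[:, 0]
        # per-step binomial sd; accumulated drift stays within 3 sd of the
        # compounded noise envelope
        sd = np.sqrt(np.arange(total + 1) * 0.25 / (2 * N))
        resid = np.abs(sim_p - expected)
        assert (resid[1:] <= 3 * sd[1:] + 1e-12).all()


class TestOffspringCap:
    def test_cap_bounds_parent_usage(self, rng):
        w = np.exp(rng.normal(0, 2, size=400))
        for cap in (1, 3, 10):
            n_off = cap * 400 // 4
            parents = sample_parents(w, n_off, rng, cap=cap)
            counts = np.bincount(parents.ravel(), minlength=400)
            assert counts.max() <= cap
            assert (parents[:, 0] != parents[:, 1]).all()

    def test_non_binding_cap_matches_uncapped_spread(self, rng):
        w = np.ones(300)
        capped = sample_parents(w, 150, rng, cap=600)
        counts = np.bincount(capped.ravel(), minlength=300)
        assert counts.max() <= 600
        assert counts.sum() == 300

    def test_infeasible_cap_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_parents(np.ones(10), 100, rng, cap=1)

    def test_capped_simulation_enforces_cap_every_generation(self, rng):
        loci = sample_locus_params(8, rng)
        cfg = _config(n_seasonal_loci=8, epistasis_y=12.0, offspring_cap=4,
                      demography=DemographySchedule(summer_size=100),
                      total_generations=30)
        sim = Simulation(cfg, loci, rng)
        sim.run(30)  # internal sampling would raise if the cap broke
        assert sim.generation == 30

    def test_zero_fitness_everywhere_raises(self, rng):
        with pytest.raises(ValueError):
            sample_parents(np.zeros(10), 5, rng)


class TestRescaling:
    def test_divides_all_size_and_time_parameters(self):
        cfg = SimulationConfig(
            n_seasonal_loci=100, epistasis_y=4.0, generations_per_season=10,
            total_generations=36_000,
            demography=DemographySchedule(summer_size=1_000_000),
            offspring_cap=20)
        scaled = rescale_config(cfg, 2)
        assert scaled.demography.summer_size == 500_000
        assert scaled.generations_per_season == 5
        assert scaled.total_generations == 18_000
        assert scaled.offspring_cap == 10
        assert scaled.epistasis_y == cfg.epistasis_y
        assert scaled.unscaled["summer_size"] == 1_000_000
        assert scaled.unscaled["offspring_cap"] == 20

    def test_factor_100_census(self):
        cfg = SimulationConfig(
            n_seasonal_loci=100, epistasis_y=4.0, generations_per_season=100,
            total_generations=36_000,
            demography=DemographySchedule(summer_size=1_000_000))
        assert rescale_config(cfg, 100).demography.summer_size == 10_000

    def test_identity_and_invalid(self):
        cfg = _config()
        assert rescale_config(cfg, 1) is cfg
        with pytest.raises(ValueError):
            rescale_config(cfg, 3)  # 200 not divisible by 3


class TestReproducibility:
    def test_same_seed_identical_trajectories(self, rng):
        loci = sample_locus_params(15, np.random.default_rng(2))
        cfg = _config(n_seasonal_loci=15, epistasis_y=4.0,
                      total_generations=30)
        t1, _ = run_scenario(cfg, loci, np.random.default_rng(99))
        t2, _ = run_scenario(cfg, loci, np.random.default_rng(99))
        np.testing.assert_array_equal(t1.frequencies, t2.frequencies)

    def test_tsv_round_trip_byte_identical(self, tmp_path, rng):
        loci = sample_locus_params(5, np.random.default_rng(3))
        cfg = _config(n_seasonal_loci=5, total_generations=10)
        out1, out2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        for out in (out1, out2):
            traj, _ = run_scenario(cfg, loci, np.random.default_rng(7))
            traj.write_tsv(out)
        assert out1.read_bytes() == out2.read_bytes()


class TestLinkedMode:
    def _linked_cfg(self, **kw):
        arms = (Arm("2L", 2_000_000), Arm("2R", 2_000_000),
                Arm("3L", 2_000_000), Arm("3R", 2_000_000))
        genome = GenomeLayout(mode="linked", arms=arms,
                              neutral_spacing_bp=500_000)
        base = dict(n_seasonal_loci=20, epistasis_y=4.0,
                    generations_per_season=5, total_generations=20,
                    demography=DemographySchedule(summer_size=120),
                    genome=genome)
        base.update(kw)
        return SimulationConfig(**base)

    def test_marker_grid_and_arm_groups(self, rng):
        loci = sample_locus_params(20, rng)
        sim = Simulation(self._linked_cfg(), loci, rng)
        sim.insert_neutral_markers()
        # 4 markers per 2 Mb arm at 500 kb spacing
        assert sim.n_markers == 16
        groups = sim.marker_arm_groups()
        assert (groups == "neutral_arm").sum() == 4
        np.testing.assert_array_equal(sim.neutral_frequencies(), 0.5)

    def test_transmission_preserves_allele_counts_without_selection(self):
        # neutral linked run: frequencies drift but stay in [0, 1] and the
        # census stays on schedule
        cfg = self._linked_cfg(n_seasonal_loci=0, epistasis_y=1.0)
        sim = Simulation(cfg, [], np.random.default_rng(11))
        sim.insert_neutral_markers()
        sim.run(10)
        f = sim.neutral_frequencies()
        assert ((f >= 0) & (f <= 1)).all()
        assert sim.n == 120

    def test_insert_remove_cycle_restores_state(self, rng):
        loci = sample_locus_params(20, rng)
        sim = Simulation(self._linked_cfg(), loci, rng)
        sim.insert_neutral_markers()
        with pytest.raises(RuntimeError):
            sim.insert_neutral_markers()
        sim.remove_neutral_markers()
        assert sim.n_markers == 0
        sim.insert_neutral_markers()
        assert sim.n_markers == 16

    def test_spacing_larger_than_arm_rejected(self, rng):
        loci = sample_locus_params(20, rng)
        sim = Simulation(self._linked_cfg(), loci, rng)
        with pytest.raises(ValueError):
            sim.insert_neutral_markers(spacing_bp=5_000_000)


class TestLossPatterns:
    def _segregating_after(self, y, generations, seed=3, n_loci=100, N=2000):
        rng = np.random.default_rng(seed)
        loci = sample_locus_params(n_loci, rng)
        cfg = SimulationConfig(
            n_seasonal_loci=n_loci, epistasis_y=y, generations_per_season=5,
            total_generations=generations,
            demography=DemographySchedule(summer_size=N), record_every=0)
        sim = Simulation(cfg, loci, rng)
        sim.run(generations)
        f = sim.seasonal_frequencies()
        return loci, (f > 0) & (f < 1)

    def test_stronger_epistasis_loses_loci_faster_initially(self):
        # early-timepoint segregating counts rank inversely with y
        counts = {y: int(self._segregating_after(y, 200)[1].sum())
                  for y in (1.0, 8.0, 20.0)}
        assert counts[1.0] >= counts[8.0] >= counts[20.0]
        assert counts[1.0] > counts[20.0]

    def test_skewed_effect_sizes_lost_preferentially(self):
        loci, seg = self._segregating_after(8.0, 1000, seed=4)
        skew = np.abs([np.log(p.delta_s / p.delta_w) for p in loci])
        assert (~seg).sum() >= 5  # enough losses to compare
        assert skew[~seg].mean() > skew[seg].mean()


class TestDemography:
    def test_boom_bust_sizes(self):
        demo = DemographySchedule(mode="boom_bust", summer_size=1000,
                                  winter_size=100)
        sizes = [demo.size_at(g, 10) for g in range(40)]
        assert sizes[:10] == [1000] * 10
        assert sizes[10:20] == [100] * 10
        assert sizes[20:30] == [1000] * 10

    def test_custom_schedule(self):
        demo = DemographySchedule(mode="custom", sizes=(10, 20, 30))
        assert [demo.size_at(g, 1) for g in (0, 1, 2, 5)] == [10, 20, 30, 30]

    def test_invalid_schedules(self):
        with pytest.raises(ValueError):
            DemographySchedule(mode="boom_bust", summer_size=100)
        with pytest.raises(ValueError):
            DemographySchedule(summer_size=1)
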