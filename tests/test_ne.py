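"""Temporal-F variance-Ne estimation: closed forms, drift calibration,
within-cycle series and the multi-generation bias curve."""

import numpy as np
import pandas as pd
import pytest

from seglift.ne import (
    estimate_reduction,
    harmonic_mean_size,
    measure_ne,
    multi_generation_ne_curve,
    standardized_variance,
    variance_ne,
    within_cycle_ne_series,
)
from seglift.simulator import DemographySchedule, Simulation, SimulationConfig
from seglift.sl_fitness import sample_locus_params
from seglift.synthetic import generate_drift


def _config(**kw):
    base = dict(n_seasonal_loci=0, epistasis_y=1.0, generations_per_season=5,
                total_generations=20,
                demography=DemographySchedule(summer_size=300))
    base.update(kw)
    return SimulationConfig(**base)


class TestClosedForms:
    @pytest.mark.parametrize("p,expected", [(0.5, 0.0), (0.6, 0.04),
                                            (0.3, 0.16), (1.0, 1.0)])
    def test_standardized_variance(self, p, expected):
        assert standardized_variance(0.5, p) == pytest.approx(expected)

    def test_warns_off_half_insertion(self):
        with pytest.warns(UserWarning):
            standardized_variance(0.4, 0.5)

    def test_variance_ne_arithmetic(self):
        assert variance_ne(0.2, 10) == pytest.approx(10 / (2 * 0.2231435513), rel=1e-6)

    def test_variance_ne_round_trip(self):
        # F = 1 - exp(-g / 2Ne) inverts exactly
        for ne_true, g in [(100, 10), (5000, 20), (37, 1)]:
            F = 1.0 - np.exp(-g / (2 * ne_true))
            assert variance_ne(F, g) == pytest.approx(ne_true, rel=1e-12)

    def test_boundaries(self):
        assert variance_ne(0.0, 10) == np.inf
        assert np.isnan(variance_ne(1.0, 10))
        with pytest.raises(ValueError):
            variance_ne(-0.1, 10)
        with pytest.raises(ValueError):
            variance_ne(0.1, 0)

    def test_monotone_decreasing_in_F(self):
        Fs = np.linspace(0.001, 0.9, 50)
        nes = [variance_ne(F, 10) for F in Fs]
        assert (np.diff(nes) < 0).all()

    def test_single_generation_drift_mean_F(self):
        # E[F] at g=1 equals 1/(2N) for p0 = 1/2
        fx = generate_drift(true_N=100, n_markers=10_000, g=1, seed=2)
        F = standardized_variance(0.5, fx.trajectories[:, 1])
        assert F.mean() == pytest.approx(1 / 200, rel=0.05)


class TestBaselines:
    def test_harmonic_mean_boom_bust_window(self):
        sizes = [10**6] * 10 + [10**5] * 10
        assert harmonic_mean_size(sizes) == pytest.approx(181_818.18, abs=0.01)

    def test_reduction_arithmetic(self):
        assert estimate_reduction(500, 1000) == pytest.approx(0.5)
        assert estimate_reduction(1000, 1000) == 0.0
        with pytest.raises(ValueError):
            estimate_reduction(10, 0)

    def test_empty_or_nonpositive_sizes_rejected(self):
        with pytest.raises(ValueError):
            harmonic_mean_size([])
        with pytest.raises(ValueError):
            harmonic_mean_size([10, 0])


class TestEstimatorCalibration:
    @pytest.mark.parametrize("true_N", [100, 1000])
    def test_drift_fixture_recovers_truth(self, true_N):
        # >= 200 markers x 20 replicates of pure drift: median estimate
        # within 10% of the true size
        estimates = []
        for seed in range(20):
            fx = generate_drift(true_N, 200, 10, seed=seed)
            F = standardized_variance(0.5, fx.trajectories[:, -1]).mean()
            estimates.append(variance_ne(F, 10))
        assert np.median(estimates) == pytest.approx(true_N, rel=0.10)

    def test_neutral_boom_bust_tracks_harmonic_mean(self):
        # varying census: the estimator recovers the harmonic-mean size,
        # i.e. reduction relative to that baseline is ~0
        demo = DemographySchedule(mode="boom_bust", summer_size=400,
                                  winter_size=100)
        reductions = []
        for seed in range(25):
            sim = Simulation(_config(demography=demo),
                             [], np.random.default_rng(seed))
            ests = measure_ne(sim, g=10, n_markers=300)
            # window covers generations 1-10: five summer sizes (400) and
            # five winter sizes (100)
            assert ests[0].baseline == pytest.approx(
                harmonic_mean_size([400] * 5 + [100] * 5))
            reductions.append(ests[0].reduction)
        assert np.mean(reductions) == pytest.approx(0.0, abs=0.10)


class TestMeasureNe:
    def test_markers_removed_after_measurement(self, rng):
        sim = Simulation(_config(), [], rng)
        measure_ne(sim, g=5, n_markers=50)
        assert sim.n_markers == 0

    def test_neutral_run_estimates_census(self):
        ests = []
        for seed in range(25):
            sim = Simulation(_config(), [], np.random.default_rng(seed))
            ests.append(measure_ne(sim, g=10, n_markers=300)[0].ne)
        assert np.mean(ests) == pytest.approx(300, rel=0.10)


class TestArmGroupConsistency:
    def test_reduction_is_genome_wide_in_linked_mode(self):
        # markers on the selection-free arm (3R) experience a reduction of
        # the same order as markers linked to seasonal loci: the effect acts
        # through reproductive variance, not hitchhiking alone
        from seglift.simulator import GenomeLayout
        from seglift.sl_fitness import sample_locus_params

        rng = np.random.default_rng(1)
        loci = sample_locus_params(60, rng)
        cfg = SimulationConfig(
            n_seasonal_loci=60, epistasis_y=15.0, generations_per_season=5,
            total_generations=200,
            demography=DemographySchedule(summer_size=300),
            genome=GenomeLayout.dmel_default(neutral_spacing_bp=1_000_000),
            record_every=0)
        sim = Simulation(cfg, loci, rng)
        sim.run(150)
        ests = {e.arm_group: e for e in measure_ne(sim, g=10)}
        sel = ests["selected_arms"].reduction
        neu = ests["neutral_arm"].reduction
        assert neu > 0
        assert sel / 2 <= neu <= sel * 2


class TestWithinCycleSeries:
    def test_neutral_series_is_flat_near_census(self):
        sim = Simulation(_config(total_generations=40),
                         [], np.random.default_rng(0))
        frames = [within_cycle_ne_series(sim, n_markers=400)
                  for _ in range(6)]
        series = pd.concat(frames)
        assert len(series) == 6 * 10
        assert (series["g"] == 1).all()
        # g=1 estimates are noisy; the mean over repeats should sit near N
        assert series["ne"].mean() == pytest.approx(300, rel=0.2)

    def test_series_spans_whole_cycle_with_season_labels(self):
        sim = Simulation(_config(), [], np.random.default_rng(1))
        series = within_cycle_ne_series(sim, n_markers=20)
        assert list(series["cycle_position"]) == list(range(10))
        assert list(series["season"].unique()) == ["summer", "winter"]


class TestMultiGenerationCurve:
    def test_drift_curve_approaches_truth(self):
        fx = generate_drift(true_N=500, n_markers=3000, g=30, seed=6)
        curve = multi_generation_ne_curve(fx.trajectories, g_s=5, max_g=30)
        assert len(curve) == 30
        late = curve[curve["g"] >= 20]["ne"]
        assert late.mean() == pytest.approx(500, rel=0.15)

    def test_fixed_markers_excluded(self):
        traj = np.vstack([
            np.full(31, 0.5),                 # survives
            np.concatenate([[0.5, 0.3], np.zeros(29)]),  # lost early
        ])
        curve = multi_generation_ne_curve(traj, g_s=5, max_g=30)
        assert (curve["n_markers"] == 1).all()

    def test_no_survivors_returns_empty(self):
        traj = np.zeros((3, 31))
        traj[:, 0] = 0.5
        curve = multi_generation_ne_curve(traj, g_s=5, max_g=30)
        assert curve.empty

    def test_short_trajectories_rejected(self):
        with pytest.raises(ValueError):
            multi_generation_ne_curve(np.zeros((2, 10)), g_s=5, max_g=30)
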