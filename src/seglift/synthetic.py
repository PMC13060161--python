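"""Synthetic trajectory generators and deterministic oracles.

Three generators back the test/validation machinery of the package:

* binomial-drift trajectories at known effective size (oracle for the
  temporal-F effective-size estimator),
* periodic trajectories of known amplitude (oracle for amplitude statistics),
* the infinite-population single-locus recursion of the segregation-lift
  model (oracle for the forward simulator's large-N behaviour).

All fixtures are reproducible from (parameters, seed) and can be written in
the same trajectory table format the forward simulator emits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sl_fitness import SUMMER, WINTER, SeasonalLocusParams

__all__ = [
    "DriftFixture",
    "PeriodicFixture",
    "generate_drift",
    "generate_periodic",
    "single_locus_recursion",
    "trajectories_to_frame",
]


@dataclass
class DriftFixture:
    """Pure binomial-drift allele-frequency trajectories at known diploid size.

    ``trajectories`` has shape ``(n_markers, g + 1)``; column 0 is the initial
    frequency ``p0``.
    """

    true_N: int
    n_markers: int
    g: int
    p0: float
    seed: int | None
    trajectories: np.ndarray = field(repr=False)


@dataclass
class PeriodicFixture:
    """Periodic trajectories with known per-cycle range ``peak - trough``."""

    period: int
    peak: float
    trough: float
    n_cycles: int
    jitter_sd: float
    seed: int | None
    trajectories: np.ndarray = field(repr=False)


def generate_drift(
    true_N: int,
    n_markers: int,
    g: int,
    seed: int | None = None,
    p0: float = 0.5,
) -> DriftFixture:
    """Simulate neutral Wright–Fisher drift: ``p(t+1) ~ Binomial(2N, p(t)) / 2N``."""
    if true_N < 2:
        raise ValueError("true_N must be >= 2")
    rng = np.random.default_rng(seed)
    traj = np.empty((n_markers, g + 1), dtype=np.float64)
    traj[:, 0] = p0
    two_n = 2 * true_N
    p = np.full(n_markers, p0)
    for t in range(1, g + 1):
        p = rng.binomial(two_n, p) / two_n
        traj[:, t] = p
    return DriftFixture(true_N, n_markers, g, p0, seed, traj)


def generate_periodic(
    period: int,
    peak: float,
    trough: float,
    n_cycles: int,
    jitter_sd: float = 0.0,
    seed: int | None = None,
    shape: str = "square",
) -> PeriodicFixture:
    """Single trajectory oscillating between ``peak`` and ``trough``.

    ``shape='square'`` (default) spends each half-cycle flat at one extreme,
    matching step-like seasonal dynamics; ``shape='sine'`` gives a sinusoid
    with the same range. Optional Gaussian jitter is added pointwise and the
    result clipped to [0, 1].
    """
    if not (0.0 <= trough <= peak <= 1.0):
        raise ValueError("require 0 <= trough <= peak <= 1")
    if period < 2 or period % 2:
        raise ValueError("period must be an even integer >= 2")
    n_gen = period * n_cycles
    t = np.arange(n_gen)
    if shape == "square":
        half = period // 2
        high = (t % period) < half
        traj = np.where(high, peak, trough).astype(np.float64)
    elif shape == "sine":
        mid, amp = 0.5 * (peak + trough), 0.5 * (peak - trough)
        traj = mid + amp * np.sin(2 * np.pi * t / period)
    else:
        raise ValueError(f"unknown shape {shape!r}")
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        traj = np.clip(traj + rng.normal(0.0, jitter_sd, size=n_gen), 0.0, 1.0)
    return PeriodicFixture(period, peak, trough, n_cycles, jitter_sd, seed, traj)


def single_locus_recursion(
    params: SeasonalLocusParams,
    y: float,
    g_s: int,
    p0: float = 0.5,
    n_generations: int = 100,
    start_season: str = SUMMER,
) -> np.ndarray:
    """Deterministic infinite-population trajectory of one seasonal locus.

    Assumes Hardy–Weinberg proportions each generation (valid under random
    mating with a single locus). With ``p`` the summer-allele frequency and
    genotype fitnesses ``w_g = (1 + c_g)**y`` from the locus's seasonal
    contributions ``c_g``, one generation of fitness-proportional reproduction
    gives

        p' = [p^2 * w_SS + p(1-p) * w_SW] / w_bar,

    where ``w_bar = p^2 w_SS + 2p(1-p) w_SW + (1-p)^2 w_WW``. The season flips
    every ``g_s`` generations. Returns frequencies of length
    ``n_generations + 1`` including ``p0``; this is the large-N expectation of
    the stochastic simulator and serves as its oracle.
    """
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must be strictly inside (0, 1)")
    if y < 0:
        raise ValueError("y must be >= 0")
    traj = np.empty(n_generations + 1, dtype=np.float64)
    traj[0] = p = p0
    for gen in range(n_generations):
        season_idx = (gen // g_s) % 2
        season = start_season if season_idx == 0 else (
            WINTER if start_season == SUMMER else SUMMER
        )
        if season == SUMMER:
            c = np.array([0.0, params.delta_s * params.d_s, params.delta_s])
        else:
            c = np.array([params.delta_w, params.delta_w * params.d_w, 0.0])
        w = (1.0 + c) ** y if y > 0 else np.ones(3)
        q = 1.0 - p
        geno = np.array([q * q, 2 * p * q, p * p])  # WW, SW, SS
        w_bar = float(geno @ w)
        p = (p * p * w[2] + p * q * w[1]) / w_bar
        traj[gen + 1] = p
    return traj


def trajectories_to_frame(
    trajectories: np.ndarray,
    g_s: int | None = None,
    start_generation: int = 0,
) -> pd.DataFrame:
    """Long-format trajectory table (generation, season, locus_id, frequency,
    segregating) matching the forward simulator's output schema."""
    traj = np.atleast_2d(np.asarray(trajectories, dtype=np.float64))
    n_loci, n_gen = traj.shape
    gens = start_generation + np.arange(n_gen)
    if g_s is None:
        season = np.full(n_gen, "na", dtype=object)
    else:
        season = np.where((gens // g_s) % 2 == 0, SUMMER, WINTER)
    frames = []
    for lid in range(n_loci):
        p = traj[lid]
        frames.append(
            pd.DataFrame(
                {
                    "generation": gens,
                    "season": season,
                    "locus_id": lid,
                    "frequency": p,
                    "segregating": (p > 0) & (p < 1),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
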