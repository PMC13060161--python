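"""Instantaneous variance effective population size from neutral-marker change.

The temporal method: a neutral marker inserted at frequency 0.5 drifts to
frequency ``p_g`` after ``g`` generations; its standardised variance is

    F = (p_g - 0.5)^2 / 0.25

(the denominator is ``p0 (1 - p0)`` at the insertion frequency of one half).
Averaging F over markers and inverting the expected decay of heterozygosity
in an ideal Wright-Fisher population gives the variance effective size

    Ne = -g / (2 ln(1 - F)),

which for small F reduces to the familiar ``Ne ~ g / (2 F)``. Under pure
drift the estimate recovers the census size; under seasonally fluctuating
selection the inflated variance in offspring number raises F genome-wide and
the estimate drops below census. Reductions are reported against the census
size under constant demography and against the harmonic mean of the
per-generation sizes over the measurement window otherwise.

Aggregation follows the mean-F-then-transform rule: F is averaged across
markers (per arm group in linked mode) before the transformation to Ne.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulator import Simulation

__all__ = [
    "NeEstimate",
    "standardized_variance",
    "variance_ne",
    "harmonic_mean_size",
    "estimate_reduction",
    "measure_ne",
    "within_cycle_ne_series",
    "multi_generation_ne_curve",
]


@dataclass
class NeEstimate:
    """Variance-Ne estimate for one group of markers over one window."""

    arm_group: str
    mean_F: float
    g: int
    ne: float                      # diploid individuals; inf when F == 0
    baseline: float                # census N or harmonic-mean size
    n_markers: int
    F_per_marker: np.ndarray = field(default=None, repr=False)

    @property
    def estimable(self) -> bool:
        return np.isfinite(self.ne)

    @property
    def reduction(self) -> float:
        """Relative shortfall 1 - Ne/baseline (0 = no reduction; negative
        values mean the estimate exceeds baseline)."""
        if not np.isfinite(self.ne):
            return 0.0 if self.mean_F == 0.0 else float("nan")
        return 1.0 - self.ne / self.baseline

    def to_row(self) -> dict:
        return {
            "arm_group": self.arm_group,
            "mean_F": self.mean_F,
            "g": self.g,
            "ne": self.ne,
            "baseline": self.baseline,
            "reduction": self.reduction,
            "n_markers": self.n_markers,
        }


def standardized_variance(p0, p_g) -> np.ndarray | float:
    """Standardised variance F of an allele-frequency change from ``p0``.

    The denominator is fixed at 0.25 = 0.5 * (1 - 0.5): markers are inserted
    at exactly one half by construction. A warning is raised if ``p0``
    deviates, since the fixed denominator then no longer equals p0 (1 - p0).
    """
    p0_arr = np.asarray(p0, dtype=np.float64)
    pg_arr = np.asarray(p_g, dtype=np.float64)
    if np.any(p0_arr != 0.5):
        warnings.warn(
            "standardized_variance assumes insertion frequency 0.5; the "
            "0.25 denominator is inexact for other p0", stacklevel=2)
    F = (pg_arr - p0_arr) ** 2 / 0.25
    return float(F) if F.ndim == 0 else F


def variance_ne(mean_F: float, g: int) -> float:
    """Invert mean F to a variance effective size: ``-g / (2 ln(1 - F))``.

    Returns ``inf`` for F == 0 (no detectable drift) and ``nan`` for F >= 1
    (every marker fixed: the decay model carries no signal).
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    if mean_F < 0:
        raise ValueError("mean F cannot be negative")
    if mean_F == 0.0:
        return float("inf")
    if mean_F >= 1.0:
        return float("nan")
    return -g / (2.0 * np.log(1.0 - mean_F))


def harmonic_mean_size(sizes) -> float:
    """Harmonic mean of per-generation census sizes (the drift-relevant
    average under varying demography)."""
    s = np.asarray(sizes, dtype=np.float64)
    if s.size == 0 or np.any(s <= 0):
        raise ValueError("sizes must be a non-empty positive sequence")
    return float(len(s) / np.sum(1.0 / s))


def estimate_reduction(ne: float, baseline: float) -> float:
    """Relative reduction 1 - Ne/baseline."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return 1.0 - ne / baseline


def _group_estimates(sim: Simulation, p_end: np.ndarray, g: int,
                     baseline: float) -> list[NeEstimate]:
    F = standardized_variance(0.5, p_end)
    groups = sim.marker_arm_groups()
    out = []
    labels = (["pooled"] if not sim.linked
              else ["pooled", "selected_arms", "neutral_arm"])
    for label in labels:
        mask = np.ones(len(F), bool) if label == "pooled" else groups == label
        if not mask.any():
            continue
        mF = float(F[mask].mean())
        out.append(NeEstimate(label, mF, g, variance_ne(mF, g), baseline,
                              int(mask.sum()), F[mask]))
    return out


def _window_baseline(sim: Simulation, start_gen: int, g: int) -> float:
    cfg = sim.config
    sizes = [cfg.demography.size_at(t, cfg.generations_per_season)
             for t in range(start_gen + 1, start_gen + g + 1)]
    if cfg.demography.mode == "constant":
        return float(sizes[0])
    return harmonic_mean_size(sizes)


def measure_ne(
    sim: Simulation,
    g: int | None = None,
    n_markers: int | None = None,
    remove_after: bool = True,
) -> list[NeEstimate]:
    """Insert fresh neutral markers at 0.5, advance ``g`` generations and
    estimate Ne from the frequency change.

    ``g`` defaults to one full seasonal cycle. In linked mode markers are laid
    on the genome grid and estimates are returned pooled and per arm group
    (arms carrying seasonal loci vs the selection-free arm); in unlinked mode
    ``n_markers`` independent markers give a single pooled estimate. The
    baseline is census size under constant demography, otherwise the harmonic
    mean over the measurement window. Markers are removed afterwards unless
    ``remove_after=False``.
    """
    cfg = sim.config
    if g is None:
        g = cfg.cycle_length
    start = sim.generation
    if sim.linked:
        sim.insert_neutral_markers()
    else:
        sim.insert_neutral_markers(count=n_markers or 200)
    sim.run(g)
    p_end = sim.neutral_frequencies()
    baseline = _window_baseline(sim, start, g)
    estimates = _group_estimates(sim, p_end, g, baseline)
    if remove_after:
        sim.remove_neutral_markers()
    return estimates


def within_cycle_ne_series(
    sim: Simulation,
    n_markers: int | None = None,
) -> pd.DataFrame:
    """Per-generation Ne across one full seasonal cycle (g = 1 estimates).

    At each of the next ``2 * generations_per_season`` generations, fresh
    markers are inserted at 0.5, the population advances one generation, Ne
    is estimated from that single-generation change, and the markers are
    removed. The caller is responsible for having burnt the simulation in to
    amplitude stationarity first. Returns one row per (generation within
    cycle, arm group).
    """
    rows = []
    for k in range(sim.config.cycle_length):
        season = sim.season
        for est in measure_ne(sim, g=1, n_markers=n_markers):
            row = est.to_row()
            row.update({"cycle_position": k, "season": season,
                        "generation": sim.generation})
            rows.append(row)
    return pd.DataFrame(rows)


def multi_generation_ne_curve(
    trajectories: np.ndarray,
    g_s: int,
    max_g: int = 30,
    p0: float = 0.5,
) -> pd.DataFrame:
    """Ne(g) for g = 1..max_g from marker trajectories, restricted to markers
    still segregating after three complete seasonal cycles.

    ``trajectories`` has shape ``(n_markers, T+1)`` with column 0 at the
    insertion frequency. Short-window estimates are expected to be biased
    toward census (noise-dominated); the curve should approach the long-run
    Ne as g grows. Returns an empty frame if no marker survives the cutoff.
    """
    traj = np.atleast_2d(np.asarray(trajectories, dtype=np.float64))
    if traj.shape[1] <= max_g:
        raise ValueError(f"trajectories must cover at least {max_g} generations")
    cutoff = min(3 * 2 * g_s, traj.shape[1] - 1)
    p_cut = traj[:, cutoff]
    surviving = (p_cut > 0.0) & (p_cut < 1.0)
    if not surviving.any():
        return pd.DataFrame(columns=["g", "mean_F", "ne", "n_markers"])
    sub = traj[surviving]
    rows = []
    for g in range(1, max_g + 1):
        mF = float(np.mean((sub[:, g] - p0) ** 2 / 0.25))
        rows.append({"g": g, "mean_F": mF, "ne": variance_ne(mF, g),
                     "n_markers": int(surviving.sum())})
    return pd.DataFrame(rows)
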