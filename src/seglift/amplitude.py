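"""Summary statistics of seasonal-locus dynamics.

The seasonal amplitude of a locus is the within-cycle range (maximum minus
minimum frequency) of its allele-frequency trajectory, averaged over
consecutive cycles (one cycle = one summer plus one winter). Summaries are
computed over segregating loci only — a lost or fixed locus no longer
fluctuates and is excluded — and report the mean, median, maximum and 90th
percentile amplitude together with the identity of the maximum-amplitude
locus, which is the best single predictor of the effective-size reduction
under this model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulator import TrajectorySet

__all__ = [
    "AmplitudeSummary",
    "locus_amplitude",
    "count_segregating",
    "summarize_window",
    "summarize_trajectories",
]


@dataclass
class AmplitudeSummary:
    """Amplitude distribution over segregating loci at one timepoint."""

    timepoint: int
    n_segregating: int
    mean: float
    median: float
    max: float
    q90: float
    max_locus_id: int                 # -1 when no locus segregates
    amplitudes: pd.DataFrame          # per-locus: locus_id, amplitude
    empty: bool = False

    def to_row(self) -> dict:
        return {
            "timepoint": self.timepoint,
            "n_segregating": self.n_segregating,
            "mean_amplitude": self.mean,
            "median_amplitude": self.median,
            "max_amplitude": self.max,
            "q90_amplitude": self.q90,
            "max_locus_id": self.max_locus_id,
        }


def locus_amplitude(trajectory, cycle_length: int, n_cycles: int = 3) -> float:
    """Mean over cycles of the within-cycle frequency range.

    ``trajectory`` must cover at least ``n_cycles * cycle_length``
    consecutive generations; only the first ``n_cycles`` complete cycles are
    used.
    """
    p = np.asarray(trajectory, dtype=np.float64)
    need = n_cycles * cycle_length
    if p.shape[-1] < need:
        raise ValueError(
            f"trajectory of length {p.shape[-1]} does not cover "
            f"{n_cycles} cycles of {cycle_length} generations")
    cyc = p[..., :need].reshape(*p.shape[:-1], n_cycles, cycle_length)
    ranges = cyc.max(axis=-1) - cyc.min(axis=-1)
    out = ranges.mean(axis=-1)
    return float(out) if out.ndim == 0 else out


def count_segregating(frequencies) -> int:
    """Number of loci with frequency strictly inside (0, 1)."""
    f = np.asarray(frequencies, dtype=np.float64)
    return int(np.sum((f > 0.0) & (f < 1.0)))


def _quantile90(values: np.ndarray) -> float:
    # linear interpolation between order statistics (numpy default)
    return float(np.quantile(values, 0.9))


def summarize_window(
    frequencies: np.ndarray,
    locus_ids: np.ndarray,
    cycle_length: int,
    timepoint: int,
    n_cycles: int = 3,
) -> AmplitudeSummary:
    """Amplitude summary from a per-generation frequency window.

    ``frequencies`` has shape ``(n_generations, L)`` covering at least
    ``n_cycles`` complete cycles ending at ``timepoint``. Loci counted as
    segregating — and entering the summary — are those segregating at the
    final recorded generation of the window.
    """
    f = np.asarray(frequencies, dtype=np.float64)
    seg = (f[-1] > 0.0) & (f[-1] < 1.0)
    ids = np.asarray(locus_ids)
    if not seg.any():
        empty_df = pd.DataFrame(columns=["locus_id", "amplitude"])
        return AmplitudeSummary(timepoint, 0, np.nan, np.nan, np.nan, np.nan,
                                -1, empty_df, empty=True)
    amps = locus_amplitude(f[:, seg].T, cycle_length, n_cycles)
    amps = np.atleast_1d(amps)
    seg_ids = ids[seg]
    per_locus = pd.DataFrame({"locus_id": seg_ids, "amplitude": amps})
    imax = int(np.argmax(amps))
    return AmplitudeSummary(
        timepoint=timepoint,
        n_segregating=int(seg.sum()),
        mean=float(amps.mean()),
        median=float(np.median(amps)),
        max=float(amps.max()),
        q90=_quantile90(amps),
        max_locus_id=int(seg_ids[imax]),
        amplitudes=per_locus,
    )


def summarize_trajectories(
    traj: TrajectorySet,
    timepoints,
    n_cycles: int = 3,
) -> pd.DataFrame:
    """Amplitude summaries at several timepoints of a recorded trajectory set.

    For each requested timepoint the window is the ``n_cycles`` complete
    cycles ending at that generation; every generation of the window must
    have been recorded. Returns one row per timepoint (see
    :meth:`AmplitudeSummary.to_row`).
    """
    cycle = 2 * traj.generations_per_season
    gen_index = {int(g): i for i, g in enumerate(traj.generations)}
    rows = []
    for tp in timepoints:
        need = [tp - k for k in range(n_cycles * cycle, 0, -1)]
        try:
            rows_idx = [gen_index[g] for g in need]
        except KeyError as exc:
            raise ValueError(
                f"timepoint {tp} requires per-generation recording over its "
                f"preceding {n_cycles} cycles (missing generation {exc})"
            ) from exc
        window = traj.frequencies[rows_idx]
        ids = (traj.locus_ids if traj.locus_ids is not None
               else np.arange(window.shape[1]))
        rows.append(summarize_window(window, ids, cycle, tp, n_cycles).to_row())
    return pd.DataFrame(rows)
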