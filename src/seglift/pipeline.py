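"""End-to-end orchestration: calibrate -> simulate -> amplitudes -> Ne.

One call runs the stages a scenario file requests and leaves a manifest
beside the outputs. A single master seed spawns independent per-stage
substreams, so rerunning any subset of stages with the same seed reproduces
its outputs bit for bit, and the amplitude stage can resume from a saved
trajectory table instead of re-simulating.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .amplitude import summarize_trajectories
from .calibration import CalibrationTarget, derive_scenario
from .config import (
    ConfigError,
    RunManifest,
    config_hash,
    load_scenario,
    stage_rngs,
)
from .ne import measure_ne
from .simulator import TrajectorySet, run_scenario
from .sl_fitness import params_to_frame, sample_locus_params

__all__ = ["run_pipeline", "resolve_calibrated_scenario"]

_STAGES = ("simulate", "amplitudes", "ne")


def _write_tsv(df: pd.DataFrame, path, chash: str) -> None:
    """TSV with a header comment recording the resolved-config hash."""
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {chash}\n")
        df.to_csv(fh, sep="\t", index=False)


def resolve_calibrated_scenario(path):
    """Load a scenario file, filling locus count and epistasis from a
    ``calibration_target`` block (n_final, mean_amplitude) when present.

    Returns (name, config, seed, derivation-dict-or-None).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    derivation = None
    if isinstance(raw, dict) and "calibration_target" in raw:
        block = raw["calibration_target"]
        try:
            target = CalibrationTarget(int(block["n_final"]),
                                       float(block["mean_amplitude"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(
                f"{path}: invalid calibration_target block ({exc})") from exc
        derivation = derive_scenario(target)
        raw.setdefault("n_seasonal_loci", derivation["n_initial_loci"])
        raw.setdefault("epistasis_y", derivation["epistasis_y"])
        import tempfile, os
        # round-trip through the ordinary loader so validation is uniform
        with tempfile.NamedTemporaryFile(
                "w", suffix=".yaml", delete=False) as tmp:
            yaml.safe_dump(raw, tmp)
            tmp_path = tmp.name
        try:
            name, config, seed = load_scenario(tmp_path)
        finally:
            os.unlink(tmp_path)
        if name == Path(tmp_path).stem:
            name = raw.get("name", Path(path).stem)
        return name, config, seed, derivation
    name, config, seed = load_scenario(path)
    return name, config, seed, None


def run_pipeline(
    config_path,
    out_dir,
    seed: int | None = None,
    stages: tuple[str, ...] = _STAGES,
    n_markers: int = 200,
    amplitude_cycles: int = 3,
) -> dict:
    """Run the requested stages of a scenario and write outputs + manifest.

    Stages: ``simulate`` (trajectory and locus-snapshot TSVs; the final
    ``amplitude_cycles`` cycles are recorded per generation), ``amplitudes``
    (summary at the final generation; resumes from ``trajectories.tsv`` if
    simulation is skipped), ``ne`` (one-cycle variance-Ne estimate from
    fresh neutral markers, requiring the simulate stage in the same run).
    Returns a dict with the manifest data and the in-memory stage results.
    """
    unknown = set(stages) - set(_STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    name, config, file_seed, derivation = resolve_calibrated_scenario(
        config_path)
    if seed is None:
        seed = file_seed
    if seed is None:
        raise ConfigError(f"{config_path}: no seed given")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rngs = stage_rngs(int(seed), ["loci", "simulation", "ne"])
    manifest = RunManifest(name, config, int(seed))
    if derivation is not None:
        manifest.data["calibration"] = derivation
    results: dict = {"name": name, "config": config, "seed": int(seed)}

    chash = config_hash(config)
    cycle = config.cycle_length
    traj = sim = None
    if "simulate" in stages:
        loci = (sample_locus_params(config.n_seasonal_loci, rngs["loci"])
                if config.n_seasonal_loci else [])
        window_start = max(0, config.total_generations
                           - amplitude_cycles * cycle)
        traj, sim = run_scenario(
            config, loci, rngs["simulation"],
            record_windows=[(window_start, config.total_generations + 1)])
        traj_path = out / "trajectories.tsv"
        traj_df = traj.to_frame()
        traj_df["frequency"] = traj_df["frequency"].map(lambda v: f"{v:.6f}")
        _write_tsv(traj_df, traj_path, chash)
        manifest.record_output("trajectories", traj_path)
        snap = params_to_frame(sim.loci)
        snap["final_frequency"] = [
            f"{v:.6f}" for v in sim.seasonal_frequencies()]
        snap_path = out / "locus_snapshot.tsv"
        _write_tsv(snap, snap_path, chash)
        manifest.record_output("locus_snapshot", snap_path)
        results["trajectories"] = traj

    if "amplitudes" in stages and config.n_seasonal_loci:
        if traj is None:
            traj_path = out / "trajectories.tsv"
            if not traj_path.exists():
                raise ConfigError(
                    "amplitude stage needs a simulate stage or a saved "
                    f"trajectory table at {traj_path}")
            df = pd.read_csv(traj_path, sep="\t", comment="#")
            wide = df.pivot(index="generation", columns="locus_id",
                            values="frequency")
            traj = TrajectorySet(
                generations=wide.index.to_numpy(),
                frequencies=wide.to_numpy(),
                generations_per_season=config.generations_per_season,
                locus_ids=wide.columns.to_numpy())
        summary = summarize_trajectories(
            traj, [int(traj.generations[-1])], n_cycles=amplitude_cycles)
        amp_path = out / "amplitude_summary.tsv"
        _write_tsv(summary, amp_path, chash)
        manifest.record_output("amplitude_summary", amp_path)
        results["amplitudes"] = summary

    if "ne" in stages:
        if sim is None:
            raise ConfigError("ne stage requires the simulate stage")
        sim.rng = rngs["ne"]  # markers and the extra cycle get their own stream
        estimates = measure_ne(sim, g=cycle, n_markers=n_markers)
        ne_df = pd.DataFrame([e.to_row() for e in estimates])
        ne_df.insert(0, "timepoint", sim.generation)
        ne_path = out / "ne_estimates.tsv"
        _write_tsv(ne_df, ne_path, chash)
        manifest.record_output("ne_estimates", ne_path)
        results["ne"] = estimates

    manifest.write(out / "manifest.json")
    results["manifest"] = manifest.data
    return results
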