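"""Scenario configuration files, run manifests and result serialisation.

Scenarios are described in YAML. A minimal file::

    name: neutral-check
    n_seasonal_loci: 0
    epistasis_y: 1.0
    generations_per_season: 10
    total_generations: 200
    demography:
      mode: constant
      summer_size: 1000
    seed: 42

Optional blocks: ``genome`` (mode, arms, neutral_spacing_bp,
seasonal_arms), ``offspring_cap``, ``scale_factor`` (applied via
:func:`seglift.simulator.rescale_config` after parsing), and
``recombination_map`` (path to a BED-like TSV: chrom, start, end,
rate-per-bp, 0-based half-open; overrides per-arm uniform rates with
per-interval arms).

A run manifest records the fully resolved (post-scaling) configuration, the
seed and every output path, so any run can be reproduced bit for bit from
its manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulator import (
    Arm,
    DemographySchedule,
    GenomeLayout,
    SimulationConfig,
    rescale_config,
)

__all__ = [
    "load_scenario",
    "read_recombination_map",
    "config_to_dict",
    "config_hash",
    "RunManifest",
]


class ConfigError(ValueError):
    pass


def read_recombination_map(path) -> list[Arm]:
    """Read a BED-like recombination map (chrom, start, end, rate_per_bp;
    0-based half-open) into per-interval arms.

    Each interval becomes its own uniform-rate arm named
    ``{chrom}:{start}-{end}`` grouped under its chromosome, giving a
    piecewise-constant map.
    """
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["chrom", "start", "end", "rate"], header=None,
                     dtype={"chrom": str})
    arms = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if end <= start:
            raise ConfigError(f"empty interval {row.chrom}:{start}-{end}")
        if row.rate < 0:
            raise ConfigError("negative recombination rate")
        arms.append(Arm(name=f"{row.chrom}:{start}-{end}",
                        length_bp=end - start, rate=float(row.rate),
                        chromosome=str(row.chrom)))
    if not arms:
        raise ConfigError(f"recombination map {path} is empty")
    return arms


def _build_genome(block: dict | None, map_path=None) -> GenomeLayout:
    block = dict(block or {})
    mode = block.get("mode", "unlinked")
    if mode == "unlinked":
        return GenomeLayout(mode="unlinked",
                            neutral_spacing_bp=block.get("neutral_spacing_bp",
                                                         100_000))
    if map_path is not None:
        arms = tuple(read_recombination_map(map_path))
    elif "arms" in block:
        arms = tuple(
            Arm(name=a["name"], length_bp=int(a["length_bp"]),
                rate=float(a.get("rate", 2e-8)),
                chromosome=a.get("chromosome"))
            for a in block["arms"])
    else:
        arms = GenomeLayout.dmel_default().arms
    kwargs = {}
    if "seasonal_arms" in block:
        kwargs["seasonal_arms"] = tuple(block["seasonal_arms"])
    elif map_path is not None:
        # seasonal loci allowed on every mapped chromosome-arm interval
        # except those on the 3R arm (kept selection-free)
        kwargs["seasonal_arms"] = tuple(
            a.name for a in arms if not a.name.startswith("3R"))
    return GenomeLayout(mode="linked", arms=arms,
                        neutral_spacing_bp=block.get("neutral_spacing_bp",
                                                     100_000),
                        **kwargs)


def _build_demography(block: dict | None, default_n: int | None = None) -> DemographySchedule:
    if block is None:
        if default_n is None:
            raise ConfigError("scenario needs a demography block or population_size")
        return DemographySchedule(summer_size=int(default_n))
    mode = block.get("mode", "constant")
    if mode == "custom":
        return DemographySchedule(mode="custom",
                                  sizes=tuple(int(s) for s in block["sizes"]))
    return DemographySchedule(
        mode=mode,
        summer_size=int(block["summer_size"]),
        winter_size=(int(block["winter_size"])
                     if block.get("winter_size") is not None else None),
    )


def load_scenario(path) -> tuple[str, SimulationConfig, int | None]:
    """Parse a scenario YAML file into (name, config, seed).

    Raises :class:`ConfigError` naming the offending key on invalid input.
    Any ``scale_factor`` in the file is applied before returning, so the
    returned config is the one that actually runs.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: scenario file must be a mapping")
    try:
        demo = _build_demography(raw.get("demography"),
                                 raw.get("population_size"))
        genome = _build_genome(raw.get("genome"),
                               raw.get("recombination_map"))
        config = SimulationConfig(
            n_seasonal_loci=int(raw["n_seasonal_loci"]),
            epistasis_y=float(raw["epistasis_y"]),
            generations_per_season=int(raw["generations_per_season"]),
            total_generations=int(raw["total_generations"]),
            demography=demo,
            genome=genome,
            offspring_cap=(int(raw["offspring_cap"])
                           if raw.get("offspring_cap") is not None else None),
            initial_frequency=float(raw.get("initial_frequency", 0.5)),
            record_every=int(raw.get("record_every", 1)),
        )
    except KeyError as exc:
        raise ConfigError(f"{path}: missing required key {exc}") from exc
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    factor = int(raw.get("scale_factor", 1))
    if factor > 1:
        config = rescale_config(config, factor)
    seed = raw.get("seed")
    return str(raw.get("name", Path(path).stem)), config, \
        (int(seed) if seed is not None else None)


def config_to_dict(config: SimulationConfig) -> dict:
    """JSON-serialisable dump of a fully resolved config."""

    def _clean(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if hasattr(obj, "__dataclass_fields__"):
            return {f: _clean(getattr(obj, f))
                    for f in obj.__dataclass_fields__}
        return obj

    return _clean(config)


def config_hash(config: SimulationConfig) -> str:
    blob = json.dumps(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


class RunManifest:
    """Reproducibility record for one pipeline run.

    Collects the scenario name, resolved config, seed, package version and
    the path of every stage output; re-running from a manifest (same
    config + seed) reproduces all stochastic outputs bit for bit because a
    single master seed spawns per-stage substreams.
    """

    def __init__(self, name: str, config: SimulationConfig, seed: int):
        from . import __version__
        self.data = {
            "scenario": name,
            "seed": int(seed),
            "version": __version__,
            "config_hash": config_hash(config),
            "config": config_to_dict(config),
            "outputs": {},
            "stamps": {},
        }

    def record_output(self, stage: str, path) -> None:
        self.data["outputs"][stage] = str(path)
        self.data["stamps"][stage] = time.strftime("%Y-%m-%dT%H:%M:%S")

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2)

    @staticmethod
    def read(path) -> dict:
        with open(path) as fh:
            return json.load(fh)


def stage_rngs(master_seed: int, stages: list[str]) -> dict[str, np.random.Generator]:
    """Independent per-stage generators spawned from one master seed, so
    adding a stage never perturbs the randomness of earlier stages."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(stages))
    return {name: np.random.default_rng(child)
            for name, child in zip(stages, children)}
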