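"""Individual-based Wright–Fisher forward simulation with seasonal cycling.

Diploid, non-overlapping generations, soft selection: each generation the
census size is dictated by the demography schedule and every offspring draws
two distinct parents with probability proportional to current-season fitness
``w(z) = (1 + z)**y``. Selection therefore redistributes reproductive success
without altering census size, and any reduction in effective size is due to
increased variance in offspring number.

Two genome modes are supported:

* ``unlinked`` — every seasonal locus and neutral marker assorts
  independently. State is a dosage matrix ``(N, L)``; this is the fast path.
* ``linked`` — loci live at basepair positions on chromosome arms (default:
  the two major D. melanogaster autosomes, arms 2L/2R/3L/3R, with seasonal
  loci excluded from 3R). Crossover counts per chromosome are Poisson with
  mean equal to the genetic map length; positions follow the cumulative
  recombination map. Chromosomes assort freely.

No mutation, migration or selfing is modelled. A per-parent offspring cap can
be imposed: parent draws beyond the quota are rejected and redrawn
(fitness-proportionally) among parents still under quota, mirroring
allocation of alternate parents once a parent has filled its quota.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import (
    mendel_transmit_kernel,
    sample_parents_kernel,
    scores_kernel,
    seed_kernel_rng,
)
from .sl_fitness import SUMMER, WINTER, SeasonalLocusParams, contribution_table

__all__ = [
    "Arm",
    "GenomeLayout",
    "DemographySchedule",
    "SimulationConfig",
    "TrajectorySet",
    "Simulation",
    "rescale_config",
    "run_scenario",
    "season_of",
]


def season_of(generation: int, g_s: int) -> str:
    """Season of a generation index. Simulations start in summer; the season
    flips every ``g_s`` generations."""
    return SUMMER if (generation // g_s) % 2 == 0 else WINTER


@dataclass(frozen=True)
class Arm:
    """Chromosome arm with a uniform per-bp recombination rate.

    ``rate`` is in Morgans per basepair per generation; ``chromosome`` groups
    arms that are physically linked (default: leading character of the name,
    so 2L/2R share chromosome "2").
    """

    name: str
    length_bp: int
    rate: float = 2e-8
    chromosome: str | None = None

    @property
    def chrom(self) -> str:
        return self.chromosome if self.chromosome is not None else self.name[0]

    @property
    def map_length(self) -> float:
        return self.rate * self.length_bp


@dataclass(frozen=True)
class GenomeLayout:
    """Genome mode and arm geometry.

    In linked mode seasonal loci are placed uniformly at random on
    ``seasonal_arms`` only; by default arm 3R carries none, so neutral markers
    there are unlinked to selection. Neutral markers are spaced every
    ``neutral_spacing_bp`` on all arms (centred grid: spacing/2, 3·spacing/2,
    ...).
    """

    mode: str = "unlinked"
    arms: tuple[Arm, ...] = ()
    seasonal_arms: tuple[str, ...] = ("2L", "2R", "3L")
    neutral_spacing_bp: int = 100_000

    def __post_init__(self) -> None:
        if self.mode not in ("unlinked", "linked"):
            raise ValueError("genome mode must be 'unlinked' or 'linked'")
        if self.mode == "linked" and not self.arms:
            raise ValueError("linked mode requires at least one arm")

    @classmethod
    def dmel_default(cls, mode: str = "linked", rate: float = 2e-8,
                     neutral_spacing_bp: int = 100_000) -> "GenomeLayout":
        """Approximate D. melanogaster major-autosome layout (2L, 2R, 3L, 3R)."""
        arms = (
            Arm("2L", 23_500_000, rate),
            Arm("2R", 25_300_000, rate),
            Arm("3L", 28_100_000, rate),
            Arm("3R", 32_100_000, rate),
        )
        return cls(mode=mode, arms=arms, neutral_spacing_bp=neutral_spacing_bp)


@dataclass(frozen=True)
class DemographySchedule:
    """Census size per generation. ``constant`` uses ``summer_size``
    throughout; ``boom_bust`` alternates ``summer_size``/``winter_size`` with
    the seasons; ``custom`` follows an explicit per-generation size array."""

    mode: str = "constant"
    summer_size: int = 1000
    winter_size: int | None = None
    sizes: tuple[int, ...] | None = None  # custom mode

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "boom_bust", "custom"):
            raise ValueError(f"unknown demography mode {self.mode!r}")
        if self.mode == "boom_bust" and self.winter_size is None:
            raise ValueError("boom_bust demography needs winter_size")
        if self.mode == "custom" and not self.sizes:
            raise ValueError("custom demography needs a sizes sequence")
        for s in self._all_sizes():
            if s < 2:
                raise ValueError("census sizes must be >= 2")

    def _all_sizes(self):
        if self.mode == "custom":
            return self.sizes
        return (self.summer_size,) if self.winter_size is None else (
            self.summer_size, self.winter_size)

    def size_at(self, generation: int, g_s: int) -> int:
        if self.mode == "custom":
            return int(self.sizes[min(generation, len(self.sizes) - 1)])
        if self.mode == "constant":
            return int(self.summer_size)
        return int(self.summer_size if season_of(generation, g_s) == SUMMER
                   else self.winter_size)


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulation scenario."""

    n_seasonal_loci: int
    epistasis_y: float
    generations_per_season: int
    total_generations: int
    demography: DemographySchedule = field(
        default_factory=DemographySchedule)
    genome: GenomeLayout = field(default_factory=GenomeLayout)
    offspring_cap: int | None = None
    initial_frequency: float = 0.5
    record_every: int = 1
    scaling_factor: int = 1            # annotation: factor already applied
    unscaled: dict | None = None       # pre-scaling parameter values

    def __post_init__(self) -> None:
        if self.n_seasonal_loci < 0:
            raise ValueError("n_seasonal_loci must be >= 0")
        if self.epistasis_y <= 0:
            raise ValueError("epistasis_y must be > 0")
        if self.generations_per_season < 1:
            raise ValueError("generations_per_season must be >= 1")
        if self.total_generations % (2 * self.generations_per_season):
            raise ValueError(
                "total_generations must cover whole seasonal cycles "
                "(a multiple of 2 * generations_per_season)")
        if self.offspring_cap is not None and self.offspring_cap < 1:
            raise ValueError("offspring_cap must be >= 1 (or None)")
        if not (0.0 < self.initial_frequency < 1.0):
            raise ValueError("initial_frequency must be in (0, 1)")

    @property
    def cycle_length(self) -> int:
        return 2 * self.generations_per_season


def rescale_config(config: SimulationConfig, factor: int) -> SimulationConfig:
    """Downscale a scenario by an integer factor for computational efficiency.

    Census sizes, generations per season, total generations and the offspring
    cap are all divided by ``factor``; selection parameters (y, effect sizes,
    dominance) are untouched. The returned config carries the unscaled values
    in its ``unscaled`` annotation so results can be reported on the original
    parameter scale.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return config
    demo = config.demography

    def _div(x, what):
        if x % factor:
            raise ValueError(f"{what} ({x}) not divisible by factor {factor}")
        return x // factor

    sizes = None
    if demo.mode == "custom":
        sizes = tuple(_div(s, "census size") for s in demo.sizes)
    new_demo = dataclasses.replace(
        demo,
        summer_size=_div(demo.summer_size, "summer_size"),
        winter_size=None if demo.winter_size is None
        else _div(demo.winter_size, "winter_size"),
        sizes=sizes,
    )
    cap = config.offspring_cap
    if cap is not None:
        cap = max(1, _div(cap, "offspring_cap"))
    return dataclasses.replace(
        config,
        demography=new_demo,
        generations_per_season=_div(config.generations_per_season,
                                    "generations_per_season"),
        total_generations=_div(config.total_generations, "total_generations"),
        offspring_cap=cap,
        scaling_factor=config.scaling_factor * factor,
        unscaled={
            "summer_size": demo.summer_size,
            "winter_size": demo.winter_size,
            "generations_per_season": config.generations_per_season,
            "total_generations": config.total_generations,
            "offspring_cap": config.offspring_cap,
        },
    )


@dataclass
class TrajectorySet:
    """Recorded per-locus allele-frequency time series.

    ``frequencies`` has shape ``(n_recorded, L)`` holding the frequency of
    the summer-favoured (or, for neutral markers, reference) allele.
    """

    generations: np.ndarray
    frequencies: np.ndarray
    generations_per_season: int
    locus_ids: np.ndarray | None = None

    @property
    def seasons(self) -> np.ndarray:
        return np.where(
            (self.generations // self.generations_per_season) % 2 == 0,
            SUMMER, WINTER)

    def segregating(self) -> np.ndarray:
        """Boolean matrix: frequency strictly inside (0, 1)."""
        f = self.frequencies
        return (f > 0.0) & (f < 1.0)

    def to_frame(self) -> pd.DataFrame:
        ids = (self.locus_ids if self.locus_ids is not None
               else np.arange(self.frequencies.shape[1]))
        n_rec, n_loci = self.frequencies.shape
        return pd.DataFrame({
            "generation": np.repeat(self.generations, n_loci),
            "season": np.repeat(self.seasons, n_loci),
            "locus_id": np.tile(ids, n_rec),
            "frequency": self.frequencies.ravel(),
            "segregating": self.segregating().ravel(),
        })

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df["frequency"] = df["frequency"].map(lambda v: f"{v:.6f}")
        df.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# parent sampling


def _draw_indices(cdf: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    idx = np.searchsorted(cdf, rng.random(n) * cdf[-1], side="right")
    return np.minimum(idx, len(cdf) - 1)


def sample_parents(
    weights: np.ndarray,
    n_offspring: int,
    rng: np.random.Generator,
    cap: int | None = None,
) -> np.ndarray:
    """Draw an ``(n_offspring, 2)`` array of parent indices.

    Parent slots are filled sequentially (offspring-major), each draw
    fitness-proportional; the two parents of an offspring are distinct (no
    selfing). If ``cap`` is given, no parent appears more than ``cap`` times
    across all slots: once a parent fills its quota it stops being drawn,
    i.e. over-quota draws are rejected and alternate parents allocated
    fitness-proportionally among those still under quota.
    """
    w = np.ascontiguousarray(weights, dtype=np.float64)
    n_parents = len(w)
    if n_parents < 2:
        raise ValueError("need at least two potential parents")
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("all fitness values are zero or non-finite")
    if cap is not None and cap * n_parents < 2 * n_offspring:
        raise ValueError(
            f"offspring cap {cap} with {n_parents} parents cannot supply "
            f"{2 * n_offspring} parent slots")
    seed_kernel_rng(np.uint32(rng.integers(0, 2**32)))
    parents = sample_parents_kernel(w, int(n_offspring),
                                    int(cap) if cap is not None else 0)
    if np.any(parents < 0):
        raise RuntimeError(
            "parent sampling ran out of eligible parents (infeasible cap "
            "or degenerate fitness distribution)")
    return parents


# --------------------------------------------------------------------------
# simulation engine


class Simulation:
    """Running state of one forward simulation.

    Construct with a :class:`SimulationConfig` and (optionally) a list of
    :class:`SeasonalLocusParams`; if ``loci`` is omitted they are drawn from
    the model's generating distributions with the simulation's RNG. Use
    :meth:`step` / :meth:`run` to advance, :meth:`seasonal_frequencies` and
    :meth:`neutral_frequencies` to observe, and the neutral-marker methods to
    support effective-size estimation.
    """

    def __init__(
        self,
        config: SimulationConfig,
        loci: list[SeasonalLocusParams] | None = None,
        rng: np.random.Generator | int | None = None,
    ):
        self.config = config
        self.rng = np.random.default_rng(rng)
        self.genome = config.genome
        self.linked = self.genome.mode == "linked"
        if loci is None:
            from .sl_fitness import sample_locus_params
            loci = sample_locus_params(config.n_seasonal_loci, self.rng) \
                if config.n_seasonal_loci else []
        if len(loci) != config.n_seasonal_loci:
            raise ValueError("loci list does not match config.n_seasonal_loci")
        self.generation = 0
        self.n = config.demography.size_at(0, config.generations_per_season)
        self.loci = self._place_loci(loci)
        self._ctab = {
            SUMMER: contribution_table(self.loci, SUMMER),
            WINTER: contribution_table(self.loci, WINTER),
        } if self.loci else {SUMMER: np.zeros((0, 3)), WINTER: np.zeros((0, 3))}
        self._init_state()
        # neutral markers (absent until inserted)
        self.n_markers = 0
        self._neutral = None          # dosage (N, M) or haplotypes (N, 2, M)
        self.marker_positions: list[tuple[str, int]] = []

    # -- construction ------------------------------------------------------

    def _place_loci(self, loci: list[SeasonalLocusParams]) -> list[SeasonalLocusParams]:
        if not self.linked or not loci:
            return list(loci)
        arms = [a for a in self.genome.arms if a.name in self.genome.seasonal_arms]
        if not arms:
            raise ValueError("no arms available for seasonal loci")
        lengths = np.array([a.length_bp for a in arms], dtype=np.float64)
        arm_idx = _draw_indices(np.cumsum(lengths), len(loci), self.rng)
        out = []
        for p, ai in zip(loci, arm_idx):
            arm = arms[ai]
            bp = int(self.rng.integers(0, arm.length_bp))
            out.append(dataclasses.replace(p, position=(arm.name, bp)))
        return out

    def _exact_half_dosage(self, n: int, n_cols: int,
                           p0: float = 0.5) -> np.ndarray:
        """Dosage matrix (n, n_cols) with the allele on exactly
        ``round(2n * p0)`` of the 2n haplotypes per column, so the starting
        frequency carries no binomial insertion noise."""
        k = round(2 * n * p0)
        out = np.empty((n, n_cols), dtype=np.uint8)
        for j in range(n_cols):
            h = np.zeros(2 * n, dtype=np.uint8)
            h[self.rng.permutation(2 * n)[:k]] = 1
            out[:, j] = h[:n] + h[n:]
        return out

    def _exact_half_haplotypes(self, n: int, n_cols: int,
                               p0: float = 0.5) -> np.ndarray:
        k = round(2 * n * p0)
        out = np.empty((n, 2, n_cols), dtype=np.uint8)
        for j in range(n_cols):
            h = np.zeros(2 * n, dtype=np.uint8)
            h[self.rng.permutation(2 * n)[:k]] = 1
            out[:, :, j] = h.reshape(n, 2)
        return out

    def _init_state(self) -> None:
        L = len(self.loci)
        p0 = self.config.initial_frequency
        if self.linked:
            self._hap = self._exact_half_haplotypes(self.n, L, p0)
            self._geno = None
        else:
            self._geno = self._exact_half_dosage(self.n, L, p0)
            self._hap = None
        # fixed-locus bookkeeping (unlinked fast path): once a locus fixes it
        # is dropped from the dosage matrix and carries a constant dosage;
        # its (now constant) fitness contribution is still applied, which
        # leaves relative fitness ranks unchanged
        self._active = np.ones(L, dtype=bool)
        self._fixed_dosage = np.zeros(L, dtype=np.uint8)

    # -- observation -------------------------------------------------------

    @property
    def season(self) -> str:
        return season_of(self.generation, self.config.generations_per_season)

    def seasonal_dosages(self) -> np.ndarray:
        """(N, L) dosage matrix of summer-favoured alleles."""
        if self.linked:
            return self._hap.sum(axis=1, dtype=np.uint8)
        full = np.empty((self.n, len(self.loci)), dtype=np.uint8)
        full[:, self._active] = self._geno
        if not self._active.all():
            fixed = ~self._active
            full[:, fixed] = self._fixed_dosage[fixed]
        return full

    def seasonal_frequencies(self) -> np.ndarray:
        if not self.loci:
            return np.zeros(0)
        if self.linked:
            return self.seasonal_dosages().sum(axis=0, dtype=np.int64) / (2.0 * self.n)
        freq = np.empty(len(self.loci))
        freq[self._active] = self._geno.sum(axis=0, dtype=np.int64) / (2.0 * self.n)
        if not self._active.all():
            fixed = ~self._active
            freq[fixed] = self._fixed_dosage[fixed] / 2.0
        return freq

    def neutral_frequencies(self) -> np.ndarray:
        if self._neutral is None:
            return np.zeros(0)
        if self.linked:
            tot = self._neutral.sum(axis=(0, 1), dtype=np.int64)
        else:
            tot = self._neutral.sum(axis=0, dtype=np.int64)
        return tot / (2.0 * self.n)

    def fitnesses(self) -> np.ndarray:
        """Current-season fitness of every individual."""
        z = self._scores(self.season)
        return (1.0 + z) ** self.config.epistasis_y

    @staticmethod
    def _score_from_dosage(geno: np.ndarray, ctab: np.ndarray,
                           base: float = 0.0) -> np.ndarray:
        """Σ_l c_l(g_il) via the decomposition c(g) = c0 + β g + γ [g == 1];
        ``base`` carries constant contributions of loci not in ``geno``."""
        c0, c1, c2 = ctab[:, 0], ctab[:, 1], ctab[:, 2]
        beta = np.ascontiguousarray((c2 - c0) / 2.0)
        gamma = np.ascontiguousarray(c1 - (c0 + c2) / 2.0)
        return scores_kernel(np.ascontiguousarray(geno),
                             float(base + c0.sum()), beta, gamma)

    def _scores(self, season: str) -> np.ndarray:
        if not self.loci:
            return np.zeros(self.n)
        ctab = self._ctab[season]
        if self.linked:
            return self._score_from_dosage(self.seasonal_dosages(), ctab)
        act = self._active
        fixed_z = 0.0
        if not act.all():
            fixed = ~act
            fixed_z = float(ctab[np.flatnonzero(fixed),
                                 self._fixed_dosage[fixed]].sum())
        return self._score_from_dosage(self._geno, ctab[act], fixed_z)

    # -- neutral markers ---------------------------------------------------

    def insert_neutral_markers(self, count: int | None = None,
                               spacing_bp: int | None = None) -> None:
        """Insert neutral markers, each at exactly 50% frequency (allele
        assigned to exactly N of the 2N haplotypes at random).

        Unlinked mode takes a marker ``count``; linked mode takes a grid
        ``spacing_bp`` (default from the genome layout), placing markers at
        spacing/2, 3·spacing/2, ... along every arm.
        """
        if self._neutral is not None:
            raise RuntimeError("neutral markers already present; remove first")
        if self.linked:
            spacing = spacing_bp or self.genome.neutral_spacing_bp
            positions = []
            for arm in self.genome.arms:
                if spacing > arm.length_bp:
                    raise ValueError(
                        f"marker spacing {spacing} exceeds arm {arm.name}")
                bp = np.arange(spacing // 2, arm.length_bp, spacing)
                positions += [(arm.name, int(x)) for x in bp]
            self.marker_positions = positions
            self.n_markers = len(positions)
            self._neutral = self._exact_half_haplotypes(self.n, self.n_markers)
        else:
            if count is None:
                raise ValueError("unlinked mode requires a marker count")
            self.n_markers = int(count)
            self.marker_positions = [("unlinked", -1)] * self.n_markers
            self._neutral = self._exact_half_dosage(self.n, self.n_markers)

    def remove_neutral_markers(self) -> None:
        """Drop all neutral markers, restoring the pre-insertion state in the
        marker dimensions (selected loci are untouched)."""
        self._neutral = None
        self.n_markers = 0
        self.marker_positions = []

    def marker_arm_groups(self) -> np.ndarray:
        """Label each marker 'selected_arms' or 'neutral_arm' according to
        whether its arm carries seasonal loci."""
        labels = []
        for arm, _ in self.marker_positions:
            on_sel = arm in self.genome.seasonal_arms and self.linked
            labels.append("selected_arms" if on_sel else "neutral_arm")
        return np.array(labels)

    # -- stepping ----------------------------------------------------------

    def step(self) -> None:
        """Advance one generation."""
        cfg = self.config
        season = self.season  # parents reproduce under their own season
        n_next = cfg.demography.size_at(self.generation + 1,
                                        cfg.generations_per_season)
        z = self._scores(season)
        w = (1.0 + z) ** cfg.epistasis_y
        parents = sample_parents(w, n_next, self.rng, cap=cfg.offspring_cap)
        if self.linked:
            self._transmit_linked(parents, n_next)
        else:
            self._transmit_unlinked(parents, n_next)
        self.n = n_next
        self.generation += 1

    def run(self, n_generations: int) -> None:
        for _ in range(n_generations):
            self.step()

    # unlinked transmission: per-locus independent Mendelian sampling

    def _transmit_unlinked(self, parents: np.ndarray, n_next: int) -> None:
        seed_kernel_rng(np.uint32(self.rng.integers(0, 2**32)))
        child, colsum = mendel_transmit_kernel(self._geno, parents)
        if self._neutral is not None:
            self._neutral, _ = mendel_transmit_kernel(
                np.ascontiguousarray(self._neutral), parents)
        # retire newly fixed/lost seasonal loci from the dosage matrix; their
        # constant contribution keeps entering the seasonal score
        lost = colsum == 0
        fixed = colsum == 2 * n_next
        retired = lost | fixed
        if retired.any():
            idx = np.flatnonzero(self._active)
            self._fixed_dosage[idx[lost]] = 0
            self._fixed_dosage[idx[fixed]] = 2
            self._active[idx[retired]] = False
            child = np.ascontiguousarray(child[:, ~retired])
        self._geno = child

    # linked transmission: crossover per chromosome, shared by seasonal loci
    # and neutral markers

    def _linked_layout(self):
        """Cache per-chromosome locus/marker position indices."""
        key = tuple(self.marker_positions)
        if getattr(self, "_layout_key", None) == key:
            return self._layout
        chrom_arms: dict[str, list[Arm]] = {}
        for arm in self.genome.arms:
            chrom_arms.setdefault(arm.chrom, []).append(arm)
        layout = []
        for chrom, arms in chrom_arms.items():
            # concatenated physical axis for the chromosome, arm by arm
            offsets, cum_map, off = {}, [0.0], 0
            for arm in arms:
                offsets[arm.name] = off
                off += arm.length_bp
                cum_map.append(cum_map[-1] + arm.map_length)
            length = off
            arm_edges_bp = np.cumsum([0] + [a.length_bp for a in arms])
            arm_rates = np.array([a.rate for a in arms])
            sel_idx = np.array([i for i, p in enumerate(self.loci)
                                if p.position != "unlinked"
                                and any(p.position[0] == a.name for a in arms)],
                               dtype=np.intp)
            sel_bp = np.array([offsets[self.loci[i].position[0]]
                               + self.loci[i].position[1] for i in sel_idx],
                              dtype=np.float64)
            neu_idx = np.array([i for i, (an, _) in enumerate(self.marker_positions)
                                if any(an == a.name for a in arms)], dtype=np.intp)
            neu_bp = np.array([offsets[an] + bp
                               for an, bp in self.marker_positions
                               if any(an == a.name for a in arms)],
                              dtype=np.float64)
            layout.append({
                "map_length": float(cum_map[-1]),
                "arm_edges_bp": arm_edges_bp.astype(np.float64),
                "cum_map": np.asarray(cum_map),
                "arm_rates": arm_rates,
                "length": length,
                "sel_idx": sel_idx, "sel_bp": sel_bp,
                "neu_idx": neu_idx, "neu_bp": neu_bp,
            })
        self._layout_key = key
        self._layout = layout
        return layout

    def _crossover_positions(self, chrom_layout, k: int) -> np.ndarray:
        """Map -> physical positions of k crossovers via the cumulative map."""
        u = self.rng.random(k) * chrom_layout["map_length"]
        cm = chrom_layout["cum_map"]
        seg = np.minimum(np.searchsorted(cm, u, side="right") - 1,
                         len(cm) - 2)
        within = (u - cm[seg]) / np.maximum(chrom_layout["arm_rates"][seg], 1e-300)
        return chrom_layout["arm_edges_bp"][seg] + within

    def _transmit_linked(self, parents: np.ndarray, n_next: int) -> None:
        layout = self._linked_layout()
        L = len(self.loci)
        M = self.n_markers
        new_hap = np.empty((n_next, 2, L), dtype=np.uint8)
        new_neu = (np.empty((n_next, 2, M), dtype=np.uint8)
                   if self._neutral is not None else None)
        for slot in range(2):
            for i in range(n_next):
                p = parents[i, slot]
                for cl in layout:
                    start = int(self.rng.integers(0, 2))
                    k = self.rng.poisson(cl["map_length"])
                    if k:
                        xpos = np.sort(self._crossover_positions(cl, k))
                    else:
                        xpos = np.empty(0)
                    if cl["sel_idx"].size:
                        phase = (start + np.searchsorted(xpos, cl["sel_bp"])) % 2
                        new_hap[i, slot, cl["sel_idx"]] = \
                            self._hap[p, phase, cl["sel_idx"]]
                    if new_neu is not None and cl["neu_idx"].size:
                        phase = (start + np.searchsorted(xpos, cl["neu_bp"])) % 2
                        new_neu[i, slot, cl["neu_idx"]] = \
                            self._neutral[p, phase, cl["neu_idx"]]
        self._hap = new_hap
        if new_neu is not None:
            self._neutral = new_neu


def run_scenario(
    config: SimulationConfig,
    loci: list[SeasonalLocusParams] | None = None,
    rng: np.random.Generator | int | None = None,
    record_windows: list[tuple[int, int]] | None = None,
    progress: "callable | None" = None,
) -> tuple[TrajectorySet, Simulation]:
    """Run a scenario to ``config.total_generations`` and record seasonal-locus
    frequencies.

    Frequencies are recorded every generation inside any ``record_windows``
    (half-open generation intervals) and every ``config.record_every``
    generations elsewhere (0 disables coarse recording). Identical config,
    loci and seed reproduce identical trajectories bit for bit.
    """
    sim = Simulation(config, loci, rng)
    windows = record_windows or []

    def _recorded(gen: int) -> bool:
        if any(a <= gen < b for a, b in windows):
            return True
        return config.record_every > 0 and gen % config.record_every == 0

    gens, freqs = [], []
    if _recorded(0):
        gens.append(0)
        freqs.append(sim.seasonal_frequencies())
    for _ in range(config.total_generations):
        sim.step()
        if _recorded(sim.generation):
            gens.append(sim.generation)
            freqs.append(sim.seasonal_frequencies())
        if progress is not None and sim.generation % 1000 == 0:
            progress(sim.generation)
    traj = TrajectorySet(
        generations=np.array(gens, dtype=np.int64),
        frequencies=np.array(freqs) if freqs else np.zeros((0, len(sim.loci))),
        generations_per_season=config.generations_per_season,
        locus_ids=np.array([p.locus_id for p in sim.loci], dtype=np.int64),
    )
    return traj, sim
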