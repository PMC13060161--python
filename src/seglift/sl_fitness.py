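"""Segregation-lift fitness model: locus contributions, seasonal scores, epistatic fitness.

The model describes multilocus adaptation to two alternating seasonal
environments (summer/winter). Each seasonal locus carries a season-specific
dominance coefficient ``d`` and effect size ``delta``. In a given season a
locus contributes

* ``delta``       if the individual is homozygous for the season-favoured allele,
* ``delta * d``   if heterozygous,
* ``0``           if homozygous for the disfavoured allele.

The seasonal score ``z`` of an individual is the sum of contributions over all
seasonal loci, and fitness is the power transformation ``w(z) = (1 + z)**y``
where ``y`` is the epistasis intensity. Any ``y`` of the form used here yields
diminishing-returns epistasis among loci. Stable polymorphism is promoted by
dominance reversal: retained loci have mean seasonal dominance
``(d_s + d_w)/2 > 0.5``, so heterozygotes sit closer to the currently favoured
homozygote in both seasons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SUMMER = "summer"
WINTER = "winter"

#: Dosage coding of genotypes: number of copies of the summer-favoured allele.
WW, SW, SS = 0, 1, 2

__all__ = [
    "SUMMER",
    "WINTER",
    "WW",
    "SW",
    "SS",
    "SeasonalLocusParams",
    "locus_contribution",
    "contribution_table",
    "seasonal_score",
    "fitness",
    "sample_locus_params",
    "params_to_frame",
    "params_from_frame",
    "write_params_tsv",
    "read_params_tsv",
]


@dataclass(frozen=True)
class SeasonalLocusParams:
    """Per-locus parameters of the segregation-lift model.

    Attributes
    ----------
    locus_id : int
        Stable identifier of the locus.
    d_s, d_w : float
        Summer / winter dominance coefficients, each in [0, 1]. Retained loci
        satisfy ``(d_s + d_w)/2 > 0.5`` (dominance reversal).
    delta_s, delta_w : float
        Summer / winter effect sizes, strictly positive (exponentiated
        correlated normal draws, i.e. bivariate log-normal).
    position : tuple[str, int] | str
        ``(chromosome_arm, basepair)`` in linked-genome mode, or the string
        ``"unlinked"`` for freely recombining loci.
    """

    locus_id: int
    d_s: float
    d_w: float
    delta_s: float
    delta_w: float
    position: tuple[str, int] | str = "unlinked"

    def __post_init__(self) -> None:
        if not (0.0 <= self.d_s <= 1.0 and 0.0 <= self.d_w <= 1.0):
            raise ValueError("dominance coefficients must lie in [0, 1]")
        if self.delta_s <= 0 or self.delta_w <= 0:
            raise ValueError("effect sizes must be strictly positive")

    @property
    def mean_dominance(self) -> float:
        return 0.5 * (self.d_s + self.d_w)

    @property
    def mean_effect_size(self) -> float:
        return 0.5 * (self.delta_s + self.delta_w)


def _check_season(season: str) -> None:
    if season not in (SUMMER, WINTER):
        raise ValueError(f"season must be {SUMMER!r} or {WINTER!r}, got {season!r}")


def locus_contribution(genotype: int, season: str, params: SeasonalLocusParams) -> float:
    """Contribution of one locus to the seasonal score of an individual.

    ``genotype`` is the dosage of the summer-favoured allele (0, 1 or 2).
    """
    _check_season(season)
    if genotype not in (WW, SW, SS):
        raise ValueError(f"genotype dosage must be 0, 1 or 2, got {genotype!r}")
    if season == SUMMER:
        delta, d = params.delta_s, params.d_s
        favoured_dosage = genotype  # summer-allele copies
    else:
        delta, d = params.delta_w, params.d_w
        favoured_dosage = 2 - genotype  # winter-allele copies
    if favoured_dosage == 2:
        return delta
    if favoured_dosage == 1:
        return delta * d
    return 0.0


def contribution_table(loci: Sequence[SeasonalLocusParams], season: str) -> np.ndarray:
    """Per-locus contribution lookup, shape ``(L, 3)`` indexed by summer-allele dosage.

    Row ``l`` holds the contributions of locus ``l`` for dosages 0, 1, 2 in the
    given season; used to vectorise score computation over whole populations.
    """
    _check_season(season)
    L = len(loci)
    tab = np.empty((L, 3), dtype=np.float64)
    for i, p in enumerate(loci):
        if season == SUMMER:
            tab[i] = (0.0, p.delta_s * p.d_s, p.delta_s)
        else:
            tab[i] = (p.delta_w, p.delta_w * p.d_w, 0.0)
    return tab


def seasonal_score(
    genotypes: Sequence[int] | np.ndarray,
    loci: Sequence[SeasonalLocusParams],
    season: str,
) -> float | np.ndarray:
    """Seasonal score ``z``: sum of locus contributions.

    ``genotypes`` may be a length-``L`` vector (one individual) or an
    ``(N, L)`` dosage matrix (whole population); the score is returned as a
    scalar or length-``N`` vector accordingly.
    """
    g = np.asarray(genotypes)
    if g.shape[-1] != len(loci):
        raise ValueError(
            f"genotype vector of length {g.shape[-1]} does not match {len(loci)} loci"
        )
    tab = contribution_table(loci, season)
    contrib = np.take_along_axis(tab, g[..., None].astype(np.intp), axis=-1)[..., 0] \
        if g.ndim == 1 else tab[np.arange(len(loci)), g]
    z = contrib.sum(axis=-1)
    return float(z) if g.ndim == 1 else z


def fitness(z: float | np.ndarray, y: float) -> float | np.ndarray:
    """Epistatic fitness ``w(z) = (1 + z)**y``.

    ``y`` is the epistasis intensity; ``y = 1`` is the additive limit
    ``w = 1 + z`` and larger ``y`` strengthens diminishing-returns
    interactions among loci.
    """
    if y <= 0:
        raise ValueError("epistasis intensity y must be > 0")
    z_arr = np.asarray(z, dtype=np.float64)
    if np.any(z_arr < 0):
        raise ValueError("seasonal score z must be >= 0")
    w = (1.0 + z_arr) ** y
    return float(w) if np.isscalar(z) or z_arr.ndim == 0 else w


def sample_locus_params(
    n_loci: int,
    rng: np.random.Generator | int | None = None,
    *,
    effect_size_sd: float = 1.0,
    effect_size_corr: float = 0.9,
) -> list[SeasonalLocusParams]:
    """Draw ``n_loci`` locus parameter sets from the model's generating distributions.

    Dominance coefficients are independent Uniform(0, 1) draws per season;
    candidate loci are redrawn until ``(d_s + d_w)/2 > 0.5`` so that exactly
    ``n_loci`` retained loci are returned (the dominance-reversal retention
    rule). Effect sizes are exponentiated draws from a bivariate normal with
    mean 0, standard deviation ``effect_size_sd`` and correlation
    ``effect_size_corr`` between the summer and winter components, giving
    correlated log-normal summer/winter effects.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(rng)
    cov = effect_size_sd**2 * np.array(
        [[1.0, effect_size_corr], [effect_size_corr, 1.0]]
    )
    out: list[SeasonalLocusParams] = []
    while len(out) < n_loci:
        need = n_loci - len(out)
        # Acceptance probability of the mean-dominance rule is 1/2; oversample.
        n_draw = max(8, int(2.4 * need))
        d = rng.uniform(0.0, 1.0, size=(n_draw, 2))
        keep = d.mean(axis=1) > 0.5
        d = d[keep][:need]
        log_delta = rng.multivariate_normal(np.zeros(2), cov, size=len(d))
        delta = np.exp(log_delta)
        for (d_s, d_w), (delta_s, delta_w) in zip(d, delta):
            out.append(
                SeasonalLocusParams(
                    locus_id=len(out),
                    d_s=float(d_s),
                    d_w=float(d_w),
                    delta_s=float(delta_s),
                    delta_w=float(delta_w),
                )
            )
    return out


# --- TSV round-tripping -----------------------------------------------------

_COLUMNS = ["locus_id", "chrom", "pos", "d_s", "d_w", "delta_s", "delta_w"]


def params_to_frame(loci: Iterable[SeasonalLocusParams]) -> pd.DataFrame:
    rows = []
    for p in loci:
        if p.position == "unlinked":
            chrom, pos = "unlinked", -1
        else:
            chrom, pos = p.position
        rows.append((p.locus_id, chrom, pos, p.d_s, p.d_w, p.delta_s, p.delta_w))
    return pd.DataFrame(rows, columns=_COLUMNS)


def params_from_frame(df: pd.DataFrame) -> list[SeasonalLocusParams]:
    out = []
    for row in df.itertuples(index=False):
        position: tuple[str, int] | str
        position = "unlinked" if row.chrom == "unlinked" else (str(row.chrom), int(row.pos))
        out.append(
            SeasonalLocusParams(
                locus_id=int(row.locus_id),
                d_s=float(row.d_s),
                d_w=float(row.d_w),
                delta_s=float(row.delta_s),
                delta_w=float(row.delta_w),
                position=position,
            )
        )
    return out


def write_params_tsv(loci: Iterable[SeasonalLocusParams], path) -> None:
    params_to_frame(loci).to_csv(path, sep="\t", index=False)


def read_params_tsv(path) -> list[SeasonalLocusParams]:
    return params_from_frame(pd.read_csv(path, sep="\t"))
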