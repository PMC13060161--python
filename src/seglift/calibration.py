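"""Regression calibration between observable fluctuation summaries and model parameters.

Three fixed-coefficient linear models link what can be measured in seasonal
allele-frequency data to simulation parameters:

* **epistasis model** — predicts the epistasis intensity ``y`` from the final
  number of segregating seasonal loci ``n`` and their mean fluctuation
  amplitude ``x`` (log10–log10 regression with interaction):

      log10(y) = -0.197 + 1.32 log10(n) + 0.721 log10(x)
                 + 0.199 log10(n) log10(x)

* **initial-loci model** — predicts the initial number of seasonal loci ``l``
  needed so that ``n`` remain segregating once oscillations stabilise, from
  ``n`` and ``y`` (untransformed, with interaction):

      l = 5.133 + 1.149 n + 0.399 y + 0.009 n y

* **reduction model** — predicts the relative reduction in variance effective
  size from the maximum seasonal amplitude across loci:

      reduction = 0.056 - 1.209 * max_amplitude

  (negative values mean Ne below census; the magnitude is the fractional
  shortfall).

The same functional forms can be re-fitted to a new simulation grid with
:func:`fit_epistasis_model` / :func:`fit_initial_loci_model` /
:func:`fit_reduction_model`, each reporting OLS coefficients, r² and an
F-test comparison of the with- vs without-interaction models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = [
    "EPISTASIS_COEFFS",
    "INITIAL_LOCI_COEFFS",
    "REDUCTION_COEFFS",
    "CalibrationTarget",
    "EMPIRICAL_TARGETS",
    "predict_epistasis",
    "predict_initial_loci",
    "predict_reduction",
    "derive_scenario",
    "ModelFit",
    "fit_epistasis_model",
    "fit_initial_loci_model",
    "fit_reduction_model",
]

#: (intercept, log10 n, log10 x, interaction) of the epistasis model.
EPISTASIS_COEFFS = (-0.197, 1.32, 0.721, 0.199)
#: (intercept, n, y, interaction) of the initial-loci model.
INITIAL_LOCI_COEFFS = (5.133, 1.149, 0.399, 0.009)
#: (intercept, slope on maximum amplitude) of the reduction model.
REDUCTION_COEFFS = (0.056, -1.209)


def _round_half(x: float) -> float:
    """Round up to the next half-integer (the resolution used for reported y
    values; the ceiling convention reproduces every published derived value,
    whereas nearest-half rounding does not)."""
    return float(np.ceil(x * 2.0) / 2.0)


def predict_epistasis(
    n_final: float,
    mean_amplitude: float,
    coeffs: tuple[float, float, float, float] = EPISTASIS_COEFFS,
    *,
    rounded: bool = True,
) -> float:
    """Epistasis intensity ``y`` implied by ``n`` segregating loci of mean
    amplitude ``x``; rounded to the nearest half-integer unless
    ``rounded=False``."""
    if n_final < 1:
        raise ValueError("n_final must be >= 1")
    if not (0.0 < mean_amplitude < 1.0):
        raise ValueError("mean_amplitude must lie strictly inside (0, 1)")
    b0, b_n, b_x, b_nx = coeffs
    ln, lx = np.log10(n_final), np.log10(mean_amplitude)
    y = 10.0 ** (b0 + b_n * ln + b_x * lx + b_nx * ln * lx)
    return _round_half(y) if rounded else float(y)


def predict_initial_loci(
    n_final: float,
    y: float,
    coeffs: tuple[float, float, float, float] = INITIAL_LOCI_COEFFS,
    *,
    rounded: bool = True,
) -> float:
    """Initial seasonal-locus count ``l`` required for ``n`` to remain
    segregating at epistasis ``y``; rounded to the nearest integer unless
    ``rounded=False``."""
    if n_final < 1 or y <= 0:
        raise ValueError("require n_final >= 1 and y > 0")
    b0, b_n, b_y, b_ny = coeffs
    l = b0 + b_n * n_final + b_y * y + b_ny * n_final * y
    return float(round(l)) if rounded else float(l)


def predict_reduction(
    max_amplitude: float,
    coeffs: tuple[float, float] = REDUCTION_COEFFS,
) -> float:
    """Signed relative Ne deviation from census predicted by the maximum
    seasonal amplitude. Negative values mean Ne sits below census by that
    fraction (e.g. -0.49 ~ 49% below census)."""
    if not (0.0 <= max_amplitude <= 1.0):
        raise ValueError("max_amplitude must lie in [0, 1]")
    b0, b1 = coeffs
    return float(b0 + b1 * max_amplitude)


@dataclass(frozen=True)
class CalibrationTarget:
    """Empirical observation to be matched: ``n_final`` segregating loci with
    mean amplitude ``mean_amplitude``, plus a free-text provenance note."""

    n_final: int
    mean_amplitude: float
    note: str = ""

    def __post_init__(self) -> None:
        if self.n_final < 1:
            raise ValueError("n_final must be >= 1")
        if not (0.0 < self.mean_amplitude < 1.0):
            raise ValueError("mean_amplitude must lie in (0, 1)")


#: Published per-study estimates of segregating seasonal loci and mean
#: amplitude in natural / outdoor-cage D. melanogaster populations.
EMPIRICAL_TARGETS = (
    CalibrationTarget(111, 0.05, "genes overlapping seasonal clusters (outdoor cages)"),
    CalibrationTarget(90, 0.08, "maximum cluster count at any time point (outdoor cages)"),
    CalibrationTarget(264, 0.02, "loci underlying the seasonal signal (orchard cages)"),
    CalibrationTarget(27, 0.04, "clusters with linked overlapping SNPs"),
    CalibrationTarget(9, 0.35, "superclusters of seasonal SNPs, top-SNP amplitudes"),
)


def derive_scenario(target: CalibrationTarget) -> dict:
    """Chain the two predictors into a ready-to-run scenario fragment.

    The initial-loci model is applied to the *rounded* epistasis value (the
    value that would be reported), and both the raw-chained and
    rounded-chained initial-loci predictions are returned.
    """
    y_raw = predict_epistasis(target.n_final, target.mean_amplitude, rounded=False)
    y = _round_half(y_raw)
    l_from_rounded = predict_initial_loci(target.n_final, y)
    l_raw = predict_initial_loci(target.n_final, y_raw, rounded=False)
    return {
        "n_final": target.n_final,
        "mean_amplitude": target.mean_amplitude,
        "epistasis_y": y,
        "epistasis_y_raw": y_raw,
        "n_initial_loci": int(l_from_rounded),
        "n_initial_loci_raw": l_raw,
    }


@dataclass
class ModelFit:
    """OLS fit of one calibration model, with interaction-term comparison."""

    model_id: str
    coeffs: tuple[float, ...]
    r_squared: float
    r_squared_no_interaction: float
    interaction_pvalue: float
    result: object  # statsmodels RegressionResults


def _fit_with_interaction(df: pd.DataFrame, response: str, a: str, b: str,
                          model_id: str) -> ModelFit:
    full = ols(f"{response} ~ {a} + {b} + {a}:{b}", data=df).fit()
    reduced = ols(f"{response} ~ {a} + {b}", data=df).fit()
    comparison = sm.stats.anova_lm(reduced, full)
    pval = float(comparison["Pr(>F)"].iloc[-1])
    coeffs = tuple(float(c) for c in full.params)
    return ModelFit(model_id, coeffs, float(full.rsquared),
                    float(reduced.rsquared), pval, full)


def fit_epistasis_model(grid: pd.DataFrame) -> ModelFit:
    """Refit the log10–log10 epistasis model to a simulation grid.

    ``grid`` needs columns ``n_final``, ``mean_amplitude``, ``y``. Returns
    coefficients ordered (intercept, log10 n, log10 x, interaction).
    """
    df = pd.DataFrame(
        {
            "log_y": np.log10(grid["y"]),
            "log_n": np.log10(grid["n_final"]),
            "log_x": np.log10(grid["mean_amplitude"]),
        }
    )
    if not np.all(np.isfinite(df.to_numpy())):
        raise ValueError("log-transformed predictors/response must be finite")
    return _fit_with_interaction(df, "log_y", "log_n", "log_x", "epistasis_model")


def fit_initial_loci_model(grid: pd.DataFrame) -> ModelFit:
    """Refit the initial-loci model (columns ``n_final``, ``y``, ``l_initial``)."""
    df = pd.DataFrame(
        {"l": grid["l_initial"], "n": grid["n_final"], "y": grid["y"]}
    )
    return _fit_with_interaction(df, "l", "n", "y", "initial_loci_model")


def fit_reduction_model(results: pd.DataFrame) -> ModelFit:
    """Refit the simple reduction-vs-maximum-amplitude regression.

    ``results`` needs columns ``max_amplitude`` and ``reduction`` (signed, on
    the fitted scale where more negative = larger shortfall below census).
    """
    fit = ols("reduction ~ max_amplitude", data=results).fit()
    coeffs = tuple(float(c) for c in fit.params)
    return ModelFit("reduction_model", coeffs, float(fit.rsquared),
                    float(fit.rsquared), float("nan"), fit)
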