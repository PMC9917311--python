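"""Estimation of model parameters from chromosome-level expression summaries.

Three estimators parameterize the karyotype-evolution model from single-cell
RNA-seq derived inputs (the upstream normalization, pathway scoring and
differential-expression testing are consumed as precomputed tables):

* integer karyotype and tumor/normal expression bias from per-chromosome
  tumor/normal mean-expression ratios, assuming at least one chromosome is
  diploid in all tumor cells and SCNAs are clonal;
* turnover rate tau = mu/lambda from a linear calibration of a cell-death
  pathway score against literature turnover rates (birth rate set to 1,
  death rate mu := tau);
* per-chromosome missegregation rate from a linear calibration of interferon
  gamma signaling activity against log2 % lagging chromosomes, converted to a
  per-division probability and divided by ploidy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

N_AUTOSOMES = 22


@dataclass(frozen=True)
class ExpressionSummary:
    """Per-chromosome mean expression in tumor and normal cell groups.

    ``de_pvalue`` is the p-value of differential chromosome-level expression
    between tumor and normal cells; chromosomes unaffected by SCNAs should be
    the least differentially expressed.
    """

    chromosomes: tuple[str, ...]
    tumor_mean: np.ndarray
    normal_mean: np.ndarray
    de_pvalue: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.tumor_mean, dtype=float)
        n = np.asarray(self.normal_mean, dtype=float)
        p = np.asarray(self.de_pvalue, dtype=float)
        if not (len(self.chromosomes) == len(t) == len(n) == len(p)):
            raise ValueError("chromosomes, means and p-values must have equal length")
        if np.any(t <= 0) or np.any(n <= 0):
            raise ValueError("tumor and normal mean expression must be strictly positive")
        if np.any(p <= 0) or np.any(p > 1):
            raise ValueError("p-values must lie in (0, 1]")
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        object.__setattr__(self, "tumor_mean", t)
        object.__setattr__(self, "normal_mean", n)
        object.__setattr__(self, "de_pvalue", p)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionSummary":
        """Build from a table with columns chromosome, tumor_mean,
        normal_mean, de_pvalue."""
        return cls(
            chromosomes=tuple(str(c) for c in df["chromosome"]),
            tumor_mean=df["tumor_mean"].to_numpy(float),
            normal_mean=df["normal_mean"].to_numpy(float),
            de_pvalue=df["de_pvalue"].to_numpy(float),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": self.chromosomes,
                "tumor_mean": self.tumor_mean,
                "normal_mean": self.normal_mean,
                "de_pvalue": self.de_pvalue,
            }
        )


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with exact halves away from zero."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class PloidyEstimate:
    """Integer karyotype and tumor/normal bias inferred from expression ratios."""

    chromosomes: tuple[str, ...]
    copies: np.ndarray  # integer copy number per chromosome, input order
    x_star: int  # number of chromosomes assumed diploid
    scale: float  # estimated tumor/normal scale factor s
    bias: float  # 1 - s (deviation of the mean diploid ratio from 1)
    error_profile: np.ndarray  # E_x for x = 1 .. len-1
    raw_j: np.ndarray  # unrounded copy estimates (NaN on the assumed-diploid set)
    assumed_diploid: tuple[str, ...]

    @property
    def min_error(self) -> float:
        return float(self.error_profile[self.x_star - 1])

    @property
    def ploidy(self) -> int:
        return int(self.copies.sum())

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": self.chromosomes,
                "copies": self.copies.astype(int),
                "raw_estimate": self.raw_j,
                "assumed_diploid": [
                    c in self.assumed_diploid for c in self.chromosomes
                ],
            }
        )


def estimate_ploidy(
    expr: ExpressionSummary,
    sort_mode: str = "diploid_first",
    error_mode: str = "full",
) -> PloidyEstimate:
    """Infer integer chromosome copy numbers from tumor/normal expression ratios.

    Chromosome-level expression is assumed proportional to copy number up to
    one global tumor/normal scale factor. Chromosomes are sorted by
    differential-expression p-value so the first ``x`` are the candidates for
    being copy-number neutral (diploid); for each ``x`` the scale is the mean
    tumor/normal ratio over those candidates, the remaining chromosomes get
    unrounded copy estimates j_k = 2 (tumor_k/normal_k) / s_x, and an error
    E_x scores how far the estimates sit from integers. The x with minimal
    E_x wins (ties go to the smallest x); the candidate set is fixed at 2
    copies and the rest are rounded half-away-from-zero.

    ``error_mode='full'`` (default) scores all chromosomes: the assumed
    diploid set by its squared deviation from exactly 2 and the rest by
    squared deviation from the nearest integer. This keeps the criterion
    identifiable when aneuploid chromosomes contaminate the scale set in a
    balanced way (e.g. one gain and one loss cancelling in the mean ratio),
    which leaves every remaining estimate near an integer even though the
    scale set is wrong. ``error_mode='scna_only'`` scores only the
    non-candidate set (mean squared deviation from nearest integers).

    ``sort_mode='diploid_first'`` (default) places the least differentially
    expressed chromosomes first, which is what makes the scale estimate a
    diploid baseline; ``'significance_first'`` applies the literal
    most-significant-first ordering for comparison.
    """
    if sort_mode not in {"diploid_first", "significance_first"}:
        raise ValueError(f"unknown sort_mode {sort_mode!r}")
    if error_mode not in {"full", "scna_only"}:
        raise ValueError(f"unknown error_mode {error_mode!r}")
    n = len(expr.chromosomes)
    if n < 2:
        raise ValueError("need at least two chromosomes")
    ratio = expr.tumor_mean / expr.normal_mean
    # stable sort: largest p-value (least significant) first by default
    key = -expr.de_pvalue if sort_mode == "diploid_first" else expr.de_pvalue
    order = np.argsort(key, kind="stable")

    errors = np.full(n - 1, np.inf)
    scales = np.full(n - 1, np.nan)
    for x in range(1, n):
        s_x = float(ratio[order[:x]].mean())
        j = 2.0 * ratio[order[x:]] / s_x
        dev = j - round_half_away(j)
        if error_mode == "scna_only":
            errors[x - 1] = float(np.mean(dev**2))
        else:
            dip_dev = 2.0 * ratio[order[:x]] / s_x - 2.0
            errors[x - 1] = float(
                (np.sum(dip_dev**2) + np.sum(dev**2)) / n
            )
        scales[x - 1] = s_x
    x_star = int(np.argmin(errors)) + 1  # argmin takes the first (smallest x) on ties

    s = scales[x_star - 1]
    copies = np.empty(n)
    raw_j = np.full(n, np.nan)
    diploid_idx = order[:x_star]
    scna_idx = order[x_star:]
    copies[diploid_idx] = 2
    j = 2.0 * ratio[scna_idx] / s
    raw_j[scna_idx] = j
    copies[scna_idx] = np.maximum(round_half_away(j), 0.0)
    return PloidyEstimate(
        chromosomes=expr.chromosomes,
        copies=copies.astype(int),
        x_star=x_star,
        scale=float(s),
        bias=float(1.0 - s),
        error_profile=errors,
        raw_j=raw_j,
        assumed_diploid=tuple(expr.chromosomes[i] for i in diploid_idx),
    )


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted linear calibration y = a x + b with OLS diagnostics."""

    slope: float
    intercept: float
    response_name: str
    adj_r_squared: float
    n_obs: int
    stderr_slope: float = field(default=float("nan"))

    def predict(self, x: Sequence[float]) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def fit_linear_calibration(
    x: Sequence[float], y: Sequence[float], response_name: str = "response"
) -> CalibrationModel:
    """Ordinary least squares fit of a univariate calibration line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(np.unique(x)) < 2:
        raise ValueError("calibration needs at least 2 distinct x values")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    if res.nobs > 2:
        adj = float(res.rsquared_adj)
        stderr = float(res.bse[1])
    else:
        # a line through 2 points has no residual degrees of freedom
        adj = 1.0 if np.allclose(res.resid, 0, atol=1e-12) else float("nan")
        stderr = float("nan")
    return CalibrationModel(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        response_name=response_name,
        adj_r_squared=adj,
        n_obs=int(res.nobs),
        stderr_slope=stderr,
    )


@dataclass(frozen=True)
class TurnoverPrediction:
    """Per-cell turnover rates tau with homeostasis flags.

    Birth rate is set to 1 and death rate mu := tau for downstream modeling;
    cells with tau > 1 (shrinking faster than dividing) are flagged rather
    than clipped, mirroring the exclusion of samples beyond homeostasis.
    """

    tau: np.ndarray
    exceeds_homeostasis: np.ndarray

    @property
    def mu(self) -> np.ndarray:
        return self.tau

    lam: float = 1.0


def predict_turnover(
    model: CalibrationModel, scores: Sequence[float]
) -> TurnoverPrediction:
    """Map per-cell pathway scores to turnover rates through the calibration."""
    tau = model.predict(scores)
    flagged = tau > 1.0
    if flagged.any():
        logger.info(
            "%d of %d cells have predicted turnover > 1 (beyond homeostasis)",
            int(flagged.sum()),
            tau.size,
        )
    return TurnoverPrediction(tau=tau, exceeds_homeostasis=flagged)


@dataclass(frozen=True)
class MissegregationPrediction:
    """Per-cell missegregation rates derived from interferon signaling."""

    beta: np.ndarray  # per chromosome copy per division
    per_division: np.ndarray  # probability of >= 1 missegregation per division
    clipped: np.ndarray  # True where beta was clipped into [0, 1]


def predict_missegregation(
    model: CalibrationModel,
    gamma: Sequence[float],
    ploidy: Sequence[float] | float,
) -> MissegregationPrediction:
    """Map interferon gamma scores to per-chromosome missegregation rates.

    The calibration response is log2 of the percentage of cells with lagging
    chromosomes, so prediction inverts the log (2^L / 100 gives the
    per-division missegregation probability) and divides by ploidy to obtain
    the per-chromosome-copy rate beta. Values outside [0, 1] are clipped and
    the clipping reported.
    """
    gamma = np.asarray(gamma, dtype=float)
    ploidy_arr = np.broadcast_to(np.asarray(ploidy, dtype=float), gamma.shape).copy()
    if np.any(ploidy_arr < 1):
        raise ValueError("ploidy must be >= 1 for every cell")
    log2_pct = model.predict(gamma)
    per_division = np.power(2.0, log2_pct) / 100.0
    beta = per_division / ploidy_arr
    clipped = (beta < 0.0) | (beta > 1.0)
    if clipped.any():
        logger.info(
            "%d of %d predicted missegregation rates clipped into [0, 1]",
            int(clipped.sum()),
            beta.size,
        )
    beta = np.clip(beta, 0.0, 1.0)
    return MissegregationPrediction(
        beta=beta, per_division=per_division, clipped=clipped
    )
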