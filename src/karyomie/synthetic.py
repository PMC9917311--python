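"""Seeded synthetic-data generators.

These emulate the inputs the inference layer consumes — chromosome-level
tumor/normal expression summaries with a known ground-truth karyotype, and
linear calibration tables — plus a Monte-Carlo division sampler that serves
as an independent oracle for the analytic shift and daughter distributions.
Everything is deterministic under a fixed seed.

The expression generator produces chromosome-level means proportional to copy
number with a global multiplicative tumor/normal bias and lognormal noise; it
does not attempt to simulate read counts, dropout or library-size effects.
The differential-expression p-values are a deterministic monotone surrogate
of |copies - 2| (only their rank order matters downstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import N_AUTOSOMES, ExpressionSummary
from .karyospace import Karyotype, as_karyotype

AUTOSOMES = tuple(f"chr{i}" for i in range(1, N_AUTOSOMES + 1))


@dataclass(frozen=True)
class FixtureSpec:
    """Ground truth for one synthetic expression summary."""

    seed: int
    true_karyotype: Karyotype
    bias: float = 1.0
    noise_sigma: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "true_karyotype", as_karyotype(self.true_karyotype))
        if self.bias <= 0:
            raise ValueError("bias must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def generate_expression_fixture(spec: FixtureSpec) -> ExpressionSummary:
    """Chromosome-level expression summary with known karyotype.

    normal_mean_k is drawn positive (lognormal around a common baseline);
    tumor_mean_k = bias * (copy_k / 2) * normal_mean_k * exp(eps_k) with
    eps_k ~ Normal(0, noise_sigma^2). p-values are large (uniform on
    [0.5, 1]) for diploid chromosomes and shrink geometrically with
    |copy - 2|, so rank order always places copy-neutral chromosomes last in
    significance.
    """
    copies = np.array(spec.true_karyotype, dtype=float)
    m = len(copies)
    chroms = AUTOSOMES if m == N_AUTOSOMES else tuple(f"chr{i+1}" for i in range(m))
    rng = np.random.default_rng(spec.seed)
    normal = 10.0 * rng.lognormal(mean=0.0, sigma=0.3, size=m)
    eps = rng.normal(0.0, spec.noise_sigma, size=m) if spec.noise_sigma > 0 else 0.0
    tumor = spec.bias * (copies / 2.0) * normal * np.exp(eps)
    jitter = rng.uniform(0.5, 1.0, size=m)
    dist = np.abs(copies - 2.0)
    pvals = np.where(dist == 0, jitter, jitter * np.power(10.0, -3.0 * dist))
    return ExpressionSummary(
        chromosomes=chroms, tumor_mean=tumor, normal_mean=normal, de_pvalue=pvals
    )


def random_fixture(
    seed: int,
    lo: int = 1,
    hi: int = 4,
    bias_range: tuple[float, float] = (0.5, 1.5),
    noise_sigma: float = 0.0,
    m: int = N_AUTOSOMES,
) -> tuple[FixtureSpec, ExpressionSummary]:
    """Random karyotype in [lo, hi]^m with random bias; returns truth + table."""
    rng = np.random.default_rng(seed)
    karyotype = tuple(int(c) for c in rng.integers(lo, hi + 1, size=m))
    bias = float(rng.uniform(*bias_range))
    spec = FixtureSpec(
        seed=int(rng.integers(0, 2**31 - 1)),
        true_karyotype=karyotype,
        bias=bias,
        noise_sigma=noise_sigma,
    )
    return spec, generate_expression_fixture(spec)


def generate_calibration_table(
    a: float, b: float, x_grid, noise_sd: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Calibration table y = a x + b + Normal(0, noise_sd^2) on a fixed grid."""
    x = np.asarray(x_grid, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 grid points")
    rng = np.random.default_rng(seed)
    y = a * x + b
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=x.shape)
    return pd.DataFrame({"score": x, "response": y})


def sample_divisions(
    parent, beta: float, n: int, seed: int = 0
) -> pd.DataFrame:
    """Monte-Carlo division sampler: empirical daughter-pair frequencies.

    Each division draws, independently per chromosome copy, whether it
    missegregates (probability ``beta``) and, if so, which daughter receives
    the whole chromatid pair (probability 1/2 each). Both daughters are
    returned per division; every sampled pair conserves copy number,
    2 i_k = j_k(1) + j_k(2). The empirical first-daughter distribution is the
    independent oracle for the analytic product-form daughter distribution.
    """
    parent = as_karyotype(parent)
    if any(c < 1 for c in parent):
        raise ValueError("dead (zero-copy) states do not divide")
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    m = len(parent)
    d1 = np.empty((n, m), dtype=np.int64)
    for k, i_k in enumerate(parent):
        mis = rng.random((n, i_k)) < beta
        to_d1 = rng.random((n, i_k)) < 0.5
        shift = np.where(mis, np.where(to_d1, 1, -1), 0).sum(axis=1)
        d1[:, k] = i_k + shift
    d2 = 2 * np.array(parent, dtype=np.int64) - d1

    cols_d1 = [f"d1_{i+1}" for i in range(m)]
    cols_d2 = [f"d2_{i+1}" for i in range(m)]
    table = pd.DataFrame(np.hstack([d1, d2]), columns=cols_d1 + cols_d2)
    counts = table.value_counts().rename("count").reset_index()
    counts["frequency"] = counts["count"] / n
    return counts


def daughter_frequencies(pair_table: pd.DataFrame) -> dict[Karyotype, float]:
    """Collapse a sampled pair table to first-daughter frequencies."""
    m = sum(c.startswith("d1_") for c in pair_table.columns)
    freq: dict[Karyotype, float] = {}
    for _, row in pair_table.iterrows():
        d1 = tuple(int(row[f"d1_{i+1}"]) for i in range(m))
        freq[d1] = freq.get(d1, 0.0) + float(row["frequency"])
    return freq
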