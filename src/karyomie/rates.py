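"""Rate models: karyotype -> (birth, death, missegregation) rate maps.

Homogeneous populations use constant kernels. Intra-tumor heterogeneity is
modeled as karyotype dependence: a linear kernel in the copy number of one
chromosome, a sinusoidal kernel in aggregate ploidy (peaking near the common
near-triploid karyotype), or an explicit table. Death kernels reuse the same
families so missegregation- and death-rate kernels can be combined pairwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from .karyospace import Karyotype, KaryotypeSpace, aggregate_ploidy, as_karyotype

RateFn = Callable[[Karyotype], float]


@dataclass(frozen=True)
class RateModel:
    """Bundle of per-karyotype birth (lambda), death (mu) and missegregation
    (beta) rate functions.

    Units: birth and death in events per cell per day; beta is a probability
    of missegregation per chromosome copy per division.
    """

    birth: RateFn
    death: RateFn
    misseg: RateFn
    birth_kind: str = "constant"
    death_kind: str = "constant"
    misseg_kind: str = "constant"
    params: dict = field(default_factory=dict)

    def validate_on(self, space: KaryotypeSpace) -> None:
        """Check rate bounds on every viable state of ``space``."""
        for s in space.states:
            lam, mu, beta = self.birth(s), self.death(s), self.misseg(s)
            if not lam > 0:
                raise ValueError(f"birth rate must be > 0; got {lam} at {s}")
            if mu < 0:
                raise ValueError(f"death rate must be >= 0; got {mu} at {s}")
            if not 0.0 <= beta <= 1.0:
                raise ValueError(f"beta must be in [0, 1]; got {beta} at {s}")

    def with_death(self, death: RateFn, kind: str = "custom") -> "RateModel":
        return RateModel(
            birth=self.birth,
            death=death,
            misseg=self.misseg,
            birth_kind=self.birth_kind,
            death_kind=kind,
            misseg_kind=self.misseg_kind,
            params=self.params,
        )

    def with_misseg(self, misseg: RateFn, kind: str = "custom") -> "RateModel":
        return RateModel(
            birth=self.birth,
            death=self.death,
            misseg=misseg,
            birth_kind=self.birth_kind,
            death_kind=self.death_kind,
            misseg_kind=kind,
            params=self.params,
        )


def constant_rates(lam: float, mu: float, beta: float) -> RateModel:
    """Homogeneous rates: identical lambda, mu, beta for every karyotype.

    Turnover mu/lam above 1 is allowed (a shrinking population is a valid
    regime, not a validation error).
    """
    lam, mu, beta = float(lam), float(mu), float(beta)
    if not lam > 0:
        raise ValueError(f"birth rate must be > 0, got {lam}")
    if mu < 0:
        raise ValueError(f"death rate must be >= 0, got {mu}")
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    return RateModel(
        birth=lambda k: lam,
        death=lambda k: mu,
        misseg=lambda k: beta,
        params={"lam": lam, "mu": mu, "beta": beta},
    )


def linear_beta_kernel(
    theta1: float,
    b0: float,
    c_ref: int = 2,
    chromosome: int = 0,
    floor: float = 1e-4,
    ceil: float = 1.0,
) -> RateFn:
    """Missegregation rate linear in the copy number of one chromosome.

    beta(i) = clip(b0 + theta1 * (i[chromosome] - c_ref), floor, ceil).
    ``theta1`` is the slope per extra copy relative to the reference copy
    number ``c_ref`` (default diploid).
    """
    if not 0.0 <= floor <= ceil <= 1.0:
        raise ValueError(f"need 0 <= floor <= ceil <= 1, got {floor}, {ceil}")

    def beta(k: Sequence[int]) -> float:
        k = as_karyotype(k)
        raw = b0 + theta1 * (k[chromosome] - c_ref)
        return min(max(raw, floor), ceil)

    return beta


def sinusoidal_beta_kernel(
    theta2: float,
    b0: float,
    p_peak: int = 66,
    period: float = 44.0,
    floor: float = 1e-4,
    ceil: float = 1.0,
) -> RateFn:
    """Missegregation rate sinusoidal in aggregate ploidy.

    beta(i) = clip(b0 + theta2 * cos(2 pi (ploidy(i) - p_peak) / period),
    floor, ceil). The cosine is anchored by its maximum at ``p_peak``
    (default 66, the near-triploid autosome total, where observed
    missegregation rates peak); karyotypes half a period away sit at the
    minimum b0 - theta2 and act as a stabilizing refuge.
    """
    if not period > 0:
        raise ValueError(f"period must be > 0, got {period}")
    if not 0.0 <= floor <= ceil <= 1.0:
        raise ValueError(f"need 0 <= floor <= ceil <= 1, got {floor}, {ceil}")

    def beta(k: Sequence[int]) -> float:
        p = aggregate_ploidy(k)
        raw = b0 + theta2 * math.cos(2.0 * math.pi * (p - p_peak) / period)
        return min(max(raw, floor), ceil)

    return beta


def tabulated_kernel(
    values: Mapping[Sequence[int], float], space: KaryotypeSpace | None = None
) -> RateFn:
    """Exact per-state rate lookup.

    If ``space`` is given the table is validated to cover every viable state
    up front; either way, evaluating a missing state raises with the state
    named.
    """
    table = {as_karyotype(k): float(v) for k, v in values.items()}
    if space is not None:
        missing = [s for s in space.states if s not in table]
        if missing:
            raise ValueError(
                f"tabulated kernel is missing {len(missing)} viable state(s), "
                f"e.g. {missing[:5]}"
            )

    def rate(k: Sequence[int]) -> float:
        kt = as_karyotype(k)
        try:
            return table[kt]
        except KeyError:
            raise KeyError(f"tabulated kernel has no entry for state {kt}") from None

    return rate


def per_division_rate(beta: float, copies: int) -> float:
    """Per-division missegregation probability 1 - (1 - beta)^copies.

    Converts the per-chromosome-copy rate beta into the probability that a
    division of a cell carrying ``copies`` total chromosome copies suffers at
    least one missegregation.
    """
    beta = float(beta)
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    copies = int(copies)
    if copies < 0:
        raise ValueError(f"copies must be >= 0, got {copies}")
    return -math.expm1(copies * math.log1p(-beta)) if beta < 1.0 else (1.0 if copies else 0.0)
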