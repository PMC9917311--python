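"""Missegregation-induced extinction (MIE) analysis.

Everything here reduces to the spectral abscissa of the Metzler generator J:
the population grows iff the largest real eigenvalue is positive, and the
critical curve in the (missegregation rate, turnover rate) plane is the locus
where it is exactly zero. The module provides

* the spectral abscissa itself (Perron root of a nonnegative shift),
* Gershgorin-circle sufficient conditions that rule MIE out without an
  eigensolve, including the three closed-form biological scenarios,
* critical curves for homogeneous rates (one eigensolve per grid point via
  the shift identity) and for heterogeneous kernels (bisection on a turnover
  multiplier),
* a Kronecker factorization that yields the joint critical turnover of many
  simultaneously constrained chromosomes from per-chromosome spectral radii,
  without enumerating the product space,
* steady-state karyotype proportions (dominant right eigenvector), and
* the closed-form extinction threshold of the continuum (reaction-diffusion)
  approximation on DNA-content space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import sparse
from scipy.linalg import eig, eigvals
from scipy.optimize import brentq
from scipy.sparse.linalg import ArpackNoConvergence, eigs

from .dynamics import GeneratorMatrix, build_generator
from .karyospace import KaryotypeSpace, build_space
from .missegregation import shift_probabilities
from .rates import RateModel, constant_rates

_DENSE_LIMIT = 1200


def _as_matrix(J) -> sparse.csr_matrix:
    if isinstance(J, GeneratorMatrix):
        return J.J.tocsr()
    if sparse.issparse(J):
        return J.tocsr()
    return sparse.csr_matrix(np.asarray(J, dtype=float))


def dominant_eigenvalue(J) -> float:
    """Spectral abscissa (largest real part) of a Metzler generator.

    For a Metzler matrix the spectral abscissa is itself an eigenvalue (the
    Perron root of the nonnegative shift J + cI minus c), so the result is
    real. Small systems use a dense eigendecomposition; large sparse systems
    use ARPACK on the shifted matrix with a dense fallback. Raises rather
    than returning NaN if no solver converges.
    """
    A = _as_matrix(J)
    n = A.shape[0]
    if A.shape[0] != A.shape[1]:
        raise ValueError("generator must be square")
    if n <= _DENSE_LIMIT:
        vals = eigvals(A.toarray())
        return float(np.max(vals.real))
    c = float(-min(A.diagonal().min(), 0.0)) + 1.0
    B = A + c * sparse.identity(n, format="csr")
    try:
        vals = eigs(B, k=1, which="LM", return_eigenvectors=False, maxiter=5000)
        rho = float(np.abs(vals[0]))
        return rho - c
    except ArpackNoConvergence:
        vals = eigvals(A.toarray())
        out = float(np.max(vals.real))
        if not np.isfinite(out):
            raise RuntimeError("eigensolver failed to produce a finite spectral abscissa")
        return out


@dataclass(frozen=True)
class GershgorinReport:
    """Margins of the Gershgorin sufficient condition for avoiding MIE."""

    row_margin: float
    col_margin: float
    mie_ruled_out: bool


def gershgorin_conditions(J) -> GershgorinReport:
    """Gershgorin-circle screen: MIE is impossible if every disc lies in the
    open right half-plane.

    ``row_margin`` is min_i (J_ii - sum_{j != i} J_ij) and ``col_margin`` the
    column analogue. Because a matrix and its transpose share a spectrum,
    either margin being positive already certifies a positive spectral
    abscissa; both are reported and the screen is their OR.
    """
    A = _as_matrix(J).toarray()
    d = np.diag(A)
    off = np.abs(A) - np.diag(np.abs(d))
    row_margin = float(np.min(d - off.sum(axis=1)))
    col_margin = float(np.min(d - off.sum(axis=0)))
    return GershgorinReport(
        row_margin=row_margin,
        col_margin=col_margin,
        mie_ruled_out=(row_margin > 0.0) or (col_margin > 0.0),
    )


def nearest_neighbor_generator(
    space: KaryotypeSpace, lam: float, mu: float, beta_division: float
) -> GeneratorMatrix:
    """Generator of the nearest-neighbor (single-missegregation) model.

    At most one chromosome missegregates per division, with per-division
    probability ``beta_division``; the resulting daughter pair is
    (i - 1, i + 1). The division-event tensor is tridiagonal:
    q_ii = 1 - beta, q_{i,i+1} = q_{i,i-1} = beta, with flux beyond the viable
    interval truncated. This is the tensor under which the closed-form
    safe-zone boundary beta_c = (1 - mu/lam) / 4 is exact.
    """
    if space.M != 1:
        raise ValueError("nearest-neighbor model is defined on a 1-D aggregate space")
    if not 0.0 <= beta_division <= 1.0:
        raise ValueError(f"beta_division must be in [0, 1], got {beta_division}")
    n = space.n_states
    J = np.zeros((n, n))
    for j in range(n):
        J[j, j] = lam * (2.0 * (1.0 - beta_division) - 1.0) - mu
        if j + 1 < n:
            J[j + 1, j] += lam * beta_division  # inflow into i+1 from i
        if j - 1 >= 0:
            J[j - 1, j] += lam * beta_division
    rates = constant_rates(lam, mu, beta_division)
    return GeneratorMatrix(
        space=space, J=sparse.csr_matrix(J), rates=rates, truncated=True
    )


def table2_condition(
    scenario: int, rates: RateModel, space: KaryotypeSpace
) -> dict:
    """Closed-form sufficient conditions to avoid MIE for three scenarios.

    1. At most one chromosome missegregates per division (nearest-neighbor
       tensor; beta interpreted per division) and homogeneous rates:
       safe iff beta < beta_c = (1 - mu/lambda) / 4.
    2. Fully heterogeneous rates on the 1-D aggregate model: safe iff
       lambda_i (1 - 3 beta_i) - mu_i - lambda_{i+1} beta_{i+1} > 0 for all i
       (states above the viable ceiling contribute no inflow).
    3. Homogeneous missegregation rate, heterogeneous birth/death: safe iff
       beta < (1 - mu_i/lambda_i) / (3 + lambda_{i+1}/lambda_i) for all i.
    """
    if space.M != 1:
        raise ValueError("closed-form conditions are stated on the 1-D aggregate model")
    states = space.states

    if scenario == 1:
        if not (
            rates.birth_kind == rates.death_kind == rates.misseg_kind == "constant"
        ):
            raise ValueError("scenario 1 requires homogeneous (constant) rates")
        s0 = states[0]
        lam, mu, beta = rates.birth(s0), rates.death(s0), rates.misseg(s0)
        beta_c = 0.25 * (1.0 - mu / lam)
        return {"satisfied": beta < beta_c, "beta_c": beta_c}

    if scenario == 2:
        margins = []
        for idx, s in enumerate(states):
            lam_i, mu_i, b_i = rates.birth(s), rates.death(s), rates.misseg(s)
            if idx + 1 < len(states):
                s_up = states[idx + 1]
                inflow = rates.birth(s_up) * rates.misseg(s_up)
            else:
                inflow = 0.0
            margins.append(lam_i * (1.0 - 3.0 * b_i) - mu_i - inflow)
        margins = np.array(margins)
        return {"satisfied": bool(np.all(margins > 0)), "per_state_margins": margins}

    if scenario == 3:
        if rates.misseg_kind != "constant":
            raise ValueError("scenario 3 requires a homogeneous missegregation rate")
        beta = rates.misseg(states[0])
        bounds = []
        for idx, s in enumerate(states):
            lam_i, mu_i = rates.birth(s), rates.death(s)
            lam_ratio = (
                rates.birth(states[idx + 1]) / lam_i if idx + 1 < len(states) else 0.0
            )
            bounds.append((1.0 - mu_i / lam_i) / (3.0 + lam_ratio))
        beta_c = float(np.min(bounds))
        return {"satisfied": beta < beta_c, "beta_c": beta_c}

    raise ValueError(f"scenario must be 1, 2 or 3, got {scenario}")


def _require_homogeneous_turnover(rates: RateModel, space: KaryotypeSpace) -> tuple[float, float]:
    s0 = space.states[0]
    lam0, mu0 = rates.birth(s0), rates.death(s0)
    if rates.birth_kind != "constant" or rates.death_kind != "constant":
        raise ValueError("the shift identity needs homogeneous birth and death rates")
    return lam0, mu0


def critical_turnover(space: KaryotypeSpace, rates: RateModel) -> float:
    """Critical turnover mu_crit/lambda for homogeneous birth/death rates.

    Death enters the generator only as -mu I, so J(mu) = A - mu I with A the
    death-free generator; the dominant eigenvalue crosses zero exactly at
    mu = s(A). One eigensolve gives the whole answer:
    mu_crit/lambda = s(A)/lambda.
    """
    lam, _ = _require_homogeneous_turnover(rates, space)
    zero_death = rates.with_death(lambda k: 0.0, kind="constant")
    A = build_generator(space, zero_death, truncate=True)
    return dominant_eigenvalue(A) / lam


@dataclass(frozen=True)
class CriticalCurve:
    """Locus of (kernel parameter, critical turnover) where the dominant
    eigenvalue of the generator is zero."""

    parameter_name: str
    parameters: np.ndarray
    critical_turnover: np.ndarray
    space_config: dict
    assumptions: str  # "homogeneous" | "kernel"

    def as_points(self) -> list[tuple[float, float]]:
        return list(zip(self.parameters.tolist(), self.critical_turnover.tolist()))


def critical_curve(
    space: KaryotypeSpace,
    parameter_name: str,
    parameter_grid: Sequence[float],
    rates_factory: Callable[[float], RateModel],
    turnover_bracket: float = 64.0,
) -> CriticalCurve:
    """Sweep a kernel parameter and find the critical turnover at each value.

    ``rates_factory(value)`` must return a RateModel with birth rate 1.
    For homogeneous death kernels the critical turnover comes from the shift
    identity (one eigensolve); for heterogeneous death kernels the dominant
    eigenvalue is driven to zero by bisection on a global multiplier of the
    death kernel, and that multiplier is reported as the critical turnover
    scale. Points where no bracket exists are reported as NaN rather than
    fabricated.
    """
    params = np.asarray(list(parameter_grid), dtype=float)
    crit = np.full(params.shape, np.nan)
    kinds = set()
    for i, value in enumerate(params):
        rates = rates_factory(float(value))
        kinds.add(rates.misseg_kind)
        if rates.death_kind == "constant":
            crit[i] = critical_turnover(space, rates)
        else:
            base_death = rates.death

            def s_of(c: float) -> float:
                scaled = rates.with_death(lambda k, c=c: c * base_death(k), kind="scaled")
                # bisection path: rebuild the generator at each multiplier
                scaledJ = build_generator(space, scaled, truncate=True)
                return dominant_eigenvalue(scaledJ)

            s0 = s_of(0.0)
            if s0 <= 0:
                continue  # flagged NaN: extinct even without death
            hi = 1.0
            while s_of(hi) > 0:
                hi *= 2.0
                if hi > turnover_bracket:
                    break
            if s_of(hi) > 0:
                continue  # no bracket within range: flagged NaN
            crit[i] = brentq(s_of, 0.0, hi, xtol=1e-10)
    assumptions = "homogeneous" if kinds == {"constant"} else "kernel"
    return CriticalCurve(
        parameter_name=parameter_name,
        parameters=params,
        critical_turnover=crit,
        space_config=space.to_config(),
        assumptions=assumptions,
    )


def single_daughter_matrix(lo: int, hi: int, beta: float) -> np.ndarray:
    """Truncated per-chromosome first-daughter transition matrix Q.

    Q[i, j] = P(j - i | i) for copy numbers i, j in [lo, hi]; rows for a
    zero-copy state (possible only if lo = 0) are zero because dead cells do
    not divide.
    """
    size = hi - lo + 1
    Q = np.zeros((size, size))
    for row, i in enumerate(range(lo, hi + 1)):
        if i < 1:
            continue
        probs = shift_probabilities(i, beta)  # t = -i .. i
        for col, j in enumerate(range(lo, hi + 1)):
            t = j - i
            if -i <= t <= i:
                Q[row, col] = probs[t + i]
    return Q


def multichromosome_critical(
    per_chrom_intervals: Sequence[tuple[int, int]],
    beta: float,
    n_copies_equal: int | None = None,
) -> float:
    """Joint critical turnover of several simultaneously constrained
    chromosomes, via Kronecker factorization.

    With homogeneous rates the joint generator is
    J = 2 lambda Qjoint^T - (lambda + mu) I where the joint single-daughter
    matrix factorizes over chromosomes, Qjoint = kron_c Q_c, because both the
    viable box and the per-chromosome shift distributions are products. Its
    dominant eigenvalue is 2 lambda prod_c rho(Q_c) - (lambda + mu), so

        mu_crit / lambda = 2 prod_c rho(Q_c) - 1.

    This makes the 22-autosome analysis a handful of small eigensolves
    instead of an 8^22-state enumeration. ``n_copies_equal`` replicates a
    single supplied interval that many times.
    """
    intervals = [(int(lo), int(hi)) for lo, hi in per_chrom_intervals]
    if n_copies_equal is not None:
        if len(intervals) != 1:
            raise ValueError("n_copies_equal expects exactly one interval to replicate")
        intervals = intervals * int(n_copies_equal)
    prod_rho = 1.0
    cache: dict[tuple[int, int], float] = {}
    for lo, hi in intervals:
        if (lo, hi) not in cache:
            Q = single_daughter_matrix(lo, hi, beta)
            cache[(lo, hi)] = float(np.max(np.abs(eigvals(Q))))
        prod_rho *= cache[(lo, hi)]
    return 2.0 * prod_rho - 1.0


def steady_state_proportions(J, gap_tol: float = 1e-9) -> np.ndarray:
    """Steady-state karyotype proportions: the dominant right eigenvector.

    Requires the dominant eigenvalue to be real and simple (checked against
    ``gap_tol``); the eigenvector is sign-fixed nonnegative and normalized to
    sum to 1.
    """
    A = _as_matrix(J).toarray()
    vals, vecs = eig(A)
    order = np.argsort(vals.real)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if abs(vals[0].imag) > gap_tol:
        raise ValueError("dominant eigenvalue is complex; proportions undefined")
    if len(vals) > 1 and abs(vals[0].real - vals[1].real) <= gap_tol and abs(
        vals[1].imag
    ) <= gap_tol:
        raise ValueError("dominant eigenvalue is not simple; proportions undefined")
    v = vecs[:, 0].real
    if v.sum() < 0:
        v = -v
    if np.any(v < -1e-8 * max(1.0, np.abs(v).max())):
        raise ValueError("dominant eigenvector is not sign-consistent")
    v = np.clip(v, 0.0, None)
    return v / v.sum()


@dataclass(frozen=True)
class ContinuumModel:
    """Reaction-diffusion approximation on continuous DNA-content space.

    dn/dt = (lambda - mu) n + beta lambda d^2 n / dp^2 with absorbing
    boundaries at p_min and p_max (karyotypes outside the viable DNA-content
    interval cannot survive). ``L_p`` is the characteristic DNA-content scale
    over which missegregation diffusion must act before extinction; it
    defaults to the full viable interval width.
    """

    lam: float
    mu: float
    beta: float
    p_min: float
    p_max: float
    L_p: float | None = None

    def __post_init__(self):
        if not self.p_max > self.p_min:
            raise ValueError("need p_max > p_min")
        if not self.lam > self.mu:
            raise ValueError("the continuum threshold assumes net growth lambda > mu")

    @property
    def r(self) -> float:
        """Net growth rate lambda - mu."""
        return self.lam - self.mu

    @property
    def width(self) -> float:
        return self.p_max - self.p_min

    @property
    def length_scale(self) -> float:
        return self.width if self.L_p is None else self.L_p

    @property
    def T_r(self) -> float:
        """Growth timescale 1/r."""
        return 1.0 / self.r

    @property
    def T_p(self) -> float:
        """Missegregation-diffusion timescale L_p^2 / (beta lambda)."""
        if self.beta == 0.0:
            return math.inf  # faithful division never diffuses out
        return self.length_scale**2 / (self.beta * self.lam)


def continuum_critical(model: ContinuumModel, heuristic_factor: float = 0.1) -> dict:
    """Closed-form extinction threshold of the continuum model.

    Separation of variables with absorbing boundaries gives the dominant
    growth eigenvalue s = (lambda - mu) - beta lambda pi^2 / L^2 with
    L = p_max - p_min, so extinction occurs iff
    lambda - mu < beta lambda pi^2 / L^2, i.e.

        mu_crit / lambda = 1 - beta pi^2 / L^2,
        beta_c = (1 - mu/lambda) L^2 / pi^2.

    Also reports the timescale heuristic (MIE plausible when the diffusion
    timescale is much shorter than the growth timescale,
    T_p < heuristic_factor * T_r).
    """
    L = model.width
    mu_crit = 1.0 - model.beta * math.pi**2 / L**2
    beta_c = (1.0 - model.mu / model.lam) * L**2 / math.pi**2
    return {
        "mu_crit_over_lambda": mu_crit,
        "beta_c_closed_form": beta_c,
        "mie_heuristic": model.T_p < heuristic_factor * model.T_r,
        "T_p": model.T_p,
        "T_r": model.T_r,
    }


def homogeneous_critical_curve(
    space: KaryotypeSpace, beta_grid: Sequence[float], lam: float = 1.0
) -> CriticalCurve:
    """Critical curve mu_crit/lambda versus beta for homogeneous rates."""
    return critical_curve(
        space,
        "beta",
        beta_grid,
        lambda b: constant_rates(lam, 0.0, b),
    )


def aggregate_space(lo: int, hi: int) -> KaryotypeSpace:
    """Convenience: 1-D aggregate (ploidy) space on [lo, hi]."""
    return build_space(1, [lo], [hi])
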