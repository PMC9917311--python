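"""Per-chromosome shift distributions and the division tensor.

During mitosis each of a parent's ``i_k`` copies of chromosome ``k``
missegregates independently with probability ``beta``; a missegregated copy's
replicated chromatid pair lands wholly in one of the two daughters with equal
probability. The net copy-number shift ``t`` of the first daughter therefore
follows

    P(t | i_k) = sum_{z = |t|, z = t mod 2}^{i_k}
                 C(i_k, z) beta^z (1-beta)^(i_k - z) (1/2)^z C(z, (z-t)/2),

where ``z`` counts missegregation events and the inner binomial splits them
into gains and losses. Copy number is conserved across the daughter pair:
2 i_k = j_k(1) + j_k(2).

The division tensor ``q`` collects these per-chromosome distributions into
parent -> daughter transition probabilities, either as the first-daughter
distribution q1 (rows sum to 1) or as the distribution over division events
(rows sum to 2 - q_ii; both daughters of an unfaithful division counted).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import sparse
from scipy.special import comb

from .karyospace import Karyotype, KaryotypeSpace, as_karyotype

if TYPE_CHECKING:  # pragma: no cover
    from .rates import RateModel

#: Stored tensor entries below this are dropped (without renormalization,
#: which would silently alter net growth).
DROP_THRESHOLD = 1e-12


@dataclass(frozen=True)
class ShiftDistribution:
    """Distribution of the first daughter's copy-number shift for one chromosome."""

    parent_copies: int
    beta: float
    probs: dict[int, float]

    def __getitem__(self, t: int) -> float:
        return self.probs.get(int(t), 0.0)

    def support(self) -> list[int]:
        return sorted(self.probs)

    def as_array(self) -> tuple[np.ndarray, np.ndarray]:
        """(shifts, probabilities) over the full support [-i_k, i_k]."""
        i = self.parent_copies
        t = np.arange(-i, i + 1)
        p = np.array([self.probs.get(int(s), 0.0) for s in t])
        return t, p


def _validate_beta(beta: float) -> float:
    beta = float(beta)
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"missegregation rate beta must be in [0, 1], got {beta}")
    return beta


def shift_probabilities(i_k: int, beta: float) -> np.ndarray:
    """Vector of P(t | i_k) for t = -i_k .. i_k (length 2 i_k + 1)."""
    i_k = int(i_k)
    if i_k < 1:
        raise ValueError(f"parent copy number must be >= 1, got {i_k}")
    beta = _validate_beta(beta)

    # Number of missegregation events z ~ Binomial(i_k, beta); given z events,
    # gains g ~ Binomial(z, 1/2) and the shift is t = g - (z - g) = 2g - z.
    z = np.arange(i_k + 1)
    pz = comb(i_k, z) * np.power(beta, z) * np.power(1.0 - beta, i_k - z)
    probs = np.zeros(2 * i_k + 1)
    for zi, pzi in zip(z, pz):
        if pzi == 0.0:
            continue
        g = np.arange(zi + 1)
        split = comb(zi, g) * 0.5**zi
        t = 2 * g - zi
        probs[t + i_k] += pzi * split
    return probs


def shift_distribution(i_k: int, beta: float) -> ShiftDistribution:
    """Exact shift distribution P(t | i_k) for one chromosome type.

    Symmetric in t, sums to 1, and satisfies P(t | i_k) <= 1/2 for every
    nonzero shift (a single missegregation event already splits its mass
    between two shift signs).
    """
    p = shift_probabilities(i_k, beta)
    i_k = int(i_k)
    probs = {int(t - i_k): float(v) for t, v in enumerate(p) if v > 0.0}
    return ShiftDistribution(parent_copies=i_k, beta=float(beta), probs=probs)


def shift_distribution_oracle(
    i_k: int, beta: float, n_samples: int, seed: int
) -> ShiftDistribution:
    """Monte-Carlo estimate of the shift distribution by direct simulation.

    Each of the ``i_k`` copies missegregates independently with probability
    ``beta``; each missegregated copy's chromatid pair goes wholly to daughter
    1 or daughter 2 with probability 1/2. Kept deliberately independent of the
    closed form so it can validate it.
    """
    i_k = int(i_k)
    if i_k < 1:
        raise ValueError(f"parent copy number must be >= 1, got {i_k}")
    beta = _validate_beta(beta)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    missegregated = rng.random((n_samples, i_k)) < beta
    to_daughter1 = rng.random((n_samples, i_k)) < 0.5
    # a copy that missegregates toward daughter 1 adds +1 there, else -1
    shifts = np.where(missegregated, np.where(to_daughter1, 1, -1), 0).sum(axis=1)
    values, counts = np.unique(shifts, return_counts=True)
    probs = {int(v): float(c) / n_samples for v, c in zip(values, counts)}
    return ShiftDistribution(parent_copies=i_k, beta=beta, probs=probs)


def _parent_shift_tables(parent: Karyotype, beta: float) -> list[np.ndarray]:
    return [shift_probabilities(i_k, beta) for i_k in parent]


def daughter_distribution(
    parent: Sequence[int], rates: "RateModel"
) -> dict[Karyotype, float]:
    """First-daughter distribution q1(parent -> j) over all reachable daughters.

    The product over chromosomes of per-chromosome shift probabilities,
    enumerated over the full reachable box j_k in [0, 2 i_k]; sums to 1
    before any viability truncation. Parents with a zero-copy chromosome are
    dead and never divide.
    """
    parent = as_karyotype(parent)
    if any(c < 1 for c in parent):
        raise ValueError(
            f"parent {parent} has a zero-copy chromosome; dead states do not divide"
        )
    beta = _validate_beta(rates.misseg(parent))
    tables = _parent_shift_tables(parent, beta)
    out: dict[Karyotype, float] = {}
    supports = [
        [(j, float(p)) for j, p in enumerate(tab) if p > DROP_THRESHOLD]
        for tab in tables
    ]
    for combo in itertools.product(*supports):
        prob = 1.0
        for _, p in combo:
            prob *= p
        if prob <= DROP_THRESHOLD:
            continue
        daughter = tuple(j for j, _ in combo)
        out[daughter] = out.get(daughter, 0.0) + prob
    return out


def division_events(
    parent: Sequence[int], rates: "RateModel"
) -> dict[Karyotype, float]:
    """Distribution over division events q(parent -> j).

    The diagonal entry is the faithful-division probability
    ``prod_k P(0 | i_k)``; every off-diagonal entry is twice the
    first-daughter probability because an unfaithful division produces the
    daughter pair (j, 2i - j) and either member counts as the event. Row sum
    is ``2 - q_ii``.
    """
    parent = as_karyotype(parent)
    q1 = daughter_distribution(parent, rates)
    out: dict[Karyotype, float] = {}
    for daughter, p in q1.items():
        if daughter == parent:
            out[daughter] = p
        else:
            out[daughter] = 2.0 * p
    return out


@dataclass(frozen=True, eq=False)
class DivisionTensor:
    """Sparse parent -> daughter transition probabilities.

    ``daughter_form`` holds the first-daughter distribution q1;
    ``division_form`` the division-event distribution q (off-diagonal entries
    doubled). Rows are parents, columns daughters, in the lexicographic index
    of ``space``. Only viable states (members of ``viable_space`` with no
    zero-copy chromosome) divide; all other rows are zero.

    In truncated form ``space`` is the viable box itself and flux to
    nonviable daughters is dropped (interpreted as immediate death, never
    renormalized away); ``truncated`` records whether any flux was dropped.
    In untruncated form ``space`` is the full reachable box [0, 2 K_c] so
    every daughter is representable and rows of viable parents sum exactly to
    1 (daughter form) and 2 - q_ii (division form).
    """

    space: KaryotypeSpace
    viable_space: KaryotypeSpace
    daughter_form: sparse.csr_matrix
    division_form: sparse.csr_matrix
    truncated: bool
    dropped_flux: float

    def is_parent(self, k: Sequence[int]) -> bool:
        kt = as_karyotype(k)
        return kt in self.viable_space and all(c >= 1 for c in kt)

    def q(self, parent: Sequence[int], daughter: Sequence[int]) -> float:
        """Division-event probability q(parent -> daughter)."""
        i = self.space.index_of(parent)
        j = self.space.index_of(daughter)
        return float(self.division_form[i, j])

    def q1(self, parent: Sequence[int], daughter: Sequence[int]) -> float:
        """First-daughter probability q1(parent -> daughter)."""
        i = self.space.index_of(parent)
        j = self.space.index_of(daughter)
        return float(self.daughter_form[i, j])

    def to_table(self) -> np.ndarray:
        """3-column dense export (parent_index, daughter_index, probability)."""
        coo = self.division_form.tocoo()
        return np.column_stack([coo.row, coo.col, coo.data])

    def write_table(self, path) -> None:
        """Write the division form as whitespace-separated sparse text."""
        np.savetxt(
            path,
            self.to_table(),
            fmt=["%d", "%d", "%.17g"],
            header="parent_index daughter_index probability",
        )

    @classmethod
    def read_table(
        cls, path, space: KaryotypeSpace, truncated: bool = True
    ) -> "DivisionTensor":
        """Rebuild a tensor from the 3-column text export."""
        raw = np.loadtxt(path, ndmin=2)
        rows = raw[:, 0].astype(int)
        cols = raw[:, 1].astype(int)
        data = raw[:, 2]
        n = space.n_states
        division = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
        diag = division.diagonal()
        daughter = division.copy().tolil()
        off = division.tocoo()
        mask = off.row != off.col
        daughter = sparse.csr_matrix(
            (
                np.concatenate([off.data[mask] / 2.0, diag[diag > 0]]),
                (
                    np.concatenate([off.row[mask], np.flatnonzero(diag > 0)]),
                    np.concatenate([off.col[mask], np.flatnonzero(diag > 0)]),
                ),
            ),
            shape=(n, n),
        )
        return cls(
            space=space,
            viable_space=space,
            daughter_form=daughter,
            division_form=division,
            truncated=truncated,
            dropped_flux=float("nan"),
        )


def division_tensor(
    space: KaryotypeSpace, rates: "RateModel", truncate: bool = True
) -> DivisionTensor:
    """Assemble the division tensor for every viable parent in ``space``.

    With ``truncate=True`` (the default for extinction analysis) the matrices
    live on the viable box and probability flux to daughters outside it is
    dropped — those daughters die immediately and simply leave the system.
    With ``truncate=False`` the matrices are enumerated over the full
    reachable box [0, 2 K_c] (parents are still only the viable states), so
    no flux is lost and normalization identities hold exactly; nonviable
    daughters appear as dead, non-dividing states.

    Parents containing a zero-copy chromosome (possible when a bound is 0)
    are dead states: they receive an all-zero row.
    """
    from .karyospace import build_space

    if truncate:
        enum_space = space
    else:
        enum_space = build_space(
            space.M, [0] * space.M, [2 * h for h in space.viable_hi]
        )
    n = enum_space.n_states
    rows: list[int] = []
    cols: list[int] = []
    d1: list[float] = []
    dev: list[float] = []
    dropped = 0.0

    for parent in space.states:
        if any(c < 1 for c in parent):
            continue  # dead state, never a parent
        pi = enum_space.index_of(parent)
        beta = rates.misseg(parent)
        _validate_beta(beta)
        q1 = daughter_distribution(parent, rates)
        for daughter, p in q1.items():
            if daughter in enum_space:
                rows.append(pi)
                cols.append(enum_space.index_of(daughter))
                d1.append(p)
                dev.append(p if daughter == parent else 2.0 * p)
            else:
                dropped += p

    daughter_form = sparse.csr_matrix((d1, (rows, cols)), shape=(n, n))
    division_form = sparse.csr_matrix((dev, (rows, cols)), shape=(n, n))
    return DivisionTensor(
        space=enum_space,
        viable_space=space,
        daughter_form=daughter_form,
        division_form=division_form,
        truncated=dropped > 0.0,
        dropped_flux=dropped,
    )
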