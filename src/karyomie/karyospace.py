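"""Karyotype state spaces.

A karyotype is an integer copy-number vector over M chromosome types. The
model's state space is the box of viable karyotypes, one copy-number interval
[k_c, K_c] per chromosome, enumerated in lexicographic order so matrix layouts
are reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

Karyotype = tuple[int, ...]
"""A karyotype: hashable tuple of nonnegative chromosome copy numbers."""

DEFAULT_SIZE_CAP = 10**6


def as_karyotype(copies: Sequence[int]) -> Karyotype:
    """Coerce a sequence of copy numbers to a validated karyotype tuple."""
    k = tuple(int(c) for c in copies)
    if any(c < 0 for c in k):
        raise ValueError(f"karyotype entries must be nonnegative, got {k}")
    return k


def aggregate_ploidy(k: Sequence[int]) -> int:
    """Total chromosome count (L1 norm) of a karyotype.

    Collapses the M-dimensional copy-number vector to the single aggregate
    coordinate used by the 1-D ploidy model.
    """
    return int(sum(as_karyotype(k)))


@dataclass(frozen=True, eq=False)
class KaryotypeSpace:
    """Enumerated box of viable karyotypes with a dense index bijection.

    States are ordered lexicographically on the copy vector; ``index_of`` and
    ``karyotype_of`` are exact inverses over the enumeration.
    """

    M: int
    viable_lo: tuple[int, ...]
    viable_hi: tuple[int, ...]
    states: tuple[Karyotype, ...]
    _index: dict[Karyotype, int] = field(repr=False)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index_of(self, k: Sequence[int]) -> int:
        kt = as_karyotype(k)
        try:
            return self._index[kt]
        except KeyError:
            raise KeyError(f"karyotype {kt} is not in the viable space") from None

    def karyotype_of(self, i: int) -> Karyotype:
        return self.states[i]

    def __contains__(self, k: object) -> bool:
        try:
            kt = as_karyotype(k)  # type: ignore[arg-type]
        except (TypeError, ValueError):
            return False
        return kt in self._index

    def __iter__(self) -> Iterator[Karyotype]:
        return iter(self.states)

    def ploidies(self) -> np.ndarray:
        """Aggregate ploidy of every state, in index order."""
        return np.array([sum(s) for s in self.states], dtype=int)

    def to_config(self) -> dict:
        """Serializable description {M, viable_lo, viable_hi}."""
        return {
            "M": self.M,
            "viable_lo": list(self.viable_lo),
            "viable_hi": list(self.viable_hi),
        }

    @classmethod
    def from_config(cls, block: dict) -> "KaryotypeSpace":
        return build_space(block["M"], block["viable_lo"], block["viable_hi"])


def build_space(
    M: int,
    viable_lo: Sequence[int],
    viable_hi: Sequence[int],
    size_cap: int = DEFAULT_SIZE_CAP,
) -> KaryotypeSpace:
    """Enumerate the viable karyotype box ``prod_c [k_c, K_c]``.

    Parameters
    ----------
    M
        Number of chromosome types (1 for the aggregate ploidy model, 22 for
        whole autosomes).
    viable_lo, viable_hi
        Per-chromosome viable copy-number interval bounds, ``0 <= lo <= hi``.
    size_cap
        Refuse to enumerate spaces larger than this. Full multi-chromosome
        boxes like 8^22 are intentionally unsupported; use the Kronecker
        factorization in :mod:`karyomie.mie` instead.
    """
    if M < 1:
        raise ValueError(f"M must be >= 1, got {M}")
    lo = tuple(int(v) for v in viable_lo)
    hi = tuple(int(v) for v in viable_hi)
    if len(lo) != M or len(hi) != M:
        raise ValueError(f"viable_lo/viable_hi must have length M={M}")
    if any(l < 0 for l in lo):
        raise ValueError(f"viable_lo must be nonnegative, got {lo}")
    if any(h < l for l, h in zip(lo, hi)):
        raise ValueError(f"need viable_lo <= viable_hi componentwise, got {lo}, {hi}")

    size = 1
    for l, h in zip(lo, hi):
        size *= h - l + 1
    if size > size_cap:
        raise ValueError(
            f"viable space has {size} states, exceeding the cap of {size_cap}; "
            "use the Kronecker-factorized analysis for large multi-chromosome boxes"
        )

    ranges = [np.arange(l, h + 1) for l, h in zip(lo, hi)]
    if M == 1:
        grid = ranges[0][:, None]
    else:
        mesh = np.meshgrid(*ranges, indexing="ij")
        grid = np.stack([m.ravel() for m in mesh], axis=1)
    states = tuple(tuple(int(c) for c in row) for row in grid)
    index = {s: i for i, s in enumerate(states)}
    return KaryotypeSpace(M=M, viable_lo=lo, viable_hi=hi, states=states, _index=index)


def is_viable(space: KaryotypeSpace, k: Sequence[int]) -> bool:
    """Whether karyotype ``k`` lies inside the viable box (bounds inclusive).

    Nullisomy (zero copies of any chromosome with lo >= 1) and copy numbers
    above the per-chromosome ceiling are nonviable.
    """
    kt = tuple(int(c) for c in k)
    if len(kt) != space.M:
        raise ValueError(f"karyotype has length {len(kt)}, expected M={space.M}")
    return all(l <= c <= h for c, l, h in zip(kt, space.viable_lo, space.viable_hi))
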