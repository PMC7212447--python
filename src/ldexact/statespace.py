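"""Enumeration of the two-locus haplotype count state space.

The Markov chain tracks the gamete counts (f11, f12, f21, f22) of the four
haplotypes A1B1, A1B2, A2B1, A2B2 in a Wright-Fisher population of
effective size Ne (2*Ne gametes).  The state space is the set of ordered
non-negative integer quadruples summing to 2*Ne; its size is the
stars-and-bars count

    k = C(2*Ne + 3, 3).

States are enumerated in lexicographic ascending order on (f11, f12, f21),
with f22 implied by the sum constraint.  Each state is annotated with its
r2 value (nan when either locus is fixed), segregation flags, and the minor
allele frequency at the marker locus B used for MAF filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import NamedTuple, Sequence

import numpy as np

from .ldstats import ld_arrays

__all__ = ["StateSpace", "StateClassification", "state_count", "enumerate_states", "classify_state"]


def _validate_ne(ne) -> int:
    if not isinstance(ne, (int, np.integer)) or isinstance(ne, bool) or ne < 1:
        raise ValueError(f"ne must be a positive integer, got {ne!r}")
    return int(ne)


def state_count(ne: int) -> int:
    """Number of haplotype count states for population size ``ne``.

    Closed form C(2*ne + 3, 3), without enumerating.

    >>> state_count(50)
    176851
    """
    ne = _validate_ne(ne)
    return comb(2 * ne + 3, 3)


@dataclass(frozen=True)
class StateSpace:
    """Complete annotated enumeration of haplotype count states.

    Attributes
    ----------
    ne
        Effective population size.
    counts
        (k, 4) integer array; row i is state i as (f11, f12, f21, f22).
    r2
        (k,) per-state squared correlation; nan where indeterminate.
    determinate
        (k,) bool; True iff both loci segregate in the state.
    segregating_a, segregating_b
        (k,) bool per-locus segregation flags.
    maf_b
        (k,) minor allele frequency at locus B, in [0, 0.5].
    """

    ne: int
    counts: np.ndarray
    r2: np.ndarray
    determinate: np.ndarray
    segregating_a: np.ndarray
    segregating_b: np.ndarray
    maf_b: np.ndarray
    _codes: np.ndarray = field(repr=False)  # code -> state index lookup

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def k(self) -> int:
        return len(self)

    def encode(self, counts: np.ndarray) -> np.ndarray:
        """Map count quadruples (..., 4) to state indices, vectorised."""
        c = np.asarray(counts, dtype=np.int64)
        n1 = 2 * self.ne + 1
        code = (c[..., 0] * n1 + c[..., 1]) * n1 + c[..., 2]
        return self._codes[code]

    def index(self, counts: Sequence[int]) -> int:
        """Position of one count quadruple in the canonical order."""
        c = np.asarray(counts, dtype=int)
        if c.shape != (4,) or np.any(c < 0) or c.sum() != 2 * self.ne:
            raise KeyError(f"{c.tolist()} is not a state for ne={self.ne}")
        return int(self.encode(c))


def enumerate_states(ne: int) -> StateSpace:
    """Enumerate all k = C(2*ne+3, 3) states for population size ``ne``.

    >>> len(enumerate_states(2))
    35
    """
    ne = _validate_ne(ne)
    n = 2 * ne
    rows = [
        (f11, f12, f21, n - f11 - f12 - f21)
        for f11 in range(n + 1)
        for f12 in range(n - f11 + 1)
        for f21 in range(n - f11 - f12 + 1)
    ]
    counts = np.array(rows, dtype=np.int64)
    assert counts.shape[0] == state_count(ne)

    d, r2, p_a1, p_b1, determinate = ld_arrays(counts, ne)
    segregating_a = (p_a1 > 0.0) & (p_a1 < 1.0)
    segregating_b = (p_b1 > 0.0) & (p_b1 < 1.0)
    maf_b = np.minimum(p_b1, 1.0 - p_b1)

    n1 = n + 1
    codes = np.full(n1 * n1 * n1, -1, dtype=np.int64)
    flat = (counts[:, 0] * n1 + counts[:, 1]) * n1 + counts[:, 2]
    codes[flat] = np.arange(counts.shape[0])

    return StateSpace(
        ne=ne,
        counts=counts,
        r2=r2,
        determinate=determinate,
        segregating_a=segregating_a,
        segregating_b=segregating_b,
        maf_b=maf_b,
        _codes=codes,
    )


class StateClassification(NamedTuple):
    segregating_a: bool
    segregating_b: bool
    maf_b: float
    passes_maf: bool


def classify_state(
    counts: Sequence[int], ne: int, maf_threshold: float = 0.05
) -> StateClassification:
    """Segregation flags and MAF-at-B status for a single state.

    The MAF comparison is inclusive: a state passes when its minor allele
    frequency at locus B is >= ``maf_threshold``.  Only locus B (the marker)
    is ever filtered; locus A is the causal variant.
    """
    ne = _validate_ne(ne)
    c = np.asarray(counts, dtype=int)
    if c.shape != (4,) or np.any(c < 0) or c.sum() != 2 * ne:
        raise ValueError(f"counts must sum to 2*ne={2 * ne} and be non-negative, got {c.tolist()}")
    p_a1 = (c[0] + c[1]) / (2 * ne)
    p_b1 = (c[0] + c[2]) / (2 * ne)
    maf_b = float(min(p_b1, 1.0 - p_b1))
    return StateClassification(
        segregating_a=bool(0.0 < p_a1 < 1.0),
        segregating_b=bool(0.0 < p_b1 < 1.0),
        maf_b=maf_b,
        passes_maf=maf_b >= maf_threshold,
    )
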