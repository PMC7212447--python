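"""Linkage-disequilibrium statistics for two-locus haplotype count states.

For a diallelic pair of loci A and B, the four gametes A1B1, A1B2, A2B1,
A2B2 have population frequencies p11, p12, p21, p22.  The gametic
covariance is

    D = p11 - pA1 * pB1,

and the squared correlation between allelic indicator variables is

    r2 = D**2 / (pA1 * (1 - pA1) * pB1 * (1 - pB1)).

r2 is indeterminate when either locus is fixed (the denominator is zero);
indeterminacy is modelled as a value (``math.nan`` plus a flag), never an
exception, because fixed states are legitimate states of the chain that are
simply excluded when the distribution of r2 is summarised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids an import cycle
    from .statespace import StateSpace
    from .dynamics import DistributionVector

__all__ = [
    "LDSummary",
    "R2Distribution",
    "GroupDecomposition",
    "ld_from_counts",
    "ld_arrays",
    "r2_distribution",
    "group_decomposition",
]


@dataclass(frozen=True)
class LDSummary:
    """Per-state LD summary: D, r2 and the frequencies they derive from."""

    d: float
    r2: float  # nan when indeterminate
    p_a1: float
    p_b1: float
    p_a1b1: float
    determinate: bool


def ld_arrays(counts: np.ndarray, ne: int):
    """Vectorised D/r2 computation for an array of count quadruples.

    Parameters
    ----------
    counts
        Integer array of shape (..., 4) with rows (f11, f12, f21, f22)
        summing to 2*ne.
    ne
        Effective population size; 2*ne gametes per state.

    Returns
    -------
    (d, r2, p_a1, p_b1, determinate) arrays; ``r2`` is nan where either
    locus is fixed.
    """
    n = 2 * ne
    f = np.asarray(counts, dtype=float)
    p_a1 = (f[..., 0] + f[..., 1]) / n
    p_b1 = (f[..., 0] + f[..., 2]) / n
    p_a1b1 = f[..., 0] / n
    d = p_a1b1 - p_a1 * p_b1
    denom = p_a1 * (1.0 - p_a1) * p_b1 * (1.0 - p_b1)
    determinate = denom > 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(determinate, d * d / np.where(determinate, denom, 1.0), np.nan)
    return d, r2, p_a1, p_b1, determinate


def ld_from_counts(counts: Sequence[int], ne: int) -> LDSummary:
    """D and r2 for a single haplotype-count state.

    >>> ld_from_counts((0, 2, 1, 1), ne=2).r2
    0.3333333333333333
    """
    counts = np.asarray(counts, dtype=int)
    if counts.shape != (4,) or np.any(counts < 0) or counts.sum() != 2 * ne:
        raise ValueError(
            f"counts must be four non-negative integers summing to 2*ne={2 * ne}, got {counts.tolist()}"
        )
    d, r2, p_a1, p_b1, det = ld_arrays(counts, ne)
    return LDSummary(
        d=float(d),
        r2=float(r2),
        p_a1=float(p_a1),
        p_b1=float(p_b1),
        p_a1b1=float(counts[0]) / (2 * ne),
        determinate=bool(det),
    )


@dataclass(frozen=True)
class R2Distribution:
    """Weighted empirical distribution of r2 values.

    ``values``/``probs`` are aligned arrays with probs summing to 1 over the
    retained (determinate, optionally MAF-passing) states; ``retained_mass``
    is the unrenormalised probability mass of those states.
    """

    values: np.ndarray
    probs: np.ndarray
    retained_mass: float

    def expectation(self) -> float:
        return float(np.dot(self.values, self.probs))


def r2_distribution(
    dist: "DistributionVector",
    space: "StateSpace",
    maf_filter: bool = False,
    maf_threshold: float = 0.05,
) -> R2Distribution:
    """Distribution of r2 under ``dist``, excluding indeterminate states.

    States where either locus is fixed carry no information about r2 and are
    dropped; with ``maf_filter`` the support is further restricted to states
    whose minor allele frequency at the marker locus B is >= ``maf_threshold``
    (inclusive).  The remaining mass is renormalised to 1.

    Raises
    ------
    ValueError
        If the retained mass is zero (empty support).
    """
    keep = space.determinate.copy()
    if maf_filter:
        keep &= space.maf_b >= maf_threshold
    mass = float(dist.probs[keep].sum())
    if mass <= 0.0:
        raise ValueError("r2 distribution has empty support: no retained probability mass")
    values, probs = _aggregate(space.r2[keep], dist.probs[keep] / mass)
    return R2Distribution(values=values, probs=probs, retained_mass=mass)


def _aggregate(r2_values: np.ndarray, weights: np.ndarray):
    """Collapse equal r2 values, dropping those carrying no probability."""
    values, inverse = np.unique(r2_values, return_inverse=True)
    probs = np.zeros(values.shape)
    np.add.at(probs, inverse, weights)
    support = probs > 0.0
    return values[support], probs[support]


@dataclass(frozen=True)
class GroupDecomposition:
    """MAF-at-B decomposition of the determinate part of a distribution.

    ``low_mass``/``high_mass`` are conditional on determinate states and sum
    to 1; the per-group r2 distributions are renormalised within group.  A
    group with zero mass has distribution ``None``.
    """

    low_mass: float
    high_mass: float
    low: R2Distribution | None
    high: R2Distribution | None


def group_decomposition(
    dist: "DistributionVector",
    space: "StateSpace",
    maf_threshold: float = 0.05,
) -> GroupDecomposition:
    """Split determinate states into MAF_B < threshold and >= threshold groups."""
    det = space.determinate
    det_mass = float(dist.probs[det].sum())
    if det_mass <= 0.0:
        raise ValueError("no determinate probability mass to decompose")
    high_sel = det & (space.maf_b >= maf_threshold)
    low_sel = det & ~(space.maf_b >= maf_threshold)
    low_mass = float(dist.probs[low_sel].sum()) / det_mass
    high_mass = float(dist.probs[high_sel].sum()) / det_mass

    def _group(sel: np.ndarray) -> R2Distribution | None:
        mass = float(dist.probs[sel].sum())
        if mass <= 0.0:
            return None
        values, probs = _aggregate(space.r2[sel], dist.probs[sel] / mass)
        return R2Distribution(values=values, probs=probs, retained_mass=mass)

    return GroupDecomposition(
        low_mass=low_mass,
        high_mass=high_mass,
        low=_group(low_sel),
        high=_group(high_sel),
    )
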