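"""Propagation of the state distribution across generations.

P_t is a probability vector over the k haplotype-count states; one
generation is P_{t+1} = A @ P_t with A the kernel's transition matrix.
For small state spaces A is built densely once; above the dense cap the
product is streamed column-block by column-block so A is never stored.

Equilibrium is primarily assessed on the distribution conditional on
determinate states (both loci segregating).  Without mutation the
unconditional chain is absorbed into monomorphic states and only this
conditional (quasi-stationary) distribution plateaus, which is the
"equilibrium" of interest for E(r2); with mutation present the
unconditional distribution itself converges and an unconditional L1
criterion is applied as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import nan
from typing import Iterable, Sequence

import numpy as np

from .kernel import (
    DENSE_STATE_CAP,
    PopulationParams,
    build_transition_matrix,
    haplotype_probs,
    multinomial_block,
)
from .ldstats import ld_arrays
from .statespace import StateSpace

__all__ = [
    "DistributionVector",
    "TrajectoryRecord",
    "EquilibriumResult",
    "initial_distribution",
    "step_distribution",
    "propagate",
    "run_to_equilibrium",
    "trajectory_summaries",
]

_SUM_TOL = 1e-10


@dataclass(frozen=True)
class DistributionVector:
    """Probability mass over the k states at one generation (P_t)."""

    probs: np.ndarray
    generation: int = 0

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.ndim != 1:
            raise ValueError("probs must be a 1-D vector")
        if np.any(p < -1e-15):
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"probabilities must sum to 1 within {_SUM_TOL}, got {p.sum()!r}")
        if self.generation < 0:
            raise ValueError("generation must be non-negative")


@dataclass(frozen=True)
class TrajectoryRecord:
    """Per-generation LD summaries.

    ``e_r2`` / ``e_r2_maf`` are expectations of r2 renormalised over
    determinate states (resp. determinate states passing the MAF filter at
    locus B); nan when the conditioning mass is zero.  ``sigma_d2`` is the
    ratio of unconditional expectations E(D^2) / E(pA(1-pA) pB(1-pB)),
    with fixed states contributing 0 to both numerator and denominator.
    """

    generation: int
    e_r2: float
    e_r2_maf: float
    mass_determinate: float
    sigma_d2: float


def initial_distribution(space: StateSpace, mode: str = "auto") -> DistributionVector:
    """Start at allele frequency 0.5 at both loci and linkage equilibrium.

    ``point-mass`` puts all mass on counts (ne/2, ne/2, ne/2, ne/2), which
    requires 2*ne divisible by 4; ``multinomial-spread`` draws the initial
    counts as Multinomial(2*ne, (1/4, 1/4, 1/4, 1/4)).  ``auto`` picks
    point-mass when available, else multinomial-spread.  Either way the
    expected allele frequency is 0.5 at both loci and expected D is 0.
    """
    n = 2 * space.ne
    if mode == "auto":
        mode = "point-mass" if n % 4 == 0 else "multinomial-spread"
    if mode == "point-mass":
        if n % 4 != 0:
            raise ValueError(
                f"point-mass start needs 2*ne divisible by 4 (ne even); ne={space.ne}"
            )
        probs = np.zeros(len(space))
        probs[space.index((n // 4,) * 4)] = 1.0
    elif mode == "multinomial-spread":
        probs = multinomial_block(space.counts, np.full((1, 4), 0.25), n)[:, 0]
    else:
        raise ValueError(f"unknown initial mode {mode!r}")
    return DistributionVector(probs=probs, generation=0)


def step_distribution(
    probs: np.ndarray,
    params: PopulationParams,
    space: StateSpace,
    matrix: np.ndarray | None = None,
    chunk: int = 2048,
) -> np.ndarray:
    """One application of the kernel: returns A @ probs.

    With ``matrix`` supplied the dense product is used; otherwise columns of
    A are generated in blocks of ``chunk`` source states and accumulated, so
    memory stays O(k * chunk).  The two paths are numerically identical.
    """
    if matrix is not None:
        out = matrix @ probs
    else:
        k = len(space)
        out = np.zeros(k)
        n = 2 * params.ne
        for start in range(0, k, chunk):
            sl = slice(start, min(start + chunk, k))
            theta = haplotype_probs(space.counts[sl], params)
            out += multinomial_block(space.counts, theta, n) @ probs[sl]
    # guard against slow drift of the total mass over thousands of generations
    return out / out.sum()


def _get_matrix(params: PopulationParams, space: StateSpace, dense_cap: int):
    return build_transition_matrix(params, space) if len(space) <= dense_cap else None


def propagate(
    dist: DistributionVector,
    params: PopulationParams,
    space: StateSpace,
    generations: int,
    dense_cap: int = DENSE_STATE_CAP,
) -> list[DistributionVector]:
    """Propagate ``generations`` steps; returns the trajectory including the start.

    Output has length ``generations + 1`` with element t at generation
    ``dist.generation + t``.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    matrix = _get_matrix(params, space, dense_cap)
    out = [dist]
    p = dist.probs
    for t in range(1, generations + 1):
        p = step_distribution(p, params, space, matrix)
        out.append(DistributionVector(probs=p, generation=dist.generation + t))
    return out


@dataclass(frozen=True)
class EquilibriumResult:
    distribution: DistributionVector
    converged: bool
    generations: int


def _conditional(probs: np.ndarray, mask: np.ndarray) -> np.ndarray | None:
    mass = probs[mask].sum()
    if mass <= 0.0:
        return None
    return probs[mask] / mass


def run_to_equilibrium(
    dist: DistributionVector,
    params: PopulationParams,
    space: StateSpace,
    tol: float = 1e-12,
    max_generations: int = 3500,
    dense_cap: int = DENSE_STATE_CAP,
) -> EquilibriumResult:
    """Iterate P_{t+1} = A P_t until the distribution of LD stops changing.

    Convergence requires the L1 distance between successive
    conditional-on-determinate distributions to fall below ``tol``; when
    mutation is present (u > 0 or v > 0) the unconditional L1 distance must
    fall below ``tol`` as well, since the chain then has a proper stationary
    distribution.  Non-convergence within ``max_generations`` is reported
    via the flag, never raised.
    """
    if tol <= 0.0:
        raise ValueError("tol must be positive")
    matrix = _get_matrix(params, space, dense_cap)
    det = space.determinate
    need_unconditional = params.u > 0.0 or params.v > 0.0
    p = dist.probs
    converged = False
    t = 0
    for t in range(1, max_generations + 1):
        p_next = step_distribution(p, params, space, matrix)
        cond_prev, cond_next = _conditional(p, det), _conditional(p_next, det)
        if cond_prev is not None and cond_next is not None:
            ok = np.abs(cond_next - cond_prev).sum() < tol
        else:
            ok = cond_prev is None and cond_next is None
        if need_unconditional:
            ok = ok and np.abs(p_next - p).sum() < tol
        p = p_next
        if ok:
            converged = True
            break
    return EquilibriumResult(
        distribution=DistributionVector(probs=p, generation=dist.generation + t),
        converged=converged,
        generations=t,
    )


def trajectory_summaries(
    dists: Iterable[DistributionVector] | Sequence[DistributionVector],
    space: StateSpace,
    maf_threshold: float = 0.05,
) -> list[TrajectoryRecord]:
    """LD summaries per generation for a sequence of distributions."""
    d, r2, p_a1, p_b1, det = ld_arrays(space.counts, space.ne)
    d2 = d * d
    het = p_a1 * (1.0 - p_a1) * p_b1 * (1.0 - p_b1)
    maf_pass = det & (space.maf_b >= maf_threshold)
    out = []
    for dist in dists:
        p = dist.probs
        mass_det = float(p[det].sum())
        mass_maf = float(p[maf_pass].sum())
        e_r2 = float(p[det] @ r2[det] / mass_det) if mass_det > 0 else nan
        e_r2_maf = float(p[maf_pass] @ r2[maf_pass] / mass_maf) if mass_maf > 0 else nan
        denom = float(p @ het)  # fixed states contribute 0 to both terms
        sigma_d2 = float(p @ (d2 * det)) / denom if denom > 0 else nan
        out.append(
            TrajectoryRecord(
                generation=dist.generation,
                e_r2=e_r2,
                e_r2_maf=e_r2_maf,
                mass_determinate=mass_det,
                sigma_d2=sigma_d2,
            )
        )
    return out
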