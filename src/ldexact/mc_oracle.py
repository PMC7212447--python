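"""Forward Monte-Carlo Wright-Fisher simulator used to cross-validate the chain.

Each replicate is an independent population evolving under the identical
model as the exact chain: per generation the parental counts are mapped to
post-recombination/mutation/selection haplotype probabilities (shared with
:mod:`ldexact.kernel`), and 2*Ne gametes are then drawn.  The sampling step
is deliberately independent of the kernel's multinomial pmf arithmetic: the
multinomial draw is realised as a chain of conditional binomials, so the
empirical state frequencies exercise the model through a different code
path than the transition matrix.

Replicates are advanced in lockstep by one vectorised generator stream
seeded from ``SeedSequence(seed)``; results are fully reproducible given
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dynamics import DistributionVector, TrajectoryRecord, trajectory_summaries
from .kernel import PopulationParams, haplotype_probs
from .statespace import StateSpace

__all__ = ["SimulationConfig", "simulate", "empirical_distribution", "summarize_sim"]


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one simulation run."""

    params: PopulationParams
    replicates: int
    generations: int
    seed: int
    initial: tuple[int, int, int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        n = 2 * self.params.ne
        initial = self.initial
        if initial is None:
            if n % 4 != 0:
                raise ValueError(
                    f"default initial state needs 2*ne divisible by 4; pass initial explicitly (ne={self.params.ne})"
                )
            initial = (n // 4,) * 4
        initial = tuple(int(x) for x in initial)
        if len(initial) != 4 or any(x < 0 for x in initial) or sum(initial) != n:
            raise ValueError(f"initial counts must be 4 non-negative integers summing to {n}")
        object.__setattr__(self, "initial", initial)


def _sample_multinomial_rows(rng: np.random.Generator, n: int, theta: np.ndarray) -> np.ndarray:
    """Draw one Multinomial(n, theta_r) per row via conditional binomials."""
    reps = theta.shape[0]
    out = np.empty((reps, 4), dtype=np.int64)
    remaining = np.full(reps, n, dtype=np.int64)
    for j in range(3):
        with np.errstate(invalid="ignore", divide="ignore"):
            tail_j = theta[:, j:].sum(axis=1)
            p = np.where(tail_j > 0.0, theta[:, j] / tail_j, 0.0)
        draw = rng.binomial(remaining, np.clip(p, 0.0, 1.0))
        out[:, j] = draw
        remaining -= draw
    out[:, 3] = remaining
    return out


def simulate(config: SimulationConfig) -> np.ndarray:
    """Run the simulator; returns counts of shape (generations+1, replicates, 4).

    Index [t, r] is the haplotype count quadruple of replicate r at
    generation t; generation 0 is the initial state.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = 2 * config.params.ne
    reps = config.replicates
    out = np.empty((config.generations + 1, reps, 4), dtype=np.int64)
    out[0] = np.asarray(config.initial, dtype=np.int64)
    for t in range(1, config.generations + 1):
        theta = haplotype_probs(out[t - 1], config.params)
        out[t] = _sample_multinomial_rows(rng, n, theta)
    return out


def empirical_distribution(
    counts: np.ndarray, space: StateSpace, generation: int = 0
) -> DistributionVector:
    """Empirical state distribution of one generation of replicates.

    ``counts`` is a (replicates, 4) slice of :func:`simulate` output.
    """
    idx = space.encode(counts)
    probs = np.bincount(idx, minlength=len(space)).astype(float)
    return DistributionVector(probs=probs / probs.sum(), generation=generation)


def summarize_sim(
    sim_counts: np.ndarray, space: StateSpace, maf_threshold: float = 0.05
) -> list[TrajectoryRecord]:
    """Per-generation LD summaries of simulated replicates.

    Same summaries as :func:`ldexact.dynamics.trajectory_summaries`, computed
    on the empirical state frequencies.
    """
    dists: Sequence[DistributionVector] = [
        empirical_distribution(sim_counts[t], space, generation=t)
        for t in range(sim_counts.shape[0])
    ]
    return trajectory_summaries(dists, space, maf_threshold=maf_threshold)
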