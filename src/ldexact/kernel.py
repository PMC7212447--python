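"""Per-generation transition kernel of the two-locus Wright-Fisher chain.

One generation applies, in order: recombination, mutation, selection, then
multinomial resampling of 2*Ne gametes.  Given a source state with counts
(f11, f12, f21, f22), the three deterministic steps transform the parental
haplotype frequencies into a probability 4-vector theta; the probability of
any destination state x is then Multinomial(2*Ne, theta) evaluated at x.
Stacking these columns over all k source states gives the column-stochastic
transition matrix A with P_{t+1} = A @ P_t.

Recombination is modelled on ordered draws of two distinct parental gametes
(without replacement), which introduces the (f - 1)/(2*Ne - 1) terms.
Mutation is symmetric across loci: allele 1 -> allele 2 at rate u and
allele 2 -> allele 1 at rate v, acting independently at the two loci, so
the 4x4 haplotype mutation matrix is the Kronecker square of the one-locus
matrix [[1-u, v], [u, 1-v]].  Selection is gametic (haploid viability):
haplotypes carrying the deleterious causal allele A1 are down-weighted by
(1 - s) and the vector renormalised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .statespace import StateSpace

__all__ = [
    "PopulationParams",
    "DegenerateFitnessError",
    "StateSpaceTooLargeError",
    "DENSE_STATE_CAP",
    "recombination_probs",
    "mutation_matrix",
    "mutation_probs",
    "selection_probs",
    "haplotype_probs",
    "transition_column",
    "build_transition_matrix",
    "multinomial_block",
]

#: Largest k for which a dense k x k transition matrix is materialised by
#: default (k = 12,341 corresponds to ne = 20, about 1.2 GB of float64).
DENSE_STATE_CAP = 12_341

# log sentinel for theta entries that are exactly zero: any destination
# placing counts on such a haplotype must get pmf exactly 0, and
# exp(count * _LOG_ZERO) underflows to 0 while 0 * _LOG_ZERO == 0.
_LOG_ZERO = -1e6


class DegenerateFitnessError(ValueError):
    """Raised when selection removes all fitness (s = 1 and only A1 gametes)."""


class StateSpaceTooLargeError(MemoryError):
    """Raised when a dense transition matrix would exceed the storage cap."""


def _check_rate(name: str, value: float, lo: float = 0.0, hi: float = 1.0) -> float:
    value = float(value)
    if not (lo <= value <= hi):
        raise ValueError(f"{name} must be in [{lo}, {hi}], got {value}")
    return value


@dataclass(frozen=True)
class PopulationParams:
    """Population parameters of the chain.

    Attributes
    ----------
    ne
        Effective population size (2*ne gametes sampled per generation).
    c
        Recombination rate between the causal locus A and marker locus B,
        in [0, 0.5].
    u
        Mutation rate allele 1 -> allele 2, shared by both loci.
    v
        Mutation rate allele 2 -> allele 1, shared by both loci.
    s
        Selection coefficient against the causal allele A1, in [0, 1].
    maf_threshold
        Minor-allele-frequency cutoff applied at locus B when filtering.
    """

    ne: int
    c: float = 0.0
    u: float = 0.0
    v: float = 0.0
    s: float = 0.0
    maf_threshold: float = 0.05

    def __post_init__(self):
        if not isinstance(self.ne, (int, np.integer)) or isinstance(self.ne, bool) or self.ne < 1:
            raise ValueError(f"ne must be a positive integer, got {self.ne!r}")
        object.__setattr__(self, "ne", int(self.ne))
        object.__setattr__(self, "c", _check_rate("c", self.c, 0.0, 0.5))
        object.__setattr__(self, "u", _check_rate("u", self.u))
        object.__setattr__(self, "v", _check_rate("v", self.v))
        object.__setattr__(self, "s", _check_rate("s", self.s))
        object.__setattr__(
            self, "maf_threshold", _check_rate("maf_threshold", self.maf_threshold, 0.0, 0.5)
        )


def recombination_probs(counts: np.ndarray, c: float, ne: int) -> np.ndarray:
    """Haplotype probabilities among gametes after recombination.

    A gamete copies a parental haplotype with probability 1 - c; with
    probability c it combines the A allele of one parental gamete with the
    B allele of a second, distinct parental gamete (ordered draws without
    replacement from the 2*ne parental gametes).

    Parameters
    ----------
    counts
        Integer array (..., 4) of parental haplotype counts.
    c
        Recombination rate in [0, 0.5].
    ne
        Effective population size (>= 1, so 2*ne - 1 >= 1).

    Returns
    -------
    Array (..., 4) of probabilities summing to 1 along the last axis.
    """
    if ne < 1:
        raise ValueError(f"ne must be >= 1, got {ne}")
    c = _check_rate("c", c, 0.0, 0.5)
    n = 2 * ne
    m = n - 1
    f = np.asarray(counts, dtype=float)
    f11, f12, f21, f22 = f[..., 0], f[..., 1], f[..., 2], f[..., 3]
    # Negative structural terms like (f11 - 1)/m at f11 = 0 are multiplied
    # by f11/n = 0, so they never contribute; no clamping needed.
    p11 = (1 - c) * f11 / n + c * f11 / n * ((f11 - 1) / m + f21 / m) + c * f12 / n * (
        f11 / m + f21 / m
    )
    p12 = (1 - c) * f12 / n + c * f11 / n * (f12 / m + f22 / m) + c * f12 / n * (
        (f12 - 1) / m + f22 / m
    )
    p21 = (1 - c) * f21 / n + c * f21 / n * (f11 / m + (f21 - 1) / m) + c * f22 / n * (
        f11 / m + f21 / m
    )
    p22 = (1 - c) * f22 / n + c * f21 / n * (f12 / m + f22 / m) + c * f22 / n * (
        f12 / m + (f22 - 1) / m
    )
    return np.stack([p11, p12, p21, p22], axis=-1)


def mutation_matrix(u: float, v: float) -> np.ndarray:
    """4x4 haplotype mutation matrix T (columns sum to 1).

    T is the Kronecker square of the one-locus mutation matrix
    [[1-u, v], [u, 1-v]] in haplotype order (A1B1, A1B2, A2B1, A2B2).
    """
    u = _check_rate("u", u)
    v = _check_rate("v", v)
    one = np.array([[1.0 - u, v], [u, 1.0 - v]])
    return np.kron(one, one)


def mutation_probs(probs: np.ndarray, u: float, v: float) -> np.ndarray:
    """Apply one round of mutation: returns T @ probs along the last axis."""
    t = mutation_matrix(u, v)
    return np.asarray(probs, dtype=float) @ t.T


def selection_probs(probs: np.ndarray, s: float) -> np.ndarray:
    """Gametic selection against allele A1 with coefficient ``s``.

    Haplotypes A1B1 and A1B2 are weighted by (1 - s); all four entries are
    renormalised by the mean fitness (1-s)*(p11+p12) + p21 + p22.

    Raises
    ------
    DegenerateFitnessError
        If the mean fitness is zero (s = 1 with no A2-carrying gametes).
    """
    s = _check_rate("s", s)
    p = np.asarray(probs, dtype=float)
    w = p * np.array([1.0 - s, 1.0 - s, 1.0, 1.0])
    denom = w.sum(axis=-1, keepdims=True)
    if np.any(denom <= 0.0):
        raise DegenerateFitnessError(
            "total fitness is zero: s = 1 with all probability on A1 haplotypes"
        )
    return w / denom


def haplotype_probs(counts: np.ndarray, params: PopulationParams) -> np.ndarray:
    """Post-recombination, post-mutation, post-selection gamete probabilities.

    The composition recombination -> mutation -> selection applied to the
    parental counts; this is the multinomial probability vector from which
    the next generation's 2*ne gametes are drawn.
    """
    probs = recombination_probs(counts, params.c, params.ne)
    probs = mutation_probs(probs, params.u, params.v)
    return selection_probs(probs, params.s)


def _log_factorials(n: int) -> np.ndarray:
    lf = np.zeros(n + 1)
    lf[1:] = np.cumsum(np.log(np.arange(1, n + 1)))
    return lf


def multinomial_block(dest_counts: np.ndarray, theta: np.ndarray, n: int) -> np.ndarray:
    """Multinomial(n, theta_j) pmf at every destination, for many thetas.

    Parameters
    ----------
    dest_counts
        (k, 4) destination count quadruples, each summing to ``n``.
    theta
        (m, 4) probability vectors (rows sum to 1).
    n
        Number of multinomial trials (2*ne).

    Returns
    -------
    (k, m) array; entry (j, i) is the pmf of destination j under theta_i.
    Computed in log space with a precomputed log-factorial table.
    """
    x = np.asarray(dest_counts, dtype=np.int64)
    th = np.atleast_2d(np.asarray(theta, dtype=float))
    lf = _log_factorials(n)
    log_coef = lf[n] - lf[x].sum(axis=1)  # (k,)
    log_theta = np.where(th > 0.0, np.log(np.where(th > 0.0, th, 1.0)), _LOG_ZERO)  # (m, 4)
    log_pmf = log_coef[:, None] + x.astype(float) @ log_theta.T  # (k, m)
    return np.exp(log_pmf)


def transition_column(
    source: np.ndarray, params: PopulationParams, space: StateSpace
) -> np.ndarray:
    """One column of the transition matrix: destination probabilities from ``source``.

    Element j is the Multinomial(2*ne, theta) probability of the j-th state
    of ``space``, with theta the post-recombination/mutation/selection
    probability vector of ``source``.  Sums to 1 within 1e-12.
    """
    source = np.asarray(source, dtype=int)
    space.index(source)  # validates membership
    theta = haplotype_probs(source, params)
    return multinomial_block(space.counts, theta[None, :], 2 * params.ne)[:, 0]


def build_transition_matrix(
    params: PopulationParams,
    space: StateSpace,
    max_dense_states: int = DENSE_STATE_CAP,
) -> np.ndarray:
    """Dense k x k column-stochastic transition matrix A.

    Column i is ``transition_column(space.counts[i])``.  Refuses to
    materialise when k exceeds ``max_dense_states`` (about 8 * k**2 bytes);
    use the streaming propagation in :mod:`ldexact.dynamics` instead, which
    computes the identical result without storing A.
    """
    k = len(space)
    if k > max_dense_states:
        raise StateSpaceTooLargeError(
            f"k = {k} exceeds the dense-storage cap of {max_dense_states} states "
            f"(~{8 * k * k / 1e9:.1f} GB); use streaming propagation"
        )
    theta = haplotype_probs(space.counts, params)
    return multinomial_block(space.counts, theta, 2 * params.ne)
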