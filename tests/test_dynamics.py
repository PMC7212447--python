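"""Distribution propagation, equilibrium detection and trajectory summaries."""

import numpy as np
import pytest

from ldexact import (
    DistributionVector,
    PopulationParams,
    initial_distribution,
    propagate,
    run_to_equilibrium,
    trajectory_summaries,
)
from ldexact.dynamics import step_distribution


def expected_allele_freq_a(dist, space):
    p_a1 = (space.counts[:, 0] + space.counts[:, 1]) / (2 * space.ne)
    return float(dist.probs @ p_a1)


def expected_heterozygosity_a(dist, space):
    p_a1 = (space.counts[:, 0] + space.counts[:, 1]) / (2 * space.ne)
    return 2.0 * float(dist.probs @ (p_a1 * (1.0 - p_a1)))


class TestInitialDistribution:
    def test_point_mass(self, space2):
        dist = initial_distribution(space2, "point-mass")
        assert dist.probs[space2.index((1, 1, 1, 1))] == 1.0

    def test_point_mass_requires_divisibility(self, space3):
        with pytest.raises(ValueError):
            initial_distribution(space3, "point-mass")

    def test_multinomial_spread_pmf(self, space2):
        dist = initial_distribution(space2, "multinomial-spread")
        assert dist.probs[space2.index((4, 0, 0, 0))] == pytest.approx(0.25**4)
        assert dist.probs.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("mode", ["point-mass", "multinomial-spread"])
    def test_symmetric_start(self, mode, space2):
        # expected allele frequency 0.5 at both loci, expected D = 0
        dist = initial_distribution(space2, mode)
        assert expected_allele_freq_a(dist, space2) == pytest.approx(0.5)
        p_b1 = (space2.counts[:, 0] + space2.counts[:, 2]) / 4
        assert float(dist.probs @ p_b1) == pytest.approx(0.5)
        d = space2.counts[:, 0] / 4 - ((space2.counts[:, 0] + space2.counts[:, 1]) / 4) * p_b1
        assert float(dist.probs @ d) == pytest.approx(0.0, abs=1e-15)


class TestPropagate:
    def test_probability_conserved_and_martingale(self, space2):
        params = PopulationParams(ne=2, c=0.1)
        dists = propagate(initial_distribution(space2), params, space2, 50)
        for dist in dists:
            assert dist.probs.sum() == pytest.approx(1.0, abs=1e-10)
            assert expected_allele_freq_a(dist, space2) == pytest.approx(0.5, abs=1e-10)

    @pytest.mark.parametrize("ne", [2, 5])
    def test_heterozygosity_geometric_decay(self, ne, spaces):
        space = spaces(ne)
        params = PopulationParams(ne=ne)
        dists = propagate(initial_distribution(space), params, space, 20)
        h0 = expected_heterozygosity_a(dists[0], space)
        ratio = 1.0 - 1.0 / (2 * ne)
        for t, dist in enumerate(dists):
            assert expected_heterozygosity_a(dist, space) == pytest.approx(
                h0 * ratio**t, abs=1e-10
            )

    def test_monomorphic_mass_nondecreasing(self, space2):
        params = PopulationParams(ne=2, c=0.3)
        mono = ~space2.segregating_a & ~space2.segregating_b
        dists = propagate(initial_distribution(space2), params, space2, 100)
        masses = [float(d.probs[mono].sum()) for d in dists]
        assert all(b >= a - 1e-12 for a, b in zip(masses, masses[1:]))
        assert masses[-1] > masses[0]

    def test_streaming_equals_dense(self, space3):
        params = PopulationParams(ne=3, c=0.07, u=1e-4, v=1e-4, s=0.05)
        dist = initial_distribution(space3)
        dense = propagate(dist, params, space3, 5)[-1]
        streamed = propagate(dist, params, space3, 5, dense_cap=0)[-1]
        assert np.allclose(dense.probs, streamed.probs, atol=1e-14)


class TestEquilibrium:
    def test_fixed_point_with_mutation(self, space2):
        params = PopulationParams(ne=2, c=0.01, u=1e-3, v=1e-3)
        result = run_to_equilibrium(
            initial_distribution(space2), params, space2, tol=1e-12, max_generations=10_000
        )
        assert result.converged
        # stationarity: one more step moves the distribution by < tol
        p = result.distribution.probs
        p_next = step_distribution(p, params, space2)
        assert np.abs(p_next - p).sum() < 1e-11

    def test_absorption_without_mutation(self, space2):
        # without mutation the unconditional chain is eventually absorbed
        # into monomorphic states (run_to_equilibrium stops earlier, at the
        # quasi-stationary plateau of the conditional distribution)
        params = PopulationParams(ne=2, c=0.1)
        final = propagate(initial_distribution(space2), params, space2, 500)[-1]
        mono = ~space2.segregating_a & ~space2.segregating_b
        assert final.probs[mono].sum() == pytest.approx(1.0, abs=1e-6)

    def test_equilibrium_independent_of_start(self, space2):
        params = PopulationParams(ne=2, c=0.1, u=1e-2, v=1e-2)
        kwargs = dict(tol=1e-13, max_generations=20_000)
        from_point = run_to_equilibrium(
            initial_distribution(space2, "point-mass"), params, space2, **kwargs
        )
        from_spread = run_to_equilibrium(
            initial_distribution(space2, "multinomial-spread"), params, space2, **kwargs
        )
        assert from_point.converged and from_spread.converged
        l1 = np.abs(from_point.distribution.probs - from_spread.distribution.probs).sum()
        assert l1 < 1e-8

    def test_nonconvergence_reported_not_raised(self, space2):
        params = PopulationParams(ne=2, c=0.1, u=1e-3, v=1e-3)
        result = run_to_equilibrium(
            initial_distribution(space2), params, space2, tol=1e-15, max_generations=3
        )
        assert not result.converged
        assert result.generations == 3


class TestTrajectorySummaries:
    def test_linkage_equilibrium_state_has_zero_r2(self, space2):
        probs = np.zeros(len(space2))
        probs[space2.index((1, 1, 1, 1))] = 1.0
        (rec,) = trajectory_summaries([DistributionVector(probs)], space2)
        assert rec.e_r2 == pytest.approx(0.0)
        assert rec.mass_determinate == pytest.approx(1.0)

    def test_weighted_mean_of_determinate_states(self, space2):
        probs = np.zeros(len(space2))
        probs[space2.index((1, 1, 1, 1))] = 0.5  # r2 = 0
        probs[space2.index((2, 0, 0, 2))] = 0.5  # r2 = 1
        (rec,) = trajectory_summaries([DistributionVector(probs)], space2)
        assert rec.e_r2 == pytest.approx(0.5)

    def test_renormalisation_excludes_indeterminate_states(self, space2):
        # half the mass on a monomorphic state must not dilute E(r2)
        probs = np.zeros(len(space2))
        probs[space2.index((0, 2, 1, 1))] = 0.5  # r2 = 1/3
        probs[space2.index((4, 0, 0, 0))] = 0.5  # indeterminate
        (rec,) = trajectory_summaries([DistributionVector(probs)], space2)
        assert rec.e_r2 == pytest.approx(1 / 3)
        assert rec.mass_determinate == pytest.approx(0.5)

    def test_e_r2_undefined_when_no_determinate_mass(self, space2):
        probs = np.zeros(len(space2))
        probs[space2.index((4, 0, 0, 0))] = 1.0
        (rec,) = trajectory_summaries([DistributionVector(probs)], space2)
        assert np.isnan(rec.e_r2)
        assert rec.mass_determinate == 0.0

    def test_sigma_d2_is_ratio_of_unconditional_expectations(self, space2):
        probs = np.full(len(space2), 1.0 / len(space2))
        (rec,) = trajectory_summaries([DistributionVector(probs)], space2)
        n = 4
        p_a = (space2.counts[:, 0] + space2.counts[:, 1]) / n
        p_b = (space2.counts[:, 0] + space2.counts[:, 2]) / n
        d = space2.counts[:, 0] / n - p_a * p_b
        het = p_a * (1 - p_a) * p_b * (1 - p_b)
        assert rec.sigma_d2 == pytest.approx(
            float(probs @ (d * d * space2.determinate)) / float(probs @ het)
        )


def test_plateau_level_decreases_with_recombination(spaces):
    """Quasi-equilibrium E(r2) under pure drift falls as c grows."""
    space = spaces(10)
    levels = []
    for c in [0.01, 0.05, 0.1, 0.5]:
        params = PopulationParams(ne=10, c=c)
        result = run_to_equilibrium(
            initial_distribution(space), params, space, tol=1e-9, max_generations=600
        )
        (rec,) = trajectory_summaries([result.distribution], space)
        levels.append(rec.e_r2)
    assert all(a > b for a, b in zip(levels, levels[1:]))
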