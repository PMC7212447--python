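# Methods

## Model

The unit of evolution is a Wright–Fisher population of effective size Nₑ,
represented by the gamete counts (f11, f12, f21, f22) of the four
haplotypes A1B1, A1B2, A2B1, A2B2 at two diallelic loci: A, the causal
variant (optionally under selection), and B, the marker (optionally
MAF-filtered). Counts sum to 2Nₑ, so the state space has
k = C(2Nₑ+3, 3) states; `statespace.enumerate_states` lists them in
lexicographic ascending order on (f11, f12, f21) with f22 implied. All
results are order-invariant; tests and the API address states by their
count quadruple, never by row number.

One generation applies four steps, in this fixed order:

1. **Recombination.** A gamete is non-recombinant with probability 1 − c,
   copying one parental gamete; with probability c it joins the A allele
   of one parental gamete and the B allele of a second, *distinct*
   parental gamete. Draws are without replacement from the 2Nₑ parents,
   giving the (f − 1)/(2Nₑ − 1) terms in `kernel.recombination_probs`.
   Algebraically this is p11 → f11/2Nₑ − c·(f11·f22 − f12·f21)/(2Nₑ(2Nₑ−1)),
   i.e. recombination decays the count-level covariance without moving
   single-locus allele frequencies (a tested invariant).
2. **Mutation.** Allele 1 → allele 2 at rate u and allele 2 → allele 1 at
   rate v, identically and independently at both loci; the 4×4 haplotype
   matrix is the Kronecker square of [[1−u, v], [u, 1−v]].
3. **Selection.** Gametic (haploid viability) selection against A1:
   haplotypes A1B1 and A1B2 are weighted by 1 − s and the vector is
   renormalised by the mean fitness. With s = 1 and no A2-carrying gamete
   mass the mean fitness is zero and the kernel raises
   `DegenerateFitnessError`; this genuinely degenerate corner (lethal
   selection with no mutation, starting from an A1-fixed state) has no
   defined next generation. No diploid dominance model is offered.
4. **Sampling.** 2Nₑ gametes are drawn i.i.d. from the resulting
   probability vector θ, so the transition probability from state i to
   state j is the Multinomial(2Nₑ, θᵢ) pmf at xⱼ.

Only the printed composition (recombination → mutation → selection →
sampling) is implemented; alternative orderings of the forces would be a
different model.

## LD summaries

Per state, D = f11/2Nₑ − p_A1·p_B1 and r² = D²/(p_A1(1−p_A1)p_B1(1−p_B1)).
r² is *indeterminate* when either locus is fixed; indeterminate states
are excluded and the remaining mass renormalised whenever a distribution
of r² or an E(r²) is reported (`e_r2` in trajectories, `r2_distribution`).
MAF filtering further restricts to states with minor allele frequency at
locus B ≥ the threshold, **inclusive**, and only at locus B — the causal
locus is never filtered. The trajectory records also report σ²_d, defined
as the ratio of unconditional expectations E(D²)/E(p_A(1−p_A)p_B(1−p_B));
fixed states contribute zero to both numerator and denominator, so no
conditioning is involved. Both the determinate-only and the MAF-filtered
expectations are reported side by side, since the filtered curve can be
read either way.

## Propagation and equilibrium

`dynamics.propagate` iterates P_{t+1} = A·P_t. For k ≤ 12,341 states
(Nₑ ≤ 20, ≈1.2 GB of float64) the dense matrix is built once; above that
cap the product is streamed in column blocks of 2,048 source states, a
numerically identical matrix-free path (tested to agree with the dense
path to 1e−14). The multinomial pmf is evaluated in log space with a
precomputed log-factorial table; haplotypes with θ = 0 use a large
negative log sentinel so structurally impossible destinations get
probability exactly 0 with no 0·∞ artefacts. Each propagated vector is
renormalised by its sum to stop O(k·ε) mass drift over thousands of
generations.

Equilibrium (`run_to_equilibrium`) is declared when the L1 distance
between successive **conditional-on-determinate** distributions falls
below `tol` (default 1e−12, cap 3,500 generations). Without mutation the
unconditional chain only converges to fixation; the quantity that
plateaus — and the "equilibrium" E(r²) of the drift-only model — is this
quasi-stationary conditional distribution. When mutation is present
(u > 0 or v > 0) the chain is irreducible and the unconditional L1
criterion must be met as well. Non-convergence sets a flag; it never
raises. Power iteration is the only mechanism (no eigendecomposition).

The default initial condition is allele frequency 0.5 at both loci with
linkage equilibrium. Two realisations are offered: a point mass on counts
(Nₑ/2, Nₑ/2, Nₑ/2, Nₑ/2), available when 2Nₑ is divisible by 4, and a
multinomial spread Multinomial(2Nₑ, (¼,¼,¼,¼)), the state after one
round of sampling from exact frequencies. `auto` picks the point mass
when available. Both have E(p) = 0.5 at both loci and E(D) = 0; under
pure drift both obey the exact geometric heterozygosity decay
H_t = H₀(1 − 1/2Nₑ)^t, which the tests assert to 1e−10 over 50
generations.

## Monte-Carlo cross-validation

`mc_oracle.simulate` evolves many independent replicate populations under
the identical model. It reuses the kernel's θ computation but *not* its
pmf arithmetic: the multinomial draw is realised as a chain of
conditional binomials, so empirical state frequencies check the
transition matrix through an independent path. Replicates advance in
lockstep in one vectorised generator stream seeded from
`SeedSequence(seed)`; output is reproducible bit-for-bit given the seed.
The simulator is a validation oracle and deliberately emulates exactly
the idealised model (discrete non-overlapping generations, two loci, no
linked background): agreement between simulator and chain demonstrates
internal correctness of the exact computation, not realism of the
Wright–Fisher idealisation for any particular real population.

## Approximations and calibration

`approx` provides Sved's 1/(1 + 4Nₑc), the Ohta–Kimura/Hill equilibrium
σ²_d = (10 + ρ + 4θ)/(22 + 13ρ + 32θ + ρ² + 6ρθ + 8θ²) (ρ = 4Nₑc,
θ = 4Nₑu; at θ = 0 it reduces to the classic (10 + ρ)/(22 + 13ρ + ρ²)),
and the calibrated regression E(r²) = 1/(β₀ + β₁Nₑc). The shipped
15-row default coefficient table (c from 6.25 × 10⁻⁵ to 0.5, fitted on
exact equilibrium values for Nₑ ≤ 50 with u = 10⁻⁹) is used verbatim;
because the coefficients are per-c fits, an unknown c raises unless
log(c) interpolation is explicitly requested. `fit_calibration` refits
per c by `scipy.optimize.curve_fit` (initial guess (1, 4), Sved's
values), returning residual MSE. Extrapolation far beyond the fitted Nₑ
range is unreliable and deliberately unguarded. The Kosambi map function
c = tanh(2d)/2 converts physical spacing (kb at cM/Mb) to a recombination
fraction.

## Problem sizes and numerical choices

The test suite works at Nₑ ≤ 20 (k ≤ 12,341). Chosen study conditions:
mutation present means u = v = 10⁻⁹ (a per-site rate) for realism, or
10⁻³ in small-Nₑ equilibrium tests where mutation–drift equilibrium must
be reached in a tractable number of generations (the equilibrium
structure depends on θ = 4Nₑu, so a larger rate at small Nₑ probes the
same regime); selection s ∈ {0.01, 0.1}; MAF threshold 0.05; c on the
grid 0.01–0.1 (step 0.01) and 0.1–0.5 (step 0.1), plus 6.25 × 10⁻⁵ for
adjacent-marker spacing. Full Nₑ = 50 equilibrium runs (k = 176,851,
memory in the hundreds of GB for a dense matrix) are supported only
through the streaming path and are not part of the test suite.

Tolerances: transition columns sum to 1 within 1e−12; distribution
vectors within 1e−10; r² comparisons at small Nₑ are exact rationals
computed in floating point and compared at 1e−12. Monte-Carlo agreement
uses total-variation distance bounds consistent with replicate counts
(e.g. TV < 0.02 at 100,000 replicates).

## Limitations

Two loci, two alleles each; gamete-count (haploid) states, no diploid
genotypes or dominance; one shared u and v for both loci; discrete
non-overlapping generations; no interference or gene conversion in the
map function; the calibrated regression is only as good as the (Nₑ, c)
range it was fitted on.
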