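# Methods

This note documents the models, algorithms and numerical choices behind
`fndmc`, in the spirit of a package reference manual: what is computed,
under which assumptions, with which defaults, and what the built-in
fixtures do and do not demonstrate about real molecular calculations.

## Model and scope

The package works in the clamped-nuclei (Born–Oppenheimer) electronic
Hamiltonian in Hartree atomic units.  Spins are fixed labels: electron
coordinates are stored spin-up block first, spin-down block second, and no
spin-flip move exists anywhere.  Antisymmetry is therefore only required —
and only tested — under exchange of two *same-spin* electrons; opposite
spins are distinguishable blocks.  Besides Coulomb systems, the catalog
carries non-interacting harmonic-trap "atoms" (optionally one-dimensional)
whose exact spectra make them ideal sampler fixtures.

## Trial wavefunctions

Every trial satisfies one contract: `sign_log`, `grad_log`, `lap_log`
evaluated in the log domain, batched over walkers.  Log-domain evaluation
keeps products of many one- and two-body factors overflow-free, and every
downstream ratio (Metropolis, Green's function) is a log difference.  All
derivatives are analytic, hand-propagated:

- pair terms (electron–nucleus exponentials, Padé–Jastrow factors) use the
  standard radial chain rule `∇²f(r) = f'' + (d-1) f'/r`;
- Slater determinants use `∇_i log|det A| = Σ_k (A⁻¹)_{ki} ∇φ_k(r_i)` and
  `∇²_i log|det A| = Σ_k (A⁻¹)_{ki} ∇²φ_k(r_i) − |∇_i log|det A||²`;
- the neural orbitals propagate (value, gradient, Laplacian) triplets
  forward through each tanh layer
  (`∇²tanh(z) = (1−t²)∇²z − 2t(1−t²)|∇z|²`).

Construction runs a self-check: a same-spin transposition must flip the
sign and preserve the log-magnitude, and gradients/Laplacians must agree
with central finite differences (the independent oracle in
`fndmc.numeric`) at random configurations, redrawing points whose stencil
straddles a node.

The electron–electron Jastrow `u(r) = a·r/(1+βr)` carries the exact Kato
cusp coefficients `a = 1/2` (antiparallel) and `a = 1/4` (parallel) for
any β > 0; STO exponents default to Slater screening rules.
`cusp_check` probes both cusps numerically by projecting the analytic
gradient onto the approach direction at 10⁻⁴ bohr and averaging over ±
direction to cancel the smooth background gradient.

The **mini neural ansatz** exists to exercise the variational-training →
DMC workflow with a trainable nodal surface, not to compete with large
neural wavefunctions.  It is two tanh layers (default width 16) mapping
per-electron nuclear-displacement features to orbitals, times a sum of
exponential envelopes (initial exponents spread over shells Z, Z/2, …) and
the cusp Jastrow.  Parameter gradients are hand-written reverse
accumulation through the determinant cotangent `(A⁻¹)ᵀ`.  With plain SGD
on Be it reaches a VMC energy of roughly −14.55 Ha and DMC of
−14.66 Ha — single-determinant-quality nodes (≈10 mHa fixed-node error),
which is the expected ceiling of an ansatz this small.

## VMC

Metropolis sampling of `ψ_T²` with symmetric Gaussian proposals; the
acceptance ratio is `exp(2Δlog|ψ|)`.  Default proposal width 0.5 bohr;
all-electron moves up to four electrons, single-electron sweeps above
(all-electron acceptance degrades with n; the crossover is a pragmatic
default, configurable via `move_mode`).  Burn-in defaults to 10% of the
chain, mirroring the DMC equilibration convention.  Singular
configurations (particle coincidences within 10⁻¹² bohr) are jittered by
10⁻⁶ bohr and counted in the diagnostics.

The optimizer is deliberately plain SGD with the covariance gradient
estimator `2[⟨E_L ∂_θ log|ψ|⟩ − ⟨E_L⟩⟨∂_θ log|ψ|⟩]` over a persistent
walker batch.  Its job is to *generate trajectories* `(k, E_VMC, E_DMC)`
for the extrapolation scheme; convergence speed is irrelevant to any
result the package reports, so no preconditioning is attempted.

## DMC

One iteration is drift–diffusion → fixed-node rejection →
Green's-function Metropolis → weighting → branch–merge → trial-energy
feedback, in that order (the standard ordering for importance-sampled
DMC).  Specifics:

- **Drift limiting.** `v̄ = v·(−1+√(1+2|v|²τ))/(|v|²τ)` per electron
  (series branch below `|v|²τ = 10⁻⁸`).  This caps the divergent drift
  near nodes at `|v̄| ≈ √(2/τ)` and reduces time-step error.
- **Node crossing** is detected as a sign change of `ψ_T` between the
  current and proposed configuration — no continuous path check.  This is
  standard practice and exact in the τ→0 limit; at finite τ undetected
  double crossings are part of the time-step bias that the τ→0
  extrapolation removes.
- **Effective time step.** `τ_eff = τ·⟨|Δx|²⟩_accepted / ⟨|Δx|²⟩_proposed`
  per iteration, used in the weight update.
- **Local-energy clipping.** `E_L` is clipped to `E_best ± α/√τ` with
  `α = 0.2·√n_electrons` by default.  The window widens as τ→0 (no bias
  in the extrapolated limit) and scales with system size so that two
  non-interacting fragments are clipped consistently with their union —
  the size-consistency test (two H atoms 20 bohr apart vs twice one atom)
  runs with clipping active.  The clip activation fraction is reported in
  the diagnostics (≈0.5% on the Be neural runs, 0 on exact-trial runs).
- **Branch–merge.** Branch threshold 2.0.  Every split is paired with a
  merge of the two lightest walkers into one, located at either parent
  with probability proportional to weight and carrying the summed weight:
  the population is exactly constant, total weight is conserved to
  round-off, and the expected weighted density is unchanged.  No merge
  happens without a branch.  A sweep is capped at 10·N events per
  iteration: a merged pair can in pathological weight distributions itself
  exceed the threshold, and the cap guarantees termination (leftover
  overweight walkers are handled next iteration).  The `merge_threshold`
  field exists for configuration compatibility but the paired rule never
  consults it.
- **Trial-energy feedback.** `E_T = E_best − log(W/W_target)/t_damp` with
  `t_damp = 10τ` by default and `E_best` a trailing 100-step average of
  the mixed-estimator series.  Feedback is negative in W; the H-atom
  closed-loop test holds the total weight within a factor 2 of target over
  thousands of steps.
- **Estimator.** Walkers start from a short `ψ_T²` Metropolis
  equilibration; the first 10% of DMC steps are discarded; the production
  energy is the total-weight-weighted mean of the per-step mixed estimator
  with a reblocked standard error (the reblocking itself is performed on
  the unweighted per-step series — weights stay within a factor ~2 of
  target, so the distinction is far below the statistical error).

`tau_extrapolated_energy` runs the engine at several τ and extrapolates
linearly to τ = 0 with inverse-variance weights.  The helium validation
uses τ ∈ {0.02, 0.01, 0.005} Ha⁻¹ with 40k/60k/100k steps and 600
walkers — chosen so that the extrapolated statistical error is ≈0.6 mHa,
comfortably resolving the 1 mHa agreement with the Hylleraas reference.

## Reblocking and the VMC–DMC extrapolation

`reblock` is Flyvbjerg–Petersen pairwise blocking; the stderr is read at
the first level where the estimate changes by <5% over two successive
levels (else the last usable level).  The mean is the exact arithmetic
mean at every level.  Sampling tests validate the estimator on i.i.d.
(15%) and AR(1), φ=0.9 (20%) series against closed forms.

`fit_linear_relation` regresses `E_DMC(k) − E_final` on
`E_VMC(k) − E_DMC(k)` by OLS — unweighted by default, since error bars
along a trajectory are typically homogeneous; an inverse-variance variant
is available.  `E_final` is the DMC energy at the last available training
step, so truncated trajectories simply refit with their last collected
point.  Absolute-energy extrapolation requires the intercept `b` as user
input (it is not identifiable from the trajectory); relative energies
cancel it: `ΔE_ex = (1+w)ΔE_DMC − w·ΔE_VMC`.
`extrapolation_distribution` fits a pooled slope (shared w, per-trajectory
intercepts, via within-trajectory demeaning) and applies the relative
formula at every shared step; averaging the resulting set reduces the
fitting error, which the tests demonstrate on noisy synthetic trajectories
whose two systems converge at different rates.

## Nodal-surface geometry

`distance_to_node` starts from the first-order estimate
`|ψ|/|∇ψ| = 1/|∇log|ψ||`, brackets a sign change along the steepest
descent direction of `|ψ|` (both orientations), bisects to tolerance, then
polishes by sliding the witness tangentially along the node toward the
query point with re-bisection.  The result is an upper bound on the true
distance up to the tolerance (verified against dense grid search); if no
sign change is found in range, the sentinel `(∞, None)` is returned.

`sample_node_points` restricts a Metropolis `ψ²` chain to the shell
`{x : d̂(x,S) < ε}` using the *first-order* distance estimate as the
membership test — the exact shell is not computable cheaply, so a
documented surrogate is used and its bias is controlled by the grid-oracle
comparisons in the tests — then pushes every retained sample onto S
through the distance-refinement witness (the nearest node point found).
Defaults: ε = 0.1 bohr, K = 4096 samples, projection tolerance 10⁻³ bohr.

The divergence `D(S₁,S₂)` is the sample mean of `d(Y_i, S₂)` over node
samples of trial 1 (the expectation form implies the mean, which is what
is implemented), reported with its Monte Carlo standard error.  It is
non-negative, vanishes on identical surfaces up to projection tolerance,
recovers the offset of parallel hyperplane nodes, and is *not* symmetric.

Visualization: `wavefunction_slice` moves one electron over a
`[−5, 5]²` bohr square (defaults) with all others frozen, returning
log-magnitudes, signs and a sign-change mask; `be_nodal_cut` scans
`r₁ ∈ [0.1, 2.1]`, `cos θ₁ ∈ [−1, 1]`, `r₃ ∈ [0.1, 2.1]` with the other
spherical coordinates pinned (r₂ = r₄ = 1.1, all remaining angles fixed at
their conventional values) and extracts the zero set by sign-change
marching.  The `[−1, 1]` range of the first electron's polar coordinate is
interpreted as a range of cos θ₁: an angular range of ±1 rad would break
the symmetry of the sweep, while the cosine reading spans the full
meridian.

## Fixtures: what they show and what they do not

The exactly solvable fixtures (hydrogenic H, harmonic traps, the 1-D
two-fermion state `(x₁−x₂)e^{−(x₁²+x₂²)/2}`) validate the samplers and
the fixed-node machinery at zero-variance points and at an exactly known
node.  The nodeless He trial validates the full weighted propagation
against an independent Hylleraas reference without any nodal error.
Synthetic extrapolation trajectories are generated directly from the
linear relation with controlled noise.  None of these probe the regime
where the fixed-node error itself dominates a chemically interesting
energy difference; the Be neural workflow probes it qualitatively but, by
design of the small ansatz, does not reach chemical accuracy.

## Known limitations

- Single process, constant per-process population; no load balancing,
  forward walking, pure estimators, excited states or released nodes.
- No pseudopotentials and no periodic systems; all-electron only, which
  limits practical system size on a CPU.
- The multi-center Slater–Jastrow places atomic orbital sets round-robin
  across nuclei — a crude localized guiding function, not an MO treatment.
- Plain SGD optimization is noisy near convergence; trajectories are fit
  for the extrapolation scheme rather than polished to a minimum.
- The node-distance refinement is a local search: for strongly curved or
  disconnected nodal sets the returned witness can be a non-nearest sheet,
  which is why the divergence is validated against grid oracles on the
  fixtures where the geometry is known.
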