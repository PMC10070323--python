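# fndmc — fixed-node diffusion Monte Carlo for small atoms and molecules

`fndmc` solves the electronic Schrödinger equation

```
H = -1/2 Σ_i ∇_i²  -  Σ_{i,I} Z_I / |r_i - R_I|  +  Σ_{i<j} 1 / |r_i - r_j|  +  Σ_{I<J} Z_I Z_J / |R_I - R_J|
```

for ground-state energies by **fixed-node diffusion Monte Carlo (FN-DMC)**
with pluggable trial wavefunctions, entirely at desk scale: small atoms
(H–Ar), small molecules (H₂, N₂), and exactly solvable harmonic-trap
fixtures.  It is aimed at people who want a transparent, fully tested QMC
reference implementation — every algorithmic ingredient (importance-sampled
drift–diffusion, constant-population branch–merge, mixed estimator,
reblocking, nodal-surface geometry) is a small, separately testable
function rather than a black box.

## What it does

A population of *walkers* (electron configurations `x` with weights `w`)
is propagated in imaginary time under `exp(-τ(H - E_T))`.  Each iteration:

1. **Diffuse** — `x' = x + v̄(x)·τ + χ√τ`, with drift `v̄` the
   Umrigar-limited `∇log|ψ_T|`; moves that change `sign ψ_T` are rejected
   unconditionally (the fixed-node constraint), the rest pass a
   Green's-function Metropolis test and an effective time step `τ_eff`
   compensates rejections.
2. **Weight** — `w ← w·exp(-τ_eff(½(E_L(x') + E_L(x)) - E_T))`, with the
   local energy `E_L = (Hψ_T)/ψ_T` clipped to `E_best ± α/√τ` for
   stability and size consistency.
3. **Branch/merge** — a walker heavier than the branch threshold splits in
   two; in the same move the two lightest walkers merge at either parent
   (probability ∝ weight).  The population size never changes and total
   weight is conserved exactly.
4. **Feedback** — `E_T = E_best - log(W/W_target)/t_damp` steers the total
   weight.

The production energy is the **mixed estimator** `⟨ψ_T|H|φ⟩/⟨ψ_T|φ⟩`
(first 10% of steps discarded) with a Flyvbjerg–Petersen **reblocked**
standard error.

On top of the core engine:

- **Trial wavefunctions** (`fndmc.trials`, `fndmc.neural`): hydrogenic and
  Gaussian eigenstates, a two-electron Padé–Jastrow, Slater–Jastrow with
  STO orbitals and exact e–e cusps, and a small two-layer neural-orbital
  ansatz with analytic derivatives — all verified against finite
  differences and antisymmetry checks at construction.
- **VMC** (`fndmc.vmc`): Metropolis sampling of `ψ_T²`, variational energy
  inference, and a plain-SGD parameter optimizer
  (`g = 2[⟨E_L O⟩ - ⟨E_L⟩⟨O⟩]`, `O = ∂_θ log|ψ|`).
- **VMC–DMC extrapolation** (`fndmc.stats`): along a variational training
  trajectory the energies obey an empirical linear relation
  `E_DMC(k) - E_ex = w·(E_VMC(k) - E_DMC(k)) + b`; for relative energies
  the intercept cancels, `ΔE_ex = (1+w)·ΔE_DMC - w·ΔE_VMC`, and averaging
  the per-step extrapolated values suppresses the fitting error.
- **Nodal geometry** (`fndmc.nodal`): distance of a configuration to the
  nodal surface, ψ²-weighted sampling *on* the node, the asymmetric nodal
  divergence `D(S₁,S₂) = E_{Y∼P₁} d(Y,S₂)`, 2-D wavefunction slices and a
  3-D spherical-coordinate nodal cut for 4-electron atoms.
- **Independent references** (`fndmc.reference`): a closed-form Hylleraas
  variational calculator for two-electron atoms (He ground state to a few
  μHa), used as an oracle by the test suite — never as the implementation.

All internal quantities are Hartree atomic units (bohr, Hartree); XYZ
geometry files are Å at the I/O boundary.

## Worked example

The hydrogen atom with the exact hydrogenic trial is a zero-variance fixed
point — DMC reproduces −0.5 Ha with zero statistical error and no
branching:

```
$ fndmc dmc --system H --trial hydrogenic --tau 0.01 --steps 1000 --walkers 200 --seed 1
E_DMC = -0.500000 +/- 0.000000 Ha
{
  "acceptance": 0.99908,
  "tau_eff_ratio": 0.9984538749815454,
  "branch_count": 0,
  ...
}
```

Helium with the nodeless Padé–Jastrow trial (`b = 0.35`): the VMC energy
is variational at the trial's quality, while FN-DMC — exact for a nodeless
trial up to time-step bias — lands at the true ground state:

```
$ fndmc vmc --system He --trial he_pade --walkers 300 --steps 800 --seed 2
E_VMC = -2.867842 +/- 0.001118 Ha

$ fndmc dmc --system He --trial he_pade --tau 0.01 --steps 4000 --walkers 400 --seed 3
E_DMC = -2.898185 +/- 0.003924 Ha
```

The VMC value sits ~36 mHa above the exact −2.90372 Ha (the trial's
correlation error); the DMC value recovers it within its error bar plus a
small O(τ) bias that a τ→0 extrapolation removes (see
`fndmc.dmc.tau_extrapolated_energy`).

Full pipelines (optimize → VMC → DMC with CSV logs, checkpoints and a JSON
summary) run from a TOML config via `fndmc run config.toml`; see also
`fndmc systems`, `fndmc optimize`, `fndmc extrapolate`,
`fndmc nodal-divergence`, `fndmc slice`, `fndmc becut`.

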