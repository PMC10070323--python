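"""Variational Monte Carlo: Metropolis sampling of psi_T^2, variational
energy estimation, and a minimal stochastic-gradient parameter optimizer.

The sampler uses symmetric Gaussian proposals, so the Metropolis acceptance
ratio is psi(x')^2 / psi(x)^2 = exp(2 (log|psi(x')| - log|psi(x)|)).  By
default all electrons move at once for small systems and one electron at a
time above four electrons, where all-electron acceptance degrades.

The optimizer exists to generate (E_VMC, E_DMC) trajectories for the
extrapolation scheme, not to compete with natural-gradient methods: it is
plain SGD on the variational energy with the standard first-order gradient
estimator

    g = 2 [ <E_L O> - <E_L> <O> ],   O = d log|psi| / d theta,

averaged over the sampled walker batch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from fndmc.stats import EnergyEstimate, reblock
from fndmc.systems import MolecularSystem, init_walkers
from fndmc.trials import potential_energy


@dataclass(frozen=True)
class VMCParams:
    n_walkers: int = 256
    n_steps: int = 1000
    step_size: float = 0.5          # proposal std, bohr
    move_mode: str = "auto"         # "all", "single", or "auto"
    burn_in_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.n_walkers < 1:
            raise ValueError("n_walkers must be >= 1")
        if not (0.0 <= self.burn_in_fraction < 1.0):
            raise ValueError("burn_in_fraction must be in [0, 1)")
        if self.move_mode not in ("all", "single", "auto"):
            raise ValueError("move_mode must be 'all', 'single' or 'auto'")


def _resolve_move_mode(params: VMCParams, system: MolecularSystem) -> str:
    if params.move_mode != "auto":
        return params.move_mode
    return "single" if system.n_electrons > 4 else "all"


def _valid_start(trial, system, n_walkers, rng) -> np.ndarray:
    """Initial ensemble with psi != 0 everywhere (resample zero-magnitude)."""
    x = init_walkers(system, n_walkers, seed=rng)
    for _ in range(100):
        _, logm = trial.sign_log(x)
        bad = ~np.isfinite(logm)
        if not bad.any():
            return x
        x[bad] = init_walkers(system, int(bad.sum()), seed=rng)
    raise RuntimeError("could not find starting points with psi != 0")


def local_energies_safe(trial, system, x, rng=None, max_retries: int = 5):
    """Per-walker local energies with singular-configuration resampling.

    Walkers sitting on a particle coincidence (or yielding a non-finite
    local energy) are jittered by 1e-6 bohr and re-evaluated; the number of
    such events is returned alongside.  The input array is modified in
    place for repaired walkers.
    """
    rng = rng or np.random.default_rng(0)
    n_repaired = 0
    for _ in range(max_retries):
        g = trial.grad_log(x)
        lap = trial.lap_log(x)
        kin = -0.5 * (lap.sum(axis=-1) + (g**2).sum(axis=(-1, -2)))
        v = potential_energy(system, x, check_singular=False)
        el = kin + v
        bad = ~np.isfinite(el)
        if not bad.any():
            return el, n_repaired
        n_repaired += int(bad.sum())
        x[bad] += rng.normal(scale=1e-6, size=x[bad].shape)
    el = np.where(np.isfinite(el), el, np.nan)
    return el, n_repaired


def metropolis_sample(trial, system: MolecularSystem, params: VMCParams,
                      initial: np.ndarray = None, return_all: bool = True):
    """Sample psi_T^2 with the Metropolis algorithm.

    Returns ``(samples, acceptance)`` where ``samples`` stacks the post-burn-in
    ensembles with shape (n_kept, n_walkers, n_electrons, dim) (or just the
    final ensemble when ``return_all=False``) and ``acceptance`` is the mean
    acceptance rate over all proposals.
    """
    rng = np.random.default_rng(params.seed)
    mode = _resolve_move_mode(params, system)
    x = np.array(initial, dtype=float) if initial is not None else _valid_start(
        trial, system, params.n_walkers, rng)
    _, logm = trial.sign_log(x)
    n_burn = int(params.burn_in_fraction * params.n_steps)
    kept = []
    n_acc = 0
    n_prop = 0
    n, d = system.n_electrons, system.dim
    for step in range(params.n_steps):
        if mode == "all":
            prop = x + rng.normal(scale=params.step_size, size=x.shape)
            _, logp = trial.sign_log(prop)
            accept = np.log(rng.random(len(x))) < 2.0 * (logp - logm)
            x[accept] = prop[accept]
            logm = np.where(accept, logp, logm)
            n_acc += int(accept.sum())
            n_prop += len(x)
        else:
            for e in range(n):
                prop = x.copy()
                prop[:, e, :] += rng.normal(scale=params.step_size, size=(len(x), d))
                _, logp = trial.sign_log(prop)
                accept = np.log(rng.random(len(x))) < 2.0 * (logp - logm)
                x[accept] = prop[accept]
                logm = np.where(accept, logp, logm)
                n_acc += int(accept.sum())
                n_prop += len(x)
        if step >= n_burn and return_all:
            kept.append(x.copy())
    acceptance = n_acc / max(n_prop, 1)
    if return_all:
        return np.asarray(kept), acceptance
    return x, acceptance


def vmc_energy(trial, system: MolecularSystem, params: VMCParams,
               initial: np.ndarray = None):
    """Variational energy <psi|H|psi>/<psi|psi> with reblocked error bar.

    Runs a Metropolis chain, discards the burn-in, averages the local
    energy over walkers at every step, and reblocks the per-step series.
    Returns an :class:`EnergyEstimate`; singular-configuration repairs are
    counted on the estimate as ``.n_singular`` (diagnostic attribute).
    """
    rng = np.random.default_rng(params.seed)
    mode = _resolve_move_mode(params, system)
    x = np.array(initial, dtype=float) if initial is not None else _valid_start(
        trial, system, params.n_walkers, rng)
    _, logm = trial.sign_log(x)
    n_burn = int(params.burn_in_fraction * params.n_steps)
    series = []
    n, d = system.n_electrons, system.dim
    n_singular = 0
    for step in range(params.n_steps):
        if mode == "all":
            prop = x + rng.normal(scale=params.step_size, size=x.shape)
            _, logp = trial.sign_log(prop)
            accept = np.log(rng.random(len(x))) < 2.0 * (logp - logm)
            x[accept] = prop[accept]
            logm = np.where(accept, logp, logm)
        else:
            for e in range(n):
                prop = x.copy()
                prop[:, e, :] += rng.normal(scale=params.step_size, size=(len(x), d))
                _, logp = trial.sign_log(prop)
                accept = np.log(rng.random(len(x))) < 2.0 * (logp - logm)
                x[accept] = prop[accept]
                logm = np.where(accept, logp, logm)
        if step >= n_burn:
            el, rep = local_energies_safe(trial, system, x, rng)
            n_singular += rep
            series.append(float(np.mean(el)))
    est = reblock(series)
    est.n_singular = n_singular
    return est


@dataclass
class OptimizationStep:
    iteration: int
    parameters: np.ndarray
    energy: EnergyEstimate


def optimize_trial(trial, system: MolecularSystem, params: VMCParams,
                   n_iters: int, learning_rate: float = 0.05,
                   steps_per_iter: int = 20, checkpoint_every: int = 1):
    """SGD minimization of the variational energy over the trial parameters.

    Keeps a persistent walker population; each iteration advances the chain
    ``steps_per_iter`` Metropolis steps, estimates the energy gradient over
    the batch and takes one SGD step.  Returns the trajectory as a list of
    :class:`OptimizationStep` (iteration, parameter vector, batch energy),
    recorded every ``checkpoint_every`` iterations plus the final state.
    A non-finite energy aborts the run, returning the trajectory collected
    up to the last good checkpoint.
    """
    if len(trial.parameters) < 1:
        raise ValueError("trial has no free parameters to optimize")
    rng = np.random.default_rng(params.seed)
    x = _valid_start(trial, system, params.n_walkers, rng)
    traj: list[OptimizationStep] = []
    inner = replace(params, n_steps=steps_per_iter, burn_in_fraction=0.0,
                    seed=int(rng.integers(2**31 - 1)))
    for k in range(n_iters):
        x, _ = metropolis_sample(trial, system, replace(
            inner, seed=int(rng.integers(2**31 - 1))), initial=x, return_all=False)
        el, _ = local_energies_safe(trial, system, x, rng)
        if not np.all(np.isfinite(el)):
            break
        e_mean = float(el.mean())
        e_err = float(el.std(ddof=1) / np.sqrt(len(el)))
        if not np.isfinite(e_mean):
            break
        if k % checkpoint_every == 0:
            traj.append(OptimizationStep(k, trial.parameters.copy(),
                                         EnergyEstimate(e_mean, e_err, len(el))))
        if learning_rate != 0.0:
            o = trial.param_grad_log(x)  # (W, P)
            grad = 2.0 * ((el[:, None] * o).mean(axis=0) - e_mean * o.mean(axis=0))
            new_params = trial.parameters - learning_rate * grad
            if not np.all(np.isfinite(new_params)):
                break
            trial = trial.with_parameters(new_params)
    # final checkpoint with a fresh energy evaluation
    el, _ = local_energies_safe(trial, system, x, rng)
    if np.all(np.isfinite(el)):
        traj.append(OptimizationStep(n_iters, trial.parameters.copy(),
                                     EnergyEstimate(float(el.mean()),
                                                    float(el.std(ddof=1) / np.sqrt(len(el))),
                                                    len(el))))
    return traj
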