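"""Importance-sampled fixed-node diffusion Monte Carlo.

One DMC iteration advances every walker by a drift-diffusion move

    x' = x + v_bar(x) tau + chi sqrt(tau),   chi ~ N(0, 1) per coordinate,

where v_bar is the drift velocity grad log|psi_T| limited per electron to
curb time-step error (Umrigar-style smooth limiting).  A proposed move that
changes the sign of psi_T is rejected unconditionally — walkers never cross
the fixed nodal surface.  Surviving proposals go through a Metropolis
accept/reject with the importance-sampled Green's-function ratio

    min(1, psi(x')^2 G(x' -> x) / [ psi(x)^2 G(x -> x') ]),

and the effective time step tau_eff = tau * <accepted |dx|^2> / <proposed
|dx|^2> compensates the rejections.  Walker weights evolve as

    w <- w exp( -tau_eff ( (E_L(x') + E_L(x))/2 - E_T ) ),

with local energies clipped to a window E_best +/- clip_alpha/sqrt(tau)
around the running energy estimate (the clipping keeps rare local-energy
spikes from destabilizing the weights while vanishing as tau -> 0, which
also preserves size consistency for well-separated fragments).

Population control keeps the per-process walker count exactly constant:
whenever a walker's weight exceeds ``branch_threshold`` it splits into two
half-weight copies, and in the same move the two lightest walkers merge
into one, positioned at either parent with probability proportional to
weight and carrying their summed weight.  No merging happens without a
branch.  Total weight is conserved exactly and the expected weighted
density is unchanged.  The trial energy E_T is steered by logarithmic
feedback on the total weight, E_T = E_best - log(W / W_target) / t_damp.

The production energy is the mixed estimator <psi_T|H|phi>/<psi_T|phi>:
the weighted mean local energy over the post-equilibration steps (the
first 10% of steps are discarded), with a reblocked standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from fndmc.stats import EnergyEstimate, reblock
from fndmc.systems import MolecularSystem
from fndmc.vmc import VMCParams, metropolis_sample, _valid_start


@dataclass(frozen=True)
class DMCParams:
    """Run parameters for the fixed-node DMC engine.

    tau : imaginary-time step, inverse Hartree.
    target_weight : population-control setpoint; defaults to n_walkers.
    et_damping : feedback time constant of the trial-energy update,
        inverse Hartree; defaults to 10 * tau.
    branch_threshold : weight above which a walker splits (> 1).
    merge_threshold : interface completeness only — the constant-population
        strategy always merges the two lightest walkers when a branch
        occurs, so no separate merge trigger is consulted.
    clip_alpha : local-energy clipping constant; the clip window is
        E_best +/- clip_alpha / sqrt(tau).  Defaults to
        0.2 * sqrt(n_electrons).
    """

    tau: float = 0.01
    n_steps: int = 2000
    n_walkers: int = 500
    target_weight: float = None
    et_damping: float = None
    branch_threshold: float = 2.0
    merge_threshold: float = 0.5
    clip_alpha: float = None
    seed: int = 0
    equilibration_fraction: float = 0.1

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not (self.branch_threshold > 1 > self.merge_threshold > 0):
            raise ValueError("require branch_threshold > 1 > merge_threshold > 0")
        if self.n_walkers < 3:
            raise ValueError("need at least 3 walkers for branch-merge")

    def resolved(self, system: MolecularSystem) -> "DMCParams":
        return replace(
            self,
            target_weight=self.target_weight or float(self.n_walkers),
            et_damping=self.et_damping or 10.0 * self.tau,
            clip_alpha=self.clip_alpha or 0.2 * np.sqrt(system.n_electrons),
        )


@dataclass
class WalkerEnsemble:
    """Fixed-size walker population with cached trial-wavefunction data."""

    configurations: np.ndarray   # (N, n, d)
    weights: np.ndarray          # (N,)
    signs: np.ndarray            # (N,)
    log_magnitudes: np.ndarray   # (N,)
    local_energies: np.ndarray   # (N,)

    @property
    def size(self) -> int:
        return len(self.weights)

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def copy(self) -> "WalkerEnsemble":
        return WalkerEnsemble(*(a.copy() for a in (
            self.configurations, self.weights, self.signs,
            self.log_magnitudes, self.local_energies)))


@dataclass
class DMCState:
    ensemble: WalkerEnsemble
    e_trial: float
    e_best: float
    tau_effective: float
    iteration: int
    energy_series: list = field(default_factory=list)
    weight_series: list = field(default_factory=list)
    et_series: list = field(default_factory=list)
    acceptance_series: list = field(default_factory=list)
    taueff_series: list = field(default_factory=list)
    rng: np.random.Generator = None
    branch_count: int = 0
    clip_count: int = 0
    sample_count: int = 0
    resample_count: int = 0


@dataclass
class DMCResult:
    energy: EnergyEstimate
    state: DMCState
    diagnostics: dict


def limited_drift(trial, x: np.ndarray, tau: float) -> np.ndarray:
    """Drift velocity grad log|psi_T| with per-electron smooth limiting:

        v_bar = v * (-1 + sqrt(1 + 2 |v|^2 tau)) / (|v|^2 tau).

    The limiter leaves small drifts untouched (v_bar -> v as |v|^2 tau -> 0)
    and caps large ones at |v_bar| ~ sqrt(2/tau), which removes the
    divergence of the drift near the nodal surface and reduces time-step
    error.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    v = trial.grad_log(x)
    v2 = (v**2).sum(axis=-1, keepdims=True)
    a = v2 * tau
    with np.errstate(invalid="ignore", divide="ignore"):
        factor = np.where(a > 1e-8, (-1.0 + np.sqrt(1.0 + 2.0 * a)) / np.maximum(a, 1e-300),
                          1.0 - 0.5 * a)
    return v * factor


def greens_log_ratio(trial, x, xp, tau, logm=None, v=None, logm_p=None, vp=None):
    """Log of the importance-sampled Green's-function Metropolis ratio

        log [ psi(x')^2 G(x' -> x) ] - log [ psi(x)^2 G(x -> x') ],

    with G(a -> b) the drift-diffusion Gaussian exp(-|b - a - v_bar(a) tau|^2
    / (2 tau)) (normalization cancels).  Cached log-magnitudes and limited
    drifts may be passed to avoid re-evaluation; batched over walkers.
    """
    if logm is None:
        _, logm = trial.sign_log(x)
    if logm_p is None:
        _, logm_p = trial.sign_log(xp)
    if v is None:
        v = limited_drift(trial, x, tau)
    if vp is None:
        vp = limited_drift(trial, xp, tau)
    log_g_fwd = -((xp - x - v * tau) ** 2).sum(axis=(-1, -2)) / (2 * tau)
    log_g_rev = -((x - xp - vp * tau) ** 2).sum(axis=(-1, -2)) / (2 * tau)
    with np.errstate(invalid="ignore"):
        ratio = 2.0 * (logm_p - logm) + log_g_rev - log_g_fwd
    return np.where(np.isfinite(ratio), ratio, -np.inf)


def _clip(el: np.ndarray, e_best: float, half_width: float):
    clipped = np.clip(el, e_best - half_width, e_best + half_width)
    return clipped, int(np.sum(clipped != el))


def _ensemble_from_configs(trial, system, x, rng) -> WalkerEnsemble:
    from fndmc.vmc import local_energies_safe

    sign, logm = trial.sign_log(x)
    el, _ = local_energies_safe(trial, system, x, rng)
    return WalkerEnsemble(x, np.ones(len(x)), sign, logm, el)


def branch_merge(ensemble: WalkerEnsemble, rng: np.random.Generator,
                 params: DMCParams) -> tuple[WalkerEnsemble, int]:
    """Constant-population branch-merge.

    Every walker whose weight exceeds ``branch_threshold`` splits into two
    half-weight copies; each split is paired with a merge of the two
    currently lightest walkers into one, located at either parent with
    probability proportional to its weight and carrying the summed weight.
    The population size never changes and total weight is conserved
    exactly.  Returns the updated ensemble and the number of branch events.
    If no branching happens, no merging is executed and the ensemble is
    returned unchanged.
    """
    w = ensemble.weights
    if not np.any(w > params.branch_threshold):
        return ensemble, 0
    ens = ensemble.copy()
    w = ens.weights
    n_branch = 0
    # a merged pair can itself exceed the threshold, so cap the sweep to
    # guarantee termination; leftover overweight walkers are picked up on
    # the next iteration of the driving loop
    max_events = 10 * ens.size
    while n_branch < max_events:
        i = int(np.argmax(w))
        if w[i] <= params.branch_threshold:
            break
        if ens.size < 3:
            raise ValueError("cannot branch-merge with fewer than 3 walkers")
        order = np.argsort(w)
        small = [int(j) for j in order if j != i][:2]
        j, k = small
        # merge j and k into the slot of the chosen survivor
        total = w[j] + w[k]
        survivor = j if rng.random() < w[j] / total else k
        victim = k if survivor == j else j
        for arr in (ens.configurations, ens.signs, ens.log_magnitudes,
                    ens.local_energies):
            arr[victim] = arr[i]
            # survivor keeps its own configuration
        w[survivor] = total
        w[victim] = w[i] / 2.0
        w[i] = w[i] / 2.0
        n_branch += 1
    return ens, n_branch


def update_trial_energy(state: DMCState, params: DMCParams) -> float:
    """Logarithmic population feedback:

        E_T = E_best - log(W / W_target) / et_damping.

    Negative feedback in the total weight W: an overweight population
    lowers E_T, damping weight growth, and vice versa.
    """
    w_tot = state.ensemble.total_weight
    if w_tot <= 0:
        raise ValueError("total weight must be positive")
    return state.e_best - np.log(w_tot / params.target_weight) / params.et_damping


def _running_best(state: DMCState, window: int = 100) -> float:
    if not state.energy_series:
        return state.e_best
    tail = state.energy_series[-window:]
    return float(np.mean(tail))


def dmc_step(trial, system: MolecularSystem, state: DMCState,
             params: DMCParams) -> DMCState:
    """Advance the DMC state by one iteration (diffuse, weight, branch-merge,
    trial-energy update).  See the module docstring for the exact rules."""
    ens = state.ensemble
    rng = state.rng
    tau = params.tau
    x = ens.configurations
    v = limited_drift(trial, x, tau)
    chi = rng.normal(size=x.shape)
    xp = x + v * tau + chi * np.sqrt(tau)
    sign_p, logm_p = trial.sign_log(xp)

    crossed = sign_p != ens.signs
    log_ratio = greens_log_ratio(trial, x, xp, tau,
                                 logm=ens.log_magnitudes, v=v, logm_p=logm_p)
    accept = (~crossed) & (np.log(rng.random(ens.size)) < log_ratio)

    dx2 = ((xp - x) ** 2).sum(axis=(-1, -2))
    denom = float(dx2.sum())
    tau_eff = tau * float(dx2[accept].sum()) / denom if denom > 0 else tau
    tau_eff = min(max(tau_eff, 1e-12), tau)

    new_x = np.where(accept[:, None, None], xp, x)
    new_sign = np.where(accept, sign_p, ens.signs)
    new_logm = np.where(accept, logm_p, ens.log_magnitudes)

    from fndmc.vmc import local_energies_safe

    new_el = ens.local_energies.copy()
    if accept.any():
        moved = new_x[accept]
        el_moved, n_rep = local_energies_safe(trial, system, moved, rng)
        bad = ~np.isfinite(el_moved)
        if bad.any():
            # irrecoverable local energy: clone a healthy walker in place
            healthy = np.flatnonzero(np.isfinite(ens.local_energies))
            pick = rng.choice(healthy, size=int(bad.sum()))
            moved[bad] = ens.configurations[pick]
            el_moved[bad] = ens.local_energies[pick]
            state.resample_count += int(bad.sum())
        new_x[accept] = moved
        state.resample_count += n_rep
        new_el[accept] = el_moved

    half_width = params.clip_alpha / np.sqrt(tau)
    el_new_clip, c1 = _clip(new_el, state.e_best, half_width)
    el_old_clip, _ = _clip(ens.local_energies, state.e_best, half_width)
    state.clip_count += c1
    state.sample_count += ens.size

    new_w = ens.weights * np.exp(-tau_eff * (0.5 * (el_new_clip + el_old_clip)
                                             - state.e_trial))
    new_ens = WalkerEnsemble(new_x, new_w, new_sign, new_logm, new_el)
    e_mixed = float((new_w * el_new_clip).sum() / new_w.sum())

    state.ensemble = new_ens
    state.energy_series.append(e_mixed)
    state.e_best = _running_best(state)
    new_ens2, n_branch = branch_merge(new_ens, rng, params)
    state.ensemble = new_ens2
    state.branch_count += n_branch
    state.e_trial = float(update_trial_energy(state, params))
    state.tau_effective = tau_eff
    state.iteration += 1
    state.weight_series.append(new_ens2.total_weight)
    state.et_series.append(state.e_trial)
    state.acceptance_series.append(float(accept.mean()))
    state.taueff_series.append(tau_eff)
    return state


def init_dmc_state(trial, system: MolecularSystem, params: DMCParams,
                   initial: np.ndarray = None, vmc_equilibration: int = 300):
    """Build the initial DMC state.

    Walkers start from a short Metropolis equilibration of psi_T^2 (from
    the Gaussian-around-nuclei initialization) unless ``initial`` is given.
    E_T and E_best start at the initial ensemble's mean local energy.
    """
    params = params.resolved(system)
    rng = np.random.default_rng(params.seed)
    if initial is None:
        if vmc_equilibration > 0:
            vp = VMCParams(n_walkers=params.n_walkers, n_steps=vmc_equilibration,
                           step_size=0.4, seed=int(rng.integers(2**31 - 1)))
            initial, _ = metropolis_sample(trial, system, vp, return_all=False)
        else:
            initial = _valid_start(trial, system, params.n_walkers, rng)
    ens = _ensemble_from_configs(trial, system, np.array(initial, float), rng)
    e0 = float(ens.local_energies.mean())
    return DMCState(ensemble=ens, e_trial=e0, e_best=e0, tau_effective=params.tau,
                    iteration=0, rng=rng)


def run_dmc(trial, system: MolecularSystem, params: DMCParams,
            initial: np.ndarray = None, state: DMCState = None) -> DMCResult:
    """Run fixed-node DMC and return the production-phase mixed estimator.

    The first ``equilibration_fraction`` (default 10%) of steps are treated
    as equilibration and discarded; the production energy is the
    total-weight-weighted mean of the per-step mixed estimator with a
    reblocked standard error.  Pass ``state`` to resume a checkpointed run.
    """
    rparams = params.resolved(system)
    if state is None:
        state = init_dmc_state(trial, system, rparams, initial=initial)
    n_remaining = rparams.n_steps - state.iteration
    for _ in range(n_remaining):
        state = dmc_step(trial, system, state, rparams)

    n_equil = int(rparams.equilibration_fraction * rparams.n_steps)
    energies = np.asarray(state.energy_series[n_equil:])
    weights = np.asarray(state.weight_series[n_equil:])
    mean = float((energies * weights).sum() / weights.sum())
    if len(energies) >= 8:
        est = reblock(energies)
        est.mean = mean  # weight-averaged production mean
    else:
        est = EnergyEstimate(mean, float(energies.std(ddof=1) / np.sqrt(len(energies)))
                             if len(energies) > 1 else 0.0, len(energies))
    diagnostics = {
        "acceptance": float(np.mean(state.acceptance_series)),
        "tau_eff_ratio": float(np.mean(state.taueff_series)) / rparams.tau,
        "branch_count": state.branch_count,
        "clip_fraction": state.clip_count / max(state.sample_count, 1),
        "resample_count": state.resample_count,
        "n_equilibration_steps": n_equil,
        "final_total_weight": state.ensemble.total_weight,
        "e_trial_final": state.e_trial,
    }
    return DMCResult(energy=est, state=state, diagnostics=diagnostics)


def tau_extrapolated_energy(trial, system: MolecularSystem,
                            taus=(0.02, 0.01, 0.005), base_params: DMCParams = None,
                            steps_at_tau=None) -> dict:
    """Linear tau -> 0 extrapolation of the DMC energy over several time
    steps.  Returns dict with per-tau estimates and the extrapolated
    intercept with its fit standard error."""
    base = base_params or DMCParams()
    results = []
    for i, tau in enumerate(taus):
        n_steps = steps_at_tau[i] if steps_at_tau else base.n_steps
        p = replace(base, tau=tau, n_steps=n_steps, seed=base.seed + i)
        results.append(run_dmc(trial, system, p))
    t = np.asarray(taus, dtype=float)
    e = np.array([r.energy.mean for r in results])
    err = np.array([max(r.energy.stderr, 1e-12) for r in results])
    wts = 1.0 / err**2
    W = wts.sum()
    tb, eb = (wts * t).sum() / W, (wts * e).sum() / W
    slope = (wts * (t - tb) * (e - eb)).sum() / (wts * (t - tb) ** 2).sum()
    intercept = eb - slope * tb
    var_int = (1.0 / W) + tb**2 / (wts * (t - tb) ** 2).sum()
    return {
        "taus": t,
        "energies": e,
        "stderrs": err,
        "extrapolated": float(intercept),
        "extrapolated_stderr": float(np.sqrt(var_int)),
        "slope": float(slope),
        "results": results,
    }
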