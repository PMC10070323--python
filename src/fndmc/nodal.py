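"""Nodal-surface geometry: distances to the node, node sampling, the nodal
divergence, and wavefunction visualization grids.

The nodal surface S of a trial wavefunction is its zero set in the n*d
dimensional configuration space.  The divergence between two nodal
surfaces is the expected distance from psi^2-weighted samples on the first
surface to the second,

    D(S1, S2) = E_{Y ~ P1} d(Y, S2),

estimated by a sample mean over K points Y_i drawn from the psi_1^2
measure concentrated onto S1.  D is non-negative, vanishes when the
surfaces coincide, and is not symmetric in its arguments (a divergence,
not a metric).

Sampling P1 works by restricting a Metropolis psi^2 chain to the thin
shell {x : d_hat(x, S) < epsilon}, with d_hat the cheap first-order
distance estimate |psi| / |grad psi| = 1 / |grad log|psi||, and then
projecting every retained sample onto S by the witness of the distance
refinement (the closest node point found).  The shell membership test is
an approximation of the exact shell; its bias is controlled in the tests
by comparison against dense grid oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class NodalDivergenceParams:
    epsilon: float = 0.1          # shell half-width, bohr
    K: int = 4096                 # sample count on the node
    projection_tol: float = 1e-3  # node-projection tolerance, bohr
    max_line_search: int = 60     # bracketing steps in the distance search
    step_size: float = 0.3        # Metropolis proposal std inside the shell
    thin: int = 5                 # chain steps between retained samples
    seed: int = 0

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.projection_tol >= self.epsilon:
            raise ValueError("projection_tol must be smaller than epsilon")


def _first_order_distance(trial, x):
    """d_hat = 1 / |grad log|psi||, batched over leading axes."""
    g = trial.grad_log(x)
    gn = np.sqrt((g**2).sum(axis=(-1, -2)))
    return 1.0 / np.maximum(gn, 1e-300)


def distance_to_node(trial, point, tol: float = 1e-4,
                     max_line_search: int = 60):
    """Distance from a configuration to the trial's nodal surface.

    Starts from the first-order estimate |psi|/|grad psi| at the point,
    brackets a sign change by a line search along the direction of
    steepest descent of |psi| (both orientations are tried), bisects to
    ``tol``, then polishes the witness by sliding it along the node
    towards the query point.  Returns ``(distance, witness)``; the
    distance is an upper bound on the true d(Y, S) up to ``tol``.  When no
    sign change is found within the search range the sentinel
    ``(inf, None)`` is returned.

    Raises ValueError if psi(point) == 0 (the point is already on S).
    """
    y = np.asarray(point, dtype=float)
    s0, l0 = trial.sign_log(y)
    s0 = float(s0)
    if not np.isfinite(l0):
        raise ValueError("psi vanishes at the query point")
    g = trial.grad_log(y)
    gn = np.sqrt((g**2).sum())
    d0 = 1.0 / max(gn, 1e-300)
    u = -g / max(gn, 1e-300)  # steepest descent of log|psi|

    def sign_at(t, direction):
        s, _ = trial.sign_log(y + t * direction)
        return float(s)

    bracket = None
    for direction in (u, -u):
        t = 0.5 * d0
        t_prev = 0.0
        for _ in range(max_line_search):
            if sign_at(t, direction) != s0:
                bracket = (t_prev, t, direction)
                break
            t_prev = t
            t *= 1.6
        if bracket:
            break
    if bracket is None:
        return np.inf, None
    lo, hi, direction = bracket
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if sign_at(mid, direction) == s0:
            lo = mid
        else:
            hi = mid
    z = y + 0.5 * (lo + hi) * direction

    # polish: slide the witness along the node towards y
    best = float(np.linalg.norm((y - z).ravel()))
    for _ in range(20):
        gz = trial.grad_log(z)
        gzn = np.sqrt((gz**2).sum())
        if gzn < 1e-300:
            break
        nu = gz / gzn
        delta = y - z
        tangential = delta - (delta * nu).sum() * nu
        z_try = z + 0.5 * tangential
        # re-land on the node by bisecting the segment y -> z_try
        z_new = _bisect_to_node(trial, y, z_try, s0, tol, max_steps=40)
        if z_new is None:
            break
        dist = float(np.linalg.norm((y - z_new).ravel()))
        if dist < best - 0.1 * tol:
            best, z = dist, z_new
        else:
            break
    return best, z


def _bisect_to_node(trial, y, z_outside, s0, tol, max_steps=40):
    """Find the sign change on the segment from y (sign s0) towards
    z_outside; returns the node point or None if no sign change."""
    s_out, _ = trial.sign_log(z_outside)
    direction = z_outside - y
    if float(s_out) == s0:
        # march past z_outside until the sign flips
        t = 1.0
        found = False
        for _ in range(20):
            t *= 1.3
            s_t, _ = trial.sign_log(y + t * direction)
            if float(s_t) != s0:
                found = True
                break
        if not found:
            return None
        lo, hi = t / 1.3, t
    else:
        lo, hi = 0.0, 1.0
    norm = float(np.linalg.norm(direction.ravel()))
    if norm < 1e-300:
        return None
    while (hi - lo) * norm > tol:
        mid = 0.5 * (lo + hi)
        s_m, _ = trial.sign_log(y + mid * direction)
        if float(s_m) == s0:
            lo = mid
        else:
            hi = mid
    return y + 0.5 * (lo + hi) * direction


def sample_node_points(trial, system, params: NodalDivergenceParams, rng=None):
    """Draw K psi^2-weighted samples concentrated on the nodal surface.

    Runs a Metropolis chain targeting psi^2 restricted to the shell
    {x : d_hat(x, S) < epsilon} (first-order distance estimate), then maps
    every retained sample to the node through the distance-refinement
    witness.  Returns an array (K, n_electrons, dim) of node points.

    Raises ValueError for nodeless trials and RuntimeError when the shell
    is never entered within the step budget (try a larger epsilon).
    """
    if getattr(trial, "nodeless", False):
        raise ValueError("trial is nodeless: it has no nodal surface to sample")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(
        params.seed if rng is None else rng)
    n, d = system.n_electrons, system.dim

    # find a starting point inside the shell: walk random configs to the node
    x = None
    for _ in range(200):
        cand = rng.normal(scale=1.0, size=(n, d))
        s, l = trial.sign_log(cand)
        if not np.isfinite(l):
            continue
        dist, witness = distance_to_node(trial, cand, tol=params.projection_tol,
                                         max_line_search=params.max_line_search)
        if witness is None:
            continue
        # step off the node to a point strictly inside the shell
        probe = witness + rng.normal(scale=0.3 * params.epsilon, size=(n, d))
        if (_first_order_distance(trial, probe) < params.epsilon
                and np.isfinite(trial.sign_log(probe)[1])):
            x = probe
            break
    if x is None:
        raise RuntimeError("could not enter the nodal shell; increase epsilon")

    _, logm = trial.sign_log(x)
    samples = []
    budget = 200 * params.K * params.thin
    steps = 0
    while len(samples) < params.K and steps < budget:
        for _ in range(params.thin):
            steps += 1
            prop = x + rng.normal(scale=params.step_size, size=(n, d))
            _, logp = trial.sign_log(prop)
            if not np.isfinite(logp):
                continue
            if _first_order_distance(trial, prop) >= params.epsilon:
                continue
            if np.log(rng.random()) < 2.0 * (logp - logm):
                x, logm = prop, logp
        dist, witness = distance_to_node(trial, x, tol=params.projection_tol,
                                         max_line_search=params.max_line_search)
        if witness is not None and np.isfinite(dist):
            samples.append(witness)
    if len(samples) < params.K:
        raise RuntimeError("node sampling exhausted its step budget; "
                           "increase epsilon or the budget")
    return np.asarray(samples)


def nodal_divergence(trial1, trial2, params: NodalDivergenceParams,
                     rng=None, system=None) -> dict:
    """D(S1, S2): mean distance from psi_1^2-weighted node samples of
    trial1 to the nodal surface of trial2.

    Returns dict with ``divergence`` (bohr), ``stderr`` (Monte Carlo),
    ``distances`` (per-sample), and ``n_infinite`` (samples for which no
    node of trial2 was found in range; excluded from the mean).
    """
    if system is None:
        system = getattr(trial1, "system", None)
    if system is None:
        raise ValueError("pass the molecular system explicitly")
    ys = sample_node_points(trial1, system, params, rng=rng)
    dists = []
    n_inf = 0
    for y in ys:
        s, l = trial2.sign_log(y)
        if not np.isfinite(l):
            dists.append(0.0)  # y happens to lie on S2
            continue
        dist, _ = distance_to_node(trial2, y, tol=params.projection_tol,
                                   max_line_search=params.max_line_search)
        if np.isfinite(dist):
            dists.append(dist)
        else:
            n_inf += 1
    dists = np.asarray(dists)
    if len(dists) == 0:
        raise RuntimeError("no finite distances: the surfaces never met the search range")
    return {
        "divergence": float(dists.mean()),
        "stderr": float(dists.std(ddof=1) / np.sqrt(len(dists))) if len(dists) > 1 else 0.0,
        "distances": dists,
        "n_infinite": n_inf,
    }


def wavefunction_slice(trial, base_config, moving_electron: int,
                       axes=(0, 1), center=None, extent: float = 5.0,
                       resolution: int = 101) -> dict:
    """Evaluate psi_T on a 2-D slice of configuration space.

    One electron moves over a square grid [-extent, extent]^2 (default
    [-5, 5] a.u.) spanned by two coordinate ``axes`` of its position, all
    other electrons held fixed at ``base_config``.  Returns dict with the
    grid coordinates, log-magnitudes, the sign mask, and a boolean
    ``node_mask`` marking pixels adjacent to a sign change.
    """
    base = np.asarray(base_config, dtype=float)
    n, d = base.shape
    if not (0 <= moving_electron < n):
        raise ValueError("moving_electron out of range")
    c = np.asarray(center, dtype=float) if center is not None else base[moving_electron]
    u = np.linspace(-extent, extent, resolution)
    v = np.linspace(-extent, extent, resolution)
    U, V = np.meshgrid(u, v, indexing="ij")
    configs = np.broadcast_to(base, (resolution, resolution, n, d)).copy()
    pos = np.broadcast_to(c, (resolution, resolution, d)).copy()
    pos[..., axes[0]] = U
    pos[..., axes[1]] = V
    configs[..., moving_electron, :] = pos
    sign, logm = trial.sign_log(configs)
    node = np.zeros_like(sign, dtype=bool)
    node[:-1, :] |= sign[:-1, :] != sign[1:, :]
    node[:, :-1] |= sign[:, :-1] != sign[:, 1:]
    return {"u": u, "v": v, "log_magnitude": logm, "sign": sign,
            "node_mask": node}


def be_nodal_cut(trial, resolution: int = 41) -> dict:
    """Three-dimensional cut of a 4-electron atomic nodal surface.

    Scans r1 in [0.1, 2.1] bohr, cos(theta1) in [-1, 1] and r3 in
    [0.1, 2.1] bohr while the remaining spherical coordinates are pinned:
    r2 = r4 = 1.1, phi1 = phi2 = 0, theta2 = theta3 = theta4 = pi/2,
    phi3 = pi/2, phi4 = 3 pi/2.  Returns the scalar field (sign and
    log-magnitude) over the grid plus a boolean mask of grid cells where
    the sign changes along any axis (the zero-level set by sign-change
    marching).
    """
    sys_n = getattr(getattr(trial, "system", None), "n_electrons", None)
    if sys_n is not None and sys_n != 4:
        raise ValueError("the cut is defined for 4-electron atoms")
    r1 = np.linspace(0.1, 2.1, resolution)
    ct1 = np.linspace(-1.0, 1.0, resolution)
    r3 = np.linspace(0.1, 2.1, resolution)
    R1, C1, R3 = np.meshgrid(r1, ct1, r3, indexing="ij")
    st1 = np.sqrt(np.maximum(1.0 - C1**2, 0.0))
    shape = R1.shape
    conf = np.zeros(shape + (4, 3))
    # spherical convention: x = r sin(t) cos(p), y = r sin(t) sin(p), z = r cos(t)
    conf[..., 0, 0] = R1 * st1          # phi1 = 0
    conf[..., 0, 2] = R1 * C1
    conf[..., 1, 0] = 1.1               # theta2 = pi/2, phi2 = 0
    conf[..., 2, 1] = R3                # theta3 = pi/2, phi3 = pi/2
    conf[..., 3, 1] = -1.1              # theta4 = pi/2, phi4 = 3 pi/2
    sign, logm = trial.sign_log(conf)
    node = np.zeros(shape, dtype=bool)
    node[:-1, :, :] |= sign[:-1, :, :] != sign[1:, :, :]
    node[:, :-1, :] |= sign[:, :-1, :] != sign[:, 1:, :]
    node[:, :, :-1] |= sign[:, :, :-1] != sign[:, :, 1:]
    return {"r1": r1, "cos_theta1": ct1, "r3": r3, "sign": sign,
            "log_magnitude": logm, "node_mask": node,
            "configurations": conf}
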