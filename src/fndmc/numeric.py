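"""Finite-difference cross-checks for trial-wavefunction derivatives.

These helpers differentiate ``log|psi|`` by central differences and are used
both by the construction-time self-check of every trial and by the test
suite as an independent oracle for analytic gradients, Laplacians and local
energies.  They are deliberately simple and make no use of the analytic
derivative code paths.
"""

from __future__ import annotations

import numpy as np


def fd_grad_log(trial, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central-difference gradient of log|psi|, shape like ``x``.

    Raises if the sign of psi changes inside any stencil (the derivative of
    log|psi| is undefined across a node at finite h).
    """
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    s0, _ = trial.sign_log(x)
    it = np.nditer(np.zeros(x.shape[-2:]), flags=["multi_index"])
    for _ in it:
        i, c = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[..., i, c] += h
        xm[..., i, c] -= h
        sp, lp = trial.sign_log(xp)
        sm, lm = trial.sign_log(xm)
        if np.any(sp != s0) or np.any(sm != s0):
            raise ValueError("finite-difference stencil straddles a node")
        g[..., i, c] = (lp - lm) / (2 * h)
    return g


def fd_lap_log(trial, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central-difference per-electron Laplacian of log|psi|, shape (..., n)."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-2]
    lap = np.zeros(x.shape[:-1])
    s0, l0 = trial.sign_log(x)
    for i in range(n):
        for c in range(x.shape[-1]):
            xp, xm = x.copy(), x.copy()
            xp[..., i, c] += h
            xm[..., i, c] -= h
            sp, lp = trial.sign_log(xp)
            sm, lm = trial.sign_log(xm)
            if np.any(sp != s0) or np.any(sm != s0):
                raise ValueError("finite-difference stencil straddles a node")
            lap[..., i] += (lp + lm - 2 * l0) / h**2
    return lap


def fd_local_energy(trial, system, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Local energy with all derivatives taken by finite differences.

    E_L = -1/2 sum_i [lap_i log|psi| + |grad_i log|psi||^2] + V.
    Independent oracle for :func:`fndmc.trials.local_energy`.
    """
    from fndmc.trials import potential_energy

    g = fd_grad_log(trial, x, h=min(h, 1e-5))
    lap = fd_lap_log(trial, x, h=h)
    kin = -0.5 * (lap.sum(axis=-1) + (g**2).sum(axis=(-1, -2)))
    return kin + potential_energy(system, x)
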