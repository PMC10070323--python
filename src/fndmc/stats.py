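"""Reblocking error analysis and the VMC-DMC linear extrapolation scheme.

Monte Carlo energy series are autocorrelated, so the naive standard error
of the mean underestimates the true uncertainty.  :func:`reblock` applies
Flyvbjerg-Petersen successive pairwise blocking: at each level neighbouring
points are averaged pairwise, and the standard-error estimate

    s_m = std(blocks, ddof=1) / sqrt(n_blocks)

grows with the level until the blocks decorrelate and it plateaus.  The
plateau value is the reported standard error.

The extrapolation scheme exploits an empirical linear relation between VMC
and DMC energies evaluated with the same trial wavefunction at successive
variational training steps k:

    E_DMC(k) - E_ex = w * (E_VMC(k) - E_DMC(k)) + b,

where E_ex is the extrapolated energy and w, b are fitted.  The slope w is
identifiable from the trajectory; the intercept b is not, so absolute
energies need b supplied externally.  For *relative* energies between two
systems the intercept is assumed shared and cancels:

    dE_ex = (1 + w) * dE_DMC - w * dE_VMC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EnergyEstimate:
    """Mean energy with a reblocked standard error.

    ``block_curve`` records the stderr estimate at every blocking level;
    ``plateau_index`` is the level the reported stderr was read from.
    """

    mean: float
    stderr: float
    n_samples: int
    block_curve: np.ndarray = field(default_factory=lambda: np.zeros(0))
    plateau_index: int = 0

    def __str__(self):
        return f"{self.mean:.6f} +/- {self.stderr:.6f} Ha (n={self.n_samples})"


@dataclass
class ExtrapolationFit:
    """OLS fit of (E_DMC(k) - E_final) against (E_VMC(k) - E_DMC(k))."""

    w: float
    b: float
    e_final: float
    residuals: np.ndarray
    r_squared: float
    w_stderr: float

    def extrapolate_absolute(self, intercept_b: float) -> float:
        """E_ex given an externally supplied intercept b (not identifiable
        from the trajectory itself)."""
        return self.e_final - intercept_b + self.b


def reblock(series, min_blocks: int = 2, plateau_rtol: float = 0.05) -> EnergyEstimate:
    """Flyvbjerg-Petersen reblocking of a (possibly autocorrelated) series.

    The mean is the exact arithmetic mean of the input (invariant under
    blocking).  The stderr is read at the first blocking level whose
    estimate changes by less than ``plateau_rtol`` over two successive
    levels, or at the last usable level when no plateau is found.

    Raises ValueError for series shorter than 8 points.
    """
    series = np.asarray(series, dtype=float).ravel()
    if len(series) < 8:
        raise ValueError(f"reblock needs at least 8 samples, got {len(series)}")
    mean = float(series.mean())
    curve = []
    blocks = series.copy()
    while len(blocks) >= min_blocks:
        curve.append(float(blocks.std(ddof=1) / np.sqrt(len(blocks))))
        if len(blocks) < 2 * min_blocks:
            break
        m = len(blocks) // 2
        blocks = 0.5 * (blocks[: 2 * m : 2] + blocks[1 : 2 * m : 2])
    curve = np.asarray(curve)
    plateau = len(curve) - 1
    for i in range(len(curve) - 2):
        if curve[i] == 0.0:
            plateau = i
            break
        d1 = abs(curve[i + 1] - curve[i]) / curve[i]
        d2 = abs(curve[i + 2] - curve[i + 1]) / max(curve[i + 1], 1e-300)
        if d1 < plateau_rtol and d2 < plateau_rtol:
            plateau = i
            break
    return EnergyEstimate(mean=mean, stderr=float(curve[plateau]),
                          n_samples=len(series), block_curve=curve,
                          plateau_index=int(plateau))


def _traj_arrays(traj):
    """Accept a list of (k, E_VMC, E_DMC) or (k, (E,err), (E,err)) records."""
    ks, ev, ed, ev_err, ed_err = [], [], [], [], []
    for rec in traj:
        k, v, d = rec[0], rec[1], rec[2]
        ks.append(float(k))
        if np.iterable(v):
            ev.append(float(v[0])); ev_err.append(float(v[1]))
        else:
            ev.append(float(v)); ev_err.append(0.0)
        if np.iterable(d):
            ed.append(float(d[0])); ed_err.append(float(d[1]))
        else:
            ed.append(float(d)); ed_err.append(0.0)
    ks = np.asarray(ks)
    if np.any(np.diff(ks) <= 0):
        raise ValueError("trajectory steps k must be strictly increasing")
    return ks, np.asarray(ev), np.asarray(ed), np.asarray(ev_err), np.asarray(ed_err)


def fit_linear_relation(traj, weighted: bool = False) -> ExtrapolationFit:
    """Fit the slope w of the VMC-DMC linear relation by ordinary least
    squares of y = E_DMC(k) - E_final on x = E_VMC(k) - E_DMC(k).

    ``traj`` is a sequence of (k, E_VMC, E_DMC) with energies either bare
    floats or (value, stderr) pairs.  E_final is the DMC energy at the last
    available step.  With ``weighted=True`` points are weighted by inverse
    DMC variance (requires stderrs).
    """
    ks, ev, ed, _, ed_err = _traj_arrays(traj)
    if len(ks) < 3:
        raise ValueError("need at least 3 trajectory points to fit the relation")
    e_final = ed[-1]
    x = ev - ed
    y = ed - e_final
    if np.ptp(x) < 1e-15:
        raise ValueError("degenerate predictor: all E_VMC - E_DMC equal")
    if weighted:
        if np.any(ed_err <= 0):
            raise ValueError("weighted fit requires positive DMC stderrs")
        wts = 1.0 / ed_err**2
    else:
        wts = np.ones_like(x)
    W = wts.sum()
    xb, yb = (wts * x).sum() / W, (wts * y).sum() / W
    sxx = (wts * (x - xb) ** 2).sum()
    sxy = (wts * (x - xb) * (y - yb)).sum()
    w = sxy / sxx
    b = yb - w * xb
    resid = y - (w * x + b)
    ss_tot = (wts * (y - yb) ** 2).sum()
    r2 = 1.0 - (wts * resid**2).sum() / ss_tot if ss_tot > 0 else 1.0
    dof = max(len(x) - 2, 1)
    sigma2 = (wts * resid**2).sum() / dof
    w_stderr = float(np.sqrt(sigma2 / sxx))
    return ExtrapolationFit(w=float(w), b=float(b), e_final=float(e_final),
                            residuals=resid, r_squared=float(r2), w_stderr=w_stderr)


def extrapolate_relative(dE_DMC: float, dE_VMC: float, w: float) -> float:
    """Relative-energy extrapolation dE_ex = (1 + w) dE_DMC - w dE_VMC."""
    return (1.0 + w) * dE_DMC - w * dE_VMC


def extrapolation_distribution(trajA, trajB, w: float = None) -> dict:
    """Per-training-step extrapolated energy differences between two systems.

    Both trajectories must share their set of steps k.  A pooled slope w is
    fitted (shared slope, separate intercepts — equivalent to OLS on the
    within-trajectory demeaned data) unless ``w`` is given.  For each shared
    k the relative-energy extrapolation is applied to dE(k) = E_A(k) -
    E_B(k); averaging the resulting set suppresses the linear-fitting error
    of any single step.

    Returns dict with keys ``k``, ``values``, ``mean``, ``std``, ``stderr``,
    ``w``.
    """
    kA, evA, edA, _, _ = _traj_arrays(trajA)
    kB, evB, edB, _, _ = _traj_arrays(trajB)
    if len(kA) != len(kB) or np.any(kA != kB):
        raise ValueError("trajectories must share a common set of steps k")
    if w is None:
        # pooled slope: demean x and y within each trajectory, stack, OLS
        xs, ys = [], []
        for ev, ed in ((evA, edA), (evB, edB)):
            x = ev - ed
            y = ed - ed[-1]
            xs.append(x - x.mean())
            ys.append(y - y.mean())
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        sxx = (x**2).sum()
        if sxx < 1e-30:
            raise ValueError("degenerate predictor in pooled slope fit")
        w = float((x * y).sum() / sxx)
    d_dmc = edA - edB
    d_vmc = evA - evB
    values = extrapolate_relative(d_dmc, d_vmc, w)
    return {
        "k": kA,
        "values": values,
        "mean": float(values.mean()),
        "std": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        "stderr": float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0,
        "w": float(w),
    }
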