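"""A small neural-network trial wavefunction.

The ansatz is a CPU-sized neural Slater-Jastrow: each one-electron orbital
is a two-layer tanh perceptron of the electron's nuclear displacement
features, multiplied by a sum of exponential envelopes that enforces decay,

    phi_k(r) = [ W_o tanh(W2 tanh(W1 f(r) + b1) + b2) + b_o ]_k
               * sum_A pi_kA exp(-zeta_kA |r - R_A|),

    f(r) = concat_A [ r - R_A, |r - R_A| ],

with one Slater determinant per spin channel and an electron-electron
Pade-Jastrow carrying the exact cusp coefficients (1/2 antiparallel, 1/4
parallel).  All coordinate derivatives (drift, Laplacian) are analytic,
propagated forward through the network; parameter gradients for the
variational optimizer are computed by reverse accumulation through the
determinants.

This exists to exercise the variational-training -> DMC workflow with a
trainable nodal surface, not to reach the accuracy of large neural
ansatzes: width and depth are deliberately tiny.
"""

from __future__ import annotations

import numpy as np

from fndmc.systems import MolecularSystem
from fndmc.trials import (TrialWavefunction, _PairJastrow, cusp_matrix,
                          _det_sign_log_grad_lap)


def _flatten(params: dict) -> np.ndarray:
    return np.concatenate([np.asarray(v).ravel() for v in params.values()])


def _unflatten(flat: np.ndarray, template: dict) -> dict:
    out, i = {}, 0
    for k, v in template.items():
        n = np.asarray(v).size
        out[k] = np.asarray(flat[i:i + n]).reshape(np.shape(v)).copy()
        i += n
    return out


class NeuralTrial(TrialWavefunction):
    """Two-layer neural orbitals in per-spin Slater determinants."""

    def __init__(self, system: MolecularSystem, hidden: int = 16, seed: int = 0,
                 params: dict = None, jastrow_beta: float = 0.5,
                 init_scale: float = 0.1):
        if system.potential != "coulomb":
            raise ValueError("neural trial is defined for Coulomb systems")
        self.system = system
        self.hidden = int(hidden)
        self.n_up, self.n_down = system.n_up, system.n_down
        self._cusp = cusp_matrix(system.n_up, system.n_down)
        m, d = system.n_nuclei, system.dim
        F = m * (d + 1)
        H = self.hidden
        if params is not None:
            self.params = {k: np.asarray(v, dtype=float) for k, v in params.items()}
        else:
            rng = np.random.default_rng(seed)
            self.params = {
                "W1": rng.normal(scale=init_scale, size=(H, F)),
                "b1": np.zeros(H),
                "W2": rng.normal(scale=init_scale, size=(H, H)),
                "b2": np.zeros(H),
                "beta": np.array([jastrow_beta]),
            }
            zmax = float(system.nuclear_charges.max())
            for tag, ns in (("u", self.n_up), ("d", self.n_down)):
                if ns == 0:
                    continue
                self.params[f"Wo_{tag}"] = rng.normal(scale=init_scale, size=(ns, H))
                self.params[f"bo_{tag}"] = np.ones(ns)
                # envelope exponents spread over shells: Z, Z/2, Z/3, ...
                zetas = np.array([[zmax / (1 + k // max(m, 1))
                                   for _ in range(m)] for k in range(ns)])
                self.params[f"zeta_{tag}"] = zetas * (1 + 0.05 * rng.normal(size=zetas.shape))
                self.params[f"pi_{tag}"] = np.ones((ns, m))
        self.nodeless = self.n_up <= 1 and self.n_down <= 1
        self.exact_node = False

    # -- parameter vector contract -----------------------------------------

    @property
    def parameters(self) -> np.ndarray:
        return _flatten(self.params)

    def with_parameters(self, flat) -> "NeuralTrial":
        new_params = _unflatten(np.asarray(flat, dtype=float), self.params)
        new_params["beta"] = np.maximum(new_params["beta"], 1e-3)
        for tag in ("u", "d"):
            key = f"zeta_{tag}"
            if key in new_params:
                new_params[key] = np.maximum(new_params[key], 0.1)
        return NeuralTrial(self.system, hidden=self.hidden, params=new_params)

    # -- forward pass with coordinate derivatives --------------------------

    def _features(self, x):
        """f (..., n, F), grad (..., n, F, d), lap (..., n, F)."""
        x = np.asarray(x, dtype=float)
        d = x.shape[-1]
        vals, grads, laps = [], [], []
        for A in range(self.system.n_nuclei):
            disp = x - self.system.nuclear_positions[A]
            r = np.maximum(np.linalg.norm(disp, axis=-1), 1e-300)
            rhat = disp / r[..., None]
            vals.append(np.concatenate([disp, r[..., None]], axis=-1))
            gd = np.broadcast_to(np.eye(d), disp.shape[:-1] + (d, d))
            grads.append(np.concatenate([gd, rhat[..., None, :]], axis=-2))
            laps.append(np.concatenate([np.zeros_like(disp),
                                        ((d - 1) / r)[..., None]], axis=-1))
        return (np.concatenate(vals, axis=-1), np.concatenate(grads, axis=-2),
                np.concatenate(laps, axis=-1))

    @staticmethod
    def _linear(W, b, a, ga, la):
        z = a @ W.T + b
        gz = np.einsum("hf,...fd->...hd", W, ga)
        lz = la @ W.T
        return z, gz, lz

    @staticmethod
    def _tanh(z, gz, lz):
        t = np.tanh(z)
        sech2 = 1.0 - t**2
        gt = sech2[..., None] * gz
        lt = sech2 * lz - 2.0 * t * sech2 * (gz**2).sum(axis=-1)
        return t, gt, lt

    def _orbitals(self, x, tag, record=None):
        """phi, grad, lap for the spin block 'u'/'d'; x is the block's
        coordinates (..., ns, d).  ``record`` collects intermediates for
        the parameter backward pass."""
        p = self.params
        f, gf, lf = self._features(x)
        z1, gz1, lz1 = self._linear(p["W1"], p["b1"], f, gf, lf)
        t1, gt1, lt1 = self._tanh(z1, gz1, lz1)
        z2, gz2, lz2 = self._linear(p["W2"], p["b2"], t1, gt1, lt1)
        t2, gt2, lt2 = self._tanh(z2, gz2, lz2)
        Wo, bo = p[f"Wo_{tag}"], p[f"bo_{tag}"]
        s, gs, ls = self._linear(Wo, bo, t2, gt2, lt2)
        # envelopes
        zeta, pi = p[f"zeta_{tag}"], p[f"pi_{tag}"]  # (K, m)
        d = x.shape[-1]
        env = 0.0
        genv = 0.0
        lenv = 0.0
        E_all = []
        for A in range(self.system.n_nuclei):
            disp = np.asarray(x, float) - self.system.nuclear_positions[A]
            r = np.maximum(np.linalg.norm(disp, axis=-1), 1e-300)
            rhat = disp / r[..., None]
            E = np.exp(-np.multiply.outer(r, zeta[:, A]))        # (..., n, K)
            E_all.append(E)
            zk = zeta[:, A]
            env = env + pi[:, A] * E
            genv = genv + (pi[:, A] * E * (-zk))[..., None] * rhat[..., None, :]
            lenv = lenv + pi[:, A] * E * (zk**2 - zk * (d - 1) / r[..., None])
        phi = s * env
        gphi = env[..., None] * gs + s[..., None] * genv
        lphi = env * ls + 2.0 * (gs * genv).sum(axis=-1) + s * lenv
        if record is not None:
            record.update(f=f, t1=t1, t2=t2, s=s, env=env, E_all=E_all, tag=tag)
        return phi, gphi, lphi

    def _evaluate(self, x, records=None):
        x = np.asarray(x, dtype=float)
        sign = np.ones(x.shape[:-2])
        log = np.zeros(x.shape[:-2])
        grad = np.zeros_like(x)
        lap = np.zeros(x.shape[:-1])
        blocks = ((0, self.n_up, "u"), (self.n_up, self.n_up + self.n_down, "d"))
        for lo, hi, tag in blocks:
            if hi == lo:
                continue
            rec = {} if records is not None else None
            phi, gphi, lphi = self._orbitals(x[..., lo:hi, :], tag, record=rec)
            s, l, g, lp = _det_sign_log_grad_lap(phi, gphi, lphi)
            sign = sign * s
            log = log + l
            grad[..., lo:hi, :] = g
            lap[..., lo:hi] = lp
            if records is not None:
                rec["phi"] = phi
                records[tag] = rec
        jb = float(self.params["beta"][0])
        if self.system.n_electrons > 1:
            J = _PairJastrow(self._cusp, jb)
            log = log + J.log(x)
            grad = grad + J.grad(x)
            lap = lap + J.lap(x)
        return sign, log, grad, lap

    def sign_log(self, x):
        sign, log, _, _ = self._evaluate(x)
        return sign, log

    def grad_log(self, x):
        return self._evaluate(x)[2]

    def lap_log(self, x):
        return self._evaluate(x)[3]

    # -- parameter gradients (reverse accumulation) ------------------------

    def param_grad_log(self, x):
        """d log|psi| / d theta, shape (..., P), P = len(self.parameters)."""
        x = np.asarray(x, dtype=float)
        batch = x.shape[:-2]
        grads = {k: np.zeros(batch + np.shape(v)) for k, v in self.params.items()}
        blocks = ((0, self.n_up, "u"), (self.n_up, self.n_up + self.n_down, "d"))
        p = self.params
        for lo, hi, tag in blocks:
            if hi == lo:
                continue
            rec: dict = {}
            phi, _, _ = self._orbitals(x[..., lo:hi, :], tag, record=rec)
            # cotangent of phi: d log|det A| / dA_ik = (A^-1)_ki
            Ainv = np.linalg.inv(phi)
            Cphi = np.swapaxes(Ainv, -1, -2)                     # (..., i, k)
            s, env, t2, t1, f = rec["s"], rec["env"], rec["t2"], rec["t1"], rec["f"]
            Cs = Cphi * env
            Cenv = Cphi * s
            Wo = p[f"Wo_{tag}"]
            grads[f"Wo_{tag}"] += np.einsum("...ik,...ih->...kh", Cs, t2)
            grads[f"bo_{tag}"] += Cs.sum(axis=-2)
            for A, E in enumerate(rec["E_all"]):
                zk = p[f"zeta_{tag}"][:, A]
                pik = p[f"pi_{tag}"][:, A]
                xb = x[..., lo:hi, :]
                r = np.maximum(np.linalg.norm(
                    xb - self.system.nuclear_positions[A], axis=-1), 1e-300)
                grads[f"pi_{tag}"][..., :, A] += (Cenv * E).sum(axis=-2)
                grads[f"zeta_{tag}"][..., :, A] += (
                    Cenv * E * pik * (-r[..., None])).sum(axis=-2)
            Ct2 = np.einsum("...ik,kh->...ih", Cs, Wo)
            Cz2 = Ct2 * (1.0 - t2**2)
            grads["W2"] += np.einsum("...ih,...ig->...hg", Cz2, t1)
            grads["b2"] += Cz2.sum(axis=-2)
            Ct1 = np.einsum("...ih,hg->...ig", Cz2, p["W2"])
            Cz1 = Ct1 * (1.0 - t1**2)
            grads["W1"] += np.einsum("...ih,...if->...hf", Cz1, f)
            grads["b1"] += Cz1.sum(axis=-2)
        if self.system.n_electrons > 1:
            J = _PairJastrow(self._cusp, float(p["beta"][0]))
            grads["beta"] += J.dbeta(x)[..., None]
        return np.concatenate([grads[k].reshape(batch + (-1,))
                               for k in self.params], axis=-1)
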