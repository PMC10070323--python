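"""Trial wavefunctions and the local-energy operator.

A trial wavefunction is an antisymmetric guiding function psi_T evaluated in
the log domain: every trial exposes

- ``sign_log(x)``  -> (sign in {-1, +1}, log|psi_T|),
- ``grad_log(x)``  -> per-electron gradients of log|psi_T|,
- ``lap_log(x)``   -> per-electron Laplacians of log|psi_T|,

for electron configurations ``x`` of shape ``(..., n, d)`` (arbitrary
leading batch axes).  Working with log-magnitudes keeps products of many
one- and two-body factors overflow-free, and all acceptance and Green's
function ratios downstream are formed from log differences.

The local energy at a configuration is

    E_L(x) = -1/2 sum_i [ lap_i log|psi| + |grad_i log|psi||^2 ] + V(x),

which is constant for exact eigenstates (zero-variance principle).

Built-in families
-----------------
hydrogenic          product of 1s exponentials exp(-zeta r_i), nodeless
gaussian            harmonic-trap Gaussian product, nodeless
he_pade             two-electron Pade-Jastrow exp(-Z(r1+r2) + r12/(2(1+b r12)))
product_1s          one 1s exponential per electron on its assigned nucleus
slater_jastrow      per-spin Slater determinants of Slater-type orbitals
                    times an electron-electron Pade-Jastrow with cusp
                    conditions built in
harmonic_fermions   (x1 - x2) exp(-(x1^2 + x2^2)/2): two same-spin 1-D
                    fermions, exact node and exact eigenstate (E = 2 at
                    omega = 1)
linear_node         (n . x - c) exp(-|x|^2/2): an arbitrary hyperplane node,
                    used as a geometric fixture
neural              small permutation-equivariant neural ansatz (see
                    :mod:`fndmc.neural`)
"""

from __future__ import annotations

import numpy as np

from fndmc.systems import MolecularSystem


class SingularConfigurationError(ValueError):
    """Two particles (electron-electron or electron-nucleus) coincide."""


class TrialConstructionError(ValueError):
    """A trial failed its construction-time contract self-check."""


# ---------------------------------------------------------------------------
# geometry helpers, batched over leading axes
# ---------------------------------------------------------------------------

def _en_displacements(x: np.ndarray, nuclei: np.ndarray):
    """(..., n, m, d) displacements and (..., n, m) distances to nuclei."""
    disp = x[..., :, None, :] - nuclei[None, :, :]
    return disp, np.linalg.norm(disp, axis=-1)


def _ee_distances(x: np.ndarray):
    """(..., n, n, d) displacements and (..., n, n) distances (diag 0)."""
    disp = x[..., :, None, :] - x[..., None, :, :]
    return disp, np.linalg.norm(disp, axis=-1)


def potential_energy(system: MolecularSystem, x: np.ndarray,
                     check_singular: bool = False) -> np.ndarray:
    """Potential part of the Hamiltonian at configurations ``x``, Hartree.

    Coulomb systems: nuclear attraction + electron repulsion + (constant)
    nuclear repulsion.  Harmonic systems: (omega^2 / 2) sum_i |r_i|^2.
    """
    x = np.asarray(x, dtype=float)
    n = system.n_electrons
    if system.potential == "harmonic":
        return 0.5 * system.omega**2 * (x**2).sum(axis=(-1, -2))
    _, r_en = _en_displacements(x, system.nuclear_positions)
    v = -(system.nuclear_charges / np.maximum(r_en, 1e-300)).sum(axis=(-1, -2))
    if n > 1:
        _, r_ee = _ee_distances(x)
        iu = np.triu_indices(n, k=1)
        pair = r_ee[..., iu[0], iu[1]]
        if check_singular and (np.any(pair < 1e-12) or np.any(r_en < 1e-12)):
            raise SingularConfigurationError("coincident particles")
        v = v + (1.0 / np.maximum(pair, 1e-300)).sum(axis=-1)
    elif check_singular and np.any(r_en < 1e-12):
        raise SingularConfigurationError("electron on a nucleus")
    return v + system.nuclear_repulsion()


def local_energy(trial, system: MolecularSystem, x: np.ndarray) -> np.ndarray:
    """E_L(x) = (H psi)/psi via log-domain derivatives; batched over walkers.

    Raises :class:`SingularConfigurationError` when any inter-particle
    distance is below 1e-12 bohr (the caller may resample the walker).
    """
    x = np.asarray(x, dtype=float)
    v = potential_energy(system, x, check_singular=True)
    g = trial.grad_log(x)
    lap = trial.lap_log(x)
    kin = -0.5 * (lap.sum(axis=-1) + (g**2).sum(axis=(-1, -2)))
    return kin + v


# ---------------------------------------------------------------------------
# the contract
# ---------------------------------------------------------------------------

class TrialWavefunction:
    """Behavioral contract shared by every trial wavefunction.

    Subclasses implement :meth:`sign_log`, :meth:`grad_log`, :meth:`lap_log`
    (batched), and optionally expose a flat real ``parameters`` vector with
    :meth:`with_parameters` and :meth:`param_grad_log` for the variational
    optimizer.

    Attributes
    ----------
    nodeless : True when psi_T > 0 everywhere (implies exact_node).
    exact_node : True when the zero set is analytically known.
    exact_energy : the eigenvalue when the trial is an exact eigenstate of
        its system's Hamiltonian, else None.
    """

    nodeless: bool = False
    exact_node: bool = False
    exact_energy: float | None = None

    def sign_log(self, x: np.ndarray):
        raise NotImplementedError

    def grad_log(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def lap_log(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def parameters(self) -> np.ndarray:
        return np.zeros(0)

    def with_parameters(self, params: np.ndarray) -> "TrialWavefunction":
        if len(np.asarray(params).ravel()) != 0:
            raise NotImplementedError(f"{type(self).__name__} has no free parameters")
        return self

    def param_grad_log(self, x: np.ndarray) -> np.ndarray:
        """d log|psi| / d theta, shape (..., n_params)."""
        raise NotImplementedError(f"{type(self).__name__} has no free parameters")

    # -- construction-time contract verification ---------------------------

    def self_check(self, system: MolecularSystem, seed: int = 1234,
                   n_points: int = 3, rtol: float = 1e-5) -> None:
        """Spot-check antisymmetry and derivative consistency.

        Raises :class:`TrialConstructionError` naming the violated invariant.
        Uses random configurations away from particle coincidences; points
        whose finite-difference stencil straddles a node are redrawn.
        """
        from fndmc.numeric import fd_grad_log, fd_lap_log

        rng = np.random.default_rng(seed)
        n, d = system.n_electrons, system.dim
        checked = 0
        attempts = 0
        while checked < n_points and attempts < 20 * n_points:
            attempts += 1
            x = rng.normal(scale=1.0, size=(n, d))
            s, l = self.sign_log(x)
            if not np.isfinite(l):
                continue
            # antisymmetry under same-spin exchange
            if system.n_up >= 2:
                xs = x.copy()
                xs[[0, 1]] = xs[[1, 0]]
                s2, l2 = self.sign_log(xs)
                if s2 != -s or abs(l2 - l) > 1e-10 * max(1.0, abs(l)):
                    raise TrialConstructionError(
                        "antisymmetry violated under same-spin exchange")
            try:
                gfd = fd_grad_log(self, x)
                lfd = fd_lap_log(self, x)
            except ValueError:
                continue  # stencil hit a node; try another point
            g = self.grad_log(x)
            lap = self.lap_log(x)
            scale_g = max(1.0, float(np.max(np.abs(gfd))))
            if np.max(np.abs(g - gfd)) > rtol * scale_g:
                raise TrialConstructionError("grad_log disagrees with finite differences")
            scale_l = max(1.0, float(np.max(np.abs(lfd))))
            if np.max(np.abs(lap - lfd)) > 100 * rtol * scale_l:
                raise TrialConstructionError("lap_log disagrees with finite differences")
            checked += 1
        if checked < n_points:
            raise TrialConstructionError("could not find valid configurations for self-check")


# ---------------------------------------------------------------------------
# nodeless product trials
# ---------------------------------------------------------------------------

class HydrogenicTrial(TrialWavefunction):
    """psi = prod_i exp(-zeta |r_i - R|) around a single nucleus.

    The exact ground state of a one-electron hydrogen-like atom when
    zeta = Z (energy -Z^2/2).  ``zeta`` is a free variational parameter.
    """

    nodeless = True
    exact_node = True

    def __init__(self, system: MolecularSystem, zeta: float = None):
        if system.n_nuclei != 1:
            raise ValueError("hydrogenic trial needs exactly one nucleus")
        self.center = system.nuclear_positions[0]
        self.zeta = float(zeta if zeta is not None else system.nuclear_charges[0])
        if self.zeta <= 0:
            raise ValueError("zeta must be positive")
        if system.n_electrons == 1 and abs(self.zeta - system.nuclear_charges[0]) < 1e-12:
            self.exact_energy = -0.5 * self.zeta**2

    def _r(self, x):
        return np.linalg.norm(np.asarray(x, dtype=float) - self.center, axis=-1)

    def sign_log(self, x):
        r = self._r(x)
        log = -self.zeta * r.sum(axis=-1)
        return np.ones(log.shape), log

    def grad_log(self, x):
        disp = np.asarray(x, dtype=float) - self.center
        r = np.linalg.norm(disp, axis=-1, keepdims=True)
        return -self.zeta * disp / np.maximum(r, 1e-300)

    def lap_log(self, x):
        d = np.asarray(x).shape[-1]
        r = self._r(x)
        return -self.zeta * (d - 1) / np.maximum(r, 1e-300)

    @property
    def parameters(self):
        return np.array([self.zeta])

    def with_parameters(self, params):
        new = HydrogenicTrial.__new__(HydrogenicTrial)
        new.center = self.center
        new.zeta = max(float(np.asarray(params).ravel()[0]), 1e-3)
        new.exact_energy = None
        return new

    def param_grad_log(self, x):
        return -self._r(x).sum(axis=-1)[..., None]


class GaussianTrial(TrialWavefunction):
    """psi = exp(-omega |x|^2 / 2): exact ground state of the isotropic
    harmonic trap with energy n * d * omega / 2."""

    nodeless = True
    exact_node = True

    def __init__(self, system: MolecularSystem, omega: float = None):
        self.omega = float(omega if omega is not None else system.omega)
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if system.potential == "harmonic" and abs(self.omega - system.omega) < 1e-12:
            self.exact_energy = 0.5 * system.n_electrons * system.dim * system.omega

    def sign_log(self, x):
        x = np.asarray(x, dtype=float)
        log = -0.5 * self.omega * (x**2).sum(axis=(-1, -2))
        return np.ones(log.shape), log

    def grad_log(self, x):
        return -self.omega * np.asarray(x, dtype=float)

    def lap_log(self, x):
        x = np.asarray(x)
        return -self.omega * x.shape[-1] * np.ones(x.shape[:-1])


class PadeJastrowTwoElectron(TrialWavefunction):
    """Two-electron nodeless trial exp(-zeta (r1+r2)) exp(r12 / (2 (1 + b r12))).

    The Jastrow factor satisfies the antiparallel electron-electron cusp
    condition (derivative 1/2 at coalescence) for every b > 0; zeta = Z
    satisfies the nuclear cusp.  ``b`` is the free variational parameter.
    """

    nodeless = True
    exact_node = True

    def __init__(self, system: MolecularSystem, b: float = 0.35, zeta: float = None):
        if system.n_electrons != 2 or system.n_nuclei != 1:
            raise ValueError("he_pade needs a two-electron single-nucleus system")
        if b <= 0:
            raise ValueError("b must be positive")
        self.center = system.nuclear_positions[0]
        self.zeta = float(zeta if zeta is not None else system.nuclear_charges[0])
        self.b = float(b)

    def _geom(self, x):
        x = np.asarray(x, dtype=float)
        disp = x - self.center
        r = np.linalg.norm(disp, axis=-1)
        d12 = x[..., 0, :] - x[..., 1, :]
        r12 = np.linalg.norm(d12, axis=-1)
        return disp, r, d12, r12

    def sign_log(self, x):
        _, r, _, r12 = self._geom(x)
        log = -self.zeta * r.sum(axis=-1) + r12 / (2 * (1 + self.b * r12))
        return np.ones(log.shape), log

    def grad_log(self, x):
        disp, r, d12, r12 = self._geom(x)
        g = -self.zeta * disp / np.maximum(r, 1e-300)[..., None]
        up = 1.0 / (2 * (1 + self.b * r12) ** 2)  # u'(r12)
        unit12 = d12 / np.maximum(r12, 1e-300)[..., None]
        g[..., 0, :] += up[..., None] * unit12
        g[..., 1, :] -= up[..., None] * unit12
        return g

    def lap_log(self, x):
        d = np.asarray(x).shape[-1]
        _, r, _, r12 = self._geom(x)
        lap = -self.zeta * (d - 1) / np.maximum(r, 1e-300)
        up = 1.0 / (2 * (1 + self.b * r12) ** 2)
        upp = -self.b / (1 + self.b * r12) ** 3
        pair = upp + (d - 1) / np.maximum(r12, 1e-300) * up
        lap = lap.copy()
        lap[..., 0] += pair
        lap[..., 1] += pair
        return lap

    @property
    def parameters(self):
        return np.array([self.b])

    def with_parameters(self, params):
        new = PadeJastrowTwoElectron.__new__(PadeJastrowTwoElectron)
        new.center, new.zeta = self.center, self.zeta
        new.b = float(np.asarray(params).ravel()[0])
        if new.b <= 0:
            new.b = 1e-6  # keep the Jastrow well defined under SGD overshoot
        return new

    def param_grad_log(self, x):
        _, _, _, r12 = self._geom(x)
        return (-(r12**2) / (2 * (1 + self.b * r12) ** 2))[..., None]


class ProductTrial(TrialWavefunction):
    """One 1s exponential per electron on a round-robin assigned nucleus.

    A crude nodeless guiding function for well-separated atoms (the
    size-consistency fixture of two hydrogens at large separation).
    """

    nodeless = True
    exact_node = True

    def __init__(self, system: MolecularSystem, zetas=None):
        if system.n_nuclei < 1:
            raise ValueError("product trial needs nuclei")
        cycle = []
        remaining = [int(round(z)) for z in system.nuclear_charges]
        while any(remaining):
            for i in range(system.n_nuclei):
                if remaining[i] > 0:
                    cycle.append(i)
                    remaining[i] -= 1
        n = system.n_electrons
        assign = [cycle[e % len(cycle)] for e in range(n)]
        self.centers = system.nuclear_positions[assign]
        if zetas is None:
            self.zetas = system.nuclear_charges[assign].astype(float)
        else:
            self.zetas = np.asarray(zetas, dtype=float)

    def _disp_r(self, x):
        disp = np.asarray(x, dtype=float) - self.centers
        return disp, np.linalg.norm(disp, axis=-1)

    def sign_log(self, x):
        _, r = self._disp_r(x)
        log = -(self.zetas * r).sum(axis=-1)
        return np.ones(log.shape), log

    def grad_log(self, x):
        disp, r = self._disp_r(x)
        return -self.zetas[:, None] * disp / np.maximum(r, 1e-300)[..., None]

    def lap_log(self, x):
        d = np.asarray(x).shape[-1]
        _, r = self._disp_r(x)
        return -self.zetas * (d - 1) / np.maximum(r, 1e-300)


class LinearNodeTrial(TrialWavefunction):
    """psi(x) = (n . vec(x) - c) * exp(-|x|^2 / 2).

    The node is the hyperplane n . vec(x) = c in the flattened (n*d)
    configuration space: a geometric fixture with an exactly known node.
    With two 1-D particles, normal (1, -1)/sqrt(2) and c = 0 this is the
    antisymmetric harmonic-trap eigenstate (x1 - x2) exp(-(x1^2+x2^2)/2)
    with energy 2 at omega = 1.
    """

    exact_node = True

    def __init__(self, normal, offset: float = 0.0, n_electrons: int = None,
                 dim: int = 1, exact_energy: float = None):
        normal = np.asarray(normal, dtype=float).ravel()
        if n_electrons is None:
            n_electrons = len(normal) // dim
        self.normal = normal.reshape(n_electrons, dim)
        self.offset = float(offset)
        self.exact_energy = exact_energy

    def _t(self, x):
        x = np.asarray(x, dtype=float)
        return (x * self.normal).sum(axis=(-1, -2)) - self.offset

    def sign_log(self, x):
        x = np.asarray(x, dtype=float)
        t = self._t(x)
        with np.errstate(divide="ignore"):
            log = np.log(np.abs(t)) - 0.5 * (x**2).sum(axis=(-1, -2))
        return np.where(t >= 0, 1.0, -1.0), log

    def grad_log(self, x):
        x = np.asarray(x, dtype=float)
        t = self._t(x)
        tt = np.where(np.abs(t) < 1e-300, 1e-300, t)
        return self.normal / tt[..., None, None] - x

    def lap_log(self, x):
        x = np.asarray(x, dtype=float)
        t = self._t(x)
        tt = np.maximum(np.abs(t), 1e-300)
        per_e = (self.normal**2).sum(axis=-1)
        return -per_e / tt[..., None] ** 2 - x.shape[-1] * np.ones(x.shape[:-1])


def harmonic_fermions_trial() -> LinearNodeTrial:
    """Exact two-fermion 1-D harmonic-trap ground state, energy 2 (omega=1)."""
    t = LinearNodeTrial([1.0, -1.0], 0.0, n_electrons=2, dim=1, exact_energy=2.0)
    return t


# ---------------------------------------------------------------------------
# Slater-Jastrow
# ---------------------------------------------------------------------------

_FILL_ORDER = [  # (radial power p, angular axis or None); zeta shells
    ("1s", 0, None), ("2s", 1, None),
    ("2px", 1, 0), ("2py", 1, 1), ("2pz", 1, 2),
    ("3s", 2, None),
    ("3px", 2, 0), ("3py", 2, 1), ("3pz", 2, 2),
]


def _slater_zeta(z: float, shell: str) -> float:
    """Slater's screening rules, a serviceable default for STO exponents."""
    z = float(z)
    n1 = min(z, 2.0)
    if shell == "1s":
        return max(z - 0.30 * max(n1 - 1, 0), 0.7)
    n2 = min(max(z - 2.0, 0.0), 8.0)
    if shell.startswith("2"):
        s = 0.85 * n1 + 0.35 * max(n2 - 1, 0)
        return max((z - s) / 2.0, 0.35)
    n3 = max(z - 10.0, 0.0)
    s = 1.0 * n1 + 0.85 * n2 + 0.35 * max(n3 - 1, 0)
    return max((z - s) / 3.0, 0.3)


class _STOSet:
    """Slater-type orbitals phi = r^p * (x_c or 1) * exp(-zeta r) on a center."""

    def __init__(self, specs):
        # specs: list of (center (d,), p, axis, zeta)
        self.specs = specs

    def value_grad_lap(self, x):
        """x (..., ne, d) -> A (..., ne, K), G (..., ne, K, d), L (..., ne, K)."""
        x = np.asarray(x, dtype=float)
        d = x.shape[-1]
        A = np.empty(x.shape[:-1] + (len(self.specs),))
        G = np.empty(x.shape[:-1] + (len(self.specs), d))
        L = np.empty_like(A)
        for k, (center, p, axis, zeta) in enumerate(self.specs):
            disp = x - center
            r = np.maximum(np.linalg.norm(disp, axis=-1), 1e-300)
            R = r**p * np.exp(-zeta * r)
            Rp = (p / r - zeta) * R
            Rpp = (p * (p - 1) / r**2 - 2 * p * zeta / r + zeta**2) * R
            lapR = Rpp + (d - 1) / r * Rp
            rhat = disp / r[..., None]
            if axis is None:
                A[..., k] = R
                G[..., k, :] = Rp[..., None] * rhat
                L[..., k] = lapR
            else:
                g = disp[..., axis]
                A[..., k] = R * g
                G[..., k, :] = (Rp * g)[..., None] * rhat
                G[..., k, axis] += R
                L[..., k] = lapR * g + 2 * Rp * g / r
        return A, G, L


def _det_sign_log_grad_lap(A, G, L):
    """Log-derivatives of a Slater determinant from orbital arrays.

    A (..., ne, ne): A[i, k] = phi_k(r_i); G, L the orbital gradients and
    Laplacians.  Returns sign, log|det|, per-electron grad (..., ne, d)
    and per-electron Laplacian contribution (..., ne) of log|det|.
    """
    sign, logdet = np.linalg.slogdet(A)
    ok = np.isfinite(logdet)
    Ainv = np.linalg.inv(np.where(ok[..., None, None], A, np.eye(A.shape[-1])))
    grad = np.einsum("...ki,...ikd->...id", Ainv, G)
    lap = np.einsum("...ki,...ik->...i", Ainv, L) - (grad**2).sum(axis=-1)
    return sign, logdet, grad, lap


class _PairJastrow:
    """exp( sum_{i<j} a_ij r_ij / (1 + beta r_ij) ) with fixed cusp matrix a."""

    def __init__(self, a_matrix: np.ndarray, beta: float):
        self.a = a_matrix  # (n, n), symmetric, zero diagonal
        self.beta = float(beta)

    def log(self, x):
        _, r = _ee_distances(x)
        u = self.a * r / (1 + self.beta * r)
        return 0.5 * u.sum(axis=(-1, -2))

    def grad(self, x):
        disp, r = _ee_distances(x)
        rr = np.maximum(r, 1e-300)
        up = self.a / (1 + self.beta * r) ** 2  # u'(r_ij)
        unit = disp / rr[..., None]
        n = r.shape[-1]
        unit[..., np.arange(n), np.arange(n), :] = 0.0
        return (up[..., None] * unit).sum(axis=-2)

    def lap(self, x):
        d = np.asarray(x).shape[-1]
        _, r = _ee_distances(x)
        rr = np.maximum(r, 1e-300)
        up = self.a / (1 + self.beta * r) ** 2
        upp = -2 * self.a * self.beta / (1 + self.beta * r) ** 3
        term = upp + (d - 1) / rr * up
        n = r.shape[-1]
        term[..., np.arange(n), np.arange(n)] = 0.0
        return term.sum(axis=-1)

    def dbeta(self, x):
        _, r = _ee_distances(x)
        du = -self.a * r**2 / (1 + self.beta * r) ** 2
        return 0.5 * du.sum(axis=(-1, -2))


def cusp_matrix(n_up: int, n_down: int) -> np.ndarray:
    """Kato cusp coefficients: 1/2 antiparallel, 1/4 parallel pairs."""
    n = n_up + n_down
    spin = np.array([0] * n_up + [1] * n_down)
    a = np.where(spin[:, None] == spin[None, :], 0.25, 0.5)
    np.fill_diagonal(a, 0.0)
    return a


class SlaterJastrowTrial(TrialWavefunction):
    """Single-determinant-per-spin Slater trial with an e-e Pade-Jastrow.

    Orbitals are Slater-type (1s, 2s, 2p, 3s, 3p filling order) with
    exponents from Slater's screening rules unless given.  On multi-center
    systems the atomic orbital sets are placed round-robin across nuclei;
    this is a crude localized guiding function, adequate for guiding DMC
    but not a quantitative molecular-orbital treatment.  The Jastrow
    satisfies the parallel and antiparallel electron-electron cusp
    conditions for any beta > 0; beta is the free parameter.
    """

    def __init__(self, system: MolecularSystem, zetas=None, beta: float = 0.5,
                 jastrow: bool = True):
        if system.potential != "coulomb":
            raise ValueError("slater_jastrow is defined for Coulomb systems")
        self.system = system
        self.beta = float(beta)
        self.jastrow = bool(jastrow)
        self._zetas_arg = zetas
        specs_by_spin = []
        for ns in (system.n_up, system.n_down):
            specs = []
            for k in range(ns):
                shell, p, axis = _FILL_ORDER[k % len(_FILL_ORDER)]
                nuc = k % system.n_nuclei if system.n_nuclei > 1 else 0
                # on multi-center systems cycle shells per center
                if system.n_nuclei > 1:
                    shell, p, axis = _FILL_ORDER[k // system.n_nuclei]
                z = system.nuclear_charges[nuc]
                zeta = (_slater_zeta(z, shell[:2]) if zetas is None
                        else float(np.asarray(zetas).ravel()[k % len(np.asarray(zetas).ravel())]))
                specs.append((system.nuclear_positions[nuc], p, axis, zeta))
            specs_by_spin.append(_STOSet(specs))
        self.up_set, self.down_set = specs_by_spin
        self.n_up, self.n_down = system.n_up, system.n_down
        self._cusp = cusp_matrix(system.n_up, system.n_down)
        self.nodeless = (system.n_up <= 1 and system.n_down <= 1)
        self.exact_node = self.nodeless

    def _split(self, x):
        return x[..., : self.n_up, :], x[..., self.n_up:, :]

    def _dets(self, x):
        xu, xd = self._split(np.asarray(x, dtype=float))
        out = []
        for xx, oset, ns in ((xu, self.up_set, self.n_up), (xd, self.down_set, self.n_down)):
            if ns == 0:
                out.append(None)
                continue
            A, G, L = oset.value_grad_lap(xx)
            out.append(_det_sign_log_grad_lap(A, G, L))
        return out

    def sign_log(self, x):
        x = np.asarray(x, dtype=float)
        sign = np.ones(x.shape[:-2])
        log = np.zeros(x.shape[:-2])
        for res in self._dets(x):
            if res is None:
                continue
            s, l, _, _ = res
            sign = sign * s
            log = log + l
        if self.jastrow and self.system.n_electrons > 1:
            log = log + _PairJastrow(self._cusp, self.beta).log(x)
        return sign, log

    def grad_log(self, x):
        x = np.asarray(x, dtype=float)
        g = np.zeros_like(x)
        up, down = self._dets(x)
        if up is not None:
            g[..., : self.n_up, :] = up[2]
        if down is not None:
            g[..., self.n_up:, :] = down[2]
        if self.jastrow and self.system.n_electrons > 1:
            g = g + _PairJastrow(self._cusp, self.beta).grad(x)
        return g

    def lap_log(self, x):
        x = np.asarray(x, dtype=float)
        lap = np.zeros(x.shape[:-1])
        up, down = self._dets(x)
        if up is not None:
            lap[..., : self.n_up] = up[3]
        if down is not None:
            lap[..., self.n_up:] = down[3]
        if self.jastrow and self.system.n_electrons > 1:
            lap = lap + _PairJastrow(self._cusp, self.beta).lap(x)
        return lap

    @property
    def parameters(self):
        return np.array([self.beta]) if self.jastrow else np.zeros(0)

    def with_parameters(self, params):
        params = np.asarray(params).ravel()
        if not self.jastrow:
            return super().with_parameters(params)
        beta = max(float(params[0]), 1e-3)
        return SlaterJastrowTrial(self.system, zetas=self._zetas_arg, beta=beta,
                                  jastrow=True)

    def param_grad_log(self, x):
        if not self.jastrow:
            return super().param_grad_log(x)
        return _PairJastrow(self._cusp, self.beta).dbeta(np.asarray(x, float))[..., None]


# ---------------------------------------------------------------------------
# diagnostics and factory
# ---------------------------------------------------------------------------

def cusp_check(trial, system: MolecularSystem, r_small: float = 1e-4,
               seed: int = 0) -> dict:
    """Numerically probe the Kato cusp conditions of a trial.

    Estimates d log|psi| / dr as one electron approaches the first nucleus
    (expected -Z) and, when the system has an antiparallel pair, as two
    antiparallel electrons approach each other (expected +1/2), by
    projecting the analytic gradient onto the separation direction at
    distance ``r_small``.  Returns a report dict with estimates, expected
    values, deviations, and pass flags at 1e-3 absolute.
    """
    rng = np.random.default_rng(seed)
    n, d = system.n_electrons, system.dim
    report: dict = {}
    x = rng.normal(scale=1.5, size=(n, d))
    if system.potential == "coulomb" and system.n_nuclei >= 1:
        z = float(system.nuclear_charges[0])
        direction = rng.normal(size=d)
        direction /= np.linalg.norm(direction)
        # the radial log-derivative at coalescence: average over +/- the
        # approach direction to cancel the smooth background gradient
        slopes = []
        for sgn in (1.0, -1.0):
            x0 = x.copy()
            x0[0] = system.nuclear_positions[0] + r_small * sgn * direction
            g = trial.grad_log(x0)
            slopes.append(float(g[0] @ (sgn * direction)))
        slope = 0.5 * (slopes[0] + slopes[1])
        report["nuclear_cusp"] = {
            "estimate": slope, "expected": -z, "deviation": abs(slope + z),
            "ok": abs(slope + z) < 1e-3 * max(1.0, z),
        }
    if system.n_up >= 1 and system.n_down >= 1:
        i, j = 0, system.n_up  # an antiparallel pair
        direction = rng.normal(size=d)
        direction /= np.linalg.norm(direction)
        mid = rng.normal(scale=0.5, size=d)
        slopes = []
        for sgn in (1.0, -1.0):
            x1 = x.copy()
            x1[i] = mid + 0.5 * r_small * sgn * direction
            x1[j] = mid - 0.5 * r_small * sgn * direction
            g = trial.grad_log(x1)
            slopes.append(float((g[i] - g[j]) @ (sgn * direction)) / 2.0)
        slope = 0.5 * (slopes[0] + slopes[1])
        report["ee_cusp_antiparallel"] = {
            "estimate": slope, "expected": 0.5, "deviation": abs(slope - 0.5),
            "ok": abs(slope - 0.5) < 1e-3,
        }
    return report


_TRIAL_BUILDERS = {}


def _register(name):
    def deco(fn):
        _TRIAL_BUILDERS[name] = fn
        return fn
    return deco


@_register("hydrogenic")
def _build_hydrogenic(system, params):
    return HydrogenicTrial(system, zeta=params.get("zeta", params.get("Z")))


@_register("gaussian")
def _build_gaussian(system, params):
    return GaussianTrial(system, omega=params.get("omega"))


@_register("he_pade")
def _build_he_pade(system, params):
    return PadeJastrowTwoElectron(system, b=params.get("b", 0.35),
                                  zeta=params.get("zeta"))


@_register("product_1s")
def _build_product(system, params):
    return ProductTrial(system, zetas=params.get("zetas"))


@_register("slater_jastrow")
def _build_sj(system, params):
    return SlaterJastrowTrial(system, zetas=params.get("zetas"),
                              beta=params.get("beta", 0.5),
                              jastrow=params.get("jastrow", True))


@_register("harmonic_fermions")
def _build_hf(system, params):
    return harmonic_fermions_trial()


@_register("linear_node")
def _build_linear(system, params):
    return LinearNodeTrial(params["normal"], params.get("offset", 0.0),
                           n_electrons=system.n_electrons, dim=system.dim,
                           exact_energy=params.get("exact_energy"))


@_register("neural")
def _build_neural(system, params):
    from fndmc.neural import NeuralTrial
    return NeuralTrial(system, **params)


def make_trial(name: str, system: MolecularSystem, params: dict = None,
               self_check: bool = True) -> TrialWavefunction:
    """Construct a catalog trial and verify the contract on construction.

    The self-check spot-tests antisymmetry under same-spin exchange and
    derivative consistency against central finite differences; failure
    raises :class:`TrialConstructionError` naming the invariant.
    """
    if name not in _TRIAL_BUILDERS:
        raise KeyError(f"unknown trial {name!r}; available: {sorted(_TRIAL_BUILDERS)}")
    trial = _TRIAL_BUILDERS[name](system, dict(params or {}))
    if self_check:
        trial.self_check(system)
    return trial


def trial_catalog() -> list[str]:
    return sorted(_TRIAL_BUILDERS)
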