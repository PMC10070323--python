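"""Molecular system definitions, XYZ geometry I/O, and walker initialization.

Everything downstream of the I/O boundary works in Hartree atomic units:
lengths in bohr, energies in Hartree.  XYZ files are read and written in
angstrom by default, following community convention.

Besides Coulombic molecules, the catalog carries a few harmonic-well test
systems (non-interacting particles in an isotropic harmonic trap).  These
have analytically known ground states and are used throughout the test
suite as exact references for the samplers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

BOHR_PER_ANGSTROM = 1.8897259886

# Z by element symbol, H through Ar (the catalog's range).
_ELEMENTS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18,
}
_SYMBOLS = {z: s for s, z in _ELEMENTS.items()}

# Ground-state (Hund-rule) spin occupations (n_up, n_down) for neutral atoms.
_ATOM_SPINS = {
    1: (1, 0), 2: (1, 1), 3: (2, 1), 4: (2, 2), 5: (3, 2), 6: (4, 2),
    7: (5, 2), 8: (5, 3), 9: (5, 4), 10: (5, 5), 11: (6, 5), 12: (6, 6),
    13: (7, 6), 14: (8, 6), 15: (9, 6), 16: (9, 7), 17: (9, 8), 18: (9, 9),
}


class XYZParseError(ValueError):
    """Raised when an XYZ file is malformed; the message names the line."""


@dataclass(frozen=True)
class MolecularSystem:
    """A fixed set of nuclei plus electron counts per spin channel.

    Parameters
    ----------
    nuclear_positions : (m, dim) array, bohr
    nuclear_charges : (m,) array of positive charges Z_I
    n_up, n_down : electron counts per spin channel; spin-up block first
    label : free-text name
    dim : spatial dimension per electron (3 for molecules; harmonic test
        systems may use 1)
    potential : ``"coulomb"`` or ``"harmonic"``
    omega : trap frequency, only meaningful for the harmonic potential
    """

    nuclear_positions: np.ndarray
    nuclear_charges: np.ndarray
    n_up: int
    n_down: int
    label: str = ""
    dim: int = 3
    potential: str = "coulomb"
    omega: float = 1.0

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.nuclear_positions, dtype=float))
        if pos.size == 0:
            pos = pos.reshape(0, self.dim)
        chg = np.asarray(self.nuclear_charges, dtype=float).ravel()
        object.__setattr__(self, "nuclear_positions", pos)
        object.__setattr__(self, "nuclear_charges", chg)
        if len(pos) != len(chg):
            raise ValueError("nuclear_positions and nuclear_charges length mismatch")
        if np.any(chg <= 0):
            raise ValueError("all nuclear charges must be positive")
        if not (self.n_up >= self.n_down >= 0):
            raise ValueError("require n_up >= n_down >= 0")
        if self.n_up + self.n_down < 1:
            raise ValueError("at least one electron required")
        if self.potential not in ("coulomb", "harmonic"):
            raise ValueError(f"unknown potential {self.potential!r}")
        if self.potential == "coulomb" and pos.shape[1] != self.dim:
            raise ValueError("nuclear position dimension disagrees with dim")

    @property
    def n_electrons(self) -> int:
        return self.n_up + self.n_down

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclear_charges)

    def nuclear_repulsion(self) -> float:
        """Sum_{I<J} Z_I Z_J / R_IJ in Hartree (0 for a single nucleus)."""
        if self.potential != "coulomb" or self.n_nuclei < 2:
            return 0.0
        e = 0.0
        for i in range(self.n_nuclei):
            for j in range(i + 1, self.n_nuclei):
                rij = np.linalg.norm(self.nuclear_positions[i] - self.nuclear_positions[j])
                e += self.nuclear_charges[i] * self.nuclear_charges[j] / rij
        return e

    def with_spins(self, n_up: int, n_down: int) -> "MolecularSystem":
        return replace(self, n_up=n_up, n_down=n_down)


def _default_spins(n_electrons: int) -> tuple[int, int]:
    # odd electron counts put the extra electron in the spin-up channel
    n_up = (n_electrons + 1) // 2
    return n_up, n_electrons - n_up


def load_xyz(path, units: str = "angstrom", n_up: int | None = None,
             n_down: int | None = None) -> MolecularSystem:
    """Read a standard XYZ file (count line, comment line, element rows).

    ``units`` selects the file's length unit, ``"angstrom"`` (default,
    converted to bohr) or ``"bohr"``.  Spin counts default to a neutral
    system with the excess electron, if any, spin-up.
    """
    if units not in ("angstrom", "bohr"):
        raise ValueError(f"units must be 'angstrom' or 'bohr', got {units!r}")
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: empty file")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise XYZParseError(f"{path}, line 1: expected an atom count") from None
    comment = lines[1] if len(lines) > 1 else ""
    rows = [ln for ln in lines[2:] if ln.strip()]
    if len(rows) != count:
        raise XYZParseError(
            f"{path}: header declares {count} atoms but {len(rows)} coordinate rows found"
        )
    symbols, coords = [], []
    for k, ln in enumerate(rows, start=3):
        parts = ln.split()
        if len(parts) < 4:
            raise XYZParseError(f"{path}, line {k}: expected 'element x y z'")
        sym = parts[0].capitalize()
        if sym not in _ELEMENTS:
            raise XYZParseError(f"{path}, line {k}: unknown element symbol {parts[0]!r}")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise XYZParseError(f"{path}, line {k}: non-numeric coordinate") from None
        symbols.append(sym)
        coords.append(xyz)
    pos = np.asarray(coords, dtype=float)
    if units == "angstrom":
        pos = pos * BOHR_PER_ANGSTROM
    charges = np.array([_ELEMENTS[s] for s in symbols], dtype=float)
    n_total = int(charges.sum())
    if n_up is None and n_down is None:
        n_up, n_down = _default_spins(n_total)
    elif n_up is None or n_down is None:
        raise ValueError("give both n_up and n_down or neither")
    return MolecularSystem(pos, charges, n_up, n_down,
                           label=comment.strip() or "-".join(symbols))


def write_xyz(system: MolecularSystem, path, units: str = "angstrom") -> None:
    """Write a system to XYZ; charges must correspond to known elements."""
    if units not in ("angstrom", "bohr"):
        raise ValueError(f"units must be 'angstrom' or 'bohr', got {units!r}")
    scale = 1.0 / BOHR_PER_ANGSTROM if units == "angstrom" else 1.0
    lines = [str(system.n_nuclei), system.label]
    for z, r in zip(system.nuclear_charges, system.nuclear_positions):
        sym = _SYMBOLS.get(int(round(z)))
        if sym is None or abs(z - round(z)) > 1e-9:
            raise ValueError(f"charge {z} has no element symbol")
        x, y, zz = (r * scale if system.dim == 3 else np.pad(r * scale, (0, 3 - system.dim)))
        lines.append(f"{sym} {x:.10f} {y:.10f} {zz:.10f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


_DIATOMIC_DEFAULTS = {"N2": 2.1, "H2": 1.401}  # bond lengths, bohr


def builtin_system(name: str, **params) -> MolecularSystem:
    """Return a system from the built-in catalog.

    Atoms ``H``..``Ar`` sit at the origin with Hund-rule spin occupations.
    ``N2``/``H2`` take a ``bond_length`` (bohr) and lie on the z axis,
    symmetric about the origin; N2 defaults to its equilibrium bond length
    of 2.1 bohr.  ``harmonic_well`` is one particle in a 3-D isotropic trap
    (``omega``); ``harmonic_fermions_1d`` is two same-spin non-interacting
    fermions in a 1-D trap, the package's minimal fixture with an exactly
    known node.
    """
    if name in _ELEMENTS:
        z = _ELEMENTS[name]
        n_up, n_down = _ATOM_SPINS[z]
        return MolecularSystem(np.zeros((1, 3)), np.array([float(z)]),
                               n_up, n_down, label=name)
    if name in _DIATOMIC_DEFAULTS:
        bond = float(params.get("bond_length", _DIATOMIC_DEFAULTS[name]))
        if bond <= 0:
            raise ValueError(f"bond length must be positive, got {bond}")
        z = float(_ELEMENTS[name[0]])
        pos = np.array([[0.0, 0.0, -bond / 2], [0.0, 0.0, bond / 2]])
        per_atom = _ATOM_SPINS[int(z)]
        n_up = n_down = per_atom[0] + per_atom[1]  # closed-shell molecule
        return MolecularSystem(pos, np.array([z, z]), n_up, n_down,
                               label=f"{name}(r={bond:g})")
    if name == "harmonic_well":
        omega = float(params.get("omega", 1.0))
        return MolecularSystem(np.zeros((0, 3)), np.zeros(0), 1, 0,
                               label="harmonic_well", dim=3,
                               potential="harmonic", omega=omega)
    if name == "harmonic_fermions_1d":
        omega = float(params.get("omega", 1.0))
        return MolecularSystem(np.zeros((0, 1)), np.zeros(0), 2, 0,
                               label="harmonic_fermions_1d", dim=1,
                               potential="harmonic", omega=omega)
    raise KeyError(f"unknown builtin system {name!r}; see catalog()")


def catalog() -> list[str]:
    """Names accepted by :func:`builtin_system`."""
    return sorted(_ELEMENTS) + ["N2", "H2", "harmonic_well", "harmonic_fermions_1d"]


def init_walkers(system: MolecularSystem, n_walkers: int, seed=0) -> np.ndarray:
    """Draw an initial walker ensemble, shape ``(n_walkers, n_electrons, dim)``.

    Electrons are assigned to nuclei round-robin weighted by charge (each
    nucleus appears Z_I times in the assignment cycle), then drawn from an
    isotropic Gaussian of width max(1/Z_I, 0.3) bohr around the assigned
    nucleus.  Harmonic systems draw from the trap's ground-state width
    1/sqrt(omega).  Deterministic given the seed.
    """
    if n_walkers < 1:
        raise ValueError("n_walkers must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, d = system.n_electrons, system.dim
    if system.potential == "harmonic" or system.n_nuclei == 0:
        width = 1.0 / math.sqrt(system.omega)
        return rng.normal(scale=width, size=(n_walkers, n, d))
    # assignment cycle: nucleus index repeated Z_I times, interleaved
    cycle: list[int] = []
    counts = [int(round(z)) for z in system.nuclear_charges]
    remaining = counts[:]
    while any(remaining):
        for i in range(system.n_nuclei):
            if remaining[i] > 0:
                cycle.append(i)
                remaining[i] -= 1
    centers = np.empty((n, d))
    widths = np.empty(n)
    for e in range(n):
        i = cycle[e % len(cycle)]
        centers[e] = system.nuclear_positions[i]
        widths[e] = max(1.0 / system.nuclear_charges[i], 0.3)
    return centers + rng.normal(size=(n_walkers, n, d)) * widths[:, None]
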