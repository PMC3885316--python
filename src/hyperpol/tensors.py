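"""Response-tensor types, rotational invariants and unit conversions.

All quantities are stored in Hartree atomic units; conversion to practical
units (Debye, cm^-1, SI) happens only through :class:`UnitRegistry`.

Tensor index convention
-----------------------
``beta[i, j, k]`` is the second derivative of the induced dipole component
``mu_i`` with respect to the field components ``F_j`` and ``F_k`` at zero
field.  With the induced-dipole Taylor expansion

    mu_i(F) = mu_i(0) + alpha_ij F_j + (1/2!) beta_ijk F_j F_k
              + (1/3!) gamma_ijkl F_j F_k F_l + ...

the 1/2! of the quadratic term cancels the second-derivative factor, so the
stored tensor multiplies ``(1/2) F_j F_k`` when evaluating the expansion.
The same convention (pure derivatives) applies to ``gamma``.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Mapping

import numpy as np
from scipy import constants as _codata

__all__ = [
    "AXES",
    "Dipole",
    "Alpha",
    "Beta",
    "Gamma",
    "UnitRegistry",
    "units",
    "axis_index",
    "beta_components",
    "beta_vec",
    "dipole_norm",
    "convert",
    "percent_change",
    "rotate_rank3",
]

AXES = ("x", "y", "z")
_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}

#: Kleinman symmetry tag: the tensor is invariant under every permutation of
#: its three indices (valid far from resonance).
KLEINMAN = "kleinman"
#: Intrinsic symmetry of a static finite-field tensor: last two indices only.
JK_SYMMETRIC = "jk-symmetric"


def axis_index(axis) -> int:
    """Map an axis label ('x'|'y'|'z' or 0|1|2) to an integer index."""
    if isinstance(axis, str):
        try:
            return _AXIS_INDEX[axis.lower()]
        except KeyError:
            raise ValueError(f"unknown axis label {axis!r}") from None
    i = int(axis)
    if i not in (0, 1, 2):
        raise ValueError(f"axis index out of range: {axis!r}")
    return i


def _as_array(values, shape, name):
    arr = np.array(values, dtype=float)
    if arr.shape != shape:
        raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
    return arr


@dataclasses.dataclass(frozen=True)
class Dipole:
    """Dipole moment vector in atomic units."""

    components: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "components", _as_array(self.components, (3,), "Dipole"))

    @classmethod
    def from_xyz(cls, x: float, y: float, z: float) -> "Dipole":
        return cls(np.array([x, y, z], dtype=float))

    @property
    def x(self) -> float:
        return float(self.components[0])

    @property
    def y(self) -> float:
        return float(self.components[1])

    @property
    def z(self) -> float:
        return float(self.components[2])

    def norm(self) -> float:
        return float(np.linalg.norm(self.components))

    def to_debye(self) -> np.ndarray:
        return self.components * units.AU_DIPOLE_TO_DEBYE


@dataclasses.dataclass(frozen=True)
class Alpha:
    """Static polarizability, a symmetric 3x3 matrix in atomic units.

    The input matrix is symmetrized on construction; an asymmetry above
    ``tolerance`` (relative to the matrix scale) raises, unless
    ``tolerance=None``, in which case the observed relative asymmetry is
    only recorded in ``asymmetry`` (useful for raw numerical estimates).
    """

    matrix: np.ndarray
    tolerance: float | None = 1e-8
    asymmetry: float = dataclasses.field(init=False, default=0.0)

    def __post_init__(self):
        m = _as_array(self.matrix, (3, 3), "Alpha")
        asym = float(np.max(np.abs(m - m.T)))
        scale = max(float(np.max(np.abs(m))), 1.0)
        if self.tolerance is not None and asym > self.tolerance * scale:
            raise ValueError(f"Alpha matrix not symmetric: max asymmetry {asym:g}")
        object.__setattr__(self, "asymmetry", asym / scale)
        object.__setattr__(self, "matrix", (m + m.T) / 2.0)

    def isotropic(self) -> float:
        return float(np.trace(self.matrix) / 3.0)


def _symmetrize_full(t: np.ndarray) -> np.ndarray:
    out = np.zeros_like(t)
    for perm in itertools.permutations(range(3)):
        out += np.transpose(t, perm)
    return out / 6.0


@dataclasses.dataclass(frozen=True)
class Beta:
    """First-order hyperpolarizability tensor (3x3x3, atomic units).

    The declared ``symmetry`` is enforced on construction by symmetrization:
    ``kleinman`` averages over all six index permutations, ``jk-symmetric``
    over the last two indices only (the intrinsic symmetry of a static
    derivative tensor).
    """

    tensor: np.ndarray
    symmetry: str = KLEINMAN

    def __post_init__(self):
        t = _as_array(self.tensor, (3, 3, 3), "Beta")
        if self.symmetry == KLEINMAN:
            t = _symmetrize_full(t)
        elif self.symmetry == JK_SYMMETRIC:
            t = (t + np.transpose(t, (0, 2, 1))) / 2.0
        else:
            raise ValueError(f"unknown Beta symmetry {self.symmetry!r}")
        object.__setattr__(self, "tensor", t)

    @classmethod
    def from_components(cls, **components: float) -> "Beta":
        """Build a Kleinman-symmetric tensor from named components.

        Keyword names are index triples such as ``xxx`` or ``zxx``; every
        permutation of a given index multiset receives the same value, which
        is exactly the Kleinman completion of a table of ``beta_ijj``-style
        entries.
        """
        t = np.zeros((3, 3, 3))
        for name, value in components.items():
            key = name.lower().removeprefix("beta_")
            if len(key) != 3 or any(c not in _AXIS_INDEX for c in key):
                raise ValueError(f"invalid beta component name {name!r}")
            idx = tuple(_AXIS_INDEX[c] for c in key)
            for perm in set(itertools.permutations(idx)):
                t[perm] = float(value)
        return cls(t, symmetry=KLEINMAN)

    def rotated(self, rotation: np.ndarray) -> "Beta":
        return Beta(rotate_rank3(self.tensor, rotation), symmetry=self.symmetry)


@dataclasses.dataclass(frozen=True)
class Gamma:
    """Second-order hyperpolarizability tensor (3x3x3x3, atomic units).

    Symmetric in its last three indices (intrinsic static symmetry); this is
    enforced by symmetrization on construction.
    """

    tensor: np.ndarray

    def __post_init__(self):
        t = _as_array(self.tensor, (3, 3, 3, 3), "Gamma")
        out = np.zeros_like(t)
        for perm in itertools.permutations((1, 2, 3)):
            out += np.transpose(t, (0,) + perm)
        object.__setattr__(self, "tensor", out / 6.0)


def rotate_rank3(tensor: np.ndarray, rotation: np.ndarray) -> np.ndarray:
    """Apply the same frame rotation to all three indices of a rank-3 tensor."""
    r = _as_array(rotation, (3, 3), "rotation")
    return np.einsum("ia,jb,kc,abc->ijk", r, r, r, np.asarray(tensor, dtype=float))


def beta_components(beta) -> np.ndarray:
    """Contracted component vector beta_i = (1/3) sum_j (b_ijj + b_jij + b_jji).

    Accepts a :class:`Beta` or a raw (possibly unsymmetric) 3x3x3 array; for
    a Kleinman-symmetric tensor the expression reduces to ``sum_j b_ijj``.
    """
    t = beta.tensor if isinstance(beta, Beta) else _as_array(beta, (3, 3, 3), "beta")
    return (
        np.einsum("ijj->i", t) + np.einsum("jij->i", t) + np.einsum("jji->i", t)
    ) / 3.0


def beta_vec(beta) -> float:
    """Rotational invariant sqrt(beta_x^2 + beta_y^2 + beta_z^2)."""
    return float(np.linalg.norm(beta_components(beta)))


def dipole_norm(dipole) -> float:
    """Euclidean norm of a dipole; accepts :class:`Dipole` or a 3-vector."""
    if isinstance(dipole, Dipole):
        return dipole.norm()
    return float(np.linalg.norm(_as_array(dipole, (3,), "dipole")))


def percent_change(reference: float, value: float) -> float:
    """Signed percent change of ``value`` relative to ``reference``."""
    if reference == 0:
        raise ValueError("percent_change requires a nonzero reference")
    return 100.0 * (value - reference) / reference


class UnitRegistry:
    """Central store of conversion constants, derived from CODATA values.

    Only this class touches unit systems; the rest of the package works in
    atomic units.  Registered quantity kinds: ``beta``, ``dipole``,
    ``energy``, ``length``.
    """

    #: 1 a.u. of first-order hyperpolarizability, e^3 a0^3 / E_h^2, in SI.
    BETA_AU_TO_SI: float
    #: 1 a.u. of dipole moment in Debye (1 D = 1e-21/c C m).
    AU_DIPOLE_TO_DEBYE: float
    #: 1 hartree expressed in cm^-1.
    HARTREE_TO_CM1: float
    #: Bohr radius in Angstrom.
    BOHR_TO_ANGSTROM: float

    def __init__(self):
        e = _codata.e
        a0 = _codata.value("Bohr radius")
        hartree = _codata.value("Hartree energy")
        debye = 1e-21 / _codata.c  # C m
        self.BETA_AU_TO_SI = e**3 * a0**3 / hartree**2
        self.AU_DIPOLE_TO_DEBYE = e * a0 / debye
        self.HARTREE_TO_CM1 = _codata.value("hartree-inverse meter relationship") / 100.0
        self.BOHR_TO_ANGSTROM = a0 * 1e10
        self._table: dict[tuple[str, str, str], float] = {}
        self._register("beta", "a.u.", "C^3 m^3 J^-2", self.BETA_AU_TO_SI)
        self._register("dipole", "a.u.", "D", self.AU_DIPOLE_TO_DEBYE)
        self._register("energy", "hartree", "cm^-1", self.HARTREE_TO_CM1)
        self._register("energy", "hartree", "eV", hartree / e)
        self._register("length", "bohr", "angstrom", self.BOHR_TO_ANGSTROM)

    def _register(self, kind: str, unit_a: str, unit_b: str, factor: float) -> None:
        self._table[(kind, unit_a, unit_b)] = factor
        self._table[(kind, unit_b, unit_a)] = 1.0 / factor
        self._table[(kind, unit_a, unit_a)] = 1.0
        self._table[(kind, unit_b, unit_b)] = 1.0

    def registered_pairs(self) -> list[tuple[str, str, str]]:
        return sorted(self._table)

    def convert(self, value: float, kind: str, from_unit: str, to_unit: str) -> float:
        try:
            factor = self._table[(kind, from_unit, to_unit)]
        except KeyError:
            raise ValueError(
                f"no conversion registered for kind={kind!r} "
                f"{from_unit!r} -> {to_unit!r}"
            ) from None
        return value * factor


#: Module-level registry shared across the package.
units = UnitRegistry()


def convert(value: float, kind: str, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` of the given quantity kind between registered units."""
    return units.convert(value, kind, from_unit, to_unit)
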