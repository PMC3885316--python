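"""Double-harmonic pure-vibrational first-order hyperpolarizability.

The lowest-order square-bracket term couples dipole and polarizability
derivatives along each normal mode:

    [mu alpha]_ijk = sum_a (dmu_i dalpha_jk + dmu_j dalpha_ik
                            + dmu_k dalpha_ij) / omega_a^2

with all derivatives taken along the mass-weighted normal coordinate in
atomic units (electron-mass weighting, bohr) and omega_a converted from
cm^-1 to hartree before squaring.  In the infinite-optical-frequency limit
the EOPE process retains (1/3) of the bracket while the SHG contribution
vanishes identically.

Spectroscopic intensities use the standard double-harmonic expressions;
the km/mol and Angstrom^4/amu conversion chains are derived from CODATA
constants at import time (see ``KM_MOL_PER_E2_AMU``).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import constants as _codata

from .tensors import Beta, KLEINMAN, beta_vec, units

__all__ = [
    "NormalMode",
    "ModeContribution",
    "mu_alpha_bracket",
    "beta_v_process",
    "per_mode_beta_vec",
    "ir_intensity",
    "raman_activity",
    "raman_invariants",
    "KM_MOL_PER_E2_AMU",
    "DEFAULT_WAVENUMBER_FLOOR",
]

#: Modes below this wavenumber (cm^-1) are treated as residual translations /
#: rotations and excluded from the 3N-6 bracket sum; override explicitly for
#: genuine large-amplitude modes.
DEFAULT_WAVENUMBER_FLOOR = 50.0

#: amu expressed in electron masses.
_AMU_PER_ME = _codata.value("atomic mass constant") / _codata.m_e

#: IR intensity (km/mol) per squared dipole derivative in e / sqrt(amu):
#: N_A * pi / (3 c^2) * e^2 / (4 pi eps0 amu), folded to km/mol.
KM_MOL_PER_E2_AMU = (
    _codata.N_A * _codata.e**2 / (12.0 * _codata.epsilon_0 * _codata.c**2
                                  * _codata.value("atomic mass constant"))
) / 1000.0

#: Same constant referred to fully atomic-unit derivatives (per sqrt(m_e)).
KM_MOL_PER_AU_DIPDERIV_SQ = KM_MOL_PER_E2_AMU * _AMU_PER_ME


@dataclasses.dataclass(frozen=True)
class NormalMode:
    """One harmonic normal mode with property derivatives.

    ``dmu`` (3-vector) and ``dalpha`` (symmetric 3x3) are derivatives of the
    dipole and polarizability with respect to the mass-weighted normal
    coordinate, in atomic units.  ``index`` follows 1-based "nu_25" style
    labelling.  A non-positive wavenumber (imaginary mode) is storable so
    that parsers can report it, but is rejected by the bracket sum.
    """

    index: int
    wavenumber: float
    dmu: np.ndarray
    dalpha: np.ndarray
    label: str = ""

    def __post_init__(self):
        dmu = np.asarray(self.dmu, dtype=float)
        dalpha = np.asarray(self.dalpha, dtype=float)
        if dmu.shape != (3,):
            raise ValueError(f"mode {self.index}: dmu must be a 3-vector")
        if dalpha.shape != (3, 3):
            raise ValueError(f"mode {self.index}: dalpha must be 3x3")
        asym = np.max(np.abs(dalpha - dalpha.T))
        if asym > 1e-8 * max(np.max(np.abs(dalpha)), 1.0):
            raise ValueError(
                f"mode {self.index}: polarizability derivative not symmetric "
                f"(max asymmetry {asym:g})"
            )
        object.__setattr__(self, "dmu", dmu)
        object.__setattr__(self, "dalpha", (dalpha + dalpha.T) / 2.0)


@dataclasses.dataclass(frozen=True)
class ModeContribution:
    """Per-mode vibrational beta contribution plus stick intensities."""

    index: int
    bracket: np.ndarray  # this mode's [mu alpha] tensor term (a.u.)
    beta_vec: float
    i_ir: float  # km/mol
    a_raman: float  # Angstrom^4 / amu
    label: str = ""


def _mode_bracket_term(mode: NormalMode) -> np.ndarray:
    omega_au = mode.wavenumber / units.HARTREE_TO_CM1
    d, a = mode.dmu, mode.dalpha
    term = (
        np.einsum("i,jk->ijk", d, a)
        + np.einsum("j,ik->ijk", d, a)
        + np.einsum("k,ij->ijk", d, a)
    )
    return term / omega_au**2


def _active_modes(modes: Sequence[NormalMode], wavenumber_floor: float):
    active = []
    for m in modes:
        if m.wavenumber <= 0:
            raise ValueError(
                f"mode {m.index} has non-positive wavenumber "
                f"{m.wavenumber:g} cm^-1; imaginary modes cannot enter the "
                "double-harmonic sum"
            )
        if m.wavenumber >= wavenumber_floor:
            active.append(m)
    return active


def mu_alpha_bracket(
    modes: Sequence[NormalMode],
    wavenumber_floor: float = DEFAULT_WAVENUMBER_FLOOR,
) -> np.ndarray:
    """Sum the double-harmonic [mu alpha] bracket over all modes (a.u.).

    The returned 3x3x3 array is fully index-symmetric (the three-term
    symmetrized product with a symmetric dalpha).  Modes below
    ``wavenumber_floor`` are skipped; a non-positive wavenumber raises.
    """
    total = np.zeros((3, 3, 3))
    for m in _active_modes(modes, wavenumber_floor):
        total += _mode_bracket_term(m)
    return total


def beta_v_process(bracket, process: str) -> Beta:
    """Infinite-frequency limit of the vibrational beta for one NLO process.

    EOPE -> (1/3) of the bracket; SHG -> the zero tensor.
    """
    t = bracket.tensor if isinstance(bracket, Beta) else np.asarray(bracket, float)
    p = process.upper()
    if p == "EOPE":
        return Beta(t / 3.0, symmetry=KLEINMAN)
    if p == "SHG":
        return Beta(np.zeros((3, 3, 3)), symmetry=KLEINMAN)
    raise ValueError(f"unknown NLO process {process!r} (expected EOPE or SHG)")


def per_mode_beta_vec(
    modes: Sequence[NormalMode],
    process: str = "EOPE",
    wavenumber_floor: float = DEFAULT_WAVENUMBER_FLOOR,
) -> list[ModeContribution]:
    """Per-mode beta_vec of each single-mode process tensor.

    Note that these scalars are norms of per-mode vectors and do NOT sum to
    the total beta_vec (which must be computed from the summed tensor;
    per-mode vectors can cancel).
    """
    out = []
    for m in _active_modes(modes, wavenumber_floor):
        term = _mode_bracket_term(m)
        bv = beta_vec(beta_v_process(term, process))
        out.append(
            ModeContribution(
                index=m.index,
                bracket=term,
                beta_vec=bv,
                i_ir=ir_intensity(m),
                a_raman=raman_activity(m),
                label=m.label,
            )
        )
    return out


def ir_intensity(mode: NormalMode) -> float:
    """Double-harmonic IR intensity in km/mol: K * |dmu/dQ|^2."""
    return KM_MOL_PER_AU_DIPDERIV_SQ * float(mode.dmu @ mode.dmu)


def raman_invariants(dalpha: np.ndarray) -> tuple[float, float]:
    """Isotropic derivative a' and anisotropy gamma'^2 of a 3x3 derivative."""
    a = np.asarray(dalpha, dtype=float)
    iso = float(np.trace(a)) / 3.0
    g2 = 0.5 * (
        (a[0, 0] - a[1, 1]) ** 2
        + (a[1, 1] - a[2, 2]) ** 2
        + (a[2, 2] - a[0, 0]) ** 2
    ) + 3.0 * (a[0, 1] ** 2 + a[1, 2] ** 2 + a[0, 2] ** 2)
    return iso, float(g2)


def raman_activity(mode: NormalMode, practical_units: bool = True) -> float:
    """Raman scattering activity 45 a'^2 + 7 gamma'^2.

    With ``practical_units`` (default) the result is in Angstrom^4/amu, the
    common tabulation unit; otherwise the raw atomic-unit invariant
    combination is returned.
    """
    iso, g2 = raman_invariants(mode.dalpha)
    activity_au = 45.0 * iso**2 + 7.0 * g2
    if not practical_units:
        return activity_au
    # a.u. derivative is per sqrt(m_e) bohr: rescale to per sqrt(amu) bohr,
    # then bohr^4 -> Angstrom^4.
    return activity_au * _AMU_PER_ME * units.BOHR_TO_ANGSTROM**4
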