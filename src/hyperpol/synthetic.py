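"""Synthetic data with analytically known responses, plus printed goldens.

Everything the analysis stages consume can be generated here with closed-form
expected values: polynomial dipole-vs-field surfaces with prescribed
mu0/alpha/beta/gamma, seeded normal-mode sets with an independently recorded
bracket tensor, and field-shifted Gaussian density grids whose beta is known
from the center-shift algebra.  The printed reference tables ship as a JSON
fixture with verbatim values for golden tests.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from types import SimpleNamespace
from typing import Callable, Sequence

import numpy as np

from .density import GridDensity
from .finite_field import DipoleSamples, FieldStencil
from .tensors import Alpha, Beta, Dipole, Gamma, KLEINMAN, units
from .vibrational import (
    KM_MOL_PER_AU_DIPDERIV_SQ,
    NormalMode,
    _AMU_PER_ME,
)

__all__ = [
    "GaussianBlob",
    "ModelMolecule",
    "PaperFixture",
    "make_model_molecule",
    "make_dipole_surface",
    "sample_surface",
    "make_mode_set",
    "make_density_grids",
    "blob_beta",
    "blob_dipole",
    "make_table2_like_modes",
    "make_dispersion_series",
    "load_reference_fixture",
]


@dataclasses.dataclass(frozen=True)
class GaussianBlob:
    """Normalized Gaussian charge blob with a field-dependent center.

    The center moves as c(F) = c0 + a F + (1/2) b (F x F); because the blob
    is normalized, its contribution to the electronic dipole is exactly
    ``-q c(F)`` and the resulting beta tensor is ``-q b`` (symmetrized in
    the last two indices) in closed form.
    """

    charge: float
    center: np.ndarray
    sigma: float
    shift_linear: np.ndarray  # a[i, j]
    shift_quadratic: np.ndarray  # b[i, j, k], symmetrized over (j, k)

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float)
        a = np.asarray(self.shift_linear, dtype=float)
        b = np.asarray(self.shift_quadratic, dtype=float)
        if c.shape != (3,) or a.shape != (3, 3) or b.shape != (3, 3, 3):
            raise ValueError("blob parameter shapes must be (3,), (3,3), (3,3,3)")
        if self.sigma <= 0:
            raise ValueError("blob width must be positive")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "shift_linear", a)
        object.__setattr__(self, "shift_quadratic", (b + np.transpose(b, (0, 2, 1))) / 2.0)

    def center_at(self, field) -> np.ndarray:
        f = np.asarray(field, dtype=float)
        return (
            self.center
            + self.shift_linear @ f
            + 0.5 * np.einsum("ijk,j,k->i", self.shift_quadratic, f, f)
        )


@dataclasses.dataclass(frozen=True)
class ModelMolecule:
    """Synthetic molecule with prescribed (exactly known) responses."""

    mu0: Dipole
    alpha: Alpha
    beta: Beta
    gamma: Gamma
    modes: tuple = ()
    blobs: tuple = ()
    seed: int = 0


def make_model_molecule(
    seed: int,
    beta_scale: float = 100.0,
    n_modes: int = 0,
    n_blobs: int = 0,
) -> ModelMolecule:
    """Seeded random model molecule; responses mimic the a.u. scale of small
    polar organics (beta sampled in the 10-300 a.u. decade by default)."""
    rng = np.random.default_rng(seed)
    mu0 = Dipole(rng.uniform(-2.0, 2.0, 3))
    a = rng.uniform(-10.0, 10.0, (3, 3))
    alpha = Alpha((a + a.T) / 2.0 + np.eye(3) * 40.0)
    beta = Beta(rng.uniform(-1.0, 1.0, (3, 3, 3)) * beta_scale, symmetry=KLEINMAN)
    gamma = Gamma(rng.uniform(-1.0, 1.0, (3, 3, 3, 3)) * 10.0 * beta_scale)
    modes = ()
    if n_modes:
        modes = tuple(make_mode_set(n_modes, seed=seed + 1)[0])
    blobs = tuple(
        _random_blob(rng, beta_scale=beta_scale) for _ in range(n_blobs)
    )
    return ModelMolecule(
        mu0=mu0, alpha=alpha, beta=beta, gamma=gamma,
        modes=modes, blobs=blobs, seed=seed,
    )


def _random_blob(rng, beta_scale: float = 10.0) -> GaussianBlob:
    return GaussianBlob(
        charge=float(rng.uniform(1.0, 3.0)),
        center=rng.uniform(-1.0, 1.0, 3),
        sigma=1.0,
        shift_linear=rng.uniform(-2.0, 2.0, (3, 3)),
        shift_quadratic=rng.uniform(-1.0, 1.0, (3, 3, 3)) * beta_scale,
    )


def make_dipole_surface(m: ModelMolecule) -> Callable:
    """Exact polynomial dipole surface through the gamma term."""
    mu0 = m.mu0.components
    alpha = m.alpha.matrix
    beta = m.beta.tensor
    gamma = m.gamma.tensor

    def mu(field) -> np.ndarray:
        f = np.asarray(field, dtype=float)
        return (
            mu0
            + alpha @ f
            + 0.5 * np.einsum("ijk,j,k->i", beta, f, f)
            + np.einsum("ijkl,j,k,l->i", gamma, f, f, f) / 6.0
        )

    return mu


def sample_surface(
    m: ModelMolecule, stencil: FieldStencil, provenance: str = "synthetic"
) -> DipoleSamples:
    return DipoleSamples.from_callable(stencil, make_dipole_surface(m), provenance)


def make_mode_set(
    n: int,
    wavenumber_range: tuple = (400.0, 3600.0),
    derivative_scale: float = 0.02,
    seed: int = 0,
):
    """Seeded normal-mode set plus an independently recorded bracket tensor.

    The recorded tensor is evaluated with an explicit (i, j, k, mode) loop,
    deliberately independent of the vectorized implementation it serves as
    an oracle for.
    """
    if n < 1:
        raise ValueError("need at least one mode")
    rng = np.random.default_rng(seed)
    lo, hi = wavenumber_range
    wavenumbers = np.sort(rng.uniform(lo, hi, n))
    modes = []
    for idx, w in enumerate(wavenumbers, start=1):
        dmu = rng.normal(0.0, derivative_scale, 3)
        raw = rng.normal(0.0, derivative_scale, (3, 3))
        dalpha = (raw + raw.T) / 2.0
        modes.append(
            NormalMode(index=idx, wavenumber=float(w), dmu=dmu, dalpha=dalpha)
        )

    recorded = np.zeros((3, 3, 3))
    for mode in modes:
        w_au = mode.wavenumber / units.HARTREE_TO_CM1
        d, a = mode.dmu, mode.dalpha
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    recorded[i, j, k] += (
                        d[i] * a[j, k] + d[j] * a[i, k] + d[k] * a[i, j]
                    ) / w_au**2
    return modes, recorded


def blob_beta(blobs: Sequence[GaussianBlob]) -> np.ndarray:
    """Closed-form beta tensor of a blob set: -sum_b q_b b_(jk-symmetrized)."""
    total = np.zeros((3, 3, 3))
    for blob in blobs:
        total -= blob.charge * blob.shift_quadratic
    return total


def blob_dipole(blobs: Sequence[GaussianBlob], field) -> np.ndarray:
    """Exact electronic dipole of the blob density at an applied field."""
    mu = np.zeros(3)
    for blob in blobs:
        mu -= blob.charge * blob.center_at(field)
    return mu


def make_density_grids(
    blobs: Sequence[GaussianBlob],
    fields: Sequence,
    n: int = 64,
    spacing: float = 0.4,
    margin_sigmas: float = 5.0,
) -> list[GridDensity]:
    """Cubic grids of the blob density at each applied field.

    The grid is centered on the origin with ``n`` voxels of ``spacing`` bohr
    per axis.  Raises when any shifted blob center comes within
    ``margin_sigmas`` standard deviations of the grid boundary (the electron
    count would no longer be conserved to quadrature tolerance).
    """
    blobs = list(blobs)
    if not blobs:
        raise ValueError("need at least one blob")
    half = (n - 1) / 2.0 * spacing
    for blob in blobs:
        for f in fields:
            c = blob.center_at(f)
            reach = float(np.max(np.abs(c))) + margin_sigmas * blob.sigma
            if reach > half:
                raise ValueError(
                    f"grid extent {half:g} bohr too small: blob at field "
                    f"{tuple(np.asarray(f, float))} reaches {reach:g} bohr "
                    f"(center + {margin_sigmas:g} sigma)"
                )
    axes = np.eye(3) * spacing
    origin = np.full(3, -half)
    coords = origin[0] + np.arange(n) * spacing  # same per axis
    grids = []
    for f in fields:
        values = np.zeros((n, n, n))
        for blob in blobs:
            c = blob.center_at(f)
            norm = (2.0 * np.pi * blob.sigma**2) ** -1.5
            gx = np.exp(-((coords - c[0]) ** 2) / (2 * blob.sigma**2))
            gy = np.exp(-((coords - c[1]) ** 2) / (2 * blob.sigma**2))
            gz = np.exp(-((coords - c[2]) ** 2) / (2 * blob.sigma**2))
            values += blob.charge * norm * np.einsum("i,j,k->ijk", gx, gy, gz)
        grids.append(
            GridDensity(origin=origin, axes=axes, values=values,
                        field=np.asarray(f, dtype=float))
        )
    return grids


# ---------------------------------------------------------------------------
# Reference fixture (printed tables) and table-shaped synthetic inputs
# ---------------------------------------------------------------------------


class _ModeRow(SimpleNamespace):
    pass


class PhaseFixture:
    """Attribute access to one phase's printed values.

    Scalar entries of the dipole/beta table become attributes
    (``fixture.gas.beta_zxx``); the per-mode rows are reachable through
    ``mode(index)``.
    """

    def __init__(self, table1: dict, table2: dict):
        self._table1 = dict(table1)
        for key, value in table1.items():
            setattr(self, key, value)
        self.modes = tuple(_ModeRow(**row) for row in table2.get("modes", []))
        self.total_beta_v = table2.get("total_beta_v")
        self.dynamic_beta_e = table2.get("dynamic_beta_e")

    def mode(self, index: int) -> _ModeRow:
        for row in self.modes:
            if row.index == index:
                return row
        raise KeyError(f"no printed row for mode nu_{index}")


class PaperFixture:
    """All printed reference values with verbatim storage and round-trip."""

    def __init__(self, raw: dict):
        self._raw = raw
        self.meta = SimpleNamespace(**raw.get("meta", {}))
        self.gas = PhaseFixture(raw["table1"]["gas"], raw["table2"]["gas"])
        self.water = PhaseFixture(raw["table1"]["water"], raw["table2"]["water"])
        self.claims = SimpleNamespace(**raw["claims"])

    def to_dict(self) -> dict:
        return json.loads(json.dumps(self._raw))

    def to_json(self) -> str:
        return json.dumps(self._raw, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PaperFixture":
        return cls(json.loads(text))


def load_reference_fixture() -> PaperFixture:
    """Load the packaged JSON of printed reference values."""
    text = (
        resources.files("hyperpol.data").joinpath("reference_values.json").read_text()
    )
    return PaperFixture.from_json(text)


def make_table2_like_modes(
    phase: str = "gas",
    include_stretch_modes: bool = True,
    fixture: PaperFixture | None = None,
) -> list[NormalMode]:
    """Normal modes whose IR/Raman sticks reproduce the printed per-mode data.

    Dipole-derivative magnitudes are inverted from the printed IR
    intensities and (isotropic) polarizability derivatives from the printed
    Raman activities, at the printed wavenumbers.  Per-mode beta
    contributions of such a set follow the printed qualitative ordering (the
    derivatives themselves are not published, so exact per-mode values are
    not reproducible).  ``include_stretch_modes`` appends generic C-H/N-H
    stretch-like modes above 3000 cm^-1 with typical intensities.
    """
    fx = fixture or load_reference_fixture()
    rows = getattr(fx, phase).modes
    modes = []
    for row in rows:
        dmu_mag = np.sqrt(row.i_ir / KM_MOL_PER_AU_DIPDERIV_SQ)
        theta = 0.7 * row.index  # deterministic in-plane direction spread
        dmu = dmu_mag * np.array([np.cos(theta), 0.0, np.sin(theta)])
        p = np.sqrt(
            row.a_raman / (45.0 * _AMU_PER_ME * units.BOHR_TO_ANGSTROM**4)
        )
        modes.append(
            NormalMode(
                index=row.index,
                wavenumber=float(row.wavenumber),
                dmu=dmu,
                dalpha=np.eye(3) * p,
                label=row.label,
            )
        )
    if include_stretch_modes:
        for offset, (w, i_ir, a_raman) in enumerate(
            [(3170.0, 5.0, 80.0), (3230.0, 2.0, 60.0), (3580.0, 60.0, 90.0),
             (3620.0, 110.0, 50.0)]
        ):
            dmu_mag = np.sqrt(i_ir / KM_MOL_PER_AU_DIPDERIV_SQ)
            theta = 0.5 * offset
            p = np.sqrt(
                a_raman / (45.0 * _AMU_PER_ME * units.BOHR_TO_ANGSTROM**4)
            )
            modes.append(
                NormalMode(
                    index=27 + offset,
                    wavenumber=w,
                    dmu=dmu_mag * np.array([np.cos(theta), 0.0, np.sin(theta)]),
                    dalpha=np.eye(3) * p,
                    label="nu_XH",
                )
            )
    return modes


def make_dispersion_series(process: str, phase: str, n_samples: int = 15):
    """Dispersion fixtures anchored at the printed static and dynamic values.

    The printed record carries only the static anchor and the value at the
    highest photon energy; intermediate samples are smooth synthetic fill.
    Monotone processes use a quadratic rise/fall; the water SHG curve uses a
    quartic chosen to dip below the EOPE curve at low energy and cross it
    near the printed crossing energy.
    """
    from .spectra import DispersionSeries  # local import to avoid a cycle

    fx = load_reference_fixture()
    hw_max = fx.claims.hw_max
    static = getattr(fx, phase).beta_vec
    x = np.linspace(0.0, 1.0, n_samples)

    if process == "static":
        values = np.full_like(x, static)
    elif process == "EOPE":
        end = getattr(fx, phase).dynamic_beta_e
        values = static + (end - static) * x**2
    elif (process, phase) == ("SHG", "gas"):
        end = static * (1.0 + fx.claims.shg_dispersion_gas_percent / 100.0)
        values = static + (end - static) * x**2
    elif (process, phase) == ("SHG", "water"):
        s1 = fx.claims.shg_dispersion_water_percent / 100.0
        e2 = fx.water.dynamic_beta_e / static - 1.0
        x_star_sq = (fx.claims.crossing_hw_water / hw_max) ** 2
        b = (s1 - e2) / (1.0 - x_star_sq)
        a = s1 - b
        values = static * (1.0 + a * x**2 + b * x**4)
    else:
        raise ValueError(f"no dispersion fixture for ({process!r}, {phase!r})")

    samples = tuple(zip(hw_max * x, values))
    return DispersionSeries(process=process, phase=phase, samples=samples)
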