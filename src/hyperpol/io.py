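"""Text interchange formats: Gaussian cube grids, TSV tables, tensor JSON.

All files are plain text.  Cube values are written with enough digits for a
lossless float round-trip; the applied-field tag rides in the second title
line as ``F= fx fy fz``.  The standard sign convention on voxel counts is
honoured on read: positive counts mean bohr, negative counts mean Angstrom
(converted to bohr internally).
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .density import GridDensity, HyperDensity
from .finite_field import DipoleSamples, FieldStencil, field_key
from .tensors import AXES, Beta, Dipole, units
from .vibrational import NormalMode

__all__ = [
    "read_cube",
    "write_cube",
    "read_mode_table",
    "write_mode_table",
    "read_dipole_samples",
    "write_dipole_samples",
    "read_tensor_json",
    "write_tensor_json",
]


class CubeFormatError(ValueError):
    """Malformed cube file; carries the offending line number."""

    def __init__(self, path, line, message):
        self.line = line
        super().__init__(f"{path}:{line}: {message}")


# ---------------------------------------------------------------------------
# Gaussian cube
# ---------------------------------------------------------------------------

_FIELD_TAG = re.compile(r"F=\s*(\S+)\s+(\S+)\s+(\S+)")


def write_cube(grid, path) -> None:
    """Write a :class:`GridDensity` or :class:`HyperDensity` as a cube file."""
    path = Path(path)
    is_hyper = isinstance(grid, HyperDensity)
    atoms = getattr(grid, "atoms", ())
    field = getattr(grid, "field", np.zeros(3))
    lines = []
    if is_hyper:
        j, k = grid.jk
        lines.append(f"hyperpol rho2 grid jk= {AXES[j]} {AXES[k]}")
        lines.append("F= 0 0 0")
    else:
        lines.append("hyperpol density grid")
        lines.append(f"F= {field[0]:.12g} {field[1]:.12g} {field[2]:.12g}")
    o = grid.origin
    lines.append(f"{len(atoms):5d} {o[0]:23.16E} {o[1]:23.16E} {o[2]:23.16E}")
    for count, axis in zip(grid.shape, grid.axes):
        lines.append(
            f"{count:5d} {axis[0]:23.16E} {axis[1]:23.16E} {axis[2]:23.16E}"
        )
    for z, charge, xyz in atoms:
        lines.append(
            f"{int(z):5d} {charge:23.16E} {xyz[0]:23.16E} {xyz[1]:23.16E} "
            f"{xyz[2]:23.16E}"
        )
    flat = grid.values.reshape(-1)
    for start in range(0, flat.size, 6):
        lines.append(" ".join(f"{v:23.16E}" for v in flat[start:start + 6]))
    path.write_text("\n".join(lines) + "\n")


def read_cube(path) -> GridDensity:
    """Read a cube file into a :class:`GridDensity` (geometry in bohr)."""
    path = Path(path)
    raw = path.read_text().splitlines()

    def need(lineno):
        if lineno >= len(raw):
            raise CubeFormatError(path, lineno + 1, "unexpected end of file")
        return raw[lineno]

    title2 = need(1)
    match = _FIELD_TAG.search(title2)
    field = (
        np.array([float(g) for g in match.groups()]) if match else np.zeros(3)
    )

    def parse(lineno, count, kind=float):
        parts = need(lineno).split()
        if len(parts) < count:
            raise CubeFormatError(
                path, lineno + 1, f"expected {count} fields, got {len(parts)}"
            )
        return [kind(p) for p in parts[:count]]

    try:
        header = parse(2, 4)
    except ValueError as exc:
        raise CubeFormatError(path, 3, f"bad header: {exc}") from None
    natoms = int(header[0])
    origin = np.array(header[1:4])

    counts, axes = [], []
    angstrom = False
    for i in range(3):
        row = parse(3 + i, 4)
        n = int(row[0])
        if n < 0:
            angstrom = True
            n = -n
        counts.append(n)
        axes.append(row[1:4])
    axes = np.array(axes)
    if angstrom:
        axes = axes / units.BOHR_TO_ANGSTROM
        origin = origin / units.BOHR_TO_ANGSTROM

    atoms = []
    for i in range(abs(natoms)):
        row = parse(6 + i, 5)
        atoms.append((int(row[0]), row[1], tuple(row[2:5])))

    first_value_line = 6 + abs(natoms)
    values = []
    for lineno in range(first_value_line, len(raw)):
        for token in raw[lineno].split():
            try:
                values.append(float(token))
            except ValueError:
                raise CubeFormatError(
                    path, lineno + 1, f"bad value token {token!r}"
                ) from None
    expected = counts[0] * counts[1] * counts[2]
    if len(values) != expected:
        raise CubeFormatError(
            path,
            len(raw),
            f"value count mismatch: expected {expected}, got {len(values)}",
        )
    return GridDensity(
        origin=origin,
        axes=axes,
        values=np.array(values).reshape(counts),
        field=field,
        atoms=tuple(atoms),
    )


# ---------------------------------------------------------------------------
# Normal-mode TSV
# ---------------------------------------------------------------------------

_ALPHA_COLS = [f"dalpha_{a}{b}" for a in "xyz" for b in "xyz"]
_MODE_COLS = ["index", "wavenumber_cm1", "dmu_x", "dmu_y", "dmu_z", *_ALPHA_COLS, "label"]


def write_mode_table(modes, path) -> None:
    rows = []
    for m in modes:
        row = {
            "index": m.index,
            "wavenumber_cm1": m.wavenumber,
            "dmu_x": m.dmu[0],
            "dmu_y": m.dmu[1],
            "dmu_z": m.dmu[2],
            "label": m.label,
        }
        for col, (i, j) in zip(_ALPHA_COLS, [(i, j) for i in range(3) for j in range(3)]):
            row[col] = m.dalpha[i, j]
        rows.append(row)
    pd.DataFrame(rows, columns=_MODE_COLS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_mode_table(path) -> list[NormalMode]:
    """Read a mode TSV; validates the symmetry of the alpha derivative."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in _MODE_COLS if c not in df.columns and c != "label"]
    if missing:
        raise ValueError(f"{path}: missing mode-table columns {missing}")
    modes = []
    for _, row in df.iterrows():
        dalpha = np.array(
            [[row[f"dalpha_{a}{b}"] for b in "xyz"] for a in "xyz"]
        )
        modes.append(
            NormalMode(
                index=int(row["index"]),
                wavenumber=float(row["wavenumber_cm1"]),
                dmu=np.array([row["dmu_x"], row["dmu_y"], row["dmu_z"]]),
                dalpha=dalpha,
                label="" if "label" not in df.columns or pd.isna(row.get("label"))
                else str(row["label"]),
            )
        )
    return modes


# ---------------------------------------------------------------------------
# Dipole-sample TSV
# ---------------------------------------------------------------------------


def write_dipole_samples(samples: DipoleSamples, path) -> None:
    st = samples.stencil
    path = Path(path)
    header = [
        f"# provenance: {samples.provenance}",
        f"# base: {st.base:.17g}",
        f"# depth: {len(st.scales)}",
        f"# axes: {','.join(AXES[a] for a in st.axes)}",
        "\t".join(["Fx", "Fy", "Fz", "mu_x", "mu_y", "mu_z"]),
    ]
    lines = list(header)
    for key in sorted(samples.values):
        mu = samples.values[key]
        lines.append(
            "\t".join(f"{v:.17g}" for v in (*key, *mu))
        )
    path.write_text("\n".join(lines) + "\n")


def read_dipole_samples(path) -> DipoleSamples:
    """Read a dipole-sample TSV and validate stencil closure."""
    path = Path(path)
    meta = {}
    rows = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
        elif line and not line.startswith("Fx"):
            parts = [float(p) for p in line.split("\t")]
            if len(parts) != 6:
                raise ValueError(f"{path}: expected 6 columns, got {len(parts)}")
            rows.append(parts)
    if "base" not in meta or "depth" not in meta or "axes" not in meta:
        raise ValueError(f"{path}: missing stencil metadata header")
    from .finite_field import build_stencil

    stencil = build_stencil(
        base=float(meta["base"]),
        ladder_depth=int(meta["depth"]),
        axes=meta["axes"].split(","),
    )
    values = {tuple(r[:3]): np.array(r[3:]) for r in rows}
    keys = {field_key(k) for k in values}
    for k in keys:
        if field_key(tuple(-v for v in k)) not in keys:
            raise ValueError(f"{path}: samples not closed under sign inversion at {k}")
    return DipoleSamples(
        stencil=stencil, values=values, provenance=meta.get("provenance", "external")
    )


# ---------------------------------------------------------------------------
# Tensor JSON
# ---------------------------------------------------------------------------


def write_tensor_json(path, phase: str, mu=None, beta=None, units_label="a.u.") -> None:
    doc: dict = {"phase": phase, "units": units_label}
    if mu is not None:
        mu = mu.components if isinstance(mu, Dipole) else np.asarray(mu, float)
        doc.update(mu_x=mu[0], mu_y=mu[1], mu_z=mu[2])
    if beta is not None:
        t = beta.tensor if isinstance(beta, Beta) else np.asarray(beta, float)
        seen = set()
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    key = "".join(sorted(AXES[i] + AXES[j] + AXES[k]))
                    if key not in seen:
                        seen.add(key)
                        doc[f"beta_{AXES[i]}{AXES[j]}{AXES[k]}"] = t[i, j, k]
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_tensor_json(path) -> dict:
    """Read a tensor JSON into {'phase', 'units', 'mu': Dipole|None, 'beta': Beta|None}.

    The ``units`` field is mandatory; any subset of ``beta_ijk`` keys is
    accepted and completed under Kleinman symmetry.
    """
    doc = json.loads(Path(path).read_text())
    if "units" not in doc:
        raise ValueError(f"{path}: mandatory 'units' field missing")
    if "phase" not in doc:
        raise ValueError(f"{path}: mandatory 'phase' field missing")
    mu = None
    if any(f"mu_{a}" in doc for a in "xyz"):
        mu = Dipole.from_xyz(*(float(doc.get(f"mu_{a}", 0.0)) for a in "xyz"))
    beta_keys = {k: v for k, v in doc.items() if k.startswith("beta_")}
    beta = Beta.from_components(**beta_keys) if beta_keys else None
    return {"phase": doc["phase"], "units": doc["units"], "mu": mu, "beta": beta}
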