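"""Static response extraction from dipole-versus-field samples.

The induced dipole is sampled on a symmetric stencil of applied fields and
the Taylor coefficients mu(0), alpha, beta, gamma are recovered by central
differences, optionally refined by Richardson (Romberg) extrapolation over a
geometric ladder of field strengths.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .tensors import Alpha, Beta, Dipole, Gamma, JK_SYMMETRIC, axis_index

__all__ = [
    "FieldStencil",
    "DipoleSamples",
    "Responses",
    "RombergResult",
    "MissingFieldError",
    "build_stencil",
    "extract_responses",
    "romberg_refine",
    "field_key",
]

#: Fields above this strength (a.u.) start to degrade a Taylor truncation.
DEFAULT_FIELD_CAP = 0.05

_KEY_DECIMALS = 12


def field_key(field) -> tuple[float, float, float]:
    """Canonical hashable key for a field vector (rounded to 1e-12 a.u.)."""
    f = np.asarray(field, dtype=float)
    return tuple(0.0 + round(float(v), _KEY_DECIMALS) for v in f)


class MissingFieldError(KeyError):
    """A required stencil field vector has no dipole sample."""

    def __init__(self, field):
        self.field = tuple(field)
        super().__init__(f"missing dipole sample at field F = {self.field}")

    def __str__(self) -> str:  # KeyError quotes its arg; we want plain text
        return f"missing dipole sample at field F = {self.field}"


@dataclasses.dataclass(frozen=True)
class FieldStencil:
    """Set of applied-field vectors supporting central differences.

    Contains the zero field, is closed under sign inversion, and carries the
    geometric ladder of base strengths (``scales``) used for Romberg
    refinement.
    """

    fields: tuple
    base: float
    scales: tuple
    axes: tuple

    def __post_init__(self):
        keys = {field_key(f) for f in self.fields}
        if field_key((0.0, 0.0, 0.0)) not in keys:
            raise ValueError("stencil must contain the zero field")
        for k in keys:
            if field_key(tuple(-v for v in k)) not in keys:
                raise ValueError(f"stencil not closed under sign inversion at {k}")
        object.__setattr__(
            self, "fields", tuple(np.asarray(f, dtype=float) for f in self.fields)
        )

    def __len__(self) -> int:
        return len(self.fields)

    def keys(self) -> set:
        return {field_key(f) for f in self.fields}


def build_stencil(
    base: float,
    ladder_depth: int,
    axes: Sequence = ("x", "y", "z"),
    cap: float = DEFAULT_FIELD_CAP,
) -> FieldStencil:
    """Build a symmetric field stencil for derivatives up to third order.

    For every scale ``s = base * 2**d`` (``d < ladder_depth``) the stencil
    holds the 1-D points ``+-s, +-2s`` along each requested axis, the four
    cross points ``(+-s, +-s)`` for each axis pair (mixed second and third
    derivatives) and, with three axes, the eight cube corners ``(+-s, +-s,
    +-s)`` for the fully mixed third derivative.
    """
    if base <= 0:
        raise ValueError("base field strength must be positive")
    if ladder_depth < 1:
        raise ValueError("ladder_depth must be >= 1")
    ax = tuple(sorted(axis_index(a) for a in axes))
    if len(set(ax)) != len(ax) or not ax:
        raise ValueError("axes must be a non-empty set of distinct axes")

    scales = tuple(base * 2.0**d for d in range(ladder_depth))
    points: dict[tuple, np.ndarray] = {}

    def add(vec):
        points.setdefault(field_key(vec), np.asarray(vec, dtype=float))

    add((0.0, 0.0, 0.0))
    for s in scales:
        for j in ax:
            for m in (s, 2 * s, -s, -2 * s):
                v = np.zeros(3)
                v[j] = m
                add(v)
        for j, k in itertools.combinations(ax, 2):
            for sj, sk in itertools.product((s, -s), repeat=2):
                v = np.zeros(3)
                v[j], v[k] = sj, sk
                add(v)
        if len(ax) == 3:
            for signs in itertools.product((s, -s), repeat=3):
                add(np.array(signs))

    max_field = 2.0 * max(scales)
    if max_field > cap:
        warnings.warn(
            f"stencil reaches field strength {max_field:g} a.u., above the "
            f"cap of {cap:g} a.u.; truncation of the Taylor expansion may "
            "contaminate the extracted responses",
            stacklevel=2,
        )
    return FieldStencil(
        fields=tuple(points.values()), base=base, scales=scales, axes=ax
    )


@dataclasses.dataclass(frozen=True)
class DipoleSamples:
    """Mapping from applied-field vectors to induced dipoles (a.u.)."""

    stencil: FieldStencil
    values: Mapping
    provenance: str = "synthetic"

    def __post_init__(self):
        vals = {field_key(k): np.asarray(v, dtype=float) for k, v in self.values.items()}
        missing = self.stencil.keys() - set(vals)
        if missing:
            raise MissingFieldError(sorted(missing)[0])
        object.__setattr__(self, "values", vals)

    @classmethod
    def from_callable(cls, stencil: FieldStencil, mu, provenance="synthetic"):
        vals = {field_key(f): np.asarray(mu(f), dtype=float) for f in stencil.fields}
        return cls(stencil=stencil, values=vals, provenance=provenance)

    def mu(self, field) -> np.ndarray:
        try:
            return self.values[field_key(field)]
        except KeyError:
            raise MissingFieldError(field_key(field)) from None


class Responses(NamedTuple):
    mu: Dipole
    alpha: Alpha
    beta: Beta
    gamma: Gamma


class RombergResult(NamedTuple):
    value: float
    table: list
    error: float


def _richardson(estimates: Sequence[np.ndarray], ratio: float) -> list:
    """Richardson triangle for an even (h^2) error series.

    ``estimates`` are ordered from the largest to the smallest step; returns
    the full triangular table, ``table[k][m]``.
    """
    t = ratio * ratio
    table = [[np.asarray(e, dtype=float)] for e in estimates]
    for k in range(1, len(estimates)):
        for m in range(1, k + 1):
            prev, above = table[k][m - 1], table[k - 1][m - 1]
            table[k].append(prev + (prev - above) / (t**m - 1.0))
    return table


def romberg_refine(estimates: Sequence[tuple]) -> RombergResult:
    """Richardson-extrapolate derivative estimates on a geometric step ladder.

    Parameters
    ----------
    estimates
        Sequence of ``(step, value)`` pairs at geometrically related steps.

    Returns the extrapolated value, the triangular convergence table, and an
    error estimate (difference of the last two diagonal entries).
    """
    if len(estimates) < 1:
        raise ValueError("need at least one estimate")
    ordered = sorted(estimates, key=lambda sv: -sv[0])
    steps = [s for s, _ in ordered]
    values = [v for _, v in ordered]
    if len(steps) == 1:
        return RombergResult(float(values[0]), [[float(values[0])]], float("nan"))
    ratios = [steps[i] / steps[i + 1] for i in range(len(steps) - 1)]
    if any(abs(r - ratios[0]) > 1e-9 * ratios[0] for r in ratios):
        raise ValueError(f"step ladder is not geometric: steps {steps}")
    table = _richardson(values, ratios[0])
    diag = [table[k][k] for k in range(len(table))]
    err = abs(float(diag[-1]) - float(diag[-2]))
    return RombergResult(float(diag[-1]), [[float(v) for v in row] for row in table], err)


def _estimates_at_scale(samples: DipoleSamples, s: float, axes):
    """Central-difference alpha/beta/gamma estimates at one field scale."""

    def mu(*pairs):
        v = np.zeros(3)
        for j, m in pairs:
            v[j] += m
        return samples.mu(v)

    mu0 = samples.mu((0.0, 0.0, 0.0))
    alpha = np.zeros((3, 3))
    beta = np.zeros((3, 3, 3))
    gamma = np.zeros((3, 3, 3, 3))

    for j in axes:
        p, m = mu((j, s)), mu((j, -s))
        p2, m2 = mu((j, 2 * s)), mu((j, -2 * s))
        alpha[:, j] = (p - m) / (2 * s)
        beta[:, j, j] = (p - 2 * mu0 + m) / s**2
        gamma[:, j, j, j] = (p2 - 2 * p + 2 * m - m2) / (2 * s**3)

    for j, k in itertools.combinations(axes, 2):
        pp = mu((j, s), (k, s))
        pm = mu((j, s), (k, -s))
        mp = mu((j, -s), (k, s))
        mm = mu((j, -s), (k, -s))
        cross = (pp - pm - mp + mm) / (4 * s**2)
        beta[:, j, k] = beta[:, k, j] = cross
        # d^3 mu / dF_j dF_k^2 and the j<->k partner; every permutation of the
        # index multiset is populated so downstream symmetrization is a no-op.
        pj, mj = mu((j, s)), mu((j, -s))
        pk, mk = mu((k, s)), mu((k, -s))
        d_jkk = (pp + pm - 2 * pj - mp - mm + 2 * mj) / (2 * s**3)
        d_kjj = (pp + mp - 2 * pk - pm - mm + 2 * mk) / (2 * s**3)
        gamma[:, j, k, k] = gamma[:, k, j, k] = gamma[:, k, k, j] = d_jkk
        gamma[:, k, j, j] = gamma[:, j, k, j] = gamma[:, j, j, k] = d_kjj

    if len(axes) == 3:
        acc = np.zeros(3)
        for signs in itertools.product((1.0, -1.0), repeat=3):
            acc += np.prod(signs) * mu(*[(j, sg * s) for j, sg in zip(axes, signs)])
        d_xyz = acc / (8 * s**3)
        for perm in itertools.permutations((0, 1, 2)):
            gamma[:, perm[0], perm[1], perm[2]] = d_xyz

    # alpha columns for unsampled field axes are filled by symmetry where the
    # transposed element is known (rows are always complete).
    for j in range(3):
        if j not in axes:
            for i in axes:
                alpha[i, j] = alpha[j, i]

    return mu0, alpha, beta, gamma


def extract_responses(samples: DipoleSamples, refine: bool = True) -> Responses:
    """Recover (mu(0), alpha, beta, gamma) from a dipole-field sample set.

    ``beta[i, j, k]`` is the pure second derivative of mu_i (Taylor
    convention); the raw tensor is jk-symmetric by construction.  With a
    ladder of two or more field scales the per-scale central-difference
    estimates are Richardson-refined, removing the leading even-order
    truncation errors.
    """
    st = samples.stencil
    axes = st.axes
    per_scale = [_estimates_at_scale(samples, s, axes) for s in st.scales]
    mu0 = per_scale[0][0]

    def refine_stack(idx):
        stack = [ps[idx] for ps in per_scale]
        if len(stack) == 1 or not refine:
            return stack[0]
        # largest step first for the Richardson triangle
        ratio = st.scales[1] / st.scales[0]
        table = _richardson(stack[::-1], ratio)
        return table[-1][-1]

    alpha = refine_stack(1)
    beta = refine_stack(2)
    gamma = refine_stack(3)
    return Responses(
        mu=Dipole(mu0),
        alpha=Alpha(alpha, tolerance=None),
        beta=Beta(beta, symmetry=JK_SYMMETRIC),
        gamma=Gamma(gamma),
    )
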