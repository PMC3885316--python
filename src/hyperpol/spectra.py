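"""Lorentzian spectral simulation and frequency-dispersion bookkeeping.

Stick spectra (IR intensities or Raman activities per mode) are broadened
with area-normalized Lorentzians so that the integral over an isolated peak
equals its stick intensity.  Dispersion series hold the frequency dependence
of beta_vec for one NLO process in one phase and support percent-dispersion,
solvent-ratio and curve-crossing queries without extrapolation.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .tensors import percent_change

__all__ = [
    "StickSpectrum",
    "DispersionSeries",
    "lorentzian",
    "broaden",
    "dispersion_percent",
    "solvent_ratio",
    "find_crossing",
    "vib_electronic_ratio",
]


@dataclasses.dataclass(frozen=True)
class StickSpectrum:
    """Discrete spectrum: (position cm^-1, intensity) sticks of one kind."""

    sticks: tuple
    kind: str = "IR"  # "IR" or "Raman"
    phase: str = "gas"

    def __post_init__(self):
        sticks = tuple((float(p), float(i)) for p, i in self.sticks)
        if any(i < 0 for _, i in sticks):
            raise ValueError("stick intensities must be non-negative")
        if self.kind not in ("IR", "Raman"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        object.__setattr__(self, "sticks", sticks)

    def total_intensity(self) -> float:
        return sum(i for _, i in self.sticks)


def lorentzian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Area-normalized Lorentzian; peak value is 2/(pi*fwhm)."""
    half = fwhm / 2.0
    return (half / np.pi) / ((np.asarray(x, dtype=float) - center) ** 2 + half**2)


def broaden(spectrum: StickSpectrum, fwhm: float, grid: np.ndarray) -> np.ndarray:
    """Sum of intensity-scaled area-normalized Lorentzians on ``grid``."""
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    grid = np.asarray(grid, dtype=float)
    out = np.zeros_like(grid)
    for position, intensity in spectrum.sticks:
        out += intensity * lorentzian(grid, position, fwhm)
    return out


@dataclasses.dataclass(frozen=True)
class DispersionSeries:
    """beta_vec versus optical photon energy for one process and phase.

    ``samples`` are (h-bar omega in a.u., beta_vec in a.u.) pairs, strictly
    increasing in energy and anchored at the static value (h-bar omega = 0).
    """

    process: str  # "static", "EOPE" or "SHG"
    phase: str  # "gas" or "water"
    samples: tuple

    def __post_init__(self):
        if self.process not in ("static", "EOPE", "SHG"):
            raise ValueError(f"unknown NLO process {self.process!r}")
        samples = tuple((float(h), float(b)) for h, b in self.samples)
        hws = [h for h, _ in samples]
        if not samples or hws[0] != 0.0:
            raise ValueError("series must start at the static anchor (hw = 0)")
        if any(h < 0 for h in hws):
            raise ValueError("photon energies must be non-negative")
        if any(b <= a for a, b in zip(hws, hws[1:])):
            raise ValueError("photon energies must be strictly increasing")
        object.__setattr__(self, "samples", samples)

    @property
    def energies(self) -> np.ndarray:
        return np.array([h for h, _ in self.samples])

    @property
    def values(self) -> np.ndarray:
        return np.array([b for h, b in self.samples])

    def beta_at(self, hw: float) -> float:
        """Value at ``hw``: exact sample if present, else nearest sample.

        No extrapolation: ``hw`` outside the sampled range raises.
        """
        hws = self.energies
        if hw < hws[0] - 1e-15 or hw > hws[-1] + 1e-15:
            raise ValueError(
                f"hw = {hw:g} a.u. outside the sampled range "
                f"[{hws[0]:g}, {hws[-1]:g}]"
            )
        idx = int(np.argmin(np.abs(hws - hw)))
        return float(self.values[idx])


def dispersion_percent(series: DispersionSeries, hw: float) -> float:
    """Percent change of beta_vec at ``hw`` relative to the static anchor."""
    return percent_change(series.beta_at(0.0), series.beta_at(hw))


def solvent_ratio(
    water: DispersionSeries, gas: DispersionSeries, hw: float
) -> float:
    """beta_vec(water) / beta_vec(gas) at the same process and energy."""
    if water.process != gas.process:
        raise ValueError(
            f"process mismatch: {water.process!r} vs {gas.process!r}"
        )
    return water.beta_at(hw) / gas.beta_at(hw)


def find_crossing(a: DispersionSeries, b: DispersionSeries):
    """Smallest hw in the common sampled range where sign(a - b) changes.

    Both series are linearly interpolated onto the union of their sample
    energies; the crossing is located by linear interpolation between the
    bracketing points.  Returns ``None`` when the difference never changes
    sign (points where the difference is exactly zero do not count as a
    change unless flanked by opposite signs).
    """
    lo = max(a.energies[0], b.energies[0])
    hi = min(a.energies[-1], b.energies[-1])
    if hi <= lo:
        return None
    grid = np.unique(np.concatenate([a.energies, b.energies]))
    grid = grid[(grid >= lo) & (grid <= hi)]
    fa = np.interp(grid, a.energies, a.values)
    fb = np.interp(grid, b.energies, b.values)
    d = fa - fb
    for i in range(len(grid) - 1):
        if d[i] == 0.0:
            if 0 < i and d[i - 1] * d[i + 1] < 0:
                return float(grid[i])
            continue
        if d[i] * d[i + 1] < 0:
            t = d[i] / (d[i] - d[i + 1])
            return float(grid[i] + t * (grid[i + 1] - grid[i]))
    if d[-1] == 0.0 and len(d) > 1 and d[-2] != 0.0:
        return float(grid[-1])
    return None


def vib_electronic_ratio(beta_v: float, beta_e: float) -> float:
    """Ratio of vibrational to electronic beta_vec for one process/phase."""
    if beta_e == 0:
        raise ValueError("electronic beta_vec must be nonzero")
    return beta_v / beta_e
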