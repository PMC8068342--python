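"""Secondary-electron fluence spectra and dose-weighted spectral averaging.

For photon qualities the damage yield Y and mutation frequency P are
dose-weighted means over the secondary-electron fluence spectrum:

    <Y> = int Y(E) Phi(E) LET(E) dE / int Phi(E) LET(E) dE

evaluated by trapezoidal quadrature on the common energy grid, with
log-log interpolation of the stopping power and linear interpolation of
the energy-resolved curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def _validated_grid(energy, values, name):
    energy = np.asarray(energy, dtype=float)
    values = np.asarray(values, dtype=float)
    if energy.ndim != 1 or energy.size < 2:
        raise ValueError(f"{name}: need a 1-D energy grid with >= 2 points")
    if (np.diff(energy) <= 0).any():
        raise ValueError(f"{name}: energy grid must be strictly increasing")
    if values.shape != energy.shape:
        raise ValueError(f"{name}: values must match the energy grid")
    return energy, values


@dataclass(frozen=True)
class FluenceSpectrum:
    """Energy fluence Phi(E) of secondary electrons (arbitrary units)."""

    energy_mev: np.ndarray
    fluence: np.ndarray

    def __post_init__(self):
        energy, fluence = _validated_grid(self.energy_mev, self.fluence,
                                          "FluenceSpectrum")
        if (fluence < 0).any():
            raise ValueError("fluence must be non-negative")
        if not (fluence > 0).any():
            raise ValueError("fluence is identically zero")
        object.__setattr__(self, "energy_mev", energy)
        object.__setattr__(self, "fluence", fluence)


@dataclass(frozen=True)
class StoppingPowerTable:
    """Unrestricted LET (keV/um) vs energy; interpolated linearly in
    log-log space."""

    energy_mev: np.ndarray
    let_kev_um: np.ndarray

    def __post_init__(self):
        energy, let = _validated_grid(self.energy_mev, self.let_kev_um,
                                      "StoppingPowerTable")
        if (let <= 0).any():
            raise ValueError("stopping power must be positive")
        object.__setattr__(self, "energy_mev", energy)
        object.__setattr__(self, "let_kev_um", let)

    def __call__(self, energy) -> np.ndarray:
        energy = np.asarray(energy, dtype=float)
        loglet = np.interp(np.log(energy), np.log(self.energy_mev),
                           np.log(self.let_kev_um))
        return np.exp(loglet)


@dataclass(frozen=True)
class EnergyResolvedYield:
    """An energy-resolved quantity Y(E) or P(E) (per Gy per Gbp)."""

    energy_mev: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        energy, values = _validated_grid(self.energy_mev, self.values,
                                         "EnergyResolvedYield")
        if (values < 0).any():
            raise ValueError("yields must be non-negative")
        object.__setattr__(self, "energy_mev", energy)
        object.__setattr__(self, "values", values)

    def __call__(self, energy) -> np.ndarray:
        return np.interp(np.asarray(energy, dtype=float),
                         self.energy_mev, self.values)


def spectrum_average(curve: EnergyResolvedYield,
                     spectrum: FluenceSpectrum,
                     let: StoppingPowerTable) -> float:
    """Dose-weighted spectral mean of ``curve`` (units of the curve).

    The weight is w(E) = Phi(E) * LET(E) on the spectrum grid restricted to
    the overlap of all three supports.
    """
    lo = max(curve.energy_mev[0], spectrum.energy_mev[0], let.energy_mev[0])
    hi = min(curve.energy_mev[-1], spectrum.energy_mev[-1], let.energy_mev[-1])
    if lo >= hi:
        # single-point overlap still works for a delta-like evaluation
        mask = np.isclose(spectrum.energy_mev, lo) & np.isclose(
            spectrum.energy_mev, hi)
        if lo > hi or not mask.any():
            raise ValueError("energy supports do not overlap")
        return float(curve(lo))
    mask = (spectrum.energy_mev >= lo) & (spectrum.energy_mev <= hi)
    grid = spectrum.energy_mev[mask]
    if grid.size == 1:
        return float(curve(grid[0]))
    weights = spectrum.fluence[mask] * let(grid)
    denom = np.trapezoid(weights, grid)
    if denom <= 0:
        raise ValueError("total spectral weight is zero on the overlap")
    return float(np.trapezoid(curve(grid) * weights, grid) / denom)


def read_two_column_csv(path) -> tuple:
    """Read an (energy, value) CSV with '#'-comment header lines."""
    frame = pd.read_csv(path, comment="#", header=None,
                        names=["energy", "value"])
    return frame["energy"].to_numpy(float), frame["value"].to_numpy(float)


def write_two_column_csv(path, energy, values, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for e, v in zip(energy, values):
            fh.write(f"{e:.8g},{v:.8g}\n")
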