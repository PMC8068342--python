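"""Synthetic inputs: parametric electron spectra and toy lesion clusters.

No measured secondary-electron spectrum ships with the package, so a
log-normal fluence shape with a smooth power-law stopping-power table acts
as a stand-in for testing the dose-weighted averaging; it is synthetic and
labelled as such.  Toy clusters give deterministic inputs for the
classification and repair unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .induction import BASE_DAMAGE, STRAND_BREAK, DamageCluster, Lesion
from .spectra import FluenceSpectrum, StoppingPowerTable, spectrum_average
from .spectra import EnergyResolvedYield


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic log-normal electron spectrum."""

    median_mev: float = 0.3
    log_width: float = 0.8
    n_points: int = 64
    e_min_mev: float = 0.01
    e_max_mev: float = 10.0
    let_scale: float = 2.0     # keV/um at 1 MeV
    let_slope: float = -0.35   # power-law exponent of LET vs energy
    seed: int = 0

    def __post_init__(self):
        if self.log_width <= 0:
            raise ValueError("log_width must be > 0")
        if self.n_points < 8:
            raise ValueError("grid must have >= 8 points")
        if not 0 < self.e_min_mev < self.e_max_mev:
            raise ValueError("need 0 < e_min < e_max")


def make_synthetic_spectrum(spec: FixtureSpec = FixtureSpec()) -> tuple:
    """Build a (FluenceSpectrum, StoppingPowerTable) pair.

    The fluence is a log-normal in energy; the stopping power is a smooth
    positive power law.  The dose-weighted mean LET is reported in the
    returned spectrum's metadata tuple element.
    """
    energy = np.geomspace(spec.e_min_mev, spec.e_max_mev, spec.n_points)
    z = (np.log(energy) - np.log(spec.median_mev)) / spec.log_width
    fluence = np.exp(-0.5 * z * z) / energy
    spectrum = FluenceSpectrum(energy, fluence)
    let = StoppingPowerTable(energy,
                             spec.let_scale * energy ** spec.let_slope)
    return spectrum, let


def dose_weighted_mean_let(spectrum: FluenceSpectrum,
                           let: StoppingPowerTable) -> float:
    """Dose-weighted mean LET of a spectrum (keV/um)."""
    curve = EnergyResolvedYield(let.energy_mev, let.let_kev_um)
    return spectrum_average(curve, spectrum, let)


def make_reference_photon_spectrum(target_mean_let: float = 2.4,
                                   spec: FixtureSpec = FixtureSpec()) -> tuple:
    """Synthetic photon-like spectrum tuned so the dose-weighted mean LET
    matches a requested value (default: the 2.4 keV/um conventionally quoted
    for Co-60 gamma-ray secondary electrons)."""
    def mean_let(scale):
        s, l = make_synthetic_spectrum(
            FixtureSpec(**{**spec.__dict__, "let_scale": float(scale)}))
        return dose_weighted_mean_let(s, l)

    # mean LET is proportional to let_scale, so one evaluation suffices
    base = mean_let(spec.let_scale)
    scale = spec.let_scale * target_mean_let / base
    return make_synthetic_spectrum(
        FixtureSpec(**{**spec.__dict__, "let_scale": float(scale)}))


def make_toy_clusters(recipe, segment_length: int = 25) -> list:
    """Deterministic clusters from explicit lesion lists.

    ``recipe`` is an iterable of lesion lists, each lesion a tuple
    ``(position, strand, kind)`` with kind in {"strand-break",
    "base-damage"} (or the shorthand "sb"/"bd").
    """
    kinds = {"sb": STRAND_BREAK, "bd": BASE_DAMAGE,
             STRAND_BREAK: STRAND_BREAK, BASE_DAMAGE: BASE_DAMAGE}
    clusters = []
    for lesion_list in recipe:
        lesions = []
        for pos, strand, kind in lesion_list:
            if kind not in kinds:
                raise ValueError(f"unknown lesion kind {kind!r}")
            lesions.append(Lesion(int(pos), int(strand), kinds[kind]))
        clusters.append(DamageCluster(lesions, segment_length=segment_length))
    return clusters
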