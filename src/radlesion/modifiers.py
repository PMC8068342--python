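"""Per-lesion survival models for radical scavenging (DMSO) and oxygen.

Both modifiers act on individual lesions *before* damage classification:
each lesion survives a Bernoulli trial with the environment's survival
factor.  The quasi-quadratic response of DSB yields (and the weaker response
of simple damage) then emerges from the clustering alone.

DMSO: ``s(c) = FNSD + (1 - FNSD) * CHMX / (CHMX + c)`` — a hyperbola from 1
at zero scavenger down to the non-scavengeable fraction ``FNSD``; ``CHMX``
is the concentration halving the scavengeable component.

Oxygen: an Alper–Howard-Flanders-type hyperbola
``h(x) = (m * x + K) / (x + K)`` normalised to 1 at the aerobic reference
(21% O2 by default), so the factor falls toward ``1/h(ref)`` in anoxia.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np


@dataclass(frozen=True)
class ScavengerParams:
    """Hyperbolic scavenger model: non-scavengeable fraction and
    half-effect concentration (mol/L)."""

    fnsd: float
    chmx: float

    def __post_init__(self):
        if not 0 < self.fnsd <= 1:
            raise ValueError("fnsd must lie in (0, 1]")
        if self.chmx <= 0:
            raise ValueError("chmx must be > 0")


@dataclass(frozen=True)
class OxygenParams:
    """Lesion-level oxygen effect: maximal modification ``m_lesion``,
    half-effect concentration ``k_o2`` (% O2) and the reference oxygen
    tension at which the survival factor is 1."""

    m_lesion: float = 1.75
    k_o2: float = 0.7
    reference_o2: float = 21.0

    def __post_init__(self):
        if self.m_lesion < 1:
            raise ValueError("m_lesion must be >= 1")
        if self.k_o2 <= 0:
            raise ValueError("k_o2 must be > 0")
        if not 0 < self.reference_o2 <= 100:
            raise ValueError("reference_o2 must lie in (0, 100]")


@dataclass(frozen=True)
class EnvironmentCondition:
    """Chemical environment of the irradiated cells."""

    dmso_M: float = 0.0
    o2_percent: float = 21.0

    def __post_init__(self):
        if self.dmso_M < 0:
            raise ValueError("dmso_M must be >= 0")
        if not 0 <= self.o2_percent <= 100:
            raise ValueError("o2_percent must lie in [0, 100]")


def dmso_survival_factor(c: float, params: ScavengerParams) -> float:
    """Fraction of lesions surviving scavenging at DMSO concentration ``c``.

    Equals 1 at c = 0, decreases monotonically and tends to ``fnsd`` as
    c -> infinity; at ``c = chmx`` the scavengeable component is halved.
    """
    if c < 0:
        raise ValueError("DMSO concentration must be >= 0")
    return params.fnsd + (1.0 - params.fnsd) * params.chmx / (params.chmx + c)


def _oxygen_h(o2: float, params: OxygenParams) -> float:
    return (params.m_lesion * o2 + params.k_o2) / (o2 + params.k_o2)


def oxygen_survival_factor(o2: float, params: OxygenParams) -> float:
    """Lesion survival factor at oxygen tension ``o2`` (% O2), normalised
    to 1 at the reference tension; monotone non-decreasing in ``o2``."""
    if not 0 <= o2 <= 100:
        raise ValueError("o2 must lie in [0, 100] percent")
    return _oxygen_h(o2, params) / _oxygen_h(params.reference_o2, params)


def combined_survival(env: EnvironmentCondition, quality) -> float:
    """Product of the DMSO and oxygen survival factors (independent,
    multiplicative mechanisms)."""
    return dmso_survival_factor(env.dmso_M, quality.scavenger) * \
        oxygen_survival_factor(env.o2_percent, quality.oxygen)


def thin_lesions(clusters, survival: float,
                 rng: Optional[np.random.Generator] = None,
                 uniforms: Optional[np.ndarray] = None):
    """Retain each lesion independently with probability ``survival``.

    Clusters emptied by thinning are discarded; cluster identity, segment
    positions and the recorded exposure are preserved.  Passing a shared
    ``uniforms`` array (one draw per lesion) couples thinning across
    survival levels: the survivors at a lower factor are then a subset of
    the survivors at any higher factor.
    """
    from .induction import ClusterPopulation

    if not 0 <= survival <= 1:
        raise ValueError("survival must lie in [0, 1]")
    as_list = not isinstance(clusters, ClusterPopulation)
    pop = ClusterPopulation.from_clusters(clusters) if as_list else clusters
    if uniforms is None:
        if rng is None:
            rng = np.random.default_rng()
        uniforms = rng.random(pop.n_lesions)
    elif uniforms.shape != (pop.n_lesions,):
        raise ValueError("uniforms must have one entry per lesion")
    keep = uniforms < survival
    sizes = np.bincount(pop.cluster_ids()[keep], minlength=len(pop))
    nonempty = sizes > 0
    offsets = np.concatenate(([0], np.cumsum(sizes[nonempty]))).astype(np.int64)
    thinned = ClusterPopulation(
        pop.positions[keep], pop.strands[keep], pop.is_break[keep], offsets,
        pop.nseg, pop.exposure_gy_gbp,
        meta={**pop.meta, "survival": float(survival)},
    )
    return list(thinned) if as_list else thinned
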