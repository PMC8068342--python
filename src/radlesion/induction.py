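"""Clustered DNA-lesion induction and damage classification.

A single radiation track deposits a *cluster* of elementary lesions (strand
breaks and base damages) within a short DNA segment.  Each cluster is
classified as one damage site using the standard taxonomy: base damage only
(BD), single-strand breaks (SSB, SSB+, 2SSB) and double-strand breaks (DSB,
DSB+, DSB++), where opposite-strand breaks within 10 bp constitute a DSB.

The sampling model: the number of clusters per exposure is Poisson with mean
``cluster_rate_rho * dose * genome_gbp``; each cluster carries ``1 +
Poisson(multiplicity_nu)`` lesions with i.i.d. uniform integer positions on
``[0, nseg)``, fair-coin strands and strand-break probability
``p_strand_break`` per lesion.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

from ._kernels import (
    BD,
    CLASS_CODES,
    CLASS_NAMES,
    DSB,
    DSBP,
    DSBPP,
    EMPTY,
    SSB,
    SSB2,
    SSBP,
    classify_flat,
)
from .modifiers import OxygenParams, ScavengerParams

STRAND_BREAK = "strand-break"
BASE_DAMAGE = "base-damage"

#: bp window within which opposite-strand breaks are scored as one DSB
DSB_PAIRING_DISTANCE_BP = 10

#: classes reported in yield tables, in column order
YIELD_CLASSES = ("BD", "SSB", "SSB+", "2SSB", "DSB", "DSB+", "DSB++")
SSB_CLASSES = ("SSB", "SSB+", "2SSB")
DSB_CLASSES = ("DSB", "DSB+", "DSB++")
NON_DSB_CLASSES = ("BD", "SSB", "SSB+", "2SSB")


@dataclass(frozen=True)
class Lesion:
    """One elementary damage: a strand break or a base damage."""

    position: int
    strand: int
    kind: str

    def __post_init__(self):
        if self.position < 0:
            raise ValueError(f"lesion position must be >= 0, got {self.position}")
        if self.strand not in (0, 1):
            raise ValueError(f"strand must be 0 or 1, got {self.strand}")
        if self.kind not in (STRAND_BREAK, BASE_DAMAGE):
            raise ValueError(f"unknown lesion kind {self.kind!r}")

    @property
    def is_break(self) -> bool:
        return self.kind == STRAND_BREAK


@dataclass
class DamageCluster:
    """A track-correlated group of lesions scored as one damage site."""

    lesions: list
    segment_length: int = 25

    def __post_init__(self):
        if self.segment_length <= 10:
            raise ValueError("segment_length must exceed 10 bp")
        for les in self.lesions:
            if not 0 <= les.position < self.segment_length:
                raise ValueError(
                    f"lesion position {les.position} outside segment "
                    f"[0, {self.segment_length})"
                )
        self.lesions = sorted(self.lesions, key=lambda l: (l.position, l.strand))

    def __len__(self):
        return len(self.lesions)


@dataclass
class RadiationQuality:
    """Per-radiation parameter bundle.

    ``let_keV_um`` is a label; the damage spectrum is controlled by the
    cluster rate (clusters / Gy / Gbp), the mean extra-lesion count per
    cluster, the per-lesion strand-break probability and the segment length.
    """

    name: str
    let_keV_um: float
    cluster_rate_rho: float
    multiplicity_nu: float
    p_strand_break: float
    nseg: int = 25
    scavenger: ScavengerParams = field(
        default_factory=lambda: ScavengerParams(fnsd=0.52, chmx=0.21)
    )
    oxygen: OxygenParams = field(default_factory=OxygenParams)
    meta: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self):
        if self.cluster_rate_rho <= 0:
            raise ValueError("cluster_rate_rho must be > 0")
        if self.multiplicity_nu < 0:
            raise ValueError("multiplicity_nu must be >= 0")
        if not 0 < self.p_strand_break < 1:
            raise ValueError("p_strand_break must lie in (0, 1)")
        if self.nseg <= 10:
            raise ValueError("nseg must exceed 10 bp")


@dataclass
class SimulationConfig:
    """Exposure and error-control settings for one simulation run."""

    dose_gy: float = 1.0
    genome_gbp: float = 1.0
    per_cell_factor: float = 6.0
    n_clusters_min: int = 0
    fixed_count: bool = False
    seed: Optional[int] = None

    def __post_init__(self):
        if self.dose_gy <= 0:
            raise ValueError("dose_gy must be > 0")
        if self.genome_gbp <= 0:
            raise ValueError("genome_gbp must be > 0")
        if self.per_cell_factor <= 0:
            raise ValueError("per_cell_factor must be > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


class ClusterPopulation(Sequence):
    """Flat, array-backed collection of :class:`DamageCluster`.

    Lesions of all clusters are stored in parallel arrays sorted by
    (cluster, position, strand); ``offsets`` delimits clusters.  The
    population records the exposure (Gy x Gbp) it represents so that yields
    can be normalised after fixed-count generation or thinning.
    """

    def __init__(self, positions, strands, is_break, offsets, nseg,
                 exposure_gy_gbp, meta=None):
        self.positions = np.asarray(positions, dtype=np.int32)
        self.strands = np.asarray(strands, dtype=np.int8)
        self.is_break = np.asarray(is_break, dtype=bool)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.nseg = int(nseg)
        self.exposure_gy_gbp = float(exposure_gy_gbp)
        self.meta = dict(meta or {})

    # -- Sequence protocol ------------------------------------------------
    def __len__(self) -> int:
        return self.offsets.size - 1

    def __getitem__(self, idx):
        if isinstance(idx, slice):
            return [self[i] for i in range(*idx.indices(len(self)))]
        i0, i1 = self.offsets[idx], self.offsets[idx + 1]
        lesions = [
            Lesion(
                int(self.positions[i]),
                int(self.strands[i]),
                STRAND_BREAK if self.is_break[i] else BASE_DAMAGE,
            )
            for i in range(i0, i1)
        ]
        return DamageCluster(lesions, segment_length=self.nseg)

    # -- helpers -----------------------------------------------------------
    @property
    def n_lesions(self) -> int:
        return self.positions.size

    def cluster_sizes(self) -> np.ndarray:
        return np.diff(self.offsets)

    def cluster_ids(self) -> np.ndarray:
        return np.repeat(np.arange(len(self)), self.cluster_sizes())

    @classmethod
    def from_clusters(cls, clusters: Iterable[DamageCluster],
                      exposure_gy_gbp: float = 1.0) -> "ClusterPopulation":
        clusters = list(clusters)
        nseg = clusters[0].segment_length if clusters else 25
        pos, strand, isb, offsets = [], [], [], [0]
        for c in clusters:
            if c.segment_length != nseg:
                raise ValueError("all clusters must share one segment length")
            for les in c.lesions:
                pos.append(les.position)
                strand.append(les.strand)
                isb.append(les.is_break)
            offsets.append(len(pos))
        return cls(pos, strand, isb, offsets, nseg, exposure_gy_gbp)


@dataclass
class DamageYields:
    """Per-class damage yields (per Gy per Gbp) with Monte Carlo errors."""

    counts: dict
    exposure_gy_gbp: float
    per_cell_factor: float = 6.0
    meta: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self):
        if self.exposure_gy_gbp <= 0:
            raise ValueError("exposure (dose x genome) must be > 0")
        self.counts = {c: int(self.counts.get(c, 0)) for c in YIELD_CLASSES}

    def yield_of(self, cls: str) -> float:
        return self.counts[cls] / self.exposure_gy_gbp

    def se_of(self, cls: str) -> float:
        return np.sqrt(self.counts[cls]) / self.exposure_gy_gbp

    def _group(self, classes) -> tuple:
        n = sum(self.counts[c] for c in classes)
        return n / self.exposure_gy_gbp, np.sqrt(n) / self.exposure_gy_gbp

    @property
    def total_ssb(self) -> float:
        return self._group(SSB_CLASSES)[0]

    @property
    def total_ssb_se(self) -> float:
        return self._group(SSB_CLASSES)[1]

    @property
    def total_dsb(self) -> float:
        return self._group(DSB_CLASSES)[0]

    @property
    def total_dsb_se(self) -> float:
        return self._group(DSB_CLASSES)[1]

    @property
    def total_damage(self) -> float:
        return self._group(YIELD_CLASSES)[0]

    @property
    def total_damage_se(self) -> float:
        return self._group(YIELD_CLASSES)[1]

    def per_cell(self, cls: str) -> float:
        """Yield per Gy per cell using the genome-size conversion factor."""
        return self.yield_of(cls) * self.per_cell_factor

    def to_dict(self) -> dict:
        out = {}
        for c in YIELD_CLASSES:
            out[c] = self.yield_of(c)
            out[f"{c}_se"] = self.se_of(c)
        out["Total SSB"], out["Total SSB_se"] = self._group(SSB_CLASSES)
        out["Total DSB"], out["Total DSB_se"] = self._group(DSB_CLASSES)
        out["Total Damage"], out["Total Damage_se"] = self._group(YIELD_CLASSES)
        return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def generate_clusters(quality: RadiationQuality, config: SimulationConfig,
                      rng: Optional[np.random.Generator] = None
                      ) -> ClusterPopulation:
    """Sample a cluster population for one exposure.

    The cluster count is Poisson with mean ``rho * dose * genome`` unless
    ``config.fixed_count`` is set, in which case exactly
    ``config.n_clusters_min`` clusters are drawn and the equivalent exposure
    ``n / rho`` is recorded on the population for dose normalisation.
    """
    if rng is None:
        rng = config.rng()
    exposure = config.dose_gy * config.genome_gbp
    if config.fixed_count:
        if config.n_clusters_min <= 0:
            raise ValueError("fixed_count mode requires n_clusters_min > 0")
        n_clusters = int(config.n_clusters_min)
        exposure = n_clusters / quality.cluster_rate_rho
    else:
        mean = quality.cluster_rate_rho * exposure
        n_clusters = int(rng.poisson(mean))
        if config.n_clusters_min and n_clusters < config.n_clusters_min:
            n_clusters = int(config.n_clusters_min)
            exposure = n_clusters / quality.cluster_rate_rho
    sizes = 1 + rng.poisson(quality.multiplicity_nu, size=n_clusters)
    total = int(sizes.sum()) if n_clusters else 0
    positions = rng.integers(0, quality.nseg, size=total)
    strands = rng.integers(0, 2, size=total)
    is_break = rng.random(total) < quality.p_strand_break
    offsets = np.concatenate(([0], np.cumsum(sizes))).astype(np.int64)
    cid = np.repeat(np.arange(n_clusters), sizes)
    order = np.lexsort((strands, positions, cid))
    return ClusterPopulation(
        positions[order], strands[order], is_break[order], offsets,
        quality.nseg, exposure,
        meta={"quality": quality.name, "n_clusters": n_clusters},
    )


def classify_cluster(cluster: DamageCluster) -> str:
    """Damage class of one cluster (lesions must be position-sorted)."""
    pos = np.array([l.position for l in cluster.lesions], dtype=np.int64)
    if pos.size and (np.diff(pos) < 0).any():
        raise RuntimeError("cluster lesions are not sorted by position")
    strands = np.array([l.strand for l in cluster.lesions], dtype=np.int64)
    isb = np.array([l.is_break for l in cluster.lesions], dtype=bool)
    offsets = np.array([0, pos.size], dtype=np.int64)
    code = classify_flat(pos, strands, isb, offsets, DSB_PAIRING_DISTANCE_BP)[0]
    return CLASS_NAMES[code]


def classify_population(pop: ClusterPopulation) -> np.ndarray:
    """Class codes (see ``CLASS_NAMES``) for every cluster, vectorised."""
    return classify_flat(pop.positions, pop.strands, pop.is_break, pop.offsets,
                         DSB_PAIRING_DISTANCE_BP)


def tally_yields(clusters, config: SimulationConfig,
                 class_codes: Optional[np.ndarray] = None) -> DamageYields:
    """Count damage classes and normalise per Gy per Gbp.

    ``clusters`` may be a :class:`ClusterPopulation` (its recorded exposure
    is used) or an iterable of :class:`DamageCluster` (exposure taken from
    ``config``).  EMPTY clusters are excluded from all yields.
    """
    if isinstance(clusters, ClusterPopulation):
        pop = clusters
        exposure = pop.exposure_gy_gbp
        if class_codes is None:
            class_codes = classify_population(pop)
    else:
        exposure = config.dose_gy * config.genome_gbp
        if class_codes is None:
            class_codes = np.array(
                [CLASS_CODES[classify_cluster(c)] for c in clusters],
                dtype=np.int8,
            )
    if exposure <= 0:
        raise ValueError("exposure (dose x genome) must be > 0")
    binned = np.bincount(class_codes, minlength=len(CLASS_NAMES))
    counts = {CLASS_NAMES[code]: int(binned[code])
              for code in range(1, len(CLASS_NAMES))}
    return DamageYields(counts, exposure, config.per_cell_factor)


def simulate_damage_spectrum(quality: RadiationQuality, environment,
                             config: SimulationConfig,
                             rng: Optional[np.random.Generator] = None,
                             survival: Optional[float] = None) -> DamageYields:
    """End-to-end damage simulation: generate, thin, classify, tally.

    ``environment`` is an :class:`~radlesion.modifiers.EnvironmentCondition`;
    the per-lesion survival factor is the product of the DMSO and oxygen
    factors for ``quality``'s modifier parameters (or ``survival`` if given
    explicitly).  The effective survival probability is recorded in the
    result metadata.
    """
    from .modifiers import combined_survival, thin_lesions

    if rng is None:
        rng = config.rng()
    gen_rng, thin_rng = rng.spawn(2)
    pop = generate_clusters(quality, config, gen_rng)
    if survival is None:
        # supra-reference oxygen would give factors > 1; retention caps at 1
        survival = min(1.0, combined_survival(environment, quality))
    if survival < 1.0:
        pop = thin_lesions(pop, survival, thin_rng)
    yields = tally_yields(pop, config)
    yields.meta.update(
        quality=quality.name,
        survival=float(survival),
        n_clusters_generated=pop.meta.get("n_clusters", len(pop)),
        n_clusters_surviving=len(pop),
    )
    return yields
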