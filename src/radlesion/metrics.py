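"""RBE, OER and percent-reduction endpoints, plus modifier sweep curves.

RBE is the ratio of a test radiation's DSB-class yield to the gamma-ray
reference yield at the same scavenger concentration; OER is the ratio of a
class yield under aerobic (21% O2) to severely hypoxic (0.001% O2)
conditions.  Standard errors propagate in quadrature on relative errors.
"""

from __future__ import annotations

from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .induction import (
    DamageYields,
    RadiationQuality,
    SimulationConfig,
    generate_clusters,
    tally_yields,
)
from .modifiers import (
    EnvironmentCondition,
    combined_survival,
    dmso_survival_factor,
    oxygen_survival_factor,
    thin_lesions,
)


class Ratio(NamedTuple):
    """A ratio endpoint with its propagated standard error."""

    value: float
    se: float


def _as_value_se(entry) -> tuple:
    if isinstance(entry, Ratio):
        return entry.value, entry.se
    if isinstance(entry, (tuple, list)) and len(entry) == 2:
        return float(entry[0]), float(entry[1])
    return float(entry), 0.0


def _ratio(numer, denom, what: str) -> Ratio:
    nv, nse = _as_value_se(numer)
    dv, dse = _as_value_se(denom)
    if dv <= 0:
        raise ValueError(f"{what}: reference yield must be > 0")
    value = nv / dv
    rel = np.hypot(nse / nv if nv > 0 else 0.0, dse / dv)
    return Ratio(value, value * rel)


def rbe(sigma_r, sigma_gamma) -> Ratio:
    """Relative biological effectiveness: test-radiation DSB yield over the
    gamma-ray reference yield.  Inputs are yields or (yield, se) pairs."""
    return _ratio(sigma_r, sigma_gamma, "rbe")


def oer(yield_aerobic, yield_hypoxic) -> Ratio:
    """Oxygen enhancement ratio: aerobic over hypoxic yield for any damage
    class (conventionally total DSB, 21% vs 0.001% O2)."""
    return _ratio(yield_aerobic, yield_hypoxic, "oer")


def percent_reduction(baseline: float, modified: float) -> float:
    """Percent decrease of ``modified`` relative to ``baseline``."""
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    return 100.0 * (1.0 - modified / baseline)


# ---------------------------------------------------------------------------
# sweep curves
# ---------------------------------------------------------------------------

def _thinned_yields(pop, survival: float, uniforms, config) -> DamageYields:
    # supra-reference oxygen would give factors > 1; retention caps at 1
    thinned = thin_lesions(pop, min(1.0, survival), uniforms=uniforms)
    return tally_yields(thinned, config)


def dmso_sweep(qualities: Sequence[RadiationQuality],
               dmso_grid: Sequence[float],
               config: SimulationConfig,
               reference: Optional[RadiationQuality] = None,
               rng: Optional[np.random.Generator] = None,
               o2_percent: float = 21.0) -> pd.DataFrame:
    """Full damage yields plus RBE versus DMSO concentration.

    The reference is a gamma-ray-equivalent quality (same baseline damage
    spectrum, gamma scavenger parameters); by convention the zero-DMSO RBE
    of a low-LET quality against it is 1.  Thinning uses per-population
    coupled uniforms across the grid for smooth, monotone curves.
    """
    if reference is None:
        reference = gamma_reference(qualities[0])
    if rng is None:
        rng = config.rng()
    ref_rng, *q_rngs = rng.spawn(len(qualities) + 1)
    ref_pop = generate_clusters(reference, config, ref_rng)
    ref_u = ref_rng.random(ref_pop.n_lesions)
    rows = []
    for quality, q_rng in zip(qualities, q_rngs):
        pop = generate_clusters(quality, config, q_rng)
        uniforms = q_rng.random(pop.n_lesions)
        for dmso in dmso_grid:
            env = EnvironmentCondition(dmso_M=dmso, o2_percent=o2_percent)
            y = _thinned_yields(pop, combined_survival(env, quality),
                                uniforms, config)
            y_ref = _thinned_yields(ref_pop, combined_survival(env, reference),
                                    ref_u, config)
            ratio = rbe((y.total_dsb, y.total_dsb_se),
                        (y_ref.total_dsb, y_ref.total_dsb_se))
            row = dict(quality=quality.name, dmso_M=dmso,
                       o2_percent=o2_percent,
                       rbe=ratio.value, rbe_se=ratio.se)
            row.update(y.to_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def o2_sweep(quality: RadiationQuality,
             o2_grid: Sequence[float],
             config: SimulationConfig,
             rng: Optional[np.random.Generator] = None,
             dmso_M: float = 0.0) -> pd.DataFrame:
    """Full damage yields plus OER versus oxygen tension.

    The curve value at each grid point is the ratio of the aerobic-reference
    yield to the yield at that tension, so it decreases from the full OER in
    anoxia to 1 at the reference tension.
    """
    if rng is None:
        rng = config.rng()
    pop = generate_clusters(quality, config, rng)
    uniforms = rng.random(pop.n_lesions)
    s_dmso = dmso_survival_factor(dmso_M, quality.scavenger)
    ref = _thinned_yields(
        pop,
        s_dmso * oxygen_survival_factor(quality.oxygen.reference_o2,
                                        quality.oxygen),
        uniforms, config)
    rows = []
    for o2 in o2_grid:
        s = s_dmso * oxygen_survival_factor(o2, quality.oxygen)
        y = _thinned_yields(pop, s, uniforms, config)
        ratio = oer((ref.total_dsb, ref.total_dsb_se),
                    (y.total_dsb, y.total_dsb_se))
        row = dict(quality=quality.name, o2_percent=o2, dmso_M=dmso_M,
                   oer=ratio.value, oer_se=ratio.se)
        row.update(y.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def gamma_reference(template: RadiationQuality) -> RadiationQuality:
    """Gamma-ray reference quality: the low-LET baseline damage spectrum
    with the gamma scavenger parameters (zero-DMSO RBE is 1 by
    construction — both qualities are low LET)."""
    from dataclasses import replace

    from .calibration import SCAVENGER_PRESETS

    return replace(template, name="cobalt60", let_keV_um=2.4,
                   scavenger=SCAVENGER_PRESETS["cobalt60"], meta={})
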