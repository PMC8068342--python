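"""Excision-repair outcomes: exact enumeration vs sampled histories."""

import numpy as np
import pytest

import radlesion as rl


def cluster_of(lesions, segment_length=30):
    return rl.make_toy_clusters([lesions], segment_length=segment_length)[0]


def sampled_probabilities(cluster, params, n=4000, seed=0):
    rng = np.random.default_rng(seed)
    counts = {"correct": 0, "point_mutation": 0, "repair_dsb": 0}
    for _ in range(n):
        counts[rl.repair_cluster(cluster, params, rng).category] += 1
    return {k: v / n for k, v in counts.items()}


# ---------------------------------------------------------------------------
# exact small-cluster cases
# ---------------------------------------------------------------------------

def test_breaks_only_cluster_never_mutates():
    cluster = cluster_of([(2, 0, "sb"), (5, 0, "sb")])
    probs = rl.repair_outcome_probabilities(cluster, rl.RepairParams())
    assert probs["point_mutation"] == 0.0
    assert probs["repair_dsb"] == 0.0
    assert probs["correct"] == pytest.approx(1.0)


def test_isolated_base_damage_is_always_correct():
    cluster = cluster_of([(7, 1, "bd")])
    for pathway in rl.PATHWAYS:
        probs = rl.repair_outcome_probabilities(
            cluster, rl.RepairParams(pathway=pathway, q_bypass=0.9))
        assert probs["correct"] == pytest.approx(1.0)


def test_opposed_base_damages_short_patch_hand_enumeration():
    """Two opposite-strand base damages at the same position, SP BER.

    Whichever is excised first, the 1-nt patch covers the template damage
    (offset 0), so the mutation probability equals q_bypass exactly; the
    second excision has no surviving template damage left.
    """
    cluster = cluster_of([(4, 0, "bd"), (4, 1, "bd")])
    params = rl.RepairParams(pathway="SP_BER", q_bypass=0.25)
    probs = rl.repair_outcome_probabilities(cluster, params)
    assert probs["point_mutation"] == pytest.approx(0.25)
    assert probs["repair_dsb"] == 0.0


def test_opposed_base_damages_long_patch_hand_enumeration():
    """Opposite-strand base damages 3 bp apart under LP BER.

    Only the left-first order can cover the right-hand template damage
    (patch grows rightward), needing L >= 4, i.e. 7 of the 9 equiprobable
    lengths: P(mutation) = (1/2) * (7/9) * q.
    """
    cluster = cluster_of([(4, 0, "bd"), (7, 1, "bd")])
    q = 0.3
    params = rl.RepairParams(pathway="LP_BER", q_bypass=q)
    probs = rl.repair_outcome_probabilities(cluster, params)
    assert probs["point_mutation"] == pytest.approx(0.5 * (7 / 9) * q)


def test_break_opposite_base_damage_converts_to_dsb_half_the_time():
    """SB and BD on opposite strands within the conversion distance: the
    BD-first order opens a discontinuity opposite the un-religated break."""
    cluster = cluster_of([(0, 0, "sb"), (5, 1, "bd")])
    probs = rl.repair_outcome_probabilities(cluster, rl.RepairParams())
    assert probs["repair_dsb"] == pytest.approx(0.5)
    # beyond the conversion distance: never converts
    far = cluster_of([(0, 0, "sb"), (15, 1, "bd")])
    probs = rl.repair_outcome_probabilities(far, rl.RepairParams())
    assert probs["repair_dsb"] == 0.0


def test_dsb_class_cluster_is_rejected():
    cluster = cluster_of([(3, 0, "sb"), (6, 1, "sb")])
    with pytest.raises(ValueError):
        rl.repair_cluster(cluster, rl.RepairParams(),
                          np.random.default_rng(0))
    with pytest.raises(ValueError):
        rl.repair_outcome_probabilities(cluster, rl.RepairParams())


@pytest.mark.parametrize("pathway", rl.PATHWAYS)
@pytest.mark.parametrize("lesions", [
    [(4, 0, "bd"), (4, 1, "bd")],
    [(4, 0, "bd"), (7, 1, "bd"), (2, 1, "sb")],
    [(0, 0, "sb"), (5, 1, "bd"), (9, 0, "bd")],
    [(1, 0, "bd"), (3, 1, "bd"), (6, 0, "bd")],
])
def test_sampled_histories_match_exact_enumeration(pathway, lesions):
    """Monte Carlo repair histories agree with the exact outcome
    distribution on small clusters (3 sigma, large q for power)."""
    params = rl.RepairParams(pathway=pathway, q_bypass=0.4)
    cluster = cluster_of(lesions)
    exact = rl.repair_outcome_probabilities(cluster, params)
    n = 4000
    sampled = sampled_probabilities(cluster, params, n=n, seed=1)
    for key in exact:
        se = np.sqrt(max(exact[key] * (1 - exact[key]), 1e-9) / n)
        assert abs(sampled[key] - exact[key]) <= 4 * se + 1e-12
    assert sum(exact.values()) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# population aggregation
# ---------------------------------------------------------------------------

def test_zero_bypass_error_forces_zero_mutation_frequency(
        proton_quality, small_config):
    pop = rl.generate_clusters(proton_quality, small_config,
                               np.random.default_rng(10))
    params = rl.RepairParams(pathway="NER_LP_BER", q_bypass=0.0)
    freq = rl.mutation_frequency(pop, params, small_config)
    assert freq.value == 0.0


def test_mutation_frequency_of_break_only_population_is_zero(small_config):
    clusters = rl.make_toy_clusters([[(2, 0, "sb")], [(5, 1, "sb")]])
    freq = rl.mutation_frequency(clusters, rl.RepairParams(), small_config)
    assert freq.value == 0.0
    assert freq.se == 0.0


def test_mutation_frequency_toy_population_equals_enumeration(small_config):
    """Two hand-enumerable clusters: the aggregated frequency equals the
    mean exact mutation probability scaled per Gy per cell."""
    recipes = [
        [(4, 0, "bd"), (4, 1, "bd")],       # P = q (see hand case above)
        [(4, 0, "bd"), (7, 1, "bd")],       # P = (1/2)(7/9) q under LP
    ]
    clusters = rl.make_toy_clusters(recipes)
    q = 0.2
    params = rl.RepairParams(pathway="LP_BER", q_bypass=q)
    cfg = rl.SimulationConfig(dose_gy=1.0, genome_gbp=1.0,
                              per_cell_factor=6.0)
    freq = rl.mutation_frequency(clusters, params, cfg)
    p1 = 1 - (1 - q)  # same-position pair: covered by any L >= 1
    p2 = 0.5 * (7 / 9) * q
    assert freq.value == pytest.approx((p1 + p2) * 6.0)


def test_mutation_frequency_monotone_under_coupled_thinning(
        proton_quality, small_config):
    pop = rl.generate_clusters(proton_quality, small_config,
                               np.random.default_rng(11))
    uniforms = np.random.default_rng(12).random(pop.n_lesions)
    params = rl.RepairParams(pathway="NER_LP_BER", q_bypass=0.01)
    values = []
    for s in (0.5, 0.75, 1.0):
        thinned = rl.thin_lesions(pop, s, uniforms=uniforms)
        values.append(rl.mutation_frequency(thinned, params,
                                            small_config).value)
    assert values[0] <= values[1] <= values[2]


def test_pathway_sweep_constant_when_survival_forced_constant(
        proton_quality):
    """A zero-width DMSO grid point repeated must give identical rows."""
    cfg = rl.SimulationConfig(n_clusters_min=20_000, fixed_count=True, seed=2)
    frame = rl.pathway_sweep(proton_quality, [0.0, 0.0], cfg,
                             pathways=("SP_BER",),
                             rng=np.random.default_rng(2))
    vals = frame["value"].to_numpy()
    assert vals[0] == pytest.approx(vals[1])


def test_pathway_frequencies_sit_in_published_band(proton_quality):
    """Aerobic, scavenger-free proton mutation frequencies of the four
    pathways span the published 0.008-0.065 per Gy per cell band (checked
    with 10% stochastic slack)."""
    cfg = rl.SimulationConfig(n_clusters_min=120_000, fixed_count=True,
                              seed=13)
    pop = rl.generate_clusters(proton_quality, cfg,
                               np.random.default_rng(13))
    values = {
        pw: rl.mutation_frequency(pop, rl.RepairParams(pathway=pw), cfg).value
        for pw in rl.PATHWAYS
    }
    assert min(values.values()) == pytest.approx(0.008, rel=0.10)
    assert max(values.values()) == pytest.approx(0.065, rel=0.10)
    for v in values.values():
        assert 0.008 * 0.9 <= v <= 0.065 * 1.1
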