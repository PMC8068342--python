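"""Cluster generation, classification and yield tallying."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import radlesion as rl
from radlesion.induction import DSB_PAIRING_DISTANCE_BP


# ---------------------------------------------------------------------------
# independent classification oracle: exhaustive maximum matching
# ---------------------------------------------------------------------------

def oracle_classify(lesions):
    """Brute-force damage class via exhaustive pairing enumeration."""
    breaks = [(p, s) for p, s, kind in lesions if kind == "sb"]
    if not lesions:
        return "EMPTY"
    if not breaks:
        return "BD"
    if len(breaks) == 1:
        return "SSB"
    s0 = [p for p, s in breaks if s == 0]
    s1 = [p for p, s in breaks if s == 1]
    best = 0
    for sub in itertools.permutations(range(len(s0)),
                                      min(len(s0), len(s1))):
        for perm in itertools.permutations(range(len(s1)), len(sub)):
            count = sum(
                1 for i, j in zip(sub, perm)
                if abs(s0[i] - s1[j]) <= DSB_PAIRING_DISTANCE_BP
            )
            best = max(best, count)
    if best >= 2:
        return "DSB++"
    if best == 1:
        return "DSB+" if len(breaks) > 2 else "DSB"
    if s0 and s1:
        return "2SSB"
    return "SSB+"


def make_cluster(lesions, segment_length=30):
    return rl.make_toy_clusters([lesions], segment_length=segment_length)[0]


lesion_strategy = st.tuples(
    st.integers(0, 29), st.integers(0, 1), st.sampled_from(["sb", "bd"])
)


@settings(max_examples=400, deadline=None, derandomize=True)
@given(st.lists(lesion_strategy, min_size=1, max_size=5))
def test_classification_matches_pairing_enumeration_oracle(lesions):
    """Greedy nearest-partner pairing agrees with exhaustive enumeration on
    every small cluster, and every non-empty cluster gets exactly one class."""
    cluster = make_cluster(lesions)
    got = rl.classify_cluster(cluster)
    assert got == oracle_classify(lesions)


@pytest.mark.parametrize("lesions, expected", [
    ([(5, 0, "sb")], "SSB"),
    ([(5, 0, "bd")], "BD"),
    ([(5, 0, "bd"), (9, 1, "bd")], "BD"),
    # opposite-strand breaks within/beyond the 10-bp opposition window
    ([(100, 0, "sb"), (106, 1, "sb")], "DSB"),
    ([(100, 0, "sb"), (120, 1, "sb")], "2SSB"),
    ([(100, 0, "sb"), (103, 0, "sb")], "SSB+"),
    # one pair plus a leftover break; two disjoint pairs
    ([(100, 0, "sb"), (106, 1, "sb"), (103, 0, "sb")], "DSB+"),
    ([(100, 0, "sb"), (103, 1, "sb"), (108, 0, "sb"), (110, 1, "sb")],
     "DSB++"),
    # base damages never change a strand-break-bearing class
    ([(100, 0, "sb"), (106, 1, "sb"), (101, 1, "bd")], "DSB"),
])
def test_classification_examples(lesions, expected):
    cluster = make_cluster(lesions, segment_length=128)
    assert rl.classify_cluster(cluster) == expected


def test_unsorted_cluster_is_rejected():
    cluster = make_cluster([(3, 0, "sb"), (9, 1, "sb")])
    cluster.lesions = cluster.lesions[::-1]  # violate the sort contract
    with pytest.raises(RuntimeError):
        rl.classify_cluster(cluster)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _quality(**kw):
    defaults = dict(name="test", let_keV_um=1.0, cluster_rate_rho=100.0,
                    multiplicity_nu=0.5, p_strand_break=0.2, nseg=25)
    defaults.update(kw)
    return rl.RadiationQuality(**defaults)


def test_cluster_count_is_poisson_with_rate_dose_genome_mean():
    quality = _quality(cluster_rate_rho=20.0)
    config = rl.SimulationConfig(dose_gy=1.0, genome_gbp=1.0)
    rng = np.random.default_rng(0)
    counts = [len(rl.generate_clusters(quality, config, rng))
              for _ in range(300)]
    mean = np.mean(counts)
    se = np.sqrt(20.0 / 300)
    assert abs(mean - 20.0) < 4 * se
    assert abs(np.var(counts) - 20.0) < 5 * 20.0 * np.sqrt(2 / 300)


def test_zero_multiplicity_gives_single_lesion_clusters_only():
    quality = _quality(multiplicity_nu=0.0)
    config = rl.SimulationConfig(n_clusters_min=20_000, fixed_count=True)
    pop = rl.generate_clusters(quality, config, np.random.default_rng(1))
    assert (pop.cluster_sizes() == 1).all()
    codes = rl.classify_population(pop)
    names = {rl.CLASS_NAMES[c] for c in set(codes.tolist())}
    assert names <= {"BD", "SSB"}


def test_mean_lesions_per_cluster_matches_one_plus_poisson_law():
    quality = _quality(multiplicity_nu=0.5)
    config = rl.SimulationConfig(n_clusters_min=100_000, fixed_count=True)
    pop = rl.generate_clusters(quality, config, np.random.default_rng(2))
    mean = pop.n_lesions / len(pop)
    se = np.sqrt(0.5 / len(pop))
    assert abs(mean - 1.5) < 3 * se


def test_generation_is_reproducible_bit_for_bit():
    quality = _quality()
    config = rl.SimulationConfig(n_clusters_min=10_000, fixed_count=True)
    a = rl.generate_clusters(quality, config, np.random.default_rng(9))
    b = rl.generate_clusters(quality, config, np.random.default_rng(9))
    assert np.array_equal(a.positions, b.positions)
    assert np.array_equal(a.strands, b.strands)
    assert np.array_equal(a.is_break, b.is_break)
    assert np.array_equal(a.offsets, b.offsets)


def test_invalid_parameters_are_rejected():
    with pytest.raises(ValueError):
        _quality(cluster_rate_rho=0.0)
    with pytest.raises(ValueError):
        _quality(p_strand_break=1.0)
    with pytest.raises(ValueError):
        rl.SimulationConfig(dose_gy=0.0)
    with pytest.raises(ValueError):
        rl.SimulationConfig(genome_gbp=-1.0)


# ---------------------------------------------------------------------------
# tallying
# ---------------------------------------------------------------------------

def test_tally_on_hand_counted_clusters():
    """10 SSB clusters at 2 Gy x 1 Gbp: yield 5.0, SE sqrt(10)/2."""
    clusters = rl.make_toy_clusters([[(5, 0, "sb")]] * 10)
    config = rl.SimulationConfig(dose_gy=2.0, genome_gbp=1.0)
    yields = rl.tally_yields(clusters, config)
    assert yields.yield_of("SSB") == pytest.approx(5.0)
    assert yields.se_of("SSB") == pytest.approx(np.sqrt(10) / 2)
    assert yields.total_damage == pytest.approx(5.0)


def test_tally_empty_collection_gives_zero_yields():
    config = rl.SimulationConfig()
    yields = rl.tally_yields([], config)
    assert yields.total_damage == 0.0


def test_yield_totals_conserve_class_counts(proton_quality, small_config):
    pop = rl.generate_clusters(proton_quality, small_config,
                               np.random.default_rng(3))
    y = rl.tally_yields(pop, small_config)
    assert y.total_ssb == pytest.approx(
        y.yield_of("SSB") + y.yield_of("SSB+") + y.yield_of("2SSB"))
    assert y.total_dsb == pytest.approx(
        y.yield_of("DSB") + y.yield_of("DSB+") + y.yield_of("DSB++"))
    assert y.total_damage == pytest.approx(
        sum(y.yield_of(c) for c in rl.induction.YIELD_CLASSES))
    # integer accounting: counts sum to the number of surviving clusters
    assert sum(y.counts.values()) == len(pop)


def test_simulate_damage_spectrum_survival_extremes(proton_quality,
                                                    small_config):
    env = rl.EnvironmentCondition()
    dead = rl.simulate_damage_spectrum(proton_quality, env, small_config,
                                       survival=0.0,
                                       rng=np.random.default_rng(4))
    assert dead.total_damage == 0.0
    full = rl.simulate_damage_spectrum(proton_quality, env, small_config,
                                       survival=1.0,
                                       rng=np.random.default_rng(4))
    plain = rl.tally_yields(
        rl.generate_clusters(proton_quality, small_config,
                             np.random.default_rng(4).spawn(2)[0]),
        small_config)
    assert full.to_dict() == plain.to_dict()
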