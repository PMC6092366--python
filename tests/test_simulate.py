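"""Simulator: tract mosaics, Wright-Fisher divergence, truth bookkeeping."""

import numpy as np
import pytest
import scipy.stats

from palettefit.simulate import (
    ConfigurationError,
    DonorPoolExhaustedError,
    ScenarioConfig,
    Tract,
    TractIntegrityError,
    TractMap,
    assemble_diploids,
    estimate_tract_rate,
    pooled_tract_lengths,
    simulate_admixed_haploid_genome,
    simulate_divergence,
    simulate_scenario,
    true_admixture_proportions,
)


def _tract_only_pools(n_haps=40, sources=("P1", "P3", "P4")):
    return {s: np.empty((n_haps, 0), dtype=np.int8) for s in sources}


# ---------------------------------------------------------------------------
# configuration validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kwargs", [
    {"scenario_name": "banana"},
    {"scenario_name": "recent_admixture", "pop_size": 0},
    {"scenario_name": "recent_admixture", "admixture_lambda": -1},
    {"scenario_name": "recent_admixture", "admixture_proportions": (0.6, 0.35, 0.15)},
    {"scenario_name": "recent_admixture", "n_snps": 0},
])
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        ScenarioConfig(**kwargs)


def test_config_defaults_match_study_conditions():
    cfg = ScenarioConfig("recent_admixture")
    assert cfg.sample_sizes == (35, 25, 70, 25)
    assert cfg.admixture_lambda == 15.0
    assert cfg.admixture_proportions == (0.50, 0.35, 0.15)
    assert cfg.n_donor_individuals_per_source == 20
    assert cfg.n_admixed_individuals == 35
    assert cfg.chromosomes_per_genome == 20
    assert cfg.bottleneck_split_time == 20
    assert cfg.ghost_split_time_p1_p2 == 1700
    assert cfg.n_populations == 13


# ---------------------------------------------------------------------------
# the mosaic generator
# ---------------------------------------------------------------------------

def test_degenerate_simplex_gives_single_source():
    pools = {s: (np.full((20, 8), i, dtype=np.int8))
             for i, s in enumerate(["P1", "P3", "P4"])}
    gpos = np.linspace(1, 99, 8)
    hap, tm = simulate_admixed_haploid_genome(
        pools, (1.0, 0.0, 0.0), 15.0, 100.0,
        genetic_pos=gpos, chrom=np.ones(8, dtype=int), seed=0)
    assert {t.source for t in tm.tracts} == {"P1"}
    assert np.array_equal(hap, np.zeros(8, dtype=np.int8))


def test_tractmap_tiles_chromosomes_exactly():
    _, tm = simulate_admixed_haploid_genome(
        _tract_only_pools(), (0.5, 0.35, 0.15), 15.0, 100.0,
        n_chromosomes=20, seed=3)
    tm.validate(tol=1e-9)
    for c in range(1, 21):
        total = sum(t.length_cm for t in tm.tracts if t.chrom == c)
        assert total == pytest.approx(100.0, abs=1e-9)


def test_tract_lengths_follow_exponential_law():
    """The generator's raw length draws pass a KS test against Exp(lambda/100)."""
    rng = np.random.default_rng(11)
    tms = []
    while sum(len(t.raw_draw_lengths) for t in tms) < 10_000:
        _, tm = simulate_admixed_haploid_genome(
            _tract_only_pools(), (0.5, 0.35, 0.15), 15.0, 100.0,
            n_chromosomes=20, seed=rng)
        tms.append(tm)
    lengths = np.concatenate([tm.raw_draw_lengths for tm in tms])
    stat = scipy.stats.kstest(lengths, "expon", args=(0, 100.0 / 15.0))
    assert stat.pvalue > 0.01
    # censored-aware MLE recovers the generating rate
    assert estimate_tract_rate(tms) == pytest.approx(0.15, rel=0.05)


def test_donor_pool_exhaustion_names_source():
    pools = {"P1": np.empty((2, 0), dtype=np.int8)}
    with pytest.raises(DonorPoolExhaustedError, match="P1"):
        # rate high enough that >2 tracts are certain
        simulate_admixed_haploid_genome(pools, (1.0,), 200.0, 100.0, seed=0)


def test_donor_haplotype_not_reused_within_chromosome():
    _, tm = simulate_admixed_haploid_genome(
        _tract_only_pools(n_haps=50), (0.5, 0.35, 0.15), 15.0, 100.0,
        n_chromosomes=5, seed=7)
    for c in range(1, 6):
        used = [(t.source, t.donor_hap) for t in tm.tracts if t.chrom == c]
        assert len(used) == len(set(used))


# ---------------------------------------------------------------------------
# diploid assembly and truth bookkeeping
# ---------------------------------------------------------------------------

def _make_genomes(n, seed=0):
    rng = np.random.default_rng(seed)
    return [simulate_admixed_haploid_genome(
        _tract_only_pools(), (0.5, 0.35, 0.15), 15.0, 100.0,
        n_chromosomes=2, seed=rng) for _ in range(n)]


def test_assemble_diploids_counts():
    empty = np.empty(0)
    ds70 = assemble_diploids(_make_genomes(70), empty, empty, empty)
    assert ds70.n_individuals == 35
    ds2 = assemble_diploids(_make_genomes(2), empty, empty, empty)
    assert ds2.n_individuals == 1
    ds0 = assemble_diploids([], empty, empty, empty)
    assert ds0.n_individuals == 0
    with pytest.raises(ValueError, match="even"):
        assemble_diploids(_make_genomes(3), empty, empty, empty)


def test_true_proportions_trivial_cases():
    tm_one = TractMap([Tract(1, 0.0, 100.0, "P3", 0)], 1, 100.0)
    q = true_admixture_proportions({"x": (tm_one, tm_one)}, ["P1", "P3", "P4"])
    assert np.allclose(q.values, [[0.0, 1.0, 0.0]])

    alt = TractMap([Tract(1, 0.0, 50.0, "P1", 0), Tract(1, 50.0, 100.0, "P3", 1)],
                   1, 100.0)
    q2 = true_admixture_proportions({"x": (alt, alt)}, ["P1", "P3"])
    assert np.allclose(q2.values, [[0.5, 0.5]])


def test_true_proportions_rejects_gaps():
    gap = TractMap([Tract(1, 0.0, 40.0, "P1", 0), Tract(1, 60.0, 100.0, "P3", 1)],
                   1, 100.0)
    with pytest.raises(TractIntegrityError):
        true_admixture_proportions({"x": (gap, gap)}, ["P1", "P3"])


def test_true_proportion_rows_sum_to_one():
    genomes = _make_genomes(8, seed=5)
    ds = assemble_diploids(genomes, np.empty(0), np.empty(0), np.empty(0))
    q = true_admixture_proportions(ds.tracts, ["P1", "P3", "P4"])
    assert np.allclose(q.values.sum(axis=1), 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# divergence backend
# ---------------------------------------------------------------------------

def _small_cfg(**kw):
    base = dict(n_populations=4, pop_size=30, sample_sizes=(6, 5, 8, 5),
                deep_split_time=80, p3_p4_split_time=50, burn_in=20,
                n_admixed_individuals=4, n_donor_individuals_per_source=5,
                chromosomes_per_genome=2, chromosome_length_cm=50.0, n_snps=60)
    base.update(kw)
    return ScenarioConfig(**base)


def test_divergence_is_deterministic():
    cfg = _small_cfg(scenario_name="recent_bottleneck", seed=9)
    d1 = simulate_divergence(cfg)
    d2 = simulate_divergence(cfg)
    assert np.array_equal(d1.haplotypes, d2.haplotypes)
    assert d1.haplotypes.tobytes() == d2.haplotypes.tobytes()
    assert np.array_equal(d1.physical_pos, d2.physical_pos)


def test_zero_split_time_means_no_divergence():
    """Sister populations that split at t=0 have equal allele frequencies."""
    cfg = _small_cfg(scenario_name="recent_bottleneck", bottleneck_split_time=1,
                     bottleneck_size=30, seed=2, n_snps=400)
    ds = simulate_divergence(cfg)
    lab = np.asarray(ds.labels)
    f1 = ds.haplotypes[np.repeat(lab == "P1", 2)].mean(axis=0)
    f2 = ds.haplotypes[np.repeat(lab == "P2", 2)].mean(axis=0)
    # one generation of drift at N=30: mean |df| ~ sqrt(2 * p q / 2N) ~ 0.08
    assert np.mean(np.abs(f1 - f2)) < 0.1
    # while the deep split (80 generations + drift) separates P1 from P3
    f3 = ds.haplotypes[np.repeat(lab == "P3", 2)].mean(axis=0)
    assert np.mean(np.abs(f1 - f3)) > np.mean(np.abs(f1 - f2))


def test_scenario_determinism_and_truth_coverage():
    cfg = _small_cfg(scenario_name="recent_admixture", seed=4)
    ds = simulate_scenario(cfg)
    ds2 = simulate_scenario(cfg)
    assert np.array_equal(ds.haplotypes, ds2.haplotypes)
    assert ds.n_individuals == 6 + 4 + 8 + 5  # P2 replaced by admixed diploids
    assert set(ds.tracts) == {i for i, l in zip(ds.individual_ids, ds.labels)
                              if l == "P2"}
    for pair in ds.tracts.values():
        for tm in pair:
            tm.validate()


def test_full_scale_mixing_recovers_proportions():
    """Genome-wide tract fractions match the 50/35/15 mixing proportions."""
    cfg = ScenarioConfig("recent_admixture", n_populations=4, seed=1, n_snps=30,
                         chromosomes_per_genome=20)
    ds = simulate_scenario(cfg)
    assert sum(l == "P2" for l in ds.labels) == 35
    q = true_admixture_proportions(ds.tracts, ["P1", "P3", "P4"])
    mean = q.values.mean(axis=0)
    # Monte-Carlo SE of a mean tract fraction at this problem size
    se = q.values.std(axis=0, ddof=1) / np.sqrt(q.shape[0])
    for m, s, target in zip(mean, se, (0.50, 0.35, 0.15)):
        assert abs(m - target) < 3 * max(s, 1e-3)
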