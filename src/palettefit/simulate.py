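"""Synthetic admixture scenarios with full true-ancestry bookkeeping.

Three demographic scenarios are generated, chosen because they produce
nearly indistinguishable admixture bar plots while having very different
true histories:

``recent_admixture``
    P2 genomes are explicit mosaics of P1/P3/P4 chromosomes created by an
    instantaneous admixture event ``lambda`` generations ago.  Ancestry
    tract lengths are exponential with rate ``lambda/100`` per cM.
``ghost_admixture``
    P2 receives ~50% of its ancestry from an unsampled "ghost" population
    most closely related to P3, via continuous migration over the last
    couple of hundred generations.
``recent_bottleneck``
    P1 splits from P2 a few generations ago and immediately undergoes a
    strong bottleneck; neither population is admixed.

Divergence between populations is produced by a discrete-generation
Wright-Fisher simulator: random mating, Haldane-map recombination on the
genetic map, symmetric per-site mutation, founder haplotypes drawn in
linkage equilibrium from shared ancestral allele frequencies.  Population
sizes are scaled down (default diploid N=100) so deep histories run at
desk scale; the per-site mutation rate keeps 4*N*mu of order 0.1-1 so that
polymorphism survives the deepest splits.

The admixed-chromosome generator is independent of the divergence backend:
it only needs donor haplotype pools, and records every copied segment in a
:class:`TractMap` so downstream palette predictions can be validated
against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SCENARIOS",
    "ScenarioConfig",
    "Tract",
    "TractMap",
    "SimulatedDataset",
    "ConfigurationError",
    "DonorPoolExhaustedError",
    "TractIntegrityError",
    "simulate_divergence",
    "simulate_admixed_haploid_genome",
    "assemble_diploids",
    "true_admixture_proportions",
    "simulate_scenario",
    "estimate_tract_rate",
    "pooled_tract_lengths",
    "simulate_correlated_genotypes",
]

SCENARIOS = ("recent_admixture", "ghost_admixture", "recent_bottleneck")


class ConfigurationError(ValueError):
    """Invalid scenario configuration."""


class DonorPoolExhaustedError(RuntimeError):
    """A donor source ran out of unused haplotypes mid-chromosome."""


class TractIntegrityError(ValueError):
    """Tracts do not tile a chromosome."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one simulation scenario.

    Sample sizes, split times, the admixture time ``admixture_lambda`` and
    the mixing proportions default to the study conditions this generator
    emulates: samples (35, 25, 70, 25) for P1..P4, a 20-generation split
    followed by a strong bottleneck for the bottleneck scenario, a
    1700-generation split plus ~50% ghost migration over 250 generations
    for the ghost scenario, and an instantaneous admixture event 15
    generations ago mixing P1/P3/P4 at 50/35/15 for the admixture scenario.
    """

    scenario_name: str
    n_populations: int = 13
    sample_sizes: tuple[int, ...] = (35, 25, 70, 25)  # P1..P4
    outgroup_sample_size: int = 10
    pop_size: int = 100            # diploid individuals per population
    bottleneck_population: str = "P1"
    bottleneck_size: int = 10      # diploid size during the bottleneck
    bottleneck_split_time: int = 20
    ghost_split_time_p1_p2: int = 1700
    deep_split_time: int = 300     # (P1,P2) vs (P3,P4) in the shallow scenarios
    p3_p4_split_time: int = 200
    ghost_p3_split_time: int = 100
    ghost_migration_fraction: float = 0.5
    ghost_migration_duration: int = 250
    admixture_lambda: float = 15.0
    admixture_proportions: tuple[float, ...] = (0.50, 0.35, 0.15)
    admixture_sources: tuple[str, ...] = ("P1", "P3", "P4")
    n_admixed_individuals: int = 35
    n_donor_individuals_per_source: int = 20
    chromosomes_per_genome: int = 20
    chromosome_length_cm: float = 100.0
    n_snps: int = 500              # per chromosome
    mutation_rate: float = 1e-3    # per site per transmission
    burn_in: int = 100             # generations of ancestral-population evolution
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario_name not in SCENARIOS:
            raise ConfigurationError(
                f"unknown scenario {self.scenario_name!r}; expected one of {SCENARIOS}"
            )
        if self.n_populations < 4:
            raise ConfigurationError("n_populations must be >= 4 (P1..P4)")
        counts = {
            "pop_size": self.pop_size,
            "bottleneck_size": self.bottleneck_size,
            "n_admixed_individuals": self.n_admixed_individuals,
            "n_donor_individuals_per_source": self.n_donor_individuals_per_source,
            "chromosomes_per_genome": self.chromosomes_per_genome,
            "n_snps": self.n_snps,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive, got {value}")
        if any(s <= 0 for s in self.sample_sizes) or len(self.sample_sizes) != 4:
            raise ConfigurationError("sample_sizes must be four positive counts (P1..P4)")
        if self.admixture_lambda <= 0:
            raise ConfigurationError("admixture_lambda must be > 0")
        if self.chromosome_length_cm <= 0:
            raise ConfigurationError("chromosome_length_cm must be > 0")
        props = np.asarray(self.admixture_proportions, dtype=float)
        if props.size != len(self.admixture_sources):
            raise ConfigurationError("admixture_proportions / admixture_sources length mismatch")
        if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-12:
            raise ConfigurationError("admixture_proportions must lie on the simplex (sum 1)")
        if not (0.0 < self.ghost_migration_fraction < 1.0):
            raise ConfigurationError("ghost_migration_fraction must be in (0, 1)")

    @property
    def focal_populations(self) -> tuple[str, ...]:
        return ("P1", "P2", "P3", "P4")

    @property
    def population_names(self) -> tuple[str, ...]:
        out = ["P1", "P2", "P3", "P4"]
        out += [f"OG{i}" for i in range(5, self.n_populations + 1)]
        return tuple(out)


@dataclass(frozen=True)
class Tract:
    """One true-ancestry segment of a haploid chromosome (cM, half-open)."""

    chrom: int          # 1-based chromosome index
    start_cm: float
    end_cm: float
    source: str         # donor population label
    donor_hap: int      # index of the donor haplotype within its source pool

    def __post_init__(self) -> None:
        if not self.start_cm < self.end_cm:
            raise TractIntegrityError(
                f"tract on chrom {self.chrom} has start {self.start_cm} >= end {self.end_cm}"
            )

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm


@dataclass
class TractMap:
    """Ordered true-ancestry segments for one haploid genome.

    ``raw_draw_lengths`` preserves the exact exponential draws the
    generator made (the final draw of each chromosome unclipped), which is
    the right sample for testing the tract-length law; the tracts
    themselves are clipped to the chromosome.
    """

    tracts: list[Tract]
    n_chromosomes: int
    chromosome_length_cm: float
    raw_draw_lengths: np.ndarray | None = None

    def validate(self, tol: float = 1e-9) -> None:
        """Check that the tracts tile every chromosome with no gaps/overlaps."""
        by_chrom: dict[int, list[Tract]] = {c: [] for c in range(1, self.n_chromosomes + 1)}
        for t in self.tracts:
            if t.chrom not in by_chrom:
                raise TractIntegrityError(f"tract on unexpected chromosome {t.chrom}")
            by_chrom[t.chrom].append(t)
        for c, segs in by_chrom.items():
            segs = sorted(segs, key=lambda t: t.start_cm)
            if not segs:
                raise TractIntegrityError(f"chromosome {c} has no tracts")
            if abs(segs[0].start_cm) > tol:
                raise TractIntegrityError(f"chromosome {c} does not start at 0")
            for prev, nxt in zip(segs, segs[1:]):
                if abs(prev.end_cm - nxt.start_cm) > tol:
                    raise TractIntegrityError(
                        f"gap/overlap on chromosome {c} at {prev.end_cm:.6g} cM"
                    )
            if abs(segs[-1].end_cm - self.chromosome_length_cm) > tol:
                raise TractIntegrityError(
                    f"chromosome {c} ends at {segs[-1].end_cm:.6g}, "
                    f"expected {self.chromosome_length_cm}"
                )

    def source_fractions(self, sources: Sequence[str]) -> np.ndarray:
        """cM-weighted fraction of this haploid genome from each source."""
        total = self.n_chromosomes * self.chromosome_length_cm
        out = np.zeros(len(sources))
        idx = {s: i for i, s in enumerate(sources)}
        for t in self.tracts:
            if t.source not in idx:
                raise KeyError(f"tract source {t.source!r} not among {tuple(sources)}")
            out[idx[t.source]] += t.length_cm
        return out / total

    def lengths(self, include_censored: bool = True) -> np.ndarray:
        """Genetic lengths of all tracts.

        Tracts that run into a chromosome end are right-censored draws; pass
        ``include_censored=False`` to keep only complete draws.
        """
        if include_censored:
            return np.array([t.length_cm for t in self.tracts])
        end = self.chromosome_length_cm
        return np.array([t.length_cm for t in self.tracts if t.end_cm < end - 1e-12])


@dataclass
class SimulatedDataset:
    """Phased haplotypes plus positions, labels and (optionally) true tracts.

    ``haplotypes`` is a ``(2N, L)`` int8 matrix; individual ``i`` owns rows
    ``2i`` and ``2i+1``.  ``tracts`` maps admixed individual ids to their
    pair of haploid :class:`TractMap` objects.
    """

    haplotypes: np.ndarray
    genetic_pos: np.ndarray        # cM from chromosome start
    physical_pos: np.ndarray       # 1-based bp
    chrom: np.ndarray              # 1-based chromosome index per site
    individual_ids: list[str]
    labels: list[str]
    tracts: dict[str, tuple[TractMap, TractMap]] = field(default_factory=dict)
    config: ScenarioConfig | None = None

    def __post_init__(self) -> None:
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.int8)
        self.genetic_pos = np.asarray(self.genetic_pos, dtype=float)
        self.physical_pos = np.asarray(self.physical_pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        if self.haplotypes.shape[0] % 2:
            raise ValueError("haplotype count must be even (phased diploids)")
        if self.haplotypes.shape[0] != 2 * len(self.individual_ids):
            raise ValueError("haplotype rows do not match individual count")
        if len(self.labels) != len(self.individual_ids):
            raise ValueError("labels do not match individuals")
        for c in np.unique(self.chrom):
            sel = self.chrom == c
            if np.any(np.diff(self.physical_pos[sel]) <= 0):
                raise ValueError(f"physical positions not strictly increasing on chrom {c}")
            if np.any(np.diff(self.genetic_pos[sel]) <= 0):
                raise ValueError(f"genetic positions not strictly increasing on chrom {c}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def genotypes(self) -> np.ndarray:
        """(N, L) dosage matrix (0/1/2)."""
        h = self.haplotypes
        return (h[0::2] + h[1::2]).astype(np.int16)

    def subset(self, indices: Sequence[int]) -> "SimulatedDataset":
        indices = list(indices)
        rows = np.array([[2 * i, 2 * i + 1] for i in indices]).reshape(-1) if indices else \
            np.empty(0, dtype=int)
        ids = [self.individual_ids[i] for i in indices]
        return SimulatedDataset(
            haplotypes=self.haplotypes[rows] if len(rows) else
            np.empty((0, self.n_sites), dtype=np.int8),
            genetic_pos=self.genetic_pos,
            physical_pos=self.physical_pos,
            chrom=self.chrom,
            individual_ids=ids,
            labels=[self.labels[i] for i in indices],
            tracts={k: v for k, v in self.tracts.items() if k in ids},
            config=self.config,
        )


# ---------------------------------------------------------------------------
# site maps
# ---------------------------------------------------------------------------

def _sample_unique_positions(n: int, span: int, rng: np.random.Generator) -> np.ndarray:
    """n distinct sorted 1-based positions in [1, span] without materializing the range."""
    if n > span:
        raise ValueError(f"cannot place {n} distinct sites in {span} bp")
    pos: np.ndarray = np.unique(rng.integers(1, span + 1, size=2 * n))
    while len(pos) < n:
        extra = rng.integers(1, span + 1, size=2 * n)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def _draw_site_map(config: ScenarioConfig, rng: np.random.Generator):
    """Random SNP positions per chromosome under a uniform 1 cM/Mb map."""
    chrom_len_bp = int(round(config.chromosome_length_cm * 1e6))
    phys, gen, chrom = [], [], []
    for c in range(1, config.chromosomes_per_genome + 1):
        bp = _sample_unique_positions(config.n_snps, chrom_len_bp, rng)
        phys.append(bp)
        gen.append(bp * 1e-6)
        chrom.append(np.full(config.n_snps, c))
    return (np.concatenate(phys).astype(np.int64),
            np.concatenate(gen),
            np.concatenate(chrom).astype(np.int64))


def _interval_switch_probs(genetic_pos: np.ndarray, chrom: np.ndarray) -> np.ndarray:
    """Per-interval probability that a gamete switches parental haplotype.

    Haldane map within a chromosome; independent assortment (0.5) across
    chromosome boundaries; index 0 is unused (phase drawn separately).
    """
    L = len(genetic_pos)
    p = np.zeros(L)
    if L == 0:
        return p
    d = np.diff(genetic_pos)
    same = chrom[1:] == chrom[:-1]
    p[1:] = np.where(same, 0.5 * (1.0 - np.exp(-2.0 * d / 100.0)), 0.5)
    return p


# ---------------------------------------------------------------------------
# Wright-Fisher forward evolution
# ---------------------------------------------------------------------------

def _wf_offspring(haps: np.ndarray, n_diploids: int, switch_p: np.ndarray,
                  mu: float, rng: np.random.Generator) -> np.ndarray:
    """One generation of random-mating offspring from a haplotype pool."""
    n_gam = 2 * n_diploids
    n_parents = haps.shape[0] // 2
    L = haps.shape[1]
    pidx = rng.integers(n_parents, size=n_gam)
    h0 = haps[2 * pidx]
    h1 = haps[2 * pidx + 1]
    start = rng.integers(2, size=(n_gam, 1))
    switches = rng.random((n_gam, L)) < switch_p[None, :]
    phase = (start + np.cumsum(switches, axis=1)) % 2
    child = np.where(phase == 0, h0, h1).astype(np.int8)
    if mu > 0:
        child ^= (rng.random((n_gam, L)) < mu).astype(np.int8)
    return child


def _scenario_events(config: ScenarioConfig):
    """(start_time, split schedule, migration window) for a scenario.

    Splits are (time, parent, child) with the parent keeping its pool; the
    populations are related by a fixed topology:
    ``((P1,P2),(P3,(P4, ghost)))`` with generic outgroups splitting from the
    root lineage before the deepest focal split.
    """
    name = config.scenario_name
    if name == "ghost_admixture":
        p1p2 = config.ghost_split_time_p1_p2
        root = p1p2 + 300
        splits = [
            (root, "ANC", "P34"),
            (p1p2, "ANC", "P1"),          # ANC lineage continues as P2
            (config.p3_p4_split_time, "P34", "P4"),   # P34 continues as P3
            (config.ghost_p3_split_time, "P34", "GHOST"),
        ]
        rename = {"ANC": "P2", "P34": "P3"}
        migration = ("GHOST", "P2", config.ghost_migration_duration,
                     config.ghost_migration_fraction)
    else:
        root = config.deep_split_time
        splits = [
            (root, "ANC", "P34"),
            (config.p3_p4_split_time, "P34", "P4"),
            (config.bottleneck_split_time, "ANC", "P1"),  # ANC continues as P2
        ]
        rename = {"ANC": "P2", "P34": "P3"}
        migration = None
    n_og = config.n_populations - 4
    for i in range(n_og):
        splits.append((root + 50 * (i + 1), "ANC", f"OG{5 + i}"))
    splits.sort(key=lambda s: -s[0])
    start = max(s[0] for s in splits) + config.burn_in
    return start, splits, rename, migration


def _simulate_populations(config: ScenarioConfig, seed_seq: np.random.SeedSequence):
    """Forward-simulate all populations; returns (pools dict, site map)."""
    rng = np.random.default_rng(seed_seq)
    phys, gen, chrom = _draw_site_map(config, rng)
    switch_p = _interval_switch_probs(gen, chrom)
    L = len(gen)

    freqs = rng.uniform(0.1, 0.9, size=L)
    pools: dict[str, np.ndarray] = {
        "ANC": (rng.random((2 * config.pop_size, L)) < freqs).astype(np.int8)
    }

    start, splits, rename, migration = _scenario_events(config)
    split_at: dict[int, list[tuple[str, str]]] = {}
    for t, parent, child in splits:
        split_at.setdefault(t, []).append((parent, child))

    bneck = config.bottleneck_population
    apply_bottleneck = config.scenario_name in ("recent_bottleneck", "recent_admixture")

    if migration is not None:
        src, dst, dur, frac = migration
        mig_rate = 1.0 - (1.0 - frac) ** (1.0 / dur)

    for t in range(start, 0, -1):
        for parent, child in split_at.get(t, []):
            pools[child] = pools[parent].copy()
        for name in list(pools):
            n_dip = config.pop_size
            if apply_bottleneck and name == bneck and t <= config.bottleneck_split_time:
                n_dip = config.bottleneck_size
            child = _wf_offspring(pools[name], n_dip, switch_p, config.mutation_rate, rng)
            if (migration is not None and name == dst and t <= dur and src in pools):
                mig_mask = rng.random(child.shape[0]) < mig_rate
                n_mig = int(mig_mask.sum())
                if n_mig:
                    mig = _wf_offspring(pools[src], n_mig, switch_p,
                                        config.mutation_rate, rng)
                    child[np.where(mig_mask)[0]] = mig[: n_mig * 2 : 2]
            pools[name] = child

    # a bottlenecked population's census can be smaller than the sample we
    # need; draw the present-day sample as one more offspring generation
    for name in list(pools):
        if pools[name].shape[0] < 2 * config.pop_size:
            pools[name] = _wf_offspring(pools[name], config.pop_size, switch_p,
                                        config.mutation_rate, rng)

    for old, new in rename.items():
        pools[new] = pools.pop(old)
    return pools, (phys, gen, chrom)


def _dataset_from_pools(pools: Mapping[str, np.ndarray], site_map, config: ScenarioConfig,
                        counts: Mapping[str, int]) -> SimulatedDataset:
    phys, gen, chrom = site_map
    blocks, ids, labels = [], [], []
    for name in config.population_names:
        k = counts.get(name, 0)
        if k == 0:
            continue
        blocks.append(pools[name][: 2 * k])
        ids += [f"{name}_{i}" for i in range(k)]
        labels += [name] * k
    haps = np.concatenate(blocks, axis=0) if blocks else np.empty((0, len(gen)), dtype=np.int8)
    return SimulatedDataset(haps, gen, phys, chrom, ids, labels, config=config)


def simulate_divergence(config: ScenarioConfig, seed: int | None = None) -> SimulatedDataset:
    """Simulate the unadmixed populations of a scenario.

    Returns every simulated individual (``pop_size`` per population; the
    ghost population, being unsampled, is excluded).  Use
    :func:`simulate_scenario` for the full pipeline including the admixture
    stage and analysis-subset sampling.
    """
    if seed is None:
        seed = config.seed
    pools, site_map = _simulate_populations(config, np.random.SeedSequence(seed))
    counts = {name: config.pop_size for name in config.population_names}
    return _dataset_from_pools(pools, site_map, config, counts)


# ---------------------------------------------------------------------------
# the admixed-chromosome mosaic generator
# ---------------------------------------------------------------------------

def _simulate_admixed_chromosome(pools, sources, props_cum, lam_rate, chrom_len,
                                 gpos, alleles_out, chrom_index, rng):
    """Tile one chromosome with exponential-length tracts; returns tracts."""
    tracts: list[Tract] = []
    raw: list[float] = []
    available = {s: list(range(pools[s].shape[0])) for s in sources}
    cur = 0.0
    while cur < chrom_len - 1e-12:
        x = rng.exponential(1.0 / lam_rate)
        raw.append(x)
        end = min(cur + x, chrom_len)
        s = sources[int(np.searchsorted(props_cum, rng.random(), side="right"))]
        if not available[s]:
            raise DonorPoolExhaustedError(
                f"donor pool for source {s!r} exhausted on chromosome {chrom_index} "
                f"at {cur:.3f} cM"
            )
        j = available[s].pop(rng.integers(len(available[s])))
        sel = (gpos >= cur) & (gpos < end)
        if alleles_out is not None and sel.any():
            alleles_out[sel] = pools[s][j, sel]
        tracts.append(Tract(chrom_index, cur, end, s, j))
        cur = end
    return tracts, raw


def simulate_admixed_haploid_genome(
    donor_pools: Mapping[str, np.ndarray],
    proportions: Sequence[float],
    lam: float,
    chromosome_length_cm: float,
    *,
    n_chromosomes: int = 1,
    genetic_pos: np.ndarray | None = None,
    chrom: np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, TractMap]:
    """Build one haploid genome as a mosaic of donor chromosomes.

    Each chromosome is tiled left to right: a genetic distance ``x`` is
    drawn from Exponential(rate = lam/100 per cM), the next ``x`` cM are
    copied from a donor chromosome whose source is drawn from
    ``proportions``, and the donor haplotype is chosen uniformly among
    those not yet used on this chromosome (sampling without replacement;
    running out raises :class:`DonorPoolExhaustedError`).  Every copied
    segment is recorded in the returned :class:`TractMap`.

    ``donor_pools`` maps source name to a ``(H, L)`` haplotype matrix;
    ``genetic_pos``/``chrom`` give per-site coordinates (may be omitted
    when only tract bookkeeping is wanted, with ``L = 0``).
    """
    sources = list(donor_pools)
    props = np.asarray(proportions, dtype=float)
    if props.size != len(sources):
        raise ValueError("proportions length must match donor_pools")
    if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    for s, pool in donor_pools.items():
        if pool.shape[0] == 0:
            raise ValueError(f"donor pool for source {s!r} is empty")
    if lam <= 0:
        raise ValueError("lam must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    L = next(iter(donor_pools.values())).shape[1]
    if L and (genetic_pos is None or chrom is None):
        raise ValueError("genetic_pos and chrom required when donor pools carry sites")
    genetic_pos = np.empty(0) if genetic_pos is None else np.asarray(genetic_pos, dtype=float)
    chrom = np.empty(0, dtype=int) if chrom is None else np.asarray(chrom, dtype=int)

    lam_rate = lam / 100.0
    props_cum = np.cumsum(props)
    props_cum[-1] = 1.0
    alleles = np.zeros(L, dtype=np.int8) if L else None
    tracts: list[Tract] = []
    raw_draws: list[float] = []
    for c in range(1, n_chromosomes + 1):
        sel = chrom == c if L else np.empty(0, dtype=bool)
        gpos_view = genetic_pos[sel] if L else np.empty(0)
        out_view = alleles[sel] if L else None
        pools_c = {s: donor_pools[s][:, sel] if L else donor_pools[s]
                   for s in sources}
        segs, raw = _simulate_admixed_chromosome(
            pools_c, sources, props_cum, lam_rate, chromosome_length_cm,
            gpos_view, out_view, c, rng,
        )
        if L:
            alleles[sel] = out_view
        tracts.extend(segs)
        raw_draws.extend(raw)
    tm = TractMap(tracts, n_chromosomes, chromosome_length_cm,
                  raw_draw_lengths=np.asarray(raw_draws))
    tm.validate()
    return (alleles if alleles is not None else np.empty(0, dtype=np.int8)), tm


def assemble_diploids(
    haploid_genomes: Sequence[tuple[np.ndarray, TractMap]],
    genetic_pos: np.ndarray,
    physical_pos: np.ndarray,
    chrom: np.ndarray,
    *,
    label: str = "P2",
    id_prefix: str | None = None,
    config: ScenarioConfig | None = None,
) -> SimulatedDataset:
    """Pair consecutive haploid genomes into phased diploid individuals."""
    n = len(haploid_genomes)
    if n % 2:
        raise ValueError(f"need an even number of haploid genomes, got {n}")
    prefix = id_prefix if id_prefix is not None else label
    ids = [f"{prefix}_{i}" for i in range(n // 2)]
    if n == 0:
        L = len(np.asarray(genetic_pos))
        return SimulatedDataset(np.empty((0, L), dtype=np.int8), genetic_pos,
                                physical_pos, chrom, [], [], config=config)
    haps = np.stack([h for h, _ in haploid_genomes])
    tracts = {ids[i]: (haploid_genomes[2 * i][1], haploid_genomes[2 * i + 1][1])
              for i in range(n // 2)}
    return SimulatedDataset(haps, genetic_pos, physical_pos, chrom, ids,
                            [label] * (n // 2), tracts=tracts, config=config)


def true_admixture_proportions(
    tracts: Mapping[str, tuple[TractMap, TractMap]],
    sources: Sequence[str],
):
    """Per-individual genome fraction (in cM) from each source population.

    Validates that every haploid genome's tracts tile all chromosomes;
    returns a :class:`palettefit.core.QMatrix` whose rows sum to 1.
    """
    from .core import QMatrix

    ids = list(tracts)
    rows = np.zeros((len(ids), len(sources)))
    for i, ind in enumerate(ids):
        for tm in tracts[ind]:
            tm.validate()
            rows[i] += tm.source_fractions(sources)
        rows[i] /= len(tracts[ind])
    return QMatrix(rows, individual_ids=ids, component_names=list(sources))


def estimate_tract_rate(tract_maps: Sequence[TractMap]) -> float:
    """Censored exponential MLE of the per-cM tract rate.

    Tracts abutting a chromosome end are right-censored draws, so the MLE
    is (#complete tracts) / (total tract length), which is unbiased for the
    generating rate lambda/100 regardless of chromosome length.
    """
    complete = 0
    total = 0.0
    for tm in tract_maps:
        end = tm.chromosome_length_cm
        for t in tm.tracts:
            total += t.length_cm
            if t.end_cm < end - 1e-12:
                complete += 1
    if total <= 0:
        raise ValueError("no tracts supplied")
    return complete / total


def pooled_tract_lengths(tract_maps: Sequence[TractMap],
                         include_censored: bool = False) -> np.ndarray:
    """All tract lengths pooled across haploid genomes."""
    arrs = [tm.lengths(include_censored=include_censored) for tm in tract_maps]
    return np.concatenate(arrs) if arrs else np.empty(0)


# ---------------------------------------------------------------------------
# full scenarios
# ---------------------------------------------------------------------------

def simulate_scenario(config: ScenarioConfig) -> SimulatedDataset:
    """Simulate one full scenario and return the analysis sample.

    For ``recent_admixture`` the P2 sample is replaced by
    ``n_admixed_individuals`` mosaic diploids built from the excess
    (unsampled) individuals of P1/P3/P4, exactly as the mixing algorithm
    specifies, and their :class:`TractMap` truth is attached to the dataset.
    """
    master = np.random.SeedSequence(config.seed)
    div_seq, mix_seq = master.spawn(2)
    pools, site_map = _simulate_populations(config, div_seq)
    phys, gen, chrom = site_map

    counts = dict(zip(("P1", "P2", "P3", "P4"), config.sample_sizes))
    for name in config.population_names[4:]:
        counts[name] = min(config.outgroup_sample_size, config.pop_size)

    if config.scenario_name != "recent_admixture":
        return _dataset_from_pools(pools, site_map, config, counts)

    # donor pools: haplotypes of excess individuals, beyond the sampled ones
    donor_pools = {}
    for s in config.admixture_sources:
        n_sampled = counts.get(s, 0)
        need = config.n_donor_individuals_per_source
        if config.pop_size - n_sampled < need:
            raise ConfigurationError(
                f"population {s} has only {config.pop_size - n_sampled} excess "
                f"individuals; {need} donors requested"
            )
        first = 2 * n_sampled
        donor_pools[s] = pools[s][first: first + 2 * need]

    rng = np.random.default_rng(mix_seq)
    genomes = []
    for _ in range(2 * config.n_admixed_individuals):
        genomes.append(simulate_admixed_haploid_genome(
            donor_pools, config.admixture_proportions, config.admixture_lambda,
            config.chromosome_length_cm,
            n_chromosomes=config.chromosomes_per_genome,
            genetic_pos=gen, chrom=chrom, seed=rng,
        ))
    admixed = assemble_diploids(genomes, gen, phys, chrom, label="P2", config=config)

    counts_unadm = dict(counts)
    counts_unadm["P2"] = 0
    unadm = _dataset_from_pools(pools, site_map, config, counts_unadm)

    # splice the admixed P2 block into position (after P1)
    n1 = counts["P1"]
    haps = np.concatenate([
        unadm.haplotypes[: 2 * n1],
        admixed.haplotypes,
        unadm.haplotypes[2 * n1:],
    ])
    ids = unadm.individual_ids[:n1] + admixed.individual_ids + unadm.individual_ids[n1:]
    labels = unadm.labels[:n1] + admixed.labels + unadm.labels[n1:]
    return SimulatedDataset(haps, gen, phys, chrom, ids, labels,
                            tracts=dict(admixed.tracts), config=config)


# ---------------------------------------------------------------------------
# auxiliary genotype generator (LD-pruning test data)
# ---------------------------------------------------------------------------

def simulate_correlated_genotypes(
    n_individuals: int,
    n_sites: int,
    *,
    block_size: int = 10,
    flip_prob: float = 0.05,
    span_bp: int = 5_000_000,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Diploid dosage matrix with block-correlated adjacent sites.

    Sites come in blocks sharing a latent genotype; within a block each
    site copies the latent dosage with a small per-allele flip probability,
    so adjacent sites are strongly correlated (r^2 near 1) while blocks are
    independent.  Returns ``(genotypes (N, L), positions_bp (L,))``.
    """
    rng = np.random.default_rng(seed)
    pos = _sample_unique_positions(n_sites, span_bp, rng)
    geno = np.empty((n_individuals, n_sites), dtype=np.int16)
    for b0 in range(0, n_sites, block_size):
        b1 = min(b0 + block_size, n_sites)
        p = rng.uniform(0.1, 0.9)
        latent = rng.binomial(1, p, size=(n_individuals, 2))
        for j in range(b0, b1):
            flips = rng.random((n_individuals, 2)) < flip_prob
            geno[:, j] = (latent ^ flips).sum(axis=1)
    return geno, pos.astype(np.int64)
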