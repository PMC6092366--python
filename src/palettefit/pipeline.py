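"""End-to-end workflows: simulate -> paint -> fit -> summarize.

``run_scenario_analysis`` is the canonical path used by the tests,
examples and CLI: it simulates a scenario, paints all individuals against
all others, estimates admixture proportions for the focal populations
with the supervised EM estimator (admixture inference itself is an input
to the method, not part of it), fits the ancestral palettes and
summarizes the residual structure.

``desk_scenario_config`` holds the reduced problem sizes used for
interactive analyses: 4 populations at diploid size 50, samples
12/10/14/10, two 60 cM chromosomes of 180 SNPs, 10 donors per source and
10 admixed diploids, with split times rescaled to preserve per-generation
drift at the smaller population size (see docs/methods.md).  The
full-scale mixing parameters (35 diploids, 20 chromosomes, lambda = 15,
proportions 50/35/15) are kept by :class:`~palettefit.simulate.ScenarioConfig`
defaults and used wherever tract statistics are the target.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .core import (FitResult, QMatrix, ResidualSummary, drift_correct,
                   fit_ancestral_palettes, residual_summary)
from .painting import PaintingParams, PaletteMatrix, paint_dataset
from .qtools import estimate_q_supervised, population_allele_frequencies
from .simulate import (ScenarioConfig, SimulatedDataset, simulate_scenario,
                       true_admixture_proportions)

__all__ = [
    "ScenarioAnalysis",
    "desk_scenario_config",
    "estimate_q_matrix",
    "run_scenario_analysis",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


def desk_scenario_config(scenario_name: str, seed: int, **overrides) -> ScenarioConfig:
    """Reduced-size scenario configuration for desk-scale analyses."""
    defaults = dict(
        n_populations=4,
        pop_size=50,
        sample_sizes=(12, 10, 14, 10),
        bottleneck_size=8,
        ghost_split_time_p1_p2=80,
        ghost_p3_split_time=40,
        deep_split_time=300,
        p3_p4_split_time=200,
        ghost_migration_duration=60,
        n_admixed_individuals=10,
        n_donor_individuals_per_source=10,
        chromosomes_per_genome=2,
        chromosome_length_cm=60.0,
        n_snps=180,
        mutation_rate=2e-3,
        burn_in=60,
    )
    defaults.update(overrides)
    return ScenarioConfig(scenario_name=scenario_name, seed=seed, **defaults)


def estimate_q_matrix(dataset: SimulatedDataset, *, sources=None,
                      individuals=None) -> QMatrix:
    """Supervised admixture proportions for selected individuals.

    Source allele frequencies are taken from the sampled individuals of
    the source populations (default: the dataset's configured admixture
    sources, P1/P3/P4), mimicking an admixture analysis in which the
    admixed group has no ancestral component of its own.
    """
    cfg = dataset.config
    if sources is None:
        sources = list(cfg.admixture_sources) if cfg else sorted(set(dataset.labels))
    ref = population_allele_frequencies(dataset.haplotypes, dataset.labels, sources)
    if individuals is None:
        individuals = list(range(dataset.n_individuals))
    geno = dataset.genotypes()
    rows = np.vstack([estimate_q_supervised(geno[i], ref) for i in individuals])
    ids = [dataset.individual_ids[i] for i in individuals]
    return QMatrix(rows, ids, list(sources))


def true_q_matrix(dataset: SimulatedDataset, sources=None) -> QMatrix:
    """True admixture proportions: tract fractions for admixed individuals,
    vertex rows for unadmixed focal individuals."""
    cfg = dataset.config
    if sources is None:
        sources = list(cfg.admixture_sources) if cfg else sorted(set(dataset.labels))
    focal = [i for i, l in enumerate(dataset.labels)
             if l in (cfg.focal_populations if cfg else set(dataset.labels))]
    rows, ids = [], []
    src_index = {s: j for j, s in enumerate(sources)}
    tract_q = true_admixture_proportions(dataset.tracts, sources) if dataset.tracts else None
    for i in focal:
        ind = dataset.individual_ids[i]
        lab = dataset.labels[i]
        if tract_q is not None and ind in tract_q.individual_ids:
            rows.append(tract_q.values[tract_q.individual_ids.index(ind)])
        elif lab in src_index:
            row = np.zeros(len(sources))
            row[src_index[lab]] = 1.0
            rows.append(row)
        else:
            raise ValueError(f"no truth available for unadmixed non-source individual {ind}")
        ids.append(ind)
    return QMatrix(np.vstack(rows), ids, list(sources))


@dataclass
class ScenarioAnalysis:
    """Everything one scenario run produces."""

    config: ScenarioConfig
    dataset: SimulatedDataset
    palette: PaletteMatrix         # all sampled individuals
    focal_palette: PaletteMatrix   # rows restricted to P1..P4
    qmatrix: QMatrix               # focal individuals
    focal_labels: list[str]
    fit: FitResult
    summary: ResidualSummary


def run_scenario_analysis(config: ScenarioConfig,
                          painting: PaintingParams | None = None,
                          q_mode: str = "supervised") -> ScenarioAnalysis:
    """Simulate, paint and fit one scenario.

    ``q_mode`` is "supervised" (EM estimates against the source
    populations' frequencies — the default, mimicking an admixture
    analysis) or "true" (tract-derived proportions; recent_admixture only
    for the admixed group).
    """
    dataset = simulate_scenario(config)
    palette = paint_dataset(dataset, painting)

    focal = [i for i, l in enumerate(dataset.labels) if l in config.focal_populations]
    focal_labels = [dataset.labels[i] for i in focal]
    if q_mode == "supervised":
        qmat = estimate_q_matrix(dataset, individuals=focal)
    elif q_mode == "true":
        qmat = true_q_matrix(dataset)
    else:
        raise ValueError(f"unknown q_mode {q_mode!r}")

    focal_palette = PaletteMatrix(
        palette.values[focal], [palette.recipient_ids[i] for i in focal],
        list(palette.donor_groups), payload=palette.payload,
    )
    fit = fit_ancestral_palettes(qmat, focal_palette)
    summary = residual_summary(fit, focal_labels)
    return ScenarioAnalysis(config, dataset, palette, focal_palette, qmat,
                            focal_labels, fit, summary)


def scenario_block_scores(seeds, *, config_factory=desk_scenario_config,
                          painting: PaintingParams | None = None) -> dict[str, list[float]]:
    """Block-structure residual scores for all three scenarios over seeds."""
    from .simulate import SCENARIOS

    out: dict[str, list[float]] = {s: [] for s in SCENARIOS}
    for s in SCENARIOS:
        for seed in seeds:
            ana = run_scenario_analysis(config_factory(s, seed), painting)
            out[s].append(ana.summary.block_score)
    return out


# ---------------------------------------------------------------------------
# CLI pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: ScenarioConfig, out_dir,
                 painting: PaintingParams | None = None,
                 *, constrained: bool = False,
                 apply_drift_correction: bool = True) -> Path:
    """Full artifact pipeline: simulate -> paint -> fit -> correct -> plot.

    Writes Q (estimated, plus truth when available), palettes, X,
    predicted values, residuals, summaries, plots, the simulated VCF with
    PLINK/tract sidecars, and a manifest sufficient to reproduce the run.
    """
    from . import io_formats, viz
    from .core import fit_ancestral_palettes_constrained

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []
    stage = "simulate"
    try:
        ana = run_scenario_analysis(config, painting)
        stage = "write"
        ds = ana.dataset
        io_formats.write_vcf(ds, out / "haplotypes.vcf")
        io_formats.write_fam(ds.individual_ids, ds.labels, out / "samples.fam")
        io_formats.write_bim(ds.chrom, ds.physical_pos, ds.genetic_pos, out / "sites.bim")
        if ds.tracts:
            io_formats.write_tracts(ds, out / "tracts.tsv")
            io_formats.write_q_file(true_q_matrix(ds), out / "q_true.Q")
        io_formats.write_q_file(ana.qmatrix, out / "q_estimated.Q")
        io_formats.write_palette_matrix(ana.palette, out / "palette.tsv")

        stage = "fit"
        fit = ana.fit
        if constrained:
            fit = fit_ancestral_palettes_constrained(ana.qmatrix, ana.focal_palette)
        if fit.negative_X_flag:
            warnings_log.append("negative entries in ancestral palettes X (poor fit)")
        ana.fit.X.to_dataframe().to_csv(out / "ancestral_palettes.tsv", sep="\t")
        np.savetxt(out / "predicted.tsv", fit.predicted, delimiter="\t", fmt="%.10g")
        fit.residual_dataframe().to_csv(out / "residuals.tsv", sep="\t")
        ana.summary.group_means.to_csv(out / "residual_group_means.tsv", sep="\t")

        if apply_drift_correction:
            stage = "drift_correct"
            dc = drift_correct(ana.focal_palette, ana.qmatrix, ana.focal_labels)
            io_formats.write_palette_matrix(dc.corrected, out / "palette_corrected.tsv")
            dc.excess.to_csv(out / "self_copy_excess.tsv", sep="\t", header=["excess"])

        stage = "plot"
        viz.plot_palette_bars(ana.focal_palette, ana.focal_labels,
                              out / "palette_bars.png")
        viz.plot_palette_bars(ana.qmatrix, ana.focal_labels, out / "admixture_bars.png")
        viz.plot_residual_matrix(fit.residual_dataframe(), ana.focal_labels,
                                 out / "residual_matrix.png")
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    manifest = {
        "palettefit_version": __version__,
        "scenario": config.scenario_name,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "painting": dataclasses.asdict(painting or PaintingParams()),
        "constrained": constrained,
        "shapes": {
            "haplotypes": list(ana.dataset.haplotypes.shape),
            "palette": list(ana.palette.values.shape),
            "Q": list(ana.qmatrix.shape),
            "X": list(ana.fit.X.values.shape),
        },
        "block_score": ana.summary.block_score,
        "sum_squared_residual": fit.sum_squared_residual,
        "warnings": warnings_log,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
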