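"""Shared fixtures: small datasets and cached scenario analyses."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from palettefit.pipeline import desk_scenario_config, run_scenario_analysis


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def scenario_analyses():
    """Supervised-Q analyses of all three scenarios over seeds 1..5."""
    out = {}
    for scenario in ("recent_admixture", "ghost_admixture", "recent_bottleneck"):
        for seed in range(1, 6):
            out[(scenario, seed)] = run_scenario_analysis(
                desk_scenario_config(scenario, seed)
            )
    return out


@pytest.fixture(scope="session")
def ra_true_analyses():
    """Recent-admixture analyses with the true tract-derived Q, seeds 1..3."""
    return {
        seed: run_scenario_analysis(desk_scenario_config("recent_admixture", seed),
                                    q_mode="true")
        for seed in (1, 2, 3)
    }


@pytest.fixture
def tiny_two_pop_dataset():
    """Two populations of internally identical haplotypes, 3+3 individuals."""
    from palettefit.simulate import SimulatedDataset

    L = 12
    hap_a = np.zeros(L, dtype=np.int8)
    hap_b = np.ones(L, dtype=np.int8)
    haps = np.vstack([hap_a] * 6 + [hap_b] * 6)
    pos = np.arange(1, L + 1) * 100_000
    return SimulatedDataset(
        haplotypes=haps,
        genetic_pos=pos * 1e-6,
        physical_pos=pos,
        chrom=np.ones(L, dtype=int),
        individual_ids=[f"A{i}" for i in range(3)] + [f"B{i}" for i in range(3)],
        labels=["A"] * 3 + ["B"] * 3,
    )
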