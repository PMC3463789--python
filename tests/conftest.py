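from __future__ import annotations

import numpy as np
import pytest

from ccstatus.funnelsim import SimConfig, simulate_funnel
from ccstatus.pedigree import Individual, Pedigree

SMALL_GENOME = {"1": 100.0, "2": 80.0, "X": 60.0}
AUTOSOME_GENOME = {"1": 100.0, "2": 80.0}


@pytest.fixture
def small_genome():
    return dict(SMALL_GENOME)


@pytest.fixture
def sim_line():
    """One seeded simulated line on the small genome (5 sib generations)."""
    cfg = SimConfig(
        n_sib_generations=5,
        chrom_lengths=SMALL_GENOME,
        marker_spacing_mb=0.2,
        recomb_rate_per_mb=0.002,
        genotyping_error=0.0,
        missing_rate=0.0,
        seed=11,
    )
    return simulate_funnel(cfg)


def make_chain_pedigree(n_chain_matings: int, line: str = "CHAIN") -> Pedigree:
    """2 founders, then ``n_chain_matings`` strict sib matings below them.

    The founder mating itself is excluded from obligate ancestors, so the
    qualifying chain is exactly the ``n_chain_matings`` sib matings.
    """
    inds = [
        Individual("P0", None, None, "male", 0, line),
        Individual("P1", None, None, "female", 0, line),
    ]
    sire, dam = "P0", "P1"
    for g in range(1, n_chain_matings + 2):
        m, f = f"G{g}a", f"G{g}b"
        inds.append(Individual(m, sire, dam, "male", g, line))
        inds.append(Individual(f, sire, dam, "female", g, line))
        sire, dam = m, f
    return Pedigree(inds, line_id=line)


@pytest.fixture
def chain_pedigree():
    return make_chain_pedigree(6)


def random_sim_pedigree(seed: int):
    """Random funnel pedigree (chain or 2-arm) with <= 60 animals."""
    rng = np.random.default_rng(seed)
    n_sib = int(rng.integers(0, 9))
    n_arms = int(rng.integers(1, 3)) if n_sib >= 2 else 1
    split = int(rng.integers(1, max(n_sib, 2))) if n_arms == 2 else 1
    cfg = SimConfig(
        n_sib_generations=n_sib,
        n_arms=n_arms,
        arm_split_generation=split,
        chrom_lengths={"1": 50.0},
        seed=seed,
        line_id=f"R{seed}",
    )
    from ccstatus.funnelsim import simulate_pedigree

    return simulate_pedigree(cfg)
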