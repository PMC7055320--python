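"""Shared fixtures: small synthetic scenarios built at test time."""

import numpy as np
import pandas as pd
import pytest

from paleomethyl.simulate import (
    PlantedDmr,
    SimulationConfig,
    generate_cpg_positions,
    generate_lineage_methylomes,
    generate_panel,
    simulate_deamination,
)
from paleomethyl.tracks import CpGCountTrack, MethylationTrack


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_config():
    """One chromosome, 6000 CpGs, four planted DMRs (one per lineage)."""
    return SimulationConfig(
        n_chromosomes=1,
        cpgs_per_chromosome=6000,
        planted_dmrs=[
            PlantedDmr("AMH", 60, 0.6, "hyper"),
            PlantedDmr("archaic", 60, 0.6, "hypo"),
            PlantedDmr("Neanderthal", 60, 0.6, "hyper"),
            PlantedDmr("Denisovan", 60, 0.6, "hypo"),
        ],
        seed=11,
    )


@pytest.fixture
def small_panel(small_config):
    return generate_panel(small_config)


@pytest.fixture
def flat_track():
    """A 2000-CpG count track with constant coverage 30 and rate 0.04."""
    rng = np.random.default_rng(5)
    n = 2000
    pos = np.arange(n) * 100
    cov = np.full(n, 30)
    t = rng.binomial(cov, 0.04)
    df = pd.DataFrame({"chrom": "chr1", "pos": pos, "c": cov - t, "t": t})
    return CpGCountTrack(df, meta={"sample_id": "flat", "pi": 0.05})


def make_methylation(values, spacing=100, chrom="chr1"):
    values = np.asarray(values, float)
    df = pd.DataFrame(
        {"chrom": chrom, "pos": np.arange(values.size) * spacing, "methylation": values}
    )
    return MethylationTrack(df)


@pytest.fixture
def make_meth_track():
    return make_methylation
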