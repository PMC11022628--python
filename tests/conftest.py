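import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

import methylprof as mp


@pytest.fixture(scope="session")
def small_synth():
    """One 200 kb chromosome with genes and TEs (deterministic)."""
    cfg = mp.ScenarioConfig(n_chrom=1, chrom_length=200_000)
    return mp.generate_genome(101, cfg), cfg


@pytest.fixture(scope="session")
def small_truth(small_synth):
    synth, cfg = small_synth
    return mp.plant_methylation(synth, cfg.model, seed=102)


@pytest.fixture(scope="session")
def small_freq(small_truth):
    return mp.simulate_site_frequencies(small_truth, 30.0, seed=103)


def make_freq(rows):
    """Build a SiteFrequency table from (chrom, pos, strand, context,
    subcontext, n_total, n_methylated) tuples."""
    df = pd.DataFrame(
        rows,
        columns=[
            "sequence_id", "pos", "strand", "context", "subcontext",
            "n_total", "n_methylated",
        ],
    )
    df["frequency"] = df["n_methylated"] / df["n_total"]
    return df


@pytest.fixture
def toy_freq_factory():
    return make_freq


@pytest.fixture
def rng():
    return np.random.default_rng(0)
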