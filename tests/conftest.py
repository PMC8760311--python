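import numpy as np
import pandas as pd
import pytest

from remiscreen import read_processing as rp
from remiscreen import synthetic_data as synth
from remiscreen import tag_reference as tagref


@pytest.fixture(scope="session")
def toy_genome():
    genome, info = synth.simulate_toy_genome(length=8000, seed=7)
    return genome, info


@pytest.fixture(scope="session")
def tag_table(toy_genome):
    genome, _ = toy_genome
    return tagref.build_tag_table(genome, genome_id="toy")


@pytest.fixture(scope="session")
def small_selection():
    """A fast 500-mutant, 2-prey selection with truth, used by several tests."""
    config = synth.SimulationConfig(
        seed=21,
        n_mutants=500,
        prey=("Ka", "Kp"),
        rounds={"Ka": 5, "Kp": 5},
        reads_per_sample=150_000,
        bottleneck_cells=100_000,
        sequence_every_round=False,
    )
    counts, truth = synth.simulate_selection(config)
    return config, rp.normalise(counts), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_estimates(means_by_bacterium, se=0.02, df=10.0):
    """Build an estimates frame from {bacterium: [means per strain]}."""
    rows = []
    for bacterium, means in means_by_bacterium.items():
        for i, m in enumerate(means):
            rows.append(
                {
                    "strain": f"S{i}",
                    "bacterium": bacterium,
                    "mean": float(m),
                    "se": se,
                    "df": df,
                }
            )
    return pd.DataFrame(rows)
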