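import numpy as np
import pandas as pd
import pytest

from myometh.io_formats import add_level
from myometh.synthetic_data import SimDesign, SimEffects, simulate_genome, simulate_methylomes


@pytest.fixture(scope="session")
def small_sim():
    """A small 4-group methylome simulation with planted regions (session-cached)."""
    design = SimDesign(n_per_group=4, chrom_lengths={"chr1": 500_000},
                       cpg_spacing_mean=100, coverage_mean=20.0, seed=11)
    effects = SimEffects(n_age_hyper=5, n_age_hypo=5)
    genome = simulate_genome(design, effects)
    tables = simulate_methylomes(genome, design, effects)
    return design, effects, genome, tables


def make_table(chrom, pos, meth, unmeth, sample_id="s"):
    table = add_level(pd.DataFrame({
        "chrom": chrom, "pos": pos,
        "meth_count": meth, "unmeth_count": unmeth,
    }))
    table.attrs["sample_id"] = sample_id
    return table


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
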