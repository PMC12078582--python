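import numpy as np
import pandas as pd
import pytest

from tblsuite.synthetic_data import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One moderately sized cohort shared by read-only tests."""
    cfg = SimulationConfig(
        seed=7, n_samples=60, n_genes=400, n_mutation_genes=80,
        driver_genes=("G0001",),
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def seg_frame(rows):
    """Build a SEG frame from (sample, chrom, start, end, probes, mean) tuples."""
    return pd.DataFrame(rows, columns=[
        "sample_id", "chromosome", "start", "end", "num_probes", "segment_mean"])
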