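import numpy as np
import pandas as pd
import pytest

import epidmr
from epidmr import SimulationConfig, simulate_dataset

# the library operation is named test_all_windows; keep pytest from
# collecting it when test modules import the symbol
epidmr.test_all_windows.__test__ = False
epidmr.diffmeth.test_all_windows.__test__ = False


def make_results(pvals, log2fcs=None, tested=None, chrom="chr1", wsize=1000):
    """Per-window results table on a 1 kb grid, for assembly tests."""
    n = len(pvals)
    if log2fcs is None:
        log2fcs = [1.0] * n
    if tested is None:
        tested = [True] * n
    starts = np.arange(n) * wsize
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + wsize,
            "p_value": pvals,
            "log2_fold_change": log2fcs,
            "tested": tested,
        }
    )


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_chromosomes=1,
        windows_per_chromosome=2000,
        n_dmrs=5,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One modest simulated dataset shared by fast tests."""
    return simulate_dataset(small_config)
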