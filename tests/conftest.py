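import numpy as np
import pandas as pd
import pytest

from acghcnv import Genome, SimParams, make_probe_grid, make_snp_map


@pytest.fixture(scope="session")
def small_genome():
    return Genome([("chr1", 2_000_000), ("chr2", 1_200_000)])


@pytest.fixture(scope="session")
def sim_params():
    return SimParams(seed=11)


@pytest.fixture(scope="session")
def annotated_probes(small_genome, sim_params):
    probes = make_probe_grid(small_genome, sim_params)
    return make_snp_map(probes, ["s1"], snp_rate=0.004, seed=12)


def bitarray_union_length(intervals, length):
    """Brute-force covered-base count on one chromosome."""
    cov = np.zeros(length, dtype=bool)
    for s, e in intervals:
        cov[s:e] = True
    return int(cov.sum())
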