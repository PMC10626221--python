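import numpy as np
import pytest

from hemaseq.binning import build_variable_bins
from hemaseq.genome import TruthProfile, make_genome


@pytest.fixture(scope="session")
def uniform_genome():
    """One 10 Mbp chromosome, constant GC 0.41, uniform mappability."""
    return make_genome(1, [10_000_000], gc_model={"kind": "constant", "value": 0.41},
                       mappability_model={"kind": "uniform"}, seed=7)


@pytest.fixture(scope="session")
def gradient_genome():
    """Five 20 Mbp chromosomes with a linear GC gradient per chromosome."""
    return make_genome(
        5, [20_000_000] * 5,
        gc_model={"kind": "linear-gradient", "start": 0.35, "stop": 0.55},
        seed=1,
    )


@pytest.fixture(scope="session")
def gradient_binmap(gradient_genome):
    return build_variable_bins(gradient_genome, 500)


@pytest.fixture(scope="session")
def desk_truth():
    """One whole-chromosome gain (CN 3) and one arm-level loss (CN 1)."""
    L = 20_000_000
    return TruthProfile(segments=(("chr2", 0, L, 3), ("chr4", L // 2, L, 1)))
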