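import numpy as np
import pandas as pd
import pytest

import cyanoscreen as cs

FLANK5 = "GTTTAAGAGCTATG"
FLANK3 = "GTTTTAGAGCTAGA"


@pytest.fixture(scope="session")
def small_genome():
    return cs.make_genome(seed=1, length_nt=20_000, n_genes=12, gc_fraction=0.48)


@pytest.fixture(scope="session")
def small_library(small_genome):
    return cs.design_library(small_genome)


@pytest.fixture(scope="session")
def library_frame(small_library):
    return small_library.to_frame()


@pytest.fixture(scope="session")
def neutral_competition(library_frame):
    """Neutral competition: every clone grows at the population rate."""
    ids = list(library_frame["guide_id"])
    truth = cs.make_truth(ids, np.full(len(ids), 0.07))
    cfg = cs.CompetitionSimConfig(
        mu_pop=0.07,
        timepoints_h=(0.0, 48.0, 96.0, 192.0),
        replicates=4,
        seed=11,
    )
    return cs.simulate_competition(ids, truth, cfg), truth
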