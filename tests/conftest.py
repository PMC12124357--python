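import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from strexpand import CohortDesign, LocusScenario, gen_cohort_matrix


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-human mini-cohort with planted conserved and expanded loci."""
    design = CohortDesign(n_human=30, seed=11)
    scenarios = [
        (LocusScenario("conserved"), 30),
        (LocusScenario("human_expanded", effect=6.0), 10),
        (LocusScenario("close_multimodal", effect=8.0), 10),
        (LocusScenario("distant_shifted", effect=6.0), 10),
    ]
    matrix, meta, truth = gen_cohort_matrix(design, scenarios)
    return matrix, meta, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
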