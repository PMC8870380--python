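import numpy as np
import pytest

import myelotrack as mt
from myelotrack.cohort import AlleleCount


@pytest.fixture(scope="session")
def table1():
    return mt.load_table1_fixture()


@pytest.fixture(scope="session")
def panel():
    return mt.load_panel_fixture()


@pytest.fixture(scope="session")
def sim_cohort():
    """Default-condition simulated cohort used by several suites."""
    return mt.simulate_cohort(mt.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def fitted(sim_cohort):
    return mt.VariantBacktracker.from_simulation(sim_cohort).fit()


KEY = ("1", 100, "A", "G")


def make_background(freq_depth_pairs, key=KEY, prefix="B"):
    """Allele counts + sample->patient map for a constructed background panel.

    Each pair is (alt_count, depth); every sample belongs to its own patient.
    """
    counts, sample_patients = [], {}
    for i, (alt, depth) in enumerate(freq_depth_pairs):
        sid = f"{prefix}{i}"
        counts.append(AlleleCount(sid, *key, depth - alt, alt))
        sample_patients[sid] = f"pat_{prefix}{i}"
    return counts, sample_patients


@pytest.fixture
def noise_free_null():
    counts, sp = make_background([(0, 500)] * 10)
    return mt.build_background_null(KEY, counts, "pat_tested", sp, n=10, seed=1)
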